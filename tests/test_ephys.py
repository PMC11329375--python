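"""Patch-clamp analysis: corrections, densities, curves, fits."""

import numpy as np
import pytest

from navloop import ephys, pipelines as pl
from navloop import synthetic as syn
from navloop.ephys import (
    BoltzmannFit,
    Recording,
    availability_at,
    boltzmann,
    fit_boltzmann,
    half_peak_noise_correct,
    p6_leak_subtract,
    peak_density,
    persistent_density,
    window_current,
)


def _flat_recording(value_pa, capacitance=20.0, total_ms=300.0, onset_ms=250.0):
    t = np.arange(int(total_ms * 10) + 1) / 10.0
    sweep = np.where(t >= onset_ms, value_pa, 0.0)
    return Recording(
        time_ms=t,
        sweeps=sweep[None, :],
        command_mv=np.array([0.0]),
        capacitance_pf=capacitance,
        depol_onset_ms=onset_ms,
    )


class TestP6:
    def test_pure_ohmic_cell_cancels(self, rng):
        # leak-only: main is 6x the (1/6-amplitude) subsweep response
        sub = np.linspace(0, 5, 100)
        main = 6 * sub
        out = p6_leak_subtract(main, np.tile(sub, (6, 1)))
        assert np.allclose(out, 0.0)

    def test_inverted_subpulse_scale(self):
        sub = np.linspace(0, -5, 100)
        main = -6 * sub
        out = p6_leak_subtract(main, np.tile(sub, (6, 1)), scale=-1 / 6)
        assert np.allclose(out, 0.0)

    def test_wrong_subsweep_count_or_length(self):
        with pytest.raises(ValueError):
            p6_leak_subtract(np.zeros(10), np.zeros((5, 10)))
        with pytest.raises(ValueError):
            p6_leak_subtract(np.zeros(10), np.zeros((6, 9)))

    def test_noise_variance_is_sevenfold(self, rng):
        """P/6 subtraction of noisy leak-only sweeps leaves zero mean and
        7x the single-sweep variance (variance algebra oracle)."""
        n = 200_00
        main = rng.normal(0, 1.0, n)
        subs = rng.normal(0, 1.0, (6, n))
        out = p6_leak_subtract(main, subs)
        assert abs(out.mean()) < 0.05
        assert out.var() == pytest.approx(7.0, rel=0.1)

    def test_leak_independence(self, channel72):
        """Corrected traces agree whether or not the cell had leak."""
        prot = syn.make_activation_protocol(10)
        leaky = syn.CellModel(leak_conductance_ns=2.0)
        tight = syn.CellModel(leak_conductance_ns=0.0)
        rec_l = pl.preprocess(
            syn.simulate_recording(channel72, leaky, prot, syn.NoiseModel(0.0, 0))
        )
        rec_t = pl.preprocess(
            syn.simulate_recording(channel72, tight, prot, syn.NoiseModel(0.0, 0))
        )
        assert np.allclose(rec_l.sweeps, rec_t.sweeps, atol=1e-8)


class TestHalfPeakNoiseCorrection:
    def test_noiseless_trace_unchanged(self):
        t = np.arange(0, 300, 0.1)
        sweep = np.where(t >= 250, -100.0, 0.0)
        out = half_peak_noise_correct(sweep, t, 250.0)
        assert np.allclose(out, sweep)

    def test_square_wave_baseline_subtracts_amplitude(self):
        t = np.arange(0, 300, 0.1)
        sweep = np.where(t >= 250, -100.0, 0.0)
        a = 3.0
        base = (t < 250) & (t >= 240)
        sweep = sweep + np.where(base, a * np.sign(np.sin(20 * t)), 0.0)
        out = half_peak_noise_correct(sweep, t, 250.0)
        # inward magnitude reduced by a: plateau moves from -100 to -100 + a
        assert out[t >= 260].mean() == pytest.approx(-100.0 + a, abs=1e-9)

    def test_window_outside_trace_rejected(self):
        t = np.arange(0, 5, 0.1)
        with pytest.raises(ValueError):
            half_peak_noise_correct(np.zeros_like(t), t, 2.0, window_ms=10.0)

    def test_gaussian_baseline_matches_range_oracle(self, rng):
        """Expected correction equals half the expected range of the
        baseline sample (Monte-Carlo oracle, 100-sample windows)."""
        n_base = 100
        t = np.arange(0, 20, 0.1)  # 10 ms baseline at 10 kHz -> 100 samples
        reps = 2000
        corrections = np.empty(reps)
        for i in range(reps):
            sweep = np.where(t >= 10, -50.0, 0.0) + rng.normal(0, 1.0, t.size)
            out = half_peak_noise_correct(sweep, t, 10.0)
            corrections[i] = out[0] - sweep[0]
        oracle = 0.5 * np.ptp(rng.normal(0, 1.0, (reps, n_base)), axis=1).mean()
        assert corrections.mean() == pytest.approx(oracle, rel=0.05)


class TestDensities:
    def test_plateau_persistent_density(self):
        rec = _flat_recording(-10.0, capacitance=20.0)
        assert persistent_density(rec)[0] == pytest.approx(-0.5)

    def test_all_zero_sweeps_give_zero_curve(self):
        rec = _flat_recording(0.0)
        iv = peak_density(rec, noise_correct=False)
        assert np.allclose(iv.density_pa_pf, 0.0)

    def test_short_trace_rejected(self):
        rec = _flat_recording(-10.0, total_ms=260.0)  # only 10 ms after onset
        with pytest.raises(ValueError):
            persistent_density(rec)

    def test_fully_inactivating_channel_leaves_no_persistent(self, cond72, cell):
        ch = syn.GroundTruthChannel(
            gmax_density_ns_pf=0.2,
            e_rev_mv=86.0,
            act=cond72.act,
            inact=syn.BoltzmannParams(-80.4, -8.4),
            persistent_fraction=0.0,
        )
        rec = syn.simulate_recording(
            ch,
            syn.CellModel(leak_conductance_ns=0.0),
            syn.make_activation_protocol(10),
            syn.NoiseModel(0.0, 0),
            include_p6=False,
        )
        i0 = int(np.argmin(np.abs(rec.command_mv - 0.0)))
        pers = persistent_density(rec)[i0]
        assert abs(pers) < 2e-3  # only the tiny steady window-current residue

    def test_peak_voltage_matches_forward_model_argmin(self, noiseless_act_rec, channel72):
        iv = peak_density(pl.preprocess(noiseless_act_rec), noise_correct=False)
        v = iv.voltage_mv
        # dense-grid oracle on the noiseless forward model at onset
        h0 = float(channel72.inact(-120.0))
        p = channel72.persistent_fraction
        drive = np.asarray(channel72.act(v)) * (v - channel72.e_rev_mv)
        oracle = drive * (p + (1 - p) * h0)
        assert v[np.argmin(iv.density_pa_pf)] == v[np.argmin(oracle)]

    def test_persistent_monotone_in_persistent_fraction(self, cond72, cell):
        prot = syn.make_activation_protocol(10)
        densities = []
        for p in (0.0, 0.01, 0.02, 0.05, 0.1):
            ch = syn.GroundTruthChannel(
                gmax_density_ns_pf=0.2,
                e_rev_mv=86.0,
                act=cond72.act,
                inact=cond72.inact,
                persistent_fraction=p,
            )
            rec = syn.simulate_recording(ch, cell, prot, syn.NoiseModel(0.0, 0))
            densities.append(abs(pl.persistent_cohort([rec], step_mv=0.0)[0]))
        assert np.all(np.diff(densities) > 0)


class TestCurves:
    def test_activation_curve_equals_open_probability(self, noiseless_act_rec, channel72):
        rec = pl.preprocess(noiseless_act_rec)
        iv = peak_density(rec, noise_correct=False)
        v, g = ephys.activation_curve(iv, channel72.e_rev_mv)
        assert g.max() == pytest.approx(1.0)
        m = np.asarray(channel72.act(v))
        # proportional to m_inf: normalising m_inf the same way matches exactly
        assert np.allclose(g[3:], (m / m.max())[3:], atol=5e-3)

    def test_activation_curve_rejects_e_rev_inside_range(self, noiseless_act_rec):
        iv = peak_density(pl.preprocess(noiseless_act_rec), noise_correct=False)
        with pytest.raises(ValueError):
            ephys.activation_curve(iv, 0.0)

    def test_inactivation_curve_reference_is_unity(self, noiseless_inact_rec):
        v, h = ephys.inactivation_curve(pl.preprocess(noiseless_inact_rec))
        assert h[int(np.argmin(v))] == pytest.approx(1.0)

    def test_inactivation_curve_matches_availability(self, cond72, cell):
        """Without a persistent component the normalised test-pulse peaks
        trace out h_inf (forward-model identity)."""
        ch = syn.GroundTruthChannel(
            gmax_density_ns_pf=0.2,
            e_rev_mv=86.0,
            act=cond72.act,
            inact=cond72.inact,
            persistent_fraction=0.0,
        )
        rec = syn.simulate_recording(
            ch, cell, syn.make_inactivation_protocol(10), syn.NoiseModel(0.0, 0)
        )
        v, h = ephys.inactivation_curve(pl.preprocess(rec))
        expected = np.asarray(cond72.inact(v)) / float(cond72.inact(-120.0))
        # residual 1e-3-scale deviation from the baseline/P6 affine terms
        assert np.allclose(h, expected, atol=2e-3)

    def test_inactivation_depolarised_prepulse_abolishes_current(self, cond72, cell):
        ch = syn.GroundTruthChannel(
            gmax_density_ns_pf=0.2,
            e_rev_mv=86.0,
            act=cond72.act,
            inact=cond72.inact,
            persistent_fraction=0.0,
        )
        rec = syn.simulate_recording(
            ch, cell, syn.make_inactivation_protocol(10), syn.NoiseModel(0.0, 0)
        )
        v, h = ephys.inactivation_curve(pl.preprocess(rec))
        assert abs(h[int(np.argmax(v))]) < 1e-3

    def test_missing_reference_prepulse_rejected(self, channel72, cell):
        prot = syn.ProtocolSpec(
            kind="inactivation",
            step_min_mv=-100.0,
            step_max_mv=30.0,
            step_increment_mv=10.0,
            prepulse_ms=250.0,
            test_mv=-10.0,
        )
        rec = syn.simulate_recording(channel72, cell, prot, syn.NoiseModel(0.0, 0))
        with pytest.raises(ValueError):
            ephys.inactivation_curve(pl.preprocess(rec))


class TestBoltzmannFit:
    @pytest.mark.parametrize(
        "v_half,k,kind",
        [(-15.2, 10.7, "activation"), (-80.4, -8.4, "inactivation")],
    )
    def test_noiseless_recovery_is_exact(self, v_half, k, kind):
        v = np.arange(-120.0, 31.0, 5.0)
        y = boltzmann(v, v_half, k)
        fit = fit_boltzmann(v, y, kind)
        assert fit.v_half_mv == pytest.approx(v_half, abs=0.01)
        assert fit.k_mv == pytest.approx(k, abs=0.01)
        assert fit.rss < 1e-8
        assert fit.converged

    def test_fitted_curve_midpoint(self):
        v = np.arange(-120.0, 31.0, 5.0)
        fit = fit_boltzmann(v, boltzmann(v, -40.0, 7.0), "activation")
        assert fit(fit.v_half_mv) == pytest.approx(0.5)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_boltzmann(np.array([0.0, 1, 2]), np.array([0.1, 0.5, 0.9]), "activation")

    def test_wrong_kind_rejected(self):
        v = np.arange(-120.0, 31.0, 5.0)
        with pytest.raises(ValueError):
            fit_boltzmann(v, boltzmann(v, -40.0, 7.0), "sigmoid")

    def test_free_amplitude_absorbs_scaling(self):
        v = np.arange(-120.0, 31.0, 5.0)
        y = 0.9 * boltzmann(v, -30.0, 9.0)
        fit = fit_boltzmann(v, y, "activation", free_amplitude=True)
        assert fit.v_half_mv == pytest.approx(-30.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(0.9, abs=1e-6)


class TestWindowAndAvailability:
    def test_acidic_shift_enlarges_window(self):
        c72, c62 = syn.PH_CONDITIONS[7.2], syn.PH_CONDITIONS[6.2]
        mk = lambda b, kind: BoltzmannFit(b.v_half_mv, b.k_mv, kind, 0.0, True)
        w72 = window_current(mk(c72.act, "activation"), mk(c72.inact, "inactivation"))
        w62 = window_current(mk(c62.act, "activation"), mk(c62.inact, "inactivation"))
        assert w62.peak_overlap > w72.peak_overlap

    def test_disjoint_step_functions_have_no_window(self):
        act = BoltzmannFit(0.0, 1.0, "activation", 0.0, True)
        inact = BoltzmannFit(-80.0, -1.0, "inactivation", 0.0, True)
        w = window_current(act, inact)
        assert w.peak_overlap < 1e-8

    def test_window_peak_bracketed_by_half_voltages(self):
        act = BoltzmannFit(-15.2, 10.7, "activation", 0.0, True)
        inact = BoltzmannFit(-80.4, -8.4, "inactivation", 0.0, True)
        w = window_current(act, inact)
        assert -80.4 <= w.peak_voltage_mv <= -15.2

    def test_wrong_fit_kinds_rejected(self):
        act = BoltzmannFit(-15.2, 10.7, "activation", 0.0, True)
        with pytest.raises(ValueError):
            window_current(act, act)

    def test_midpoint_availability(self):
        fit = BoltzmannFit(-18.9, -8.0, "inactivation", 0.0, True)
        res = availability_at([fit], vm_mv=-18.9)
        assert res.fraction == pytest.approx(0.5)

    def test_acidic_mean_parameters_availability(self):
        """h_inf(-18.9 mV) at the acidic-condition mean inactivation
        parameters, against direct formula evaluation."""
        fit = BoltzmannFit(-73.3, -11.9, "inactivation", 0.0, True)
        res = availability_at([fit], vm_mv=-18.9)
        assert res.fraction == pytest.approx(1.0 / (1.0 + np.exp(54.4 / 11.9)), rel=1e-6)
        assert res.fraction == pytest.approx(0.0102, abs=5e-4)

    def test_depolarising_shift_increases_availability(self):
        c72, c62 = syn.PH_CONDITIONS[7.2], syn.PH_CONDITIONS[6.2]
        f72 = BoltzmannFit(c72.inact.v_half_mv, c72.inact.k_mv, "inactivation", 0.0, True)
        f62 = BoltzmannFit(c62.inact.v_half_mv, c62.inact.k_mv, "inactivation", 0.0, True)
        a72 = availability_at([f72]).fraction
        a62 = availability_at([f62]).fraction
        assert a62 > a72

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            availability_at([])


class TestRecordingValidation:
    def test_nonpositive_capacitance_rejected(self):
        t = np.arange(10.0)
        with pytest.raises(ValueError):
            Recording(t, np.zeros((1, 10)), np.array([0.0]), 0.0, 5.0)

    def test_shape_mismatch_rejected(self):
        t = np.arange(10.0)
        with pytest.raises(ValueError):
            Recording(t, np.zeros((2, 10)), np.array([0.0]), 20.0, 5.0)

    def test_nonmonotone_time_rejected(self):
        t = np.array([0.0, 1.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            Recording(t, np.zeros((1, 4)), np.array([0.0]), 20.0, 1.0)
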