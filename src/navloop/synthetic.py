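"""Synthetic data generation for every pipeline input.

Everything downstream — patch-clamp analysis, the ECAR estimator, the
calibration pipelines — is testable without any external data because
this module generates its inputs from declared ground truth:

* Hodgkin-Huxley-style Na+ current families (instantaneous activation,
  exponentially relaxing inactivation, a non-inactivating persistent
  fraction) under the two standard voltage protocols, with linear leak,
  P/6 sub-records, and Gaussian current noise;
* extracellular-flux (Seahorse-style) plate time series with an
  injection step change and a decaying injection artefact;
* ratiometric plate fluorescence with background wells;
* pH-microelectrode voltage series with interleaved calibration blocks
  and a block-wise junction-potential drift.

Ground-truth channel parameters for the two pH conditions studied
(pH_e 7.2 and 6.2) are tabulated in :data:`PH_CONDITIONS`; maximal
conductance and persistent fraction are recovered from target peak and
persistent current densities by closed-form inversion of the noiseless
measurement equation, so generator truth is stated in the same units
the analysis reports (pA/pF).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationPoint, CalibrationSeries, FluorescencePlate, Measurement
from .ecar import SeahorsePlate
from .ephys import Recording, boltzmann

__all__ = [
    "GAS_CONSTANT",
    "FARADAY",
    "BoltzmannParams",
    "GroundTruthChannel",
    "CellModel",
    "ProtocolSpec",
    "NoiseModel",
    "ProtocolError",
    "PH_CONDITIONS",
    "CellVariability",
    "nernst_potential",
    "make_activation_protocol",
    "make_inactivation_protocol",
    "simulate_recording",
    "persistent_fraction_for_density",
    "channel_from_densities",
    "make_cohort",
    "simulate_seahorse",
    "simulate_plate_fluorescence",
    "simulate_electrode_series",
]

GAS_CONSTANT = 8.31446261815324  # J / (mol K)
FARADAY = 96485.33212  # C / mol

#: Default inactivation time constant (ms).  Activation is treated as
#: instantaneous; only inactivation carries kinetics, and 1.5 ms (typical
#: for Na_v_1.5 near 0 mV) puts the transient peak well before the
#: 20-25 ms persistent window.
DEFAULT_TAU_INACT_MS = 1.5

#: Default trace noise SD (pA); whole-cell recordings post-filtered at
#: 1 kHz sit near a 1 pA RMS noise floor.
DEFAULT_NOISE_SD_PA = 1.0


class ProtocolError(ValueError):
    """Raised for protocol specifications outside the supported design."""


def nernst_potential(
    out_mm: float = 149.0, in_mm: float = 5.0, temperature_c: float = 21.0
) -> float:
    """Nernst reversal potential (mV) for a monovalent cation.

    Defaults describe the recording solutions: ~149 mM extracellular Na+
    (144 mM NaCl plus NaOH titration) against 5 mM pipette Na+ at 21 C.
    """
    t_k = temperature_c + 273.15
    return 1e3 * GAS_CONSTANT * t_k / FARADAY * math.log(out_mm / in_mm)


@dataclass(frozen=True)
class BoltzmannParams:
    """Ground-truth Boltzmann parameters (v_half mV, signed slope k mV)."""

    v_half_mv: float
    k_mv: float

    def __call__(self, v: np.ndarray | float) -> np.ndarray | float:
        return boltzmann(v, self.v_half_mv, self.k_mv)


@dataclass(frozen=True)
class GroundTruthChannel:
    """Declared truth for one cell's Na+ channel population."""

    gmax_density_ns_pf: float
    e_rev_mv: float
    act: BoltzmannParams
    inact: BoltzmannParams
    tau_inact_ms: float = DEFAULT_TAU_INACT_MS
    persistent_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.gmax_density_ns_pf > 0:
            raise ValueError("gmax_density must be positive")
        if not 0.0 <= self.persistent_fraction <= 1.0:
            raise ValueError("persistent_fraction must lie in [0, 1]")
        if not self.act.k_mv > 0:
            raise ValueError("activation slope factor must be positive")
        if not self.inact.k_mv < 0:
            raise ValueError("inactivation slope factor must be negative")
        if not self.tau_inact_ms > 0:
            raise ValueError("tau_inact must be positive")


@dataclass(frozen=True)
class CellModel:
    """Passive cell properties."""

    capacitance_pf: float = 20.0
    leak_conductance_ns: float = 1.0
    leak_reversal_mv: float = 0.0

    def __post_init__(self) -> None:
        if not self.capacitance_pf > 0:
            raise ValueError("capacitance must be positive")
        if self.leak_conductance_ns < 0:
            raise ValueError("leak conductance must be non-negative")


@dataclass(frozen=True)
class ProtocolSpec:
    """Voltage-clamp protocol description."""

    kind: str  # "activation" | "inactivation"
    holding_mv: float = -120.0
    holding_ms: float = 250.0
    step_min_mv: float = -120.0
    step_max_mv: float = 30.0
    step_increment_mv: float = 10.0
    prepulse_ms: float | None = None
    test_mv: float | None = None
    test_ms: float = 50.0
    sample_khz: float = 50.0

    def __post_init__(self) -> None:
        if self.kind not in ("activation", "inactivation"):
            raise ProtocolError(f"unknown protocol kind {self.kind!r}")
        if not self.step_increment_mv > 0:
            raise ProtocolError("step increment must be positive")
        if self.step_min_mv > self.step_max_mv:
            raise ProtocolError("step_min_mv must not exceed step_max_mv")
        if not (self.holding_ms > 0 and self.test_ms > 0 and self.sample_khz > 0):
            raise ProtocolError("durations and sampling rate must be positive")
        if self.kind == "inactivation" and (
            self.prepulse_ms is None or self.test_mv is None
        ):
            raise ProtocolError("inactivation protocol needs prepulse_ms and test_mv")

    @property
    def step_levels_mv(self) -> np.ndarray:
        n = int(round((self.step_max_mv - self.step_min_mv) / self.step_increment_mv))
        return self.step_min_mv + self.step_increment_mv * np.arange(n + 1)

    @property
    def depol_onset_ms(self) -> float:
        """Onset of the analysed depolarisation (test pulse if present)."""
        if self.kind == "inactivation":
            assert self.prepulse_ms is not None
            return self.holding_ms + self.prepulse_ms
        return self.holding_ms


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian white current noise."""

    sd_pa: float = DEFAULT_NOISE_SD_PA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_pa < 0:
            raise ValueError("noise SD must be non-negative")


def make_activation_protocol(increment_mv: float = 10.0, **overrides) -> ProtocolSpec:
    """Activation protocol: hold -120 mV / 250 ms, then 50 ms steps to
    test potentials between -120 and +30 mV in 5 or 10 mV increments."""
    if increment_mv not in (5, 10):
        raise ProtocolError(f"step increment must be 5 or 10 mV, got {increment_mv}")
    return ProtocolSpec(kind="activation", step_increment_mv=float(increment_mv), **overrides)


def make_inactivation_protocol(increment_mv: float = 10.0, **overrides) -> ProtocolSpec:
    """Steady-state inactivation protocol: hold -120 mV / 250 ms, 250 ms
    prepulses between -120 and +30 mV, then a 50 ms test pulse to -10 mV."""
    if increment_mv not in (5, 10):
        raise ProtocolError(f"step increment must be 5 or 10 mV, got {increment_mv}")
    overrides.setdefault("prepulse_ms", 250.0)
    overrides.setdefault("test_mv", -10.0)
    return ProtocolSpec(kind="inactivation", step_increment_mv=float(increment_mv), **overrides)


# ---------------------------------------------------------------------------
# Forward model


def _segments(protocol: ProtocolSpec, step_mv: float) -> list[tuple[float, float]]:
    """(voltage, duration) segments of one sweep's command waveform."""
    if protocol.kind == "activation":
        return [
            (protocol.holding_mv, protocol.holding_ms),
            (step_mv, protocol.test_ms),
        ]
    assert protocol.prepulse_ms is not None and protocol.test_mv is not None
    return [
        (protocol.holding_mv, protocol.holding_ms),
        (step_mv, protocol.prepulse_ms),
        (protocol.test_mv, protocol.test_ms),
    ]


def _sweep_current(
    channel: GroundTruthChannel,
    cell: CellModel,
    segments: list[tuple[float, float]],
    time_ms: np.ndarray,
) -> np.ndarray:
    """Noiseless membrane current (channel + leak) for one command waveform.

    Activation is instantaneous (m = m_inf); the available fraction h
    relaxes exponentially with tau_inact towards its steady state at the
    current voltage, starting from equilibrium at the first segment.
    A ``persistent_fraction`` of the conductance never inactivates.
    """
    g_ns = channel.gmax_density_ns_pf * cell.capacitance_pf
    p = channel.persistent_fraction
    current = np.empty_like(time_ms)
    h = float(channel.inact(segments[0][0]))  # equilibrated at holding
    start = 0.0
    for seg_i, (v, dur) in enumerate(segments):
        end = start + dur
        if seg_i == len(segments) - 1:
            mask = (time_ms >= start - 1e-9) & (time_ms <= end + 1e-9)
        else:
            mask = (time_ms >= start - 1e-9) & (time_ms < end - 1e-9)
        t_rel = time_ms[mask] - start
        h_inf = float(channel.inact(v))
        h_t = h_inf + (h - h_inf) * np.exp(-t_rel / channel.tau_inact_ms)
        m = float(channel.act(v))
        i_chan = g_ns * m * (p + (1.0 - p) * h_t) * (v - channel.e_rev_mv)
        i_leak = cell.leak_conductance_ns * (v - cell.leak_reversal_mv)
        current[mask] = i_chan + i_leak
        h = h_inf + (h - h_inf) * math.exp(-dur / channel.tau_inact_ms)
        start = end
    return current


def simulate_recording(
    channel: GroundTruthChannel,
    cell: CellModel,
    protocol: ProtocolSpec,
    noise: NoiseModel | None = None,
    include_p6: bool = True,
    p6_scale: float = -1.0 / 6.0,
    meta: dict | None = None,
) -> Recording:
    """Simulate one cell's sweep family under a protocol.

    Per step V the current is
    ``g_max C_m m_inf(V) [p + (1-p) h(t)] (V - E_rev) + leak + noise``
    with the P/6 leak sub-records generated by the same forward model,
    so the downstream leak subtraction faces the same small
    imperfections a real P/6 protocol does.  The subpulse command
    excursion from holding is scaled by ``p6_scale``; the inverted
    (-1/6, hyperpolarising) default keeps the channels shut during
    sub-records, so the scaled subtraction does not fold amplified
    subthreshold channel current into small persistent signals.
    Reproducible given the noise seed.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    steps = protocol.step_levels_mv
    n_samples = int(round(
        sum(d for _, d in _segments(protocol, steps[0])) * protocol.sample_khz
    )) + 1
    time_ms = np.arange(n_samples) / protocol.sample_khz

    sweeps = np.empty((steps.size, n_samples))
    subsweeps = np.empty((steps.size, 6, n_samples)) if include_p6 else None
    for i, v in enumerate(steps):
        segs = _segments(protocol, v)
        clean = _sweep_current(channel, cell, segs, time_ms)
        sweeps[i] = clean + rng.normal(0.0, noise.sd_pa, n_samples)
        if include_p6:
            sub_segs = [
                (protocol.holding_mv + (sv - protocol.holding_mv) * p6_scale, dur)
                for sv, dur in segs
            ]
            sub_clean = _sweep_current(channel, cell, sub_segs, time_ms)
            assert subsweeps is not None
            subsweeps[i] = sub_clean + rng.normal(0.0, noise.sd_pa, (6, n_samples))

    info = {
        "protocol": protocol.kind,
        "seed": noise.seed,
        "e_rev_mv": channel.e_rev_mv,
        "holding_mv": protocol.holding_mv,
        "p6_scale": p6_scale,
    }
    if meta:
        info.update(meta)
    return Recording(
        time_ms=time_ms,
        sweeps=sweeps,
        command_mv=steps,
        capacitance_pf=cell.capacitance_pf,
        depol_onset_ms=protocol.depol_onset_ms,
        prepulse_onset_ms=(
            protocol.holding_ms if protocol.kind == "inactivation" else None
        ),
        test_mv=protocol.test_mv,
        subsweeps=subsweeps,
        meta=info,
    )


# ---------------------------------------------------------------------------
# Closed-form inversions: densities -> (gmax, persistent fraction)


def persistent_fraction_for_density(
    gmax_density_ns_pf: float,
    act: BoltzmannParams,
    inact: BoltzmannParams,
    e_rev_mv: float,
    target_density_pa_pf: float,
    step_mv: float = 0.0,
) -> float:
    """Persistent fraction giving a target steady current density.

    At t >> tau_inact the current density at a step V is
    ``gmax m_inf(V) [p + (1-p) h_inf(V)] (V - E_rev)`` (the steady
    window-current residue rides on top of the truly persistent
    component); solving for p is exact.
    """
    m = float(act(step_mv))
    h = float(inact(step_mv))
    drive = m * (step_mv - e_rev_mv)
    if drive == 0:
        raise ValueError("zero driving force at the persistent measurement step")
    total = target_density_pa_pf / (gmax_density_ns_pf * drive)
    p = (total - h) / (1.0 - h)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"inverted persistent fraction {p:.4g} outside [0, 1]")
    return p


def channel_from_densities(
    peak_density_pa_pf: float,
    persistent_density_pa_pf: float,
    act: BoltzmannParams,
    inact: BoltzmannParams,
    e_rev_mv: float | None = None,
    protocol: ProtocolSpec | None = None,
    tau_inact_ms: float = DEFAULT_TAU_INACT_MS,
    persistent_step_mv: float = 0.0,
    p6_scale: float = -1.0 / 6.0,
) -> GroundTruthChannel:
    """Build a channel whose noiseless *measured* densities match targets.

    Inverts the full measurement equation of the analysis pipeline, not
    just the bare channel current.  A baseline-referenced, P/6-corrected
    density at command voltage V reads

        M(V) = D(V) - 7 D(V_hold) + 6 D(V_sub),   V_sub = V_hold + (V - V_hold) * p6_scale

    where ``D(V) = gmax m_inf(V)(V - E_rev)(p + (1-p) h)`` with h at its
    local steady state (persistent window) or at the holding steady
    state h0 (peak, read at depolarisation onset).  Every D is linear in
    gmax and gmax*p, so target peak (most-negative M over the steps) and
    target persistent density fix both by a closed-form 2x2 solve; the
    peak's argmax step is refined by one fixed-point pass.
    """
    if e_rev_mv is None:
        e_rev_mv = nernst_potential()
    if protocol is None:
        protocol = make_activation_protocol(10)
    steps = protocol.step_levels_mv
    v_hold = protocol.holding_mv
    h0 = float(inact(v_hold))

    def coeffs_steady(v: float) -> tuple[float, float]:
        # D(v) = gmax * a + (gmax p) * b at local steady state
        drive = float(act(v)) * (v - e_rev_mv)
        h = float(inact(v))
        return drive * h, drive * (1.0 - h)

    def coeffs_onset(v: float) -> tuple[float, float]:
        # D(v) at depolarisation onset: h frozen at the holding steady state
        drive = float(act(v)) * (v - e_rev_mv)
        return drive * h0, drive * (1.0 - h0)

    def measured(v: float, onset: bool) -> tuple[float, float]:
        v_sub = v_hold + (v - v_hold) * p6_scale
        main = coeffs_onset(v) if onset else coeffs_steady(v)
        sub = coeffs_onset(v_sub) if onset else coeffs_steady(v_sub)
        hold = coeffs_steady(v_hold)
        return (
            main[0] - 7.0 * hold[0] + 6.0 * sub[0],
            main[1] - 7.0 * hold[1] + 6.0 * sub[1],
        )

    a_p, b_p = measured(persistent_step_mv, onset=False)

    def solve(v_peak: float) -> tuple[float, float]:
        a_pk, b_pk = measured(v_peak, onset=True)
        mat = np.array([[a_pk, b_pk], [a_p, b_p]])
        gmax, gp = np.linalg.solve(
            mat, [peak_density_pa_pf, persistent_density_pa_pf]
        )
        return float(gmax), float(gp)

    # initial argmax from the dominant (availability-weighted) drive term
    v_peak = steps[int(np.argmax([abs(measured(v, True)[0]) for v in steps]))]
    gmax, gp = solve(v_peak)
    peak_by_step = [
        measured(v, True)[0] * gmax + measured(v, True)[1] * gp for v in steps
    ]
    v_peak2 = steps[int(np.argmin(peak_by_step))]
    if v_peak2 != v_peak:
        gmax, gp = solve(v_peak2)
    if gmax <= 0:
        raise ValueError("peak target too small relative to the persistent target")
    p = gp / gmax
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"inverted persistent fraction {p:.4g} outside [0, 1]")
    return GroundTruthChannel(
        gmax_density_ns_pf=gmax,
        e_rev_mv=e_rev_mv,
        act=act,
        inact=inact,
        tau_inact_ms=tau_inact_ms,
        persistent_fraction=p,
    )


# ---------------------------------------------------------------------------
# Cohorts at the measured pH conditions


@dataclass(frozen=True)
class PhCondition:
    """Measured cohort-mean Na+ current parameters at one extracellular pH."""

    ph_e: float
    peak_density_pa_pf: float
    persistent_density_pa_pf: float
    act: BoltzmannParams
    inact: BoltzmannParams
    persistent_sd_pa_pf: float  # inter-cell biological spread used by cohorts


#: Cohort-mean gating and density parameters measured in MDA-MB-231
#: cells at extracellular pH 7.2 and 6.2.
PH_CONDITIONS: dict[float, PhCondition] = {
    7.2: PhCondition(
        ph_e=7.2,
        peak_density_pa_pf=-13.5,
        persistent_density_pa_pf=-0.31,
        act=BoltzmannParams(-15.2, 10.7),
        inact=BoltzmannParams(-80.4, -8.4),
        persistent_sd_pa_pf=0.05,
    ),
    6.2: PhCondition(
        ph_e=6.2,
        peak_density_pa_pf=-9.6,
        persistent_density_pa_pf=-0.71,
        act=BoltzmannParams(-12.9, 9.5),
        inact=BoltzmannParams(-73.3, -11.9),
        persistent_sd_pa_pf=0.08,
    ),
}


@dataclass(frozen=True)
class CellVariability:
    """Inter-cell biological spread used when drawing cohort members.

    Deliberately smaller than the spread of published cohort statistics,
    which folds in seal quality and measurement error on top of biology;
    trace noise is added separately per sweep.
    """

    v_half_sd_mv: float = 1.5
    k_sd_mv: float = 0.5
    peak_sd_pa_pf: float = 1.0
    capacitance_sd_pf: float = 2.0


def make_cohort(
    ph_e: float,
    kind: str,
    n_cells: int,
    seed: int,
    increment_mv: float = 5.0,
    variability: CellVariability | None = None,
    noise_sd_pa: float = DEFAULT_NOISE_SD_PA,
    e_rev_mv: float | None = None,
    tau_inact_ms: float = DEFAULT_TAU_INACT_MS,
) -> tuple[list[Recording], dict[str, np.ndarray]]:
    """Simulate a cohort of cells at one pH condition.

    Per-cell ground truth is drawn around the condition's cohort means
    with :class:`CellVariability` jitter; maximal conductance and
    persistent fraction are then fixed per cell by closed-form inversion
    of that cell's drawn densities.  Returns the recordings and the
    drawn per-cell truths (for parameter-recovery checks).
    """
    if ph_e not in PH_CONDITIONS:
        raise KeyError(f"no tabulated condition at pH {ph_e}")
    cond = PH_CONDITIONS[ph_e]
    var = variability or CellVariability()
    if e_rev_mv is None:
        e_rev_mv = nernst_potential()
    rng = np.random.default_rng(seed)

    if kind == "activation":
        protocol = make_activation_protocol(increment_mv)
    elif kind == "inactivation":
        protocol = make_inactivation_protocol(increment_mv)
    else:
        raise ProtocolError(f"unknown cohort kind {kind!r}")
    inversion_protocol = make_activation_protocol(increment_mv)

    recordings: list[Recording] = []
    truths: dict[str, list[float]] = {
        k: []
        for k in (
            "peak_density",
            "persistent_density",
            "act_v_half",
            "act_k",
            "inact_v_half",
            "inact_k",
            "capacitance",
        )
    }
    for i in range(n_cells):
        act = BoltzmannParams(
            rng.normal(cond.act.v_half_mv, var.v_half_sd_mv),
            max(1.0, rng.normal(cond.act.k_mv, var.k_sd_mv)),
        )
        inact = BoltzmannParams(
            rng.normal(cond.inact.v_half_mv, var.v_half_sd_mv),
            min(-1.0, rng.normal(cond.inact.k_mv, var.k_sd_mv)),
        )
        peak = min(-1.0, rng.normal(cond.peak_density_pa_pf, var.peak_sd_pa_pf))
        pers = min(
            -0.01, rng.normal(cond.persistent_density_pa_pf, cond.persistent_sd_pa_pf)
        )
        cap = max(8.0, rng.normal(20.0, var.capacitance_sd_pf))
        channel = channel_from_densities(
            peak, pers, act, inact, e_rev_mv, inversion_protocol, tau_inact_ms
        )
        cell = CellModel(capacitance_pf=cap)
        noise = NoiseModel(sd_pa=noise_sd_pa, seed=int(rng.integers(2**31)))
        rec = simulate_recording(
            channel, cell, protocol, noise, meta={"ph_e": ph_e, "cell": i}
        )
        recordings.append(rec)
        truths["peak_density"].append(peak)
        truths["persistent_density"].append(pers)
        truths["act_v_half"].append(act.v_half_mv)
        truths["act_k"].append(act.k_mv)
        truths["inact_v_half"].append(inact.v_half_mv)
        truths["inact_k"].append(inact.k_mv)
        truths["capacitance"].append(cap)
    return recordings, {k: np.asarray(v) for k, v in truths.items()}


# ---------------------------------------------------------------------------
# Extracellular-flux (Seahorse-style) plates


def simulate_seahorse(
    baseline_mpH_min: float,
    step_change_mpH_min: float,
    n_wells: int = 6,
    n_timepoints: int = 16,
    injection_index: int = 6,
    noise_sd: float = 1.5,
    seed: int = 0,
    cycle_min: float = 6.0,
    artefact_mpH_min: float = -5.0,
    artefact_span_min: float = 15.0,
) -> SeahorsePlate:
    """One plate of ECAR traces with an injection step change.

    Treated wells shift by ``step_change_mpH_min`` (negative for an
    inhibitor) at the injection timepoint and additionally carry a
    decaying injection artefact that returns to baseline within
    ``artefact_span_min`` (the analysis excludes this window); control
    wells hold the baseline.  Gaussian well noise throughout.
    """
    if noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    if not 0 <= injection_index < n_timepoints:
        raise ValueError("injection_index must fall inside the time series")
    if n_wells < 1:
        raise ValueError("need at least one well")
    rng = np.random.default_rng(seed)
    times = np.arange(n_timepoints) * cycle_min
    post = times >= times[injection_index]
    dt_post = times - times[injection_index]
    tau = artefact_span_min / 3.0  # decayed to ~5 % of its amplitude by the span
    artefact = np.where(
        post & (dt_post <= artefact_span_min),  # back at baseline after the span
        artefact_mpH_min * np.exp(-np.maximum(dt_post, 0) / tau),
        0.0,
    )

    treated_mean = baseline_mpH_min + np.where(post, step_change_mpH_min, 0.0) + artefact
    control_mean = np.full(n_timepoints, baseline_mpH_min)
    treated = treated_mean + rng.normal(0.0, noise_sd, (n_wells, n_timepoints))
    control = control_mean + rng.normal(0.0, noise_sd, (n_wells, n_timepoints))
    return SeahorsePlate(
        times_min=times,
        treated=treated,
        control=control,
        injection_index=injection_index,
        meta={"seed": seed, "baseline": baseline_mpH_min, "step": step_change_mpH_min},
    )


# ---------------------------------------------------------------------------
# Ratiometric plate fluorescence


def simulate_plate_fluorescence(
    true_ratio_fold: float,
    background_340: float,
    background_380: float,
    n_wells: int = 5,
    noise_sd: float = 20.0,
    seed: int = 0,
    base_f380: float = 1000.0,
    base_ratio: float = 1.5,
    n_background_wells: int = 3,
) -> tuple[FluorescencePlate, FluorescencePlate]:
    """(treated, vehicle) plates whose background-corrected 340/380 ratio
    differs by ``true_ratio_fold``.

    Well readings are signal plus the per-wavelength background plus
    Gaussian noise; background wells carry background and noise only.
    """
    if background_340 < 0 or background_380 < 0:
        raise ValueError("backgrounds must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    rng = np.random.default_rng(seed)

    def plate(fold: float) -> FluorescencePlate:
        f380 = base_f380 + background_380 + rng.normal(0, noise_sd, n_wells)
        f340 = (
            base_ratio * fold * base_f380
            + background_340
            + rng.normal(0, noise_sd, n_wells)
        )
        bg340 = background_340 + rng.normal(0, noise_sd, n_background_wells)
        bg380 = background_380 + rng.normal(0, noise_sd, n_background_wells)
        return FluorescencePlate(f340=f340, f380=f380, bg340=bg340, bg380=bg380)

    return plate(true_ratio_fold), plate(1.0)


# ---------------------------------------------------------------------------
# pH-microelectrode series


def simulate_electrode_series(
    true_ph_sequence: np.ndarray,
    slope_mv_per_ph: float = -58.0,
    intercept_mv: float = 376.0,
    offset_drift_mv_per_block: float = 2.0,
    seed: int = 0,
    noise_mv: float = 0.5,
    cal_phs: tuple[float, ...] = (6.0, 7.0, 8.0),
    labels: list[str] | None = None,
) -> CalibrationSeries:
    """Electrode voltage series with interleaved calibration blocks.

    Measurement voltages lie on ``V = intercept + slope * pH`` plus a
    junction-potential offset that drifts by a fixed amount per block
    (offsets re-measured every block, i.e. at most every 12
    measurements).  Calibration points in known-pH buffers are emitted
    before, half-way through, and at the end of the measurement series,
    each carrying its block's offset.
    """
    if slope_mv_per_ph == 0:
        raise ValueError("electrode slope must be non-zero")
    seq = np.asarray(true_ph_sequence, dtype=float)
    if labels is not None and len(labels) != seq.size:
        raise ValueError("labels must align with the pH sequence")
    rng = np.random.default_rng(seed)

    half = (seq.size + 1) // 2
    block_of = lambda i: 0 if i < half else 1  # noqa: E731
    offsets_true = {b: b * offset_drift_mv_per_block for b in (0, 1, 2)}
    offsets = {b: o + rng.normal(0.0, noise_mv) for b, o in offsets_true.items()}

    points = [
        CalibrationPoint(
            block=b,
            known_ph=ph,
            voltage_mv=intercept_mv
            + slope_mv_per_ph * ph
            + offsets_true[b]
            + rng.normal(0.0, noise_mv),
        )
        for b in (0, 1, 2)
        for ph in cal_phs
    ]
    measurements = [
        Measurement(
            block=block_of(i),
            voltage_mv=intercept_mv
            + slope_mv_per_ph * ph
            + offsets_true[block_of(i)]
            + rng.normal(0.0, noise_mv),
            label=None if labels is None else labels[i],
        )
        for i, ph in enumerate(seq)
    ]
    return CalibrationSeries(points=points, offsets=offsets, measurements=measurements)
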