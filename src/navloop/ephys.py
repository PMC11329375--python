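"""Whole-cell voltage-clamp analysis for Na_v_1.5 currents.

Implements the measurement chain used to characterise transient and
persistent Na+ currents in breast cancer cells: P/6 leak subtraction,
half peak-to-peak noise correction, peak and persistent current densities,
conductance/availability curves, Boltzmann fits of activation and
steady-state inactivation, the window current, and channel availability
at the resting membrane potential.

Conventions
-----------
Currents are in pA (inward negative), voltages in mV, time in ms,
capacitance in pF, densities in pA/pF.  Boltzmann curves use the single
signed-slope form ``y = 1 / (1 + exp((v_half - v) / k))`` so that
activation (k > 0) and inactivation (k < 0) share one fitter, matching
the sign convention of printed slope factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from lmfit import Model
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "Recording",
    "IVCurve",
    "BoltzmannFit",
    "WindowCurrent",
    "AvailabilityResult",
    "boltzmann",
    "baseline_reference",
    "p6_leak_subtract",
    "apply_p6",
    "half_peak_noise_correct",
    "lowpass_filter",
    "peak_density",
    "persistent_density",
    "activation_curve",
    "inactivation_curve",
    "fit_boltzmann",
    "window_current",
    "availability_at",
]


def boltzmann(v: np.ndarray | float, v_half: float, k: float) -> np.ndarray | float:
    """Two-state Boltzmann curve ``1 / (1 + exp((v_half - v) / k))``.

    With k > 0 this is an activation curve (rises with depolarisation);
    with k < 0 it is a steady-state inactivation curve (falls).
    """
    return 1.0 / (1.0 + np.exp((v_half - np.asarray(v, dtype=float)) / k))


# ---------------------------------------------------------------------------
# Containers


@dataclass
class Recording:
    """One cell's voltage-clamp sweep family.

    Attributes
    ----------
    time_ms:
        Sample times, strictly increasing, shared by all sweeps.
    sweeps:
        Current matrix (n_steps, n_samples) in pA.
    command_mv:
        Per-sweep command (step or prepulse) voltage in mV.
    capacitance_pf:
        Membrane capacitance used for density normalisation.
    depol_onset_ms:
        Time of the analysed depolarisation within each trace (for the
        inactivation protocol this is the test-pulse onset).
    prepulse_onset_ms:
        Prepulse onset (inactivation protocol only), else None.
    test_mv:
        Test-pulse potential (inactivation protocol only), else None.
    subsweeps:
        Optional P/6 leak sub-records, shape (n_steps, 6, n_samples).
    meta:
        Free-form metadata (pH_e, pH_i, cell id, protocol, seed...).
    """

    time_ms: np.ndarray
    sweeps: np.ndarray
    command_mv: np.ndarray
    capacitance_pf: float
    depol_onset_ms: float
    prepulse_onset_ms: float | None = None
    test_mv: float | None = None
    subsweeps: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        self.command_mv = np.asarray(self.command_mv, dtype=float)
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time_ms must be strictly increasing")
        if self.sweeps.shape != (self.command_mv.size, self.time_ms.size):
            raise ValueError(
                f"sweeps shape {self.sweeps.shape} inconsistent with "
                f"{self.command_mv.size} steps x {self.time_ms.size} samples"
            )
        if not self.capacitance_pf > 0:
            raise ValueError("capacitance_pf must be positive")

    @property
    def n_steps(self) -> int:
        return int(self.command_mv.size)

    def replace_sweeps(self, sweeps: np.ndarray) -> "Recording":
        return Recording(
            time_ms=self.time_ms,
            sweeps=sweeps,
            command_mv=self.command_mv,
            capacitance_pf=self.capacitance_pf,
            depol_onset_ms=self.depol_onset_ms,
            prepulse_onset_ms=self.prepulse_onset_ms,
            test_mv=self.test_mv,
            subsweeps=self.subsweeps,
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class IVCurve:
    """Current density-voltage relationship."""

    voltage_mv: np.ndarray
    density_pa_pf: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.voltage_mv, dtype=float)
        d = np.asarray(self.density_pa_pf, dtype=float)
        if v.size != d.size:
            raise ValueError("voltage and density vectors differ in length")
        if np.unique(v).size != v.size:
            raise ValueError("voltages must be unique")
        object.__setattr__(self, "voltage_mv", v)
        object.__setattr__(self, "density_pa_pf", d)


@dataclass(frozen=True)
class BoltzmannFit:
    """Fitted Boltzmann parameters with diagnostics."""

    v_half_mv: float
    k_mv: float
    kind: Literal["activation", "inactivation"]
    rss: float
    converged: bool
    amplitude: float = 1.0
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.kind == "activation" and not self.k_mv > 0:
            raise ValueError("activation fits require k > 0")
        if self.kind == "inactivation" and not self.k_mv < 0:
            raise ValueError("inactivation fits require k < 0")

    def __call__(self, v: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the *normalised* fitted curve (unit amplitude, no floor)."""
        return boltzmann(v, self.v_half_mv, self.k_mv)


@dataclass(frozen=True)
class WindowCurrent:
    """Overlap (product) of activation and inactivation curves."""

    voltage_mv: np.ndarray
    overlap: np.ndarray
    peak_voltage_mv: float
    peak_overlap: float


@dataclass(frozen=True)
class AvailabilityResult:
    """Mean channel availability h_inf(Vm) over a cohort of cells."""

    vm_mv: float
    fraction: float
    per_cell: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Trace corrections


def _window_slice(
    time_ms: np.ndarray, lo: float, hi: float, closed_end: bool = True
) -> np.ndarray:
    if closed_end:
        mask = (time_ms >= lo - 1e-9) & (time_ms <= hi + 1e-9)
    else:
        # half-open: baseline windows must exclude the sample at the
        # depolarisation onset itself
        mask = (time_ms >= lo - 1e-9) & (time_ms < hi - 1e-9)
    if not np.any(mask):
        raise ValueError(f"window [{lo}, {hi}] ms outside the trace")
    return mask


def baseline_reference(
    rec: Recording, window_ms: float = 10.0, onset_ms: float | None = None
) -> Recording:
    """Zero each sweep (and P/6 subsweep) on its pre-depolarisation baseline.

    Subtracts the mean current over the ``window_ms`` period immediately
    before ``onset_ms`` (default: the recording's analysed depolarisation
    onset, or the prepulse onset when one exists) from the whole trace.
    This removes the standing holding-level leak so that P/6 subtraction
    only has to cancel the step-dependent linear component.
    """
    if onset_ms is None:
        onset_ms = (
            rec.prepulse_onset_ms
            if rec.prepulse_onset_ms is not None
            else rec.depol_onset_ms
        )
    mask = _window_slice(rec.time_ms, onset_ms - window_ms, onset_ms, closed_end=False)
    sweeps = rec.sweeps - rec.sweeps[:, mask].mean(axis=1, keepdims=True)
    out = rec.replace_sweeps(sweeps)
    if rec.subsweeps is not None:
        out.subsweeps = rec.subsweeps - rec.subsweeps[:, :, mask].mean(
            axis=2, keepdims=True
        )
    return out


def p6_leak_subtract(
    main_sweep: np.ndarray, subsweeps: Sequence[np.ndarray], scale: float = 1.0 / 6.0
) -> np.ndarray:
    """P/6 leak subtraction: ``main - mean(subsweeps) / scale``.

    The six subsweeps are recorded with the command waveform scaled by
    ``scale`` (1/6); for an ideal ohmic leak the scaled average equals the
    linear component of the main sweep exactly.  Sweeps must be
    baseline-referenced so only step-dependent current remains.
    """
    subs = np.atleast_2d(np.asarray(subsweeps, dtype=float))
    main = np.asarray(main_sweep, dtype=float)
    if subs.shape[0] != 6:
        raise ValueError(f"P/6 requires exactly 6 subsweeps, got {subs.shape[0]}")
    if subs.shape[1] != main.size:
        raise ValueError("subsweep length does not match the main sweep")
    return main - subs.mean(axis=0) / scale


def apply_p6(rec: Recording) -> Recording:
    """Apply P/6 leak subtraction to every sweep of a recording.

    The subpulse scale is taken from the recording metadata
    (``p6_scale``); inverted (hyperpolarising, -1/6) subpulses are the
    default, which keeps voltage-gated channels shut during the
    sub-records.
    """
    if rec.subsweeps is None:
        raise ValueError("recording carries no P/6 subsweeps")
    scale = float(rec.meta.get("p6_scale", -1.0 / 6.0))
    corrected = np.stack(
        [
            p6_leak_subtract(rec.sweeps[i], rec.subsweeps[i], scale=scale)
            for i in range(rec.n_steps)
        ]
    )
    out = rec.replace_sweeps(corrected)
    out.subsweeps = None
    return out


def half_peak_noise_correct(
    sweep: np.ndarray,
    time_ms: np.ndarray,
    depol_onset_ms: float,
    window_ms: float = 10.0,
    polarity: int = -1,
) -> np.ndarray:
    """Shift a sweep by half the peak-to-peak baseline noise.

    The correction equals ``(max - min) / 2`` of the ``window_ms`` period
    before depolarisation and is applied so that it reduces the apparent
    magnitude of currents of the given polarity (inward, -1, by default).
    It compensates the extremum-selection bias incurred when a peak is
    read off a noisy trace, so genuinely small currents are not reported
    larger than the noise floor warrants.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    sweep = np.asarray(sweep, dtype=float)
    lo = depol_onset_ms - window_ms
    if lo < time_ms[0] - 1e-9 or depol_onset_ms > time_ms[-1] + 1e-9:
        raise ValueError("baseline window lies outside the trace")
    mask = _window_slice(time_ms, lo, depol_onset_ms, closed_end=False)
    base = sweep[mask]
    half_p2p = 0.5 * (base.max() - base.min())
    return sweep - polarity * half_p2p


def lowpass_filter(rec: Recording, cutoff_khz: float = 1.0, order: int = 4) -> Recording:
    """Optional zero-phase Butterworth low-pass (off by default in pipelines)."""
    dt_ms = float(np.median(np.diff(rec.time_ms)))
    fs_khz = 1.0 / dt_ms
    sos = butter(order, cutoff_khz / (fs_khz / 2.0), btype="low", output="sos")
    return rec.replace_sweeps(sosfiltfilt(sos, rec.sweeps, axis=1))


# ---------------------------------------------------------------------------
# Current measurements


def peak_density(
    rec: Recording,
    window_ms: tuple[float, float] | None = None,
    polarity: Literal["inward", "outward"] = "inward",
    noise_correct: bool = True,
    search_ms: float = 5.0,
) -> IVCurve:
    """Peak current density per voltage step.

    For inward currents, the most-negative current in the peak search
    window divided by capacitance; ``outward`` flips the convention for
    K+ current families.  The search window defaults to the first
    ``search_ms`` after depolarisation: the transient peaks within a
    couple of ms of the step, and restricting the extremum search keeps
    its noise-selection bias matched to the half peak-to-peak
    correction, which ``noise_correct`` applies to each sweep first.
    """
    if window_ms is None:
        window_ms = (rec.depol_onset_ms, rec.depol_onset_ms + search_ms)
    mask = _window_slice(rec.time_ms, *window_ms)
    sign = -1 if polarity == "inward" else +1
    peaks = np.empty(rec.n_steps)
    for i in range(rec.n_steps):
        sweep = rec.sweeps[i]
        if noise_correct:
            sweep = half_peak_noise_correct(
                sweep, rec.time_ms, rec.depol_onset_ms, polarity=sign
            )
        seg = sweep[mask]
        peaks[i] = seg.min() if sign < 0 else seg.max()
    return IVCurve(rec.command_mv.copy(), peaks / rec.capacitance_pf)


def persistent_density(
    rec: Recording, window_ms: tuple[float, float] = (20.0, 25.0)
) -> np.ndarray:
    """Mean current density in a late window after depolarisation, per sweep.

    The window (default 20-25 ms, closed at both ends on the sampling
    grid) isolates the non-inactivating persistent component: the
    transient current has decayed to a negligible residue by 20 ms.
    A window *mean* is unbiased under zero-mean noise, so no
    peak-to-peak correction is applied here.
    """
    lo, hi = window_ms
    if rec.time_ms[-1] + 1e-9 < rec.depol_onset_ms + hi:
        raise ValueError(
            f"trace ends {rec.time_ms[-1]:.1f} ms, persistent window needs "
            f">= {rec.depol_onset_ms + hi:.1f} ms"
        )
    mask = _window_slice(
        rec.time_ms, rec.depol_onset_ms + lo, rec.depol_onset_ms + hi
    )
    return rec.sweeps[:, mask].mean(axis=1) / rec.capacitance_pf


def activation_curve(iv: IVCurve, e_rev_mv: float) -> tuple[np.ndarray, np.ndarray]:
    """Normalised conductance-voltage curve from a peak I-V relationship.

    ``G(V) = I_peak(V) / (V - e_rev)`` normalised to its maximum.  The
    reversal potential must lie outside the range of step voltages.
    """
    v = iv.voltage_mv
    if np.any(np.isclose(v, e_rev_mv)):
        raise ValueError("a step voltage equals the reversal potential")
    if v.min() < e_rev_mv < v.max():
        raise ValueError("e_rev lies inside the voltage range of the peaks")
    g = iv.density_pa_pf / (v - e_rev_mv)
    gmax = g.max()
    if gmax <= 0:
        raise ValueError("non-positive maximal conductance")
    return v.copy(), g / gmax


def inactivation_curve(
    rec: Recording, amplitude: Literal["peak", "early_mean"] = "peak"
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised test-pulse current amplitude vs. prepulse voltage.

    Requires an inactivation-protocol recording (prepulse family plus a
    fixed test pulse).  Amplitudes are normalised to the most
    hyperpolarised (-120 mV) prepulse, the full-availability reference.

    ``amplitude="peak"`` reads the most-negative current in the test
    window (the conventional reading; exact on noiseless traces).
    ``amplitude="early_mean"`` averages the first 2 ms of the test
    pulse instead: a window mean is unbiased under noise and remains an
    exactly affine function of prepulse availability, which a
    free-amplitude/floor Boltzmann fit parameterises away — preferred
    for noisy cohorts.
    """
    if rec.prepulse_onset_ms is None or rec.test_mv is None:
        raise ValueError("recording was not made with the inactivation protocol")
    if amplitude == "early_mean":
        onset = rec.depol_onset_ms
        mask = _window_slice(rec.time_ms, onset, onset + 2.0)
        iv = IVCurve(
            rec.command_mv.copy(),
            rec.sweeps[:, mask].mean(axis=1) / rec.capacitance_pf,
        )
    else:
        iv = peak_density(rec)
    ref_idx = int(np.argmin(rec.command_mv))
    if not np.isclose(rec.command_mv[ref_idx], -120.0):
        raise ValueError("missing -120 mV reference prepulse")
    ref = iv.density_pa_pf[ref_idx]
    if ref == 0:
        raise ValueError("zero reference current at -120 mV prepulse")
    return rec.command_mv.copy(), iv.density_pa_pf / ref


# ---------------------------------------------------------------------------
# Curve fitting


def _boltzmann_model(v, v_half, k, amplitude, floor):
    return floor + amplitude / (1.0 + np.exp((v_half - v) / k))


def fit_boltzmann(
    voltage_mv: np.ndarray,
    response: np.ndarray,
    kind: Literal["activation", "inactivation"],
    free_amplitude: bool = False,
    free_floor: bool = False,
) -> BoltzmannFit:
    """Least-squares Boltzmann fit of a normalised (in)activation curve.

    Fits ``y = floor + amplitude / (1 + exp((v_half - v) / k))`` with the
    amplitude fixed to 1 and floor to 0 unless freed.  Freeing the
    amplitude (activation G-V curves normalised at a finite maximal
    voltage) or the floor (inactivation curves with a persistent
    pedestal) removes small normalisation biases; the reported curve is
    always the unit-amplitude Boltzmann of the fitted v_half and k.

    Initialisation: v_half from the linearly interpolated half-maximum
    crossing; |k| from a quarter of the 0.25-0.75 crossing span, bounded
    to [1, 50] mV with the sign fixed by ``kind``.  Non-convergence is
    reported through the ``converged`` flag, never silently.
    """
    v = np.asarray(voltage_mv, dtype=float)
    y = np.asarray(response, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 points spanning the transition")
    if kind not in ("activation", "inactivation"):
        raise ValueError(f"unknown kind {kind!r}")

    order = np.argsort(v)
    vs, ys = v[order], y[order]
    span = float(ys.max() - ys.min()) or 1.0

    def crossing(level: float) -> float:
        target = ys.min() + level * span
        idx = np.nonzero(np.diff(np.sign(ys - target)))[0]
        if idx.size == 0:
            return float(vs[np.argmin(np.abs(ys - target))])
        i = idx[0]
        f = (target - ys[i]) / (ys[i + 1] - ys[i])
        return float(vs[i] + f * (vs[i + 1] - vs[i]))

    v_half0 = crossing(0.5)
    k0 = max(1.0, min(50.0, abs(crossing(0.75) - crossing(0.25)) / 4.0))
    if kind == "inactivation":
        k0 = -k0

    model = Model(_boltzmann_model)
    params = model.make_params(
        v_half=v_half0, k=k0, amplitude=1.0, floor=0.0
    )
    if kind == "activation":
        params["k"].set(min=1.0, max=50.0)
    else:
        params["k"].set(min=-50.0, max=-1.0)
    params["amplitude"].set(vary=free_amplitude, min=0.1, max=10.0)
    params["floor"].set(vary=free_floor, min=-0.5, max=0.5)

    result = model.fit(ys, params, v=vs)
    rss = float(np.sum(result.residual**2))
    return BoltzmannFit(
        v_half_mv=float(result.params["v_half"].value),
        k_mv=float(result.params["k"].value),
        kind=kind,
        rss=rss,
        converged=bool(result.success),
        amplitude=float(result.params["amplitude"].value),
        floor=float(result.params["floor"].value),
    )


def window_current(
    act: BoltzmannFit,
    inact: BoltzmannFit,
    voltage_grid: np.ndarray | None = None,
) -> WindowCurrent:
    """Overlap of activation and steady-state inactivation curves.

    The pointwise product ``m_inf(V) * h_inf(V)`` quantifies the voltage
    range in which channels both activate and remain available, i.e. a
    steady inward Na+ flux.  Reports the grid maximum and its location,
    which is bracketed by the two half-voltages.
    """
    if act.kind != "activation" or inact.kind != "inactivation":
        raise ValueError("window_current needs one activation and one inactivation fit")
    if voltage_grid is None:
        voltage_grid = np.linspace(-120.0, 30.0, 1501)
    grid = np.asarray(voltage_grid, dtype=float)
    overlap = np.asarray(act(grid)) * np.asarray(inact(grid))
    i = int(np.argmax(overlap))
    return WindowCurrent(grid, overlap, float(grid[i]), float(overlap[i]))


def availability_at(
    inact_fits: Sequence[BoltzmannFit], vm_mv: float = -18.9
) -> AvailabilityResult:
    """Fraction of channels available at a membrane potential, per cell.

    Evaluates each cell's fitted steady-state inactivation curve at
    ``vm_mv`` and averages the per-cell fractions (per-cell averaging,
    as for cohort statistics of fitted parameters).
    """
    if len(inact_fits) == 0:
        raise ValueError("no inactivation fits supplied")
    for f in inact_fits:
        if f.kind != "inactivation":
            raise ValueError("availability requires inactivation fits")
    per_cell = np.array([float(f(vm_mv)) for f in inact_fits])
    return AvailabilityResult(vm_mv=vm_mv, fraction=float(per_cell.mean()), per_cell=per_cell)
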