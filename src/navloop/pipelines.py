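"""Cohort-level analysis pipelines composing the per-trace operations.

Each pipeline mirrors the analysis applied to a recorded cohort:
baseline referencing, P/6 leak subtraction, the relevant current
measurement, and (for gating) Boltzmann fitting.  The functions take
lists of :class:`~navloop.ephys.Recording` so they run identically on
synthetic and file-loaded data.
"""

from __future__ import annotations

import numpy as np

from .ephys import (
    BoltzmannFit,
    Recording,
    activation_curve,
    apply_p6,
    baseline_reference,
    fit_boltzmann,
    inactivation_curve,
    lowpass_filter,
    peak_density,
    persistent_density,
)

__all__ = [
    "preprocess",
    "persistent_cohort",
    "peak_cohort",
    "activation_fits",
    "inactivation_fits",
    "cohort_mean_sem",
]


def preprocess(rec: Recording) -> Recording:
    """Baseline-reference each sweep and apply P/6 leak subtraction."""
    rec = baseline_reference(rec)
    if rec.subsweeps is not None:
        rec = apply_p6(rec)
    return rec


def persistent_cohort(
    recordings: list[Recording],
    step_mv: float = 0.0,
    window_ms: tuple[float, float] = (20.0, 25.0),
) -> np.ndarray:
    """Per-cell persistent current density (pA/pF) at one step voltage.

    Leak-subtracted, baseline-referenced window mean 20-25 ms after
    depolarisation, taken from the sweep whose command voltage matches
    ``step_mv``.
    """
    out = []
    for rec in recordings:
        rec = preprocess(rec)
        idx = int(np.argmin(np.abs(rec.command_mv - step_mv)))
        if abs(rec.command_mv[idx] - step_mv) > 1e-6:
            raise ValueError(f"no sweep at {step_mv} mV in this recording")
        out.append(persistent_density(rec, window_ms)[idx])
    return np.asarray(out)


def peak_cohort(recordings: list[Recording]) -> np.ndarray:
    """Per-cell peak inward current density (most-negative over steps)."""
    out = []
    for rec in recordings:
        iv = peak_density(preprocess(rec))
        out.append(iv.density_pa_pf.min())
    return np.asarray(out)


def activation_fits(
    recordings: list[Recording],
    e_rev_mv: float | None = None,
    lowpass_khz: float | None = 1.0,
) -> list[BoltzmannFit]:
    """Per-cell activation Boltzmann fits from peak conductance curves.

    Traces are post-filtered at 1 kHz before the peaks are read, as is
    standard when small currents must be resolved against noise; the
    filter attenuates every step's sharp transient by the same factor,
    which the free-amplitude fit absorbs.  Conductance uses the
    configured reversal potential; the free amplitude also removes the
    bias from normalising at a finite maximal voltage.
    """
    fits = []
    for rec in recordings:
        rec = preprocess(rec)
        if lowpass_khz is not None:
            rec = lowpass_filter(rec, cutoff_khz=lowpass_khz)
        erev = e_rev_mv if e_rev_mv is not None else rec.meta.get("e_rev_mv")
        if erev is None:
            raise ValueError("reversal potential required (argument or recording meta)")
        v, g = activation_curve(peak_density(rec), float(erev))
        fits.append(fit_boltzmann(v, g, "activation", free_amplitude=True))
    return fits


def inactivation_fits(
    recordings: list[Recording], amplitude: str = "early_mean"
) -> list[BoltzmannFit]:
    """Per-cell steady-state inactivation fits from normalised test-pulse
    amplitudes.

    Amplitudes are read as early-window means (unbiased under noise and
    exactly affine in prepulse availability); the fit frees the
    amplitude and floor, so the persistent-current pedestal and the
    window-mean attenuation — both affine effects — drop out of v_half
    and k.
    """
    fits = []
    for rec in recordings:
        v, h = inactivation_curve(preprocess(rec), amplitude=amplitude)
        fits.append(
            fit_boltzmann(v, h, "inactivation", free_amplitude=True, free_floor=True)
        )
    return fits


def cohort_mean_sem(values: np.ndarray) -> tuple[float, float]:
    """Cohort mean and standard error of the mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need >= 2 cells for a cohort SEM")
    return float(values.mean()), float(values.std(ddof=1) / np.sqrt(values.size))
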