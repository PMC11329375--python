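"""Measurement calibrations: pH microelectrodes, BCECF, and SBFI.

Three procedures share this module because they are all linear
calibrations of a raw signal:

* **pH-selective microelectrodes** — voltages are offset-corrected with
  junction potentials measured every block of (at most) 12 tissue
  measurements, a straight line is fitted to the offset-corrected
  voltage/pH calibration points, and the line is inverted to turn tissue
  voltages into pH.
* **BCECF** intracellular pH — a per-cell two-point line through the
  nigericin-clamped ratios at pH 7.0 and 8.0.
* **SBFI** intracellular Na+ — background-subtracted 340/380 ratios,
  five-well plate means, and treated/vehicle fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationPoint",
    "Measurement",
    "CalibrationSeries",
    "LinearMap",
    "RatioMeasurement",
    "FluorescencePlate",
    "apply_offset_schedule",
    "fit_electrode",
    "electrode_ph",
    "bcecf_resting_ph",
    "sbfi_fold_change",
]

MAX_MEASUREMENTS_PER_BLOCK = 12


@dataclass(frozen=True)
class CalibrationPoint:
    block: int
    known_ph: float
    voltage_mv: float


@dataclass(frozen=True)
class Measurement:
    block: int
    voltage_mv: float
    label: str | None = None


@dataclass
class CalibrationSeries:
    """Interleaved electrode calibration points, offsets, and measurements.

    ``offsets`` maps each block index to its empirically measured
    junction-potential voltage (mV); every measurement and calibration
    point belongs to a block.  Blocks are limited to 12 measurements,
    matching the offset-measurement cadence.
    """

    points: list[CalibrationPoint] = field(default_factory=list)
    offsets: dict[int, float] = field(default_factory=dict)
    measurements: list[Measurement] = field(default_factory=list)

    def validate(self) -> None:
        if len({p.known_ph for p in self.points}) < 2:
            raise ValueError("need calibration points at >= 2 distinct pH values")
        counts: dict[int, int] = {}
        for m in self.measurements:
            if m.block not in self.offsets:
                raise ValueError(f"measurement in block {m.block} has no offset")
            counts[m.block] = counts.get(m.block, 0) + 1
        for p in self.points:
            if p.block not in self.offsets:
                raise ValueError(f"calibration point in block {p.block} has no offset")
        for block, n in counts.items():
            if n > MAX_MEASUREMENTS_PER_BLOCK:
                raise ValueError(
                    f"block {block} holds {n} measurements "
                    f"(max {MAX_MEASUREMENTS_PER_BLOCK} between offset measurements)"
                )


@dataclass(frozen=True)
class LinearMap:
    """Straight-line electrode response, voltage = intercept + slope * pH."""

    slope_mv_per_ph: float
    intercept_mv: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope_mv_per_ph == 0:
            raise ValueError("degenerate electrode line (zero slope)")

    def voltage(self, ph: np.ndarray | float) -> np.ndarray | float:
        return self.intercept_mv + self.slope_mv_per_ph * np.asarray(ph, dtype=float)

    def ph(self, voltage_mv: np.ndarray | float) -> np.ndarray | float:
        """Analytic inverse: pH corresponding to a corrected voltage."""
        return (np.asarray(voltage_mv, dtype=float) - self.intercept_mv) / self.slope_mv_per_ph


@dataclass(frozen=True)
class RatioMeasurement:
    """Background-corrected two-wavelength fluorescence ratio."""

    f_num: float
    f_den: float
    background_num: float
    background_den: float

    @property
    def ratio(self) -> float:
        return self.f_num / self.f_den


@dataclass
class FluorescencePlate:
    """One plate of ratiometric wells plus matched background wells.

    ``f340``/``f380`` are the raw (background-containing) well readings;
    ``bg340``/``bg380`` are readings from wells with no cells.
    """

    f340: np.ndarray
    f380: np.ndarray
    bg340: np.ndarray
    bg380: np.ndarray

    def corrected_ratios(self) -> np.ndarray:
        if np.size(self.bg340) == 0 or np.size(self.bg380) == 0:
            raise ValueError("missing background wells")
        b340 = float(np.mean(self.bg340))
        b380 = float(np.mean(self.bg380))
        return (np.asarray(self.f340, float) - b340) / (
            np.asarray(self.f380, float) - b380
        )


# ---------------------------------------------------------------------------
# pH microelectrodes


def apply_offset_schedule(series: CalibrationSeries) -> CalibrationSeries:
    """Subtract each block's junction-potential offset from its voltages.

    Offsets are held piecewise-constant within a block (no interpolation
    across blocks): each offset is an empirical reading taken with the
    electrode pair freshly placed, and applies to the measurements and
    calibration points recorded until the next offset measurement.
    """
    series.validate()
    points = [
        replace(p, voltage_mv=p.voltage_mv - series.offsets[p.block])
        for p in series.points
    ]
    measurements = [
        replace(m, voltage_mv=m.voltage_mv - series.offsets[m.block])
        for m in series.measurements
    ]
    return CalibrationSeries(
        points=points,
        offsets={b: 0.0 for b in series.offsets},
        measurements=measurements,
    )


def fit_electrode(
    series: CalibrationSeries, regressand: str = "voltage"
) -> LinearMap:
    """Ordinary least squares line through offset-corrected calibration points.

    By default voltage is regressed on pH and the line inverted
    analytically when converting measurements; ``regressand="ph"``
    fits the reverse regression instead (identical for two points,
    slightly different with >= 3 noisy points).
    """
    ph = np.array([p.known_ph for p in series.points], dtype=float)
    mv = np.array([p.voltage_mv for p in series.points], dtype=float)
    if np.unique(ph).size < 2:
        raise ValueError("rank-deficient calibration: need >= 2 distinct pH values")
    if regressand == "voltage":
        fit = stats.linregress(ph, mv)
        slope, intercept = fit.slope, fit.intercept
    elif regressand == "ph":
        fit = stats.linregress(mv, ph)
        slope, intercept = 1.0 / fit.slope, -fit.intercept / fit.slope
    else:
        raise ValueError(f"unknown regressand {regressand!r}")
    return LinearMap(float(slope), float(intercept), float(fit.rvalue**2))


def electrode_ph(
    series: CalibrationSeries, regressand: str = "voltage"
) -> tuple[np.ndarray, list[str | None], LinearMap]:
    """Full electrode pipeline: offset-correct, fit, invert.

    Returns the recovered pH of every measurement (in series order),
    the measurement labels, and the fitted line.
    """
    corrected = apply_offset_schedule(series)
    line = fit_electrode(corrected, regressand=regressand)
    volts = np.array([m.voltage_mv for m in corrected.measurements], dtype=float)
    labels = [m.label for m in corrected.measurements]
    return np.asarray(line.ph(volts)), labels, line


# ---------------------------------------------------------------------------
# BCECF intracellular pH


def bcecf_resting_ph(
    ratios_at_ph7: np.ndarray,
    ratios_at_ph8: np.ndarray,
    resting_ratios: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Per-cell two-point BCECF calibration and cohort mean.

    For each cell a straight line is drawn through its nigericin-clamped
    ratios at pH 7.0 and 8.0 and inverted at the resting ratio.  Cells
    whose two calibration ratios coincide define no line and are
    rejected.  Returns (per-cell pH, cohort mean).
    """
    r7 = np.asarray(ratios_at_ph7, dtype=float)
    r8 = np.asarray(ratios_at_ph8, dtype=float)
    rr = np.asarray(resting_ratios, dtype=float)
    if not (r7.shape == r8.shape == rr.shape):
        raise ValueError("all three ratio arrays must have one entry per cell")
    if np.any(r8 == r7):
        raise ValueError("degenerate per-cell calibration: equal ratios at pH 7 and 8")
    ph = 7.0 + (rr - r7) / (r8 - r7) * (8.0 - 7.0)
    return ph, float(ph.mean())


# ---------------------------------------------------------------------------
# SBFI fold change


def sbfi_fold_change(
    treated_plates: list[FluorescencePlate],
    vehicle_plates: list[FluorescencePlate],
) -> tuple[np.ndarray, float, float]:
    """Treated/vehicle SBFI ratio fold change over experimental repeats.

    Per plate: subtract the mean background from each wavelength, form
    the 340/380 ratio per well, and average the wells (one plate = one
    experimental repeat).  The fold change for a repeat is the treated
    plate mean divided by the matched vehicle plate mean.  Returns
    (per-repeat folds, mean fold, SEM over repeats).
    """
    if len(treated_plates) != len(vehicle_plates) or len(treated_plates) == 0:
        raise ValueError("need matched, non-empty treated and vehicle plate lists")
    folds = np.array(
        [
            t.corrected_ratios().mean() / v.corrected_ratios().mean()
            for t, v in zip(treated_plates, vehicle_plates)
        ]
    )
    sem = float(folds.std(ddof=1) / np.sqrt(folds.size)) if folds.size > 1 else float("nan")
    return folds, float(folds.mean()), sem
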