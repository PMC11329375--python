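"""Stoichiometric prediction and measurement of Na_v_1.5-dependent ECAR.

The model chains the persistent Na+ influx through Na_v_1.5 to the
extracellular acidification rate (ECAR) it should cause, assuming the
influx is exactly counteracted by the Na+/K+ ATPase (NKA) at steady
state:

    persistent current (pA/pF) x capacitance (pF)  ->  Na+ flux (mol/s/cell)
    / 3 Na+ per ATP (NKA stoichiometry)            ->  ATP demand (mol/s/cell)
    x 1 H+ per glycolytic ATP                      ->  H+ efflux (mol/s/cell)
    x cells per well / assay volume                ->  mol H+ / L / s
    / buffering power (mol/L/pH), x 60             ->  mpH/min

Glycolytic fermentation yields 2 ATP and 2 lactate per glucose; coupled
to ATP hydrolysis this nets 2 H+ per glucose, i.e. one H+ per ATP.  The
buffering power is a single lumped linear coefficient, appropriate for
the bicarbonate-free assay medium in which ECAR is reported in mpH/min.

The module also implements the plate-reader effect estimator used to
produce the measured comparator: per-well means of the last six
timepoints, contrasted between control and treated wells, with the
post-injection artefact window excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FARADAY_C_PER_MOL",
    "StoichiometryParams",
    "WellGeometry",
    "EcarPrediction",
    "SeahorsePlate",
    "na_flux_per_cell",
    "predict_ecar",
    "measure_ecar_effect",
    "order_of_magnitude_check",
]

FARADAY_C_PER_MOL = 96485.33212

#: Lumped buffering power (mol H+ per litre per pH unit) of the
#: bicarbonate-free assay medium, consistent with the published
#: prediction chain at 20 pF and -0.31 pA/pF.
DEFAULT_BUFFERING_POWER = 1.65e-4

#: Capacitance (pF) used when reproducing the headline ECAR prediction.
DEFAULT_CAPACITANCE_PF = 20.0


@dataclass(frozen=True)
class StoichiometryParams:
    """Ion/metabolite stoichiometry of the NKA-glycolysis chain."""

    na_per_atp: float = 3.0
    h_per_atp: float = 1.0
    atp_per_glucose: float = 2.0
    lactate_per_glucose: float = 2.0

    def __post_init__(self) -> None:
        for name in ("na_per_atp", "h_per_atp", "atp_per_glucose", "lactate_per_glucose"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        # One H+ per ATP follows from lactate/ATP accounting; warn loudly if
        # a caller supplies an inconsistent trio.
        implied = self.lactate_per_glucose / self.atp_per_glucose
        if not math.isclose(self.h_per_atp, implied, rel_tol=1e-9):
            raise ValueError(
                f"h_per_atp={self.h_per_atp} inconsistent with "
                f"lactate_per_glucose/atp_per_glucose={implied}"
            )


@dataclass(frozen=True)
class WellGeometry:
    """Assay-well geometry and medium buffering."""

    cells_per_well: float = 3.0e4
    volume_l: float = 180e-6
    buffering_power_mol_per_l_ph: float = DEFAULT_BUFFERING_POWER

    def __post_init__(self) -> None:
        for name in ("cells_per_well", "volume_l", "buffering_power_mol_per_l_ph"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class EcarPrediction:
    """Intermediate fluxes and predicted ECAR of the stoichiometric chain."""

    na_flux_mol_s_cell: float
    atp_flux_mol_s_cell: float
    h_flux_mol_s_cell: float
    ecar_mpH_min: float

    def __post_init__(self) -> None:
        for name in (
            "na_flux_mol_s_cell",
            "atp_flux_mol_s_cell",
            "h_flux_mol_s_cell",
            "ecar_mpH_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def na_flux_per_cell(
    persistent_density_pa_pf: float, capacitance_pf: float
) -> float:
    """Na+ influx per cell (mol/s) carried by the persistent current.

    ``|density| * capacitance`` gives the persistent current in pA;
    conversion to mol/s divides by the Faraday constant.  The sign of
    the (inward, negative) density is dropped: the chain tracks flux
    magnitudes.
    """
    if not (math.isfinite(persistent_density_pa_pf) and math.isfinite(capacitance_pf)):
        raise ValueError("non-finite input")
    if not capacitance_pf > 0:
        raise ValueError("capacitance must be positive")
    current_a = abs(persistent_density_pa_pf) * capacitance_pf * 1e-12
    return current_a / FARADAY_C_PER_MOL


def predict_ecar(
    persistent_density_pa_pf: float,
    capacitance_pf: float = DEFAULT_CAPACITANCE_PF,
    stoich: StoichiometryParams | None = None,
    well: WellGeometry | None = None,
) -> EcarPrediction:
    """Predicted ECAR (mpH/min) from a persistent current density.

    Chains Na+ flux -> ATP demand -> H+ efflux -> per-well acid load ->
    pH change rate, reporting every intermediate.
    """
    stoich = stoich or StoichiometryParams()
    well = well or WellGeometry()
    na_flux = na_flux_per_cell(persistent_density_pa_pf, capacitance_pf)
    atp_flux = na_flux / stoich.na_per_atp
    h_flux = atp_flux * stoich.h_per_atp
    mol_per_l_per_s = h_flux * well.cells_per_well / well.volume_l
    ph_per_min = mol_per_l_per_s * 60.0 / well.buffering_power_mol_per_l_ph
    return EcarPrediction(
        na_flux_mol_s_cell=na_flux,
        atp_flux_mol_s_cell=atp_flux,
        h_flux_mol_s_cell=h_flux,
        ecar_mpH_min=ph_per_min * 1e3,
    )


@dataclass
class SeahorsePlate:
    """One plate of extracellular-flux time series (wells x timepoints)."""

    times_min: np.ndarray
    treated: np.ndarray
    control: np.ndarray
    injection_index: int
    ocr_treated: np.ndarray | None = None
    ocr_control: np.ndarray | None = None
    meta: dict | None = None

    @property
    def injection_time_min(self) -> float:
        return float(self.times_min[self.injection_index])


def _last_n_well_means(
    plate: SeahorsePlate, wells: np.ndarray, n_last: int, exclusion_min: float
) -> np.ndarray:
    times = np.asarray(plate.times_min, dtype=float)
    usable = times >= plate.injection_time_min + exclusion_min
    if usable.sum() < n_last:
        raise ValueError(
            f"only {int(usable.sum())} post-injection timepoints outside the "
            f"{exclusion_min} min exclusion window; need {n_last}"
        )
    idx = np.nonzero(usable)[0][-n_last:]
    return np.asarray(wells, dtype=float)[:, idx].mean(axis=1)


def measure_ecar_effect(
    plates: list[SeahorsePlate],
    exclusion_min: float = 15.0,
    n_last: int = 6,
) -> tuple[float, float, np.ndarray]:
    """Injection effect on ECAR: mean(control) - mean(treated), mpH/min.

    Per well, the mean of the last ``n_last`` timepoints (all of which
    must fall outside the post-injection artefact exclusion window);
    each plate is one experimental repeat, and the returned SEM is taken
    over repeats.  Returns (effect, sem, per-repeat effects).
    """
    if len(plates) == 0:
        raise ValueError("no plates supplied")
    effects = []
    for plate in plates:
        treated = _last_n_well_means(plate, plate.treated, n_last, exclusion_min)
        control = _last_n_well_means(plate, plate.control, n_last, exclusion_min)
        effects.append(control.mean() - treated.mean())
    effects = np.asarray(effects)
    sem = (
        float(effects.std(ddof=1) / np.sqrt(effects.size))
        if effects.size > 1
        else float("nan")
    )
    return float(effects.mean()), sem, effects


def order_of_magnitude_check(
    predicted: float, measured: float
) -> tuple[float, bool]:
    """Ratio of the larger to the smaller value, and whether it is <= 10."""
    if not (predicted > 0 and measured > 0):
        raise ValueError("both quantities must be positive")
    ratio = max(predicted, measured) / min(predicted, measured)
    return float(ratio), bool(ratio <= 10.0)
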