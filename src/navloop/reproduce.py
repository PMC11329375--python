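"""End-to-end reproduction runs: generate, analyse, and summarise.

Each function simulates a study-scale synthetic dataset whose ground
truth is the corresponding published cohort value, runs the full
analysis pipeline on it, and reports the recovered estimate together
with the generator truth and the cohort SEM.  :func:`compute_targets`
bundles the whole battery into a flat summary keyed by short run ids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import pipelines
from .calibration import electrode_ph
from .ecar import measure_ecar_effect
from .synthetic import (
    make_cohort,
    simulate_electrode_series,
    simulate_plate_fluorescence,
    simulate_seahorse,
)
from .calibration import sbfi_fold_change

__all__ = ["RunResult", "compute_targets", "TARGET_IDS"]

TARGET_IDS = ("t2", "t3", "t4", "t5", "t6", "t7", "t8", "t9", "t10")

# Study-condition constants (generator ground truth / cohort sizes)
SEAHORSE_BASELINE = 60.0  # mpH/min, typical basal glycolytic ECAR
SEAHORSE_EFFECT = 9.8  # mpH/min drop on Na_v_1.5 block
SBFI_FOLD = 2.2  # fold [Na+]_i rise on NKA inhibition
PH_CORE, PH_PERIPHERY = 7.0, 6.8
PH_SLICE_SD = 0.3  # inter-tumour spread of regional pH
N_SLICES = 9


@dataclass(frozen=True)
class RunResult:
    """Outcome of one reproduction run.

    ``truth`` is the realised generator truth of the simulated dataset
    (the mean of the drawn per-cell/per-slice truths); ``nominal`` is
    the published cohort value those draws were centred on.
    """

    value: float
    n: int
    sem: float
    truth: float
    nominal: float

    def within_2sem(self) -> bool:
        """Recovery check: estimate within 2 SEM of the generator truth."""
        return abs(self.value - self.truth) <= 2.0 * self.sem


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(2**31, size=n)]


def seahorse_effect_run(seed: int, n_repeats: int = 3) -> RunResult:
    """TTX-style ECAR reduction recovered by the last-6-timepoints estimator."""
    plates = [
        simulate_seahorse(
            SEAHORSE_BASELINE,
            -SEAHORSE_EFFECT,
            n_wells=6,
            n_timepoints=16,
            injection_index=6,
            noise_sd=1.5,
            seed=s,
        )
        for s in _child_seeds(seed, n_repeats)
    ]
    effect, sem, _ = measure_ecar_effect(plates)
    return RunResult(
        value=effect, n=n_repeats, sem=sem, truth=SEAHORSE_EFFECT, nominal=SEAHORSE_EFFECT
    )


def persistent_density_run(seed: int, ph_e: float, n_cells: int = 10) -> RunResult:
    """Cohort-mean persistent density via the 20-25 ms window estimator."""
    recs, truths = make_cohort(ph_e, "activation", n_cells, seed, increment_mv=10)
    densities = pipelines.persistent_cohort(recs, step_mv=0.0)
    mean, sem = pipelines.cohort_mean_sem(densities)
    from .synthetic import PH_CONDITIONS

    return RunResult(
        value=mean,
        n=n_cells,
        sem=sem,
        truth=float(truths["persistent_density"].mean()),
        nominal=PH_CONDITIONS[ph_e].persistent_density_pa_pf,
    )


def peak_density_run(seed: int, ph_e: float = 7.2, n_cells: int = 11) -> RunResult:
    """Cohort-mean peak transient density via the corrected peak estimator."""
    recs, truths = make_cohort(ph_e, "activation", n_cells, seed, increment_mv=10)
    mean, sem = pipelines.cohort_mean_sem(pipelines.peak_cohort(recs))
    from .synthetic import PH_CONDITIONS

    return RunResult(
        value=mean,
        n=n_cells,
        sem=sem,
        truth=float(truths["peak_density"].mean()),
        nominal=PH_CONDITIONS[ph_e].peak_density_pa_pf,
    )


def activation_vhalf_run(seed: int, ph_e: float = 7.2, n_cells: int = 10) -> RunResult:
    """Cohort-mean activation v_half from conductance-curve Boltzmann fits."""
    recs, truths = make_cohort(ph_e, "activation", n_cells, seed, increment_mv=5)
    fits = pipelines.activation_fits(recs)
    mean, sem = pipelines.cohort_mean_sem(np.array([f.v_half_mv for f in fits]))
    from .synthetic import PH_CONDITIONS

    return RunResult(
        value=mean,
        n=n_cells,
        sem=sem,
        truth=float(truths["act_v_half"].mean()),
        nominal=PH_CONDITIONS[ph_e].act.v_half_mv,
    )


def inactivation_fit_run(
    seed: int, ph_e: float = 7.2, n_cells: int = 10
) -> tuple[RunResult, RunResult]:
    """Cohort-mean inactivation (v_half, k) from normalised test-pulse fits."""
    recs, truths = make_cohort(ph_e, "inactivation", n_cells, seed, increment_mv=5)
    fits = pipelines.inactivation_fits(recs)
    v_mean, v_sem = pipelines.cohort_mean_sem(np.array([f.v_half_mv for f in fits]))
    k_mean, k_sem = pipelines.cohort_mean_sem(np.array([f.k_mv for f in fits]))
    from .synthetic import PH_CONDITIONS

    cond = PH_CONDITIONS[ph_e]
    return (
        RunResult(
            value=v_mean,
            n=n_cells,
            sem=v_sem,
            truth=float(truths["inact_v_half"].mean()),
            nominal=cond.inact.v_half_mv,
        ),
        RunResult(
            value=k_mean,
            n=n_cells,
            sem=k_sem,
            truth=float(truths["inact_k"].mean()),
            nominal=cond.inact.k_mv,
        ),
    )


def sbfi_fold_run(seed: int, n_repeats: int = 6) -> RunResult:
    """Ouabain-style [Na+]_i fold change via the SBFI ratio pipeline."""
    treated, vehicle = [], []
    for s in _child_seeds(seed, n_repeats):
        t, v = simulate_plate_fluorescence(
            SBFI_FOLD, background_340=150.0, background_380=100.0, n_wells=5, seed=s
        )
        treated.append(t)
        vehicle.append(v)
    _, fold, sem = sbfi_fold_change(treated, vehicle)
    return RunResult(value=fold, n=n_repeats, sem=sem, truth=SBFI_FOLD, nominal=SBFI_FOLD)


def electrode_periphery_run(seed: int, n_slices: int = N_SLICES) -> RunResult:
    """Mean peripheral tumour-slice pH via the electrode calibration pipeline."""
    rng = np.random.default_rng(seed)
    slice_means = []
    periph_truths = []
    for s in _child_seeds(int(rng.integers(2**31)), n_slices):
        core = rng.normal(PH_CORE, PH_SLICE_SD)
        periph = rng.normal(PH_PERIPHERY, PH_SLICE_SD)
        periph_truths.append(periph)
        seq, labels = [], []
        for _ in range(6):  # 12 alternating measurements per slice
            seq += [core, periph]
            labels += ["core", "periphery"]
        series = simulate_electrode_series(
            np.array(seq),
            offset_drift_mv_per_block=2.0,
            seed=s,
            noise_mv=0.5,
            labels=labels,
        )
        ph, labs, _ = electrode_ph(series)
        slice_means.append(ph[[i for i, l in enumerate(labs) if l == "periphery"]].mean())
    mean, sem = pipelines.cohort_mean_sem(np.asarray(slice_means))
    return RunResult(
        value=mean,
        n=n_slices,
        sem=sem,
        truth=float(np.mean(periph_truths)),
        nominal=PH_PERIPHERY,
    )


def compute_targets(seed: int) -> dict[str, dict[str, float]]:
    """Run the full reproduction battery with independent sub-seeds."""
    seeds = _child_seeds(seed, 16)
    t6, t7 = inactivation_fit_run(seeds[4])
    runs: dict[str, RunResult] = {
        "t2": seahorse_effect_run(seeds[0]),
        "t3": persistent_density_run(seeds[1], ph_e=7.2),
        "t4": persistent_density_run(seeds[2], ph_e=6.2),
        "t5": activation_vhalf_run(seeds[3]),
        "t6": t6,
        "t7": t7,
        "t8": peak_density_run(seeds[5]),
        "t9": sbfi_fold_run(seeds[6]),
        "t10": electrode_periphery_run(seeds[7]),
    }
    return {
        tid: {"value": round(float(r.value), 6), "n": int(r.n)} for tid, r in runs.items()
    }
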