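"""Positive-feedback loop between extracellular pH and persistent Na+ current.

Acidic extracellular pH (pH_e) increases the persistent Na+ current
through Na_v_1.5; the extra Na+ influx raises NKA ATP demand, met by
glycolysis, whose H+ export acidifies the extracellular space further.
This module closes that loop as a scalar model of pH_e:

    d(pH_e)/dt = r (pH_bath - pH_e) - g * ECAR(I_pers(pH_e)) / 1000

with r the first-order relaxation towards the bulk/perfusion pH (per
minute), g a dimensionless gain on the acid source (g = 0 disables the
feedback), ECAR in mpH/min from the stoichiometric chain, and
I_pers(pH_e) a declared monotone map through the two measured anchors
(-0.31 pA/pF at pH 7.2, -0.71 pA/pF at pH 6.2).

Only two pH points were measured, so the interpolation form of the
current-vs-pH map is an assumption: the default is linear in pH between
the anchors and clamped flat outside [6.0, 7.4]; a log-[H+]-linear
alternative is provided.  The loop is closed at the level of persistent
current density only; no rate constants for pH relaxation or acid
export capacity are published, so results are comparative statics, not
quantitative tumour predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .ecar import StoichiometryParams, WellGeometry, predict_ecar

__all__ = [
    "CurrentVsPh",
    "linear_current_map",
    "log_h_current_map",
    "FeedbackParams",
    "FeedbackState",
    "steady_state",
    "simulate_dynamics",
    "feedback_amplification",
]

PH_GUARD = (5.5, 8.0)

ANCHOR_ACID = (6.2, -0.71)  # (pH_e, persistent density pA/pF)
ANCHOR_PHYS = (7.2, -0.31)
CLAMP_RANGE = (6.0, 7.4)


@dataclass(frozen=True)
class CurrentVsPh:
    """Monotone (non-increasing in pH) persistent-density map, clamped
    flat outside ``clamp`` to avoid extrapolating beyond measured pH."""

    fn: callable
    clamp: tuple[float, float] = CLAMP_RANGE

    def __call__(self, ph: float) -> float:
        lo, hi = self.clamp
        return float(self.fn(min(max(ph, lo), hi)))


def linear_current_map(
    anchor_a: tuple[float, float] = ANCHOR_ACID,
    anchor_b: tuple[float, float] = ANCHOR_PHYS,
    clamp: tuple[float, float] = CLAMP_RANGE,
) -> CurrentVsPh:
    """Straight line in pH through the two measured anchors."""
    (ph_a, d_a), (ph_b, d_b) = anchor_a, anchor_b
    slope = (d_b - d_a) / (ph_b - ph_a)
    return CurrentVsPh(fn=lambda ph: d_a + slope * (ph - ph_a), clamp=clamp)


def log_h_current_map(
    anchor_a: tuple[float, float] = ANCHOR_ACID,
    anchor_b: tuple[float, float] = ANCHOR_PHYS,
    clamp: tuple[float, float] = CLAMP_RANGE,
) -> CurrentVsPh:
    """Density linear in [H+] (i.e. in 10**-pH) through the anchors."""
    (ph_a, d_a), (ph_b, d_b) = anchor_a, anchor_b
    h_a, h_b = 10.0**-ph_a, 10.0**-ph_b
    slope = (d_b - d_a) / (h_b - h_a)
    return CurrentVsPh(fn=lambda ph: d_a + slope * (10.0**-ph - h_a), clamp=clamp)


@dataclass(frozen=True)
class FeedbackParams:
    """Closure parameters of the pH_e feedback loop."""

    ph_bath: float = 7.4
    relaxation_per_min: float = 1.0
    gain: float = 1.0
    current_vs_ph: CurrentVsPh = field(default_factory=linear_current_map)
    capacitance_pf: float = 20.0
    stoich: StoichiometryParams = field(default_factory=StoichiometryParams)
    well: WellGeometry = field(default_factory=WellGeometry)

    def __post_init__(self) -> None:
        if not self.relaxation_per_min > 0:
            raise ValueError("relaxation rate must be positive")
        if self.gain < 0:
            raise ValueError("gain must be non-negative")

    def acid_source_mpH_min(self, ph_e: float) -> float:
        """Instantaneous ECAR (mpH/min) at a given extracellular pH."""
        density = self.current_vs_ph(ph_e)
        return predict_ecar(
            density, self.capacitance_pf, self.stoich, self.well
        ).ecar_mpH_min


@dataclass(frozen=True)
class FeedbackState:
    """Coupled state of the loop at one extracellular pH."""

    ph_e: float
    persistent_density_pa_pf: float
    acid_source_mpH_min: float

    def __post_init__(self) -> None:
        lo, hi = PH_GUARD
        if not lo <= self.ph_e <= hi:
            raise ValueError(f"pH_e {self.ph_e:.3f} outside the simulation guard {PH_GUARD}")


def _state_at(params: FeedbackParams, ph: float) -> FeedbackState:
    return FeedbackState(
        ph_e=ph,
        persistent_density_pa_pf=params.current_vs_ph(ph),
        acid_source_mpH_min=params.acid_source_mpH_min(ph),
    )


def _loop_map(params: FeedbackParams, ph: float) -> float:
    """One application of the fixed-point map
    ``G(pH) = pH_bath - gain * ECAR(pH)/1000 / relaxation``."""
    return params.ph_bath - params.gain * params.acid_source_mpH_min(ph) / 1000.0 / (
        params.relaxation_per_min
    )


def steady_state(
    params: FeedbackParams,
    tol: float = 1e-9,
    max_iter: int = 10_000,
    damping: float = 0.5,
) -> FeedbackState:
    """Steady extracellular pH of the closed loop.

    Solves ``pH* = G(pH*)`` by damped fixed-point iteration with a
    bisection (Brent) fallback on ``pH - G(pH)`` over the guard
    interval.  The acid source is non-negative and non-increasing in
    pH over the clamped map, so G is monotone and a root exists in
    [guard_lo, pH_bath]; a numerical contraction check asserts local
    uniqueness of the iterate.
    """
    ph = params.ph_bath
    for _ in range(max_iter):
        nxt = (1.0 - damping) * ph + damping * _loop_map(params, ph)
        # step size underestimates the distance to the fixed point by a
        # 1/(1-|G'|) factor; stop well below tol to absorb it
        if abs(nxt - ph) < 1e-3 * tol * damping:
            ph = nxt
            break
        ph = nxt
    else:
        # Fixed-point iteration did not settle; fall back to root bracketing.
        f = lambda x: x - _loop_map(params, x)  # noqa: E731
        lo, hi = PH_GUARD[0], params.ph_bath
        if f(lo) * f(hi) > 0:
            raise RuntimeError(
                f"no steady state bracketed in [{lo}, {hi}]: "
                f"f(lo)={f(lo):.3g}, f(hi)={f(hi):.3g}"
            )
        ph = brentq(f, lo, hi, xtol=tol)
    # contraction check: |G'| < 1 near the fixed point implies uniqueness
    eps = 1e-6
    slope = (_loop_map(params, ph + eps) - _loop_map(params, ph - eps)) / (2 * eps)
    if abs(slope) >= 1.0:
        raise RuntimeError(
            f"loop map is not a contraction near pH*={ph:.4f} (|G'|={abs(slope):.3f}); "
            "steady state may not be unique"
        )
    return _state_at(params, ph)


def simulate_dynamics(
    params: FeedbackParams,
    ph0: float,
    t_span_min: float,
    dt_min: float,
) -> tuple[np.ndarray, list[FeedbackState]]:
    """Fixed-step explicit (RK4) integration of the pH_e dynamics.

    Returns (times in minutes, states).  The scalar autonomous system is
    monotone: the trajectory approaches the steady state without
    overshoot for any stable step size; a breach of the pH guard rails
    flags step-size instability.
    """
    if dt_min <= 0:
        raise ValueError("dt must be positive")
    n = int(round(t_span_min / dt_min))
    times = np.arange(n + 1) * dt_min

    def rhs(ph: float) -> float:
        return params.relaxation_per_min * (params.ph_bath - ph) - (
            params.gain * params.acid_source_mpH_min(ph) / 1000.0
        )

    ph = float(ph0)
    states = [_state_at(params, ph)]
    lo, hi = PH_GUARD
    for _ in range(n):
        k1 = rhs(ph)
        k2 = rhs(ph + 0.5 * dt_min * k1)
        k3 = rhs(ph + 0.5 * dt_min * k2)
        k4 = rhs(ph + dt_min * k3)
        ph = ph + dt_min / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not lo <= ph <= hi:
            raise RuntimeError(
                f"pH guard breached (pH={ph:.3f}): step size {dt_min} min is unstable"
            )
        states.append(_state_at(params, ph))
    return times, states


def feedback_amplification(params: FeedbackParams) -> float:
    """Ratio of closed-loop to open-loop steady acidification.

    Open loop fixes the persistent current at its bath-pH value (no
    pH dependence), so the ratio isolates how much the pH-sensitivity of
    the persistent current amplifies acidification; >= 1 by monotonicity.
    """
    if not params.gain > 0:
        raise ValueError("amplification defined for positive gain only")
    closed = steady_state(params)
    open_drop = (
        params.gain * params.acid_source_mpH_min(params.ph_bath) / 1000.0
    ) / params.relaxation_per_min
    if open_drop == 0:
        raise ValueError("zero open-loop acidification: no acid source at bath pH")
    closed_drop = params.ph_bath - closed.ph_e
    return float(closed_drop / open_drop)
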