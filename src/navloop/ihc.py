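"""Modified Allred scoring of Na_v_1.5 immunostaining.

The total score is the sum of a proportion score (0-5, binned fraction
of positive carcinoma cells) and an intensity score (0-3); totals of
0-3 are classed 'low' and 4-8 'high'.

Boundary convention (a declared decision — the printed bin labels do not
state it): the strict inequalities "<1/100" and ">2/3" of the printed
bins are honoured, and interior boundaries follow the worked placements
1/100 -> 2, exactly 1/3 -> 3, exactly 2/3 -> 4:

    0            -> 0
    (0, 1/100)   -> 1
    [1/100, 1/10)-> 2
    [1/10, 1/3]  -> 3
    (1/3, 2/3]   -> 4
    (2/3, 1]     -> 5
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

__all__ = ["AllredScore", "proportion_score", "allred_total", "LOW_HIGH_CUT"]

#: Totals <= this are 'low'; above it, 'high'.
LOW_HIGH_CUT = 3


@dataclass(frozen=True)
class AllredScore:
    proportion_fraction: float
    proportion_score: int
    intensity_score: int
    total: int
    category: Literal["low", "high"]

    def __post_init__(self) -> None:
        if self.total != self.proportion_score + self.intensity_score:
            raise ValueError("total must equal proportion + intensity score")
        expected = "low" if self.total <= LOW_HIGH_CUT else "high"
        if self.category != expected:
            raise ValueError(f"category {self.category!r} inconsistent with total {self.total}")
        if (self.proportion_fraction == 0) != (self.proportion_score == 0):
            raise ValueError("zero fraction and zero proportion score must coincide")


def proportion_score(fraction: float) -> int:
    """Bin a positive-cell fraction into the 0-5 proportion score."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    if fraction == 0.0:
        return 0
    if fraction < 1.0 / 100.0:
        return 1
    if fraction < 1.0 / 10.0:
        return 2
    if fraction <= 1.0 / 3.0:
        return 3
    if fraction <= 2.0 / 3.0:
        return 4
    return 5


def allred_total(fraction: float, intensity: int) -> AllredScore:
    """Total modified-Allred score and low/high category.

    A core with no positive cells must also have intensity 0; the
    inconsistent combination (zero fraction, positive intensity) is
    rejected.
    """
    if intensity not in (0, 1, 2, 3):
        raise ValueError(f"intensity must be an integer 0-3, got {intensity!r}")
    p = proportion_score(fraction)
    if fraction == 0 and intensity != 0:
        raise ValueError("zero positive fraction is inconsistent with nonzero intensity")
    total = p + intensity
    return AllredScore(
        proportion_fraction=float(fraction),
        proportion_score=p,
        intensity_score=int(intensity),
        total=total,
        category="low" if total <= LOW_HIGH_CUT else "high",
    )
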