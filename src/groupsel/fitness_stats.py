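"""Competition statistics: Malthusian relative fitness and assortment.

Relative fitness over a competition interval is the ratio of Malthusian
growth parameters, w = ln(E_f/E_0) / ln(A_f/A_0), for evolved (E) and
ancestral (A) counts taken at the same two time points; an optional
normalizer (e.g. an ancestor-vs-ancestor control fitness) divides the result.

Assortment quantifies genotypic enrichment of a focal strain among groups
that survive settling, controlling for its overall population frequency:
a = (f_set - f_pop) / (1 - f_pop). It is 0 when settling leaves the
frequency unchanged and 1 when the settled fraction is pure focal strain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CompetitionCounts",
    "AssortmentObservation",
    "UndefinedFitnessError",
    "malthusian_fitness",
    "assortment",
]


class UndefinedFitnessError(ValueError):
    """Raised when the reference strain did not change in count."""


@dataclass(frozen=True)
class CompetitionCounts:
    """Paired strain counts at the start and end of a competition.

    Counts may be in any consistent unit (whole clusters for snowflake
    competitions, deflocculated cells for floc); the unit is carried as
    metadata only.
    """

    evolved_initial: float
    evolved_final: float
    ancestor_initial: float
    ancestor_final: float
    unit: str = "cells"

    def __post_init__(self) -> None:
        for name in ("evolved_initial", "evolved_final", "ancestor_initial", "ancestor_final"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def swapped(self) -> "CompetitionCounts":
        """The same competition viewed from the other strain."""
        return CompetitionCounts(
            evolved_initial=self.ancestor_initial,
            evolved_final=self.ancestor_final,
            ancestor_initial=self.evolved_initial,
            ancestor_final=self.evolved_final,
            unit=self.unit,
        )


@dataclass(frozen=True)
class AssortmentObservation:
    """Focal-strain frequencies after settling (f_set) and overall (f_pop)."""

    f_set: float
    f_pop: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_set <= 1.0:
            raise ValueError("f_set must lie in [0, 1]")
        if not 0.0 <= self.f_pop < 1.0:
            raise ValueError("f_pop must lie in [0, 1)")


def malthusian_fitness(
    counts: CompetitionCounts, normalizer: float | None = None
) -> float:
    """Relative fitness as the ratio of Malthusian growth parameters."""
    denom = math.log(counts.ancestor_final / counts.ancestor_initial)
    if denom == 0.0:
        raise UndefinedFitnessError(
            "ancestor count did not change; Malthusian ratio undefined"
        )
    w = math.log(counts.evolved_final / counts.evolved_initial) / denom
    if normalizer is not None:
        if normalizer <= 0:
            raise ValueError("normalizer must be > 0")
        w /= normalizer
    return w


def assortment(obs: AssortmentObservation) -> float:
    """Frequency-controlled genotypic enrichment, (f_set - f_pop)/(1 - f_pop)."""
    return (obs.f_set - obs.f_pop) / (1.0 - obs.f_pop)
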