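"""Analytic extinction probability of a rare mutant lineage under group selection.

One round of settling selection keeps a fraction ``f`` of ``N`` groups, drawn
without replacement. A mutant lineage present in ``k`` of the groups survives
iff at least one of those groups is drawn; the probability that none is drawn
is the zero-success term of a hypergeometric distribution,

    p_e = prod_{i=0}^{fN-1} (N - k - i) / (N - i),

which for large ``N`` is well approximated by ``exp(-k f / (1 - f))``.

How many groups carry the mutant depends on the developmental mode: clonal
development concentrates the ``m`` mutant cells into ``ceil(m / mean size)``
groups, whereas aggregative development at low mutant frequency scatters them
one per group (``k = m``). That difference is the genetic bottleneck separating
the two life cycles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SelectionRegime",
    "LineageContext",
    "extinction_prob_exact",
    "extinction_prob_approx",
    "mutant_group_count",
]

MODES = ("clonal", "aggregative")


def _n_draws(N: int, f: float) -> int:
    """Number of groups drawn, round(f*N) with a floor of one draw."""
    return max(1, int(math.floor(f * N + 0.5)))


@dataclass(frozen=True)
class SelectionRegime:
    """One settling-selection bottleneck.

    Parameters
    ----------
    N : total number of groups.
    f : surviving fraction of groups, in (0, 1).
    k : number of groups containing at least one mutant cell.
    """

    N: int
    f: float
    k: int

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if not 0.0 < self.f < 1.0:
            raise ValueError(f"f must lie in (0, 1), got {self.f}")
        if not 0 <= self.k <= self.N:
            raise ValueError(f"k must lie in [0, N={self.N}], got {self.k}")
        if self.n_draws > self.N:
            raise ValueError(
                f"round(f*N) = {self.n_draws} draws exceed N = {self.N}"
            )

    @property
    def n_draws(self) -> int:
        return _n_draws(self.N, self.f)


@dataclass(frozen=True)
class LineageContext:
    """A mutant lineage of ``n_mutant_cells`` cells partitioned into groups."""

    n_mutant_cells: int
    mean_group_size: float = 50.0
    mode: str = "clonal"

    def __post_init__(self) -> None:
        if self.n_mutant_cells < 0:
            raise ValueError("n_mutant_cells must be >= 0")
        if self.mean_group_size < 1:
            raise ValueError("mean_group_size must be >= 1")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")


def extinction_prob_exact(regime: SelectionRegime) -> float:
    """Exact single-round extinction probability (hypergeometric, no success).

    Computed in log space so large ``N`` does not underflow. Equals the
    probability that a without-replacement draw of ``round(f*N)`` groups from
    ``N`` avoids all ``k`` mutant-bearing groups.
    """
    N, k, d = regime.N, regime.k, regime.n_draws
    if k == 0:
        return 1.0
    if d > N - k:  # pigeonhole: cannot avoid every mutant group
        return 0.0
    i = np.arange(d, dtype=np.float64)
    logp = np.sum(np.log(N - k - i)) - np.sum(np.log(N - i))
    return float(np.exp(logp))


def extinction_prob_approx(k: int, f: float) -> float:
    """Large-N exponential approximation ``exp(-k f / (1 - f))``."""
    if not 0.0 < f < 1.0:
        raise ValueError(f"f must lie in (0, 1), got {f}")
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    return float(math.exp(-k * f / (1.0 - f)))


def mutant_group_count(ctx: LineageContext) -> int:
    """Number of mutant-bearing groups ``k`` implied by the developmental mode.

    Aggregative development at low mutant frequency puts one mutant cell per
    group (``k = m``); clonal development packs them into
    ``ceil(m / mean group size)`` groups (a partially filled group still
    carries the lineage).
    """
    m = ctx.n_mutant_cells
    if m == 0:
        return 0
    if ctx.mode == "aggregative":
        return m
    return int(math.ceil(m / ctx.mean_group_size))
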