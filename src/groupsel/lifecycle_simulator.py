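"""Stochastic fate of a mutant lineage under growth/settling selection cycles.

Each round has three stages. (1) Growth: ancestral and mutant cells grow
exponentially, the mutant at rate ``λ(1+s_c)``, until the whole population has
increased ``growth_fold``-fold; the stopping time solves
``(I-m)e^{λt} + m e^{λ(1+s_c)t} = growth_fold·I``. (2) Development: the grown
cells are packed into groups drawn from a group-size distribution — clonally
(mutants fill randomly chosen groups whole, leaving at most one mixed group)
or aggregatively (each cell lands in a group with probability proportional to
group size). (3) Settling selection: groups are sampled without replacement
with weight ``n + (1+s_g)·m`` until a fraction ``survival_fraction`` of cells
survives; the overshoot is rescaled away proportionally. Surviving mutants
seed the next round. Extinction (no mutants) and fixation (only mutants) are
absorbing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .synthetic_data import SizeDistributionSpec, sample_sizes

__all__ = [
    "Group",
    "GroupPopulation",
    "SimParams",
    "SimResult",
    "EnsembleSummary",
    "grow",
    "allocate_clonal",
    "allocate_aggregative",
    "settle_select",
    "run_lineage",
    "run_ensemble",
]

MODES = ("clonal", "aggregative")


@dataclass(frozen=True)
class Group:
    """One multicellular unit: ancestral and mutant cell counts."""

    n_ancestral: int
    n_mutant: int

    def __post_init__(self) -> None:
        if self.n_ancestral < 0 or self.n_mutant < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n_ancestral + self.n_mutant < 1:
            raise ValueError("a group must contain at least one cell")

    @property
    def size(self) -> int:
        return self.n_ancestral + self.n_mutant

    def weight(self, s_g: float) -> float:
        return self.n_ancestral + (1.0 + s_g) * self.n_mutant


@dataclass
class GroupPopulation:
    """Array-backed population of groups."""

    n_ancestral: np.ndarray
    n_mutant: np.ndarray

    def __post_init__(self) -> None:
        self.n_ancestral = np.asarray(self.n_ancestral, dtype=np.int64)
        self.n_mutant = np.asarray(self.n_mutant, dtype=np.int64)
        if self.n_ancestral.shape != self.n_mutant.shape or self.n_ancestral.ndim != 1:
            raise ValueError("n_ancestral and n_mutant must be 1-D and equal length")
        if (self.n_ancestral < 0).any() or (self.n_mutant < 0).any():
            raise ValueError("cell counts must be non-negative")
        if (self.sizes < 1).any():
            raise ValueError("every group must contain at least one cell")

    @property
    def sizes(self) -> np.ndarray:
        return self.n_ancestral + self.n_mutant

    @property
    def n_groups(self) -> int:
        return self.n_ancestral.size

    @property
    def total_cells(self) -> int:
        return int(self.sizes.sum())

    @property
    def total_mutants(self) -> int:
        return int(self.n_mutant.sum())

    def weights(self, s_g: float) -> np.ndarray:
        return self.n_ancestral + (1.0 + s_g) * self.n_mutant

    def groups(self) -> list[Group]:
        return [Group(int(a), int(m)) for a, m in zip(self.n_ancestral, self.n_mutant)]


@dataclass(frozen=True)
class SimParams:
    """Configuration of the lineage simulator.

    ``growth_rate`` (λ) only sets the time scale of the growth phase and does
    not affect the final composition; ``s_c`` and ``s_g`` are the cell-growth
    and group-survival selection coefficients. Defaults follow the daily
    regime of the settling-selection experiment: 100-fold growth and survival
    of 1/100th of cells, iterated five times, starting from a single mutant.
    """

    growth_rate: float = 1.0
    s_c: float = 0.0
    s_g: float = 0.0
    growth_fold: float = 100.0
    survival_fraction: float = 0.01
    rounds: int = 5
    mode: str = "clonal"
    initial_mutants: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.growth_rate <= 0:
            raise ValueError("growth_rate must be > 0")
        if self.s_c <= -1:
            raise ValueError("s_c must be > -1")
        if self.s_g < 0:
            raise ValueError("s_g must be >= 0")
        if self.growth_fold <= 1:
            raise ValueError("growth_fold must be > 1")
        if not 0 < self.survival_fraction < 1:
            raise ValueError("survival_fraction must lie in (0, 1)")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.initial_mutants < 0:
            raise ValueError("initial_mutants must be >= 0")


@dataclass(frozen=True)
class SimResult:
    """Fate of one replicate lineage."""

    extinct: bool
    fixed: bool
    mutant_frequency_by_round: tuple[float, ...]
    replicate_seed: int


@dataclass(frozen=True)
class EnsembleSummary:
    n_replicates: int
    extinction_fraction: float
    fixation_fraction: float
    mean_trajectory: np.ndarray  # absorbing-value padded, length = rounds
    results: tuple[SimResult, ...]


def _stochastic_round(x: float, rng: np.random.Generator | None) -> int:
    """Round to an integer without systematic bias (floor + Bernoulli)."""
    if rng is None:
        return int(math.floor(x + 0.5))
    lo = math.floor(x)
    return int(lo + (rng.random() < (x - lo)))


def grow(
    I: int, m: int, params: SimParams, rng: np.random.Generator | None = None
) -> tuple[int, int]:
    """Grow the population ``growth_fold``-fold; return (total', mutants').

    Solves the two-exponential stopping condition for the growth time, then
    evaluates the mutant subpopulation at that time. Counts are rounded
    stochastically when an ``rng`` is given, to nearest otherwise.
    """
    if I <= 0:
        raise ValueError("I must be > 0")
    if not 0 <= m <= I:
        raise ValueError("m must lie in [0, I]")
    G, lam, sc = params.growth_fold, params.growth_rate, params.s_c
    total = int(round(G * I))
    if m == 0:
        return total, 0
    if m == I or sc == 0.0:
        m_final = m * G
    else:
        target = G * I

        def excess(t: float) -> float:
            return (I - m) * math.exp(lam * t) + m * math.exp(lam * (1 + sc) * t) - target

        t_hi = math.log(G) / (lam * min(1.0, 1.0 + sc))
        for _ in range(200):
            if excess(t_hi) >= 0:
                break
            t_hi *= 2.0
        else:  # pragma: no cover - defensive
            raise RuntimeError(
                f"growth solver failed to bracket: I={I}, m={m}, s_c={sc}, G={G}"
            )
        t_star = brentq(excess, 0.0, t_hi, xtol=1e-12, rtol=8.9e-16)
        m_final = m * math.exp(lam * (1 + sc) * t_star)
    m_int = _stochastic_round(m_final, rng)
    return total, min(m_int, total)


def allocate_clonal(
    sizes: Sequence[int], m: int, rng: np.random.Generator
) -> GroupPopulation:
    """Pack ``m`` clonal mutant cells into randomly chosen groups, whole.

    Groups are picked uniformly at random; each is filled entirely with
    mutants before the next is picked, so at most one group ends up mixed.
    """
    sizes = np.asarray(sizes, dtype=np.int64)
    if (sizes < 1).any():
        raise ValueError("group sizes must be >= 1")
    if not 0 <= m <= sizes.sum():
        raise ValueError("m must lie in [0, total cells]")
    mutants = np.zeros_like(sizes)
    if m > 0:
        order = rng.permutation(sizes.size)
        csum = np.cumsum(sizes[order])
        n_full = int(np.searchsorted(csum, m, side="right"))
        mutants[order[:n_full]] = sizes[order[:n_full]]
        remainder = m - (int(csum[n_full - 1]) if n_full else 0)
        if remainder > 0:
            mutants[order[n_full]] = remainder
    return GroupPopulation(n_ancestral=sizes - mutants, n_mutant=mutants)


def allocate_aggregative(
    sizes: Sequence[int], m: int, rng: np.random.Generator
) -> GroupPopulation:
    """Scatter ``m`` mutant cells into groups with probability ∝ group size.

    Equivalent to marking ``m`` of the cells uniformly at random, so larger
    groups receive proportionally more mutants while respecting capacity
    (multivariate hypergeometric allocation).
    """
    sizes = np.asarray(sizes, dtype=np.int64)
    if (sizes < 1).any():
        raise ValueError("group sizes must be >= 1")
    if not 0 <= m <= sizes.sum():
        raise ValueError("m must lie in [0, total cells]")
    mutants = rng.multivariate_hypergeometric(sizes, m)
    return GroupPopulation(n_ancestral=sizes - mutants, n_mutant=mutants)


def settle_select(
    pop: GroupPopulation,
    s_g: float,
    survival_fraction: float,
    rng: np.random.Generator,
) -> GroupPopulation:
    """Settling selection: weighted sampling of groups without replacement.

    Groups are drawn without replacement with probability proportional to
    ``n + (1+s_g)·m`` until the drawn groups hold at least
    ``survival_fraction`` of all cells; the sequential renormalized-weight
    scheme is realized by sorting exponential keys ``Exp(1)/weight``
    (successive sampling). The overshoot beyond the cell target is removed by
    discarding uniformly chosen cells from the selected groups, which scales
    every group (and its mutant:ancestral ratio) proportionally in
    expectation while keeping the surviving total exactly
    ``round(survival_fraction · total)`` and the surviving composition free
    of rounding bias.
    """
    if pop.n_groups == 0:
        raise ValueError("population is empty")
    if not 0 < survival_fraction < 1:
        raise ValueError("survival_fraction must lie in (0, 1)")
    if s_g < 0:
        raise ValueError("s_g must be >= 0")
    total = pop.total_cells
    target = max(1, int(math.floor(survival_fraction * total + 0.5)))
    keys = rng.exponential(size=pop.n_groups) / pop.weights(s_g)
    order = np.argsort(keys, kind="stable")
    csum = np.cumsum(pop.sizes[order])
    n_sel = int(np.searchsorted(csum, target, side="left")) + 1
    sel = order[:n_sel]
    sel_total = int(csum[n_sel - 1])
    anc = pop.n_ancestral[sel].copy()
    mut = pop.n_mutant[sel].copy()
    if sel_total > target:
        removals = rng.multivariate_hypergeometric(
            np.concatenate([anc, mut]), sel_total - target
        )
        anc -= removals[:n_sel]
        mut -= removals[n_sel:]
    keep = (anc + mut) >= 1
    return GroupPopulation(n_ancestral=anc[keep], n_mutant=mut[keep])


def _sizes_for_total(
    spec: SizeDistributionSpec, total: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw group sizes until they hold ``total`` cells, trimming the last."""
    mean = max(1.0, spec.mean_size)
    out = []
    held = 0
    while held < total:
        need = max(8, int((total - held) / mean * 1.2) + 4)
        batch = sample_sizes(spec, need, rng)
        csum = np.cumsum(batch) + held
        cut = int(np.searchsorted(csum, total, side="left"))
        if cut < batch.size:
            last = total - (int(csum[cut - 1]) if cut else held)
            if last >= 1:
                batch = np.concatenate([batch[:cut], [last]])
            else:  # exact fill on the previous group
                batch = batch[:cut]
            out.append(batch)
            held = total
        else:
            out.append(batch)
            held = int(csum[-1])
    return np.concatenate(out).astype(np.int64)


def run_lineage(
    params: SimParams, sizes_source: SizeDistributionSpec
) -> SimResult:
    """Simulate one mutant lineage over ``params.rounds`` selection rounds.

    The mutant arises at the very start of the first growth phase in a
    population whose size is set by ``sizes_source`` (n_groups draws). Group
    structure is redrawn from the size distribution every round; only the
    surviving cell and mutant totals carry over between rounds.
    """
    rng = np.random.default_rng(params.seed)
    init_sizes = sample_sizes(sizes_source, sizes_source.n_groups, rng)
    I = int(init_sizes.sum())
    m = params.initial_mutants
    if m > I:
        raise ValueError(f"initial_mutants={m} exceeds initial population {I}")
    freqs: list[float] = []
    if m == 0:
        return SimResult(True, False, (0.0,), params.seed)
    for _ in range(params.rounds):
        total, m = grow(I, m, params, rng)
        sizes = _sizes_for_total(sizes_source, total, rng)
        if params.mode == "clonal":
            pop = allocate_clonal(sizes, m, rng)
        else:
            pop = allocate_aggregative(sizes, m, rng)
        pop = settle_select(pop, params.s_g, params.survival_fraction, rng)
        I, m = pop.total_cells, pop.total_mutants
        freqs.append(m / I)
        if m == 0 or m == I:
            break
    return SimResult(
        extinct=(m == 0),
        fixed=(m == I and m > 0),
        mutant_frequency_by_round=tuple(freqs),
        replicate_seed=params.seed,
    )


def run_ensemble(
    params: SimParams,
    sizes_source: SizeDistributionSpec,
    n_replicates: int,
) -> EnsembleSummary:
    """Run independent replicates and aggregate extinction/fixation fractions.

    Replicate seeds are spawned deterministically from ``params.seed``;
    trajectories shorter than ``rounds`` are padded with their absorbing value
    for averaging.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    child_seeds = np.random.SeedSequence(params.seed).generate_state(n_replicates)
    results = tuple(
        run_lineage(replace(params, seed=int(s)), sizes_source) for s in child_seeds
    )
    traj = np.empty((n_replicates, params.rounds))
    for i, r in enumerate(results):
        t = np.asarray(r.mutant_frequency_by_round)
        traj[i, : t.size] = t
        traj[i, t.size :] = t[-1]
    return EnsembleSummary(
        n_replicates=n_replicates,
        extinction_fraction=float(np.mean([r.extinct for r in results])),
        fixation_fraction=float(np.mean([r.fixed for r in results])),
        mean_trajectory=traj.mean(axis=0),
        results=results,
    )
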