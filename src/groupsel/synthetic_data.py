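"""Synthetic inputs with known ground truth for every estimator in the package.

Generators for: group-size distributions (the default lognormal family is
right-skewed and strictly positive, like observed cluster-size histograms;
empirical lists are accepted verbatim), annotated toy genomes for SNP
classification, settling videos with a programmed sedimentation speed,
flow-cytometry-like per-group size samples, and two-strain competition count
tables with a known true fitness. Every generator is bit-reproducible given
its spec and seed, and noise-free outputs round-trip exactly through the
corresponding downstream estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fitness_stats import CompetitionCounts
from .genomes import AnnotatedGenome, GeneModel
from .group_phenotypes import VideoStack

__all__ = [
    "SizeDistributionSpec",
    "SyntheticGenomeSpec",
    "SettlingVideoSpec",
    "CompetitionSpec",
    "gen_group_sizes",
    "sample_sizes",
    "gen_annotated_genome",
    "gen_settling_video",
    "gen_competition_counts",
]

_FAMILIES = ("empirical-list", "lognormal", "fixed")
_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class SizeDistributionSpec:
    """A distribution of group sizes (cells per group).

    ``mean_size`` is the distribution mean; ``dispersion`` is the log-scale
    standard deviation of the lognormal family (ignored for ``fixed``).
    ``sizes`` supplies the values for the ``empirical-list`` family.
    """

    family: str = "lognormal"
    mean_size: float = 50.0
    dispersion: float = 0.5
    n_groups: int = 100
    sizes: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if self.mean_size <= 0:
            raise ValueError("mean_size must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_groups < 1:
            raise ValueError("n_groups must be > 0")
        if self.family == "empirical-list":
            if not self.sizes:
                raise ValueError("empirical-list family requires sizes")
            object.__setattr__(self, "sizes", tuple(int(s) for s in self.sizes))
            if any(s < 1 for s in self.sizes):
                raise ValueError("empirical sizes must be >= 1")


def sample_sizes(
    spec: SizeDistributionSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` integer group sizes (>= 1) from the spec's distribution."""
    if spec.family == "fixed" or (spec.family == "lognormal" and spec.dispersion == 0):
        return np.full(n, max(1, int(round(spec.mean_size))), dtype=np.int64)
    if spec.family == "lognormal":
        sigma = spec.dispersion
        mu = math.log(spec.mean_size) - 0.5 * sigma**2  # E[X] = exp(mu + sigma^2/2)
        x = rng.lognormal(mu, sigma, size=n)
        return np.maximum(1, np.rint(x)).astype(np.int64)
    return rng.choice(np.asarray(spec.sizes, dtype=np.int64), size=n, replace=True)


def gen_group_sizes(spec: SizeDistributionSpec, seed: int | None = None) -> list[int]:
    """Generate ``spec.n_groups`` group sizes; reproducible under the seed.

    An empirical list whose length equals ``n_groups`` is returned verbatim;
    otherwise the empirical distribution is resampled with replacement.
    """
    if spec.family == "empirical-list" and len(spec.sizes) == spec.n_groups:
        return [int(s) for s in spec.sizes]
    rng = np.random.default_rng(seed)
    return [int(s) for s in sample_sizes(spec, spec.n_groups, rng)]


# ---------------------------------------------------------------------------
# Annotated toy genome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Layout of a toy annotated genome.

    Defaults give a compact, gene-dense genome (GC content near the 0.38 of
    budding yeast). Genes are single-CDS, non-overlapping, and placed on the
    forward strand unless ``random_strand`` is set.
    """

    n_contigs: int = 2
    contig_length: int = 5000
    n_genes: int = 16
    gene_length: int = 300
    upstream_window: int = 100
    gc_content: float = 0.38
    random_strand: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contigs < 1 or self.contig_length < 1:
            raise ValueError("n_contigs and contig_length must be >= 1")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.gene_length < 6 or self.gene_length % 3:
            raise ValueError("gene_length must be >= 6 and divisible by 3")
        if self.upstream_window < 0:
            raise ValueError("upstream_window must be >= 0")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must lie in (0, 1)")
        slot = self.gene_length + 2 * self.upstream_window
        if self.n_genes * slot > self.n_contigs * self.contig_length:
            raise ValueError(
                f"cannot pack {self.n_genes} genes of footprint {slot} bp into "
                f"{self.n_contigs} x {self.contig_length} bp"
            )


def _random_cds(n_codons: int, rng: np.random.Generator, p: np.ndarray) -> str:
    """ATG + (n_codons-2) stop-free random codons + a random stop codon."""
    bases = np.array(list("ACGT"))
    body = []
    for _ in range(n_codons - 2):
        codon = "".join(rng.choice(bases, size=3, p=p))
        while codon in _STOPS:
            codon = "".join(rng.choice(bases, size=3, p=p))
        body.append(codon)
    return "ATG" + "".join(body) + _STOPS[rng.integers(3)]


def gen_annotated_genome(spec: SyntheticGenomeSpec) -> AnnotatedGenome:
    """Generate a genome satisfying the annotation invariants.

    Genes are laid out on an even stride per contig, each slot leaving at
    least ``upstream_window`` bp clear on both sides, so upstream windows
    never run into a neighbouring CDS.
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    slot = spec.gene_length + 2 * spec.upstream_window
    capacity = spec.contig_length // slot if slot else spec.contig_length
    if spec.n_genes > capacity * spec.n_contigs:
        raise ValueError(
            f"cannot pack {spec.n_genes} genes: per-contig capacity is {capacity}"
        )

    contigs: dict[str, str] = {}
    genes: list[GeneModel] = []
    remaining = spec.n_genes
    for ci in range(spec.n_contigs):
        name = f"contig_{ci + 1}"
        seq = rng.choice(bases, size=spec.contig_length, p=p)
        k = min(remaining, capacity)
        remaining -= k
        if k:
            stride = spec.contig_length // k
            for gi in range(k):
                start = gi * stride + spec.upstream_window + 1  # 1-based
                end = start + spec.gene_length - 1
                strand = "+" if not spec.random_strand else "+-"[rng.integers(2)]
                cds = _random_cds(spec.gene_length // 3, rng, p)
                if strand == "-":
                    cds = cds.translate(str.maketrans("ACGT", "TGCA"))[::-1]
                seq[start - 1 : end] = list(cds)
                genes.append(
                    GeneModel(
                        name=f"gene_{len(genes) + 1}",
                        contig=name,
                        start=start,
                        end=end,
                        strand=strand,
                    )
                )
        contigs[name] = "".join(seq)
    return AnnotatedGenome(
        contigs=contigs, genes=genes, upstream_window=spec.upstream_window
    )


# ---------------------------------------------------------------------------
# Settling video
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SettlingVideoSpec:
    """A settling video: a unit-intensity biomass band on a dark background
    sliding down at ``front_speed`` pixels/frame, plus Gaussian sensor noise.

    Sub-pixel band edges keep the total biomass and the centroid displacement
    exact for non-integer speeds; noise is clipped at zero so intensities
    remain valid.
    """

    height: int = 300
    width: int = 64
    n_frames: int = 100
    frame_interval: float = 1.0
    front_speed: float = 2.0
    noise_sd: float = 0.0
    band_height: int | None = None  # defaults to height // 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 1 or self.n_frames < 2:
            raise ValueError("need height >= 2, width >= 1, n_frames >= 2")
        if self.front_speed < 0:
            raise ValueError("front_speed must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        bh = self.band_height if self.band_height is not None else max(1, self.height // 5)
        if bh < 1 or bh > self.height:
            raise ValueError("band_height must lie in [1, height]")
        if self.front_speed * (self.n_frames - 1) + bh > self.height:
            raise ValueError("front would exit the frame before the last frame")

    @property
    def effective_band_height(self) -> int:
        return self.band_height if self.band_height is not None else max(1, self.height // 5)


def gen_settling_video(spec: SettlingVideoSpec) -> VideoStack:
    """Render the video stack described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    bh = spec.effective_band_height
    rows = np.arange(spec.height, dtype=float)
    frames = np.empty((spec.n_frames, spec.height, spec.width))
    for t in range(spec.n_frames):
        y0 = spec.front_speed * t
        cover = np.clip(np.minimum(rows + 1, y0 + bh) - np.maximum(rows, y0), 0.0, 1.0)
        frames[t] = cover[:, None]
    if spec.noise_sd > 0:
        frames = np.clip(frames + rng.normal(0.0, spec.noise_sd, frames.shape), 0.0, None)
    return VideoStack(frames=frames, frame_interval=spec.frame_interval)


# ---------------------------------------------------------------------------
# Competition counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompetitionSpec:
    """A two-strain competition with a programmed true relative fitness.

    The ancestor grows ``generations_ancestor`` doublings over the interval
    (default log2(100), i.e. 100-fold daily growth); the evolved strain's log
    growth is ``true_fitness`` times the ancestor's, so the Malthusian ratio
    recovers ``true_fitness`` exactly in the noise-free case. Poisson noise
    models count acquisition.
    """

    initial_count_evolved: int = 10_000
    initial_count_ancestor: int = 10_000
    true_fitness: float = 1.0
    generations_ancestor: float = math.log2(100.0)
    count_noise: str = "none"  # or "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_count_evolved <= 0 or self.initial_count_ancestor <= 0:
            raise ValueError("initial counts must be > 0")
        if self.true_fitness <= 0:
            raise ValueError("true_fitness must be > 0")
        if self.generations_ancestor <= 0:
            raise ValueError("generations_ancestor must be > 0")
        if self.count_noise not in ("none", "poisson"):
            raise ValueError("count_noise must be 'none' or 'poisson'")


def gen_competition_counts(spec: CompetitionSpec) -> CompetitionCounts:
    """Generate a competition count table with known true fitness."""
    rng = np.random.default_rng(spec.seed)
    g = spec.generations_ancestor
    anc_final = spec.initial_count_ancestor * 2.0**g
    ev_final = spec.initial_count_evolved * 2.0 ** (g * spec.true_fitness)
    counts = [
        float(spec.initial_count_evolved),
        ev_final,
        float(spec.initial_count_ancestor),
        anc_final,
    ]
    if spec.count_noise == "poisson":
        counts = [max(1.0, float(rng.poisson(c))) for c in counts]
    return CompetitionCounts(
        evolved_initial=counts[0],
        evolved_final=counts[1],
        ancestor_initial=counts[2],
        ancestor_final=counts[3],
    )
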