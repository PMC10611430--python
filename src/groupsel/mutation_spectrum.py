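"""Drift-vs-selection test for mutation-class spectra.

Random SNPs are scattered uniformly over an annotated genome and classified
into four effect classes — missense, nonsense, synonymous, and
upstream/intergenic — giving a null spectrum expected under drift alone.
Observed class counts from an evolution experiment are then compared to
bootstrap resamples of that null: for each class we report the proportion of
resamples at least as large (and at least as small) as the observation, with
ties counted in both tails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .genomes import AnnotatedGenome

__all__ = [
    "MISSENSE",
    "NONSENSE",
    "SYNONYMOUS",
    "UPSTREAM",
    "INTERGENIC",
    "UPSTREAM_INTERGENIC",
    "FOUR_CLASSES",
    "SnpRecord",
    "ClassTail",
    "BootstrapResult",
    "classify_snp",
    "simulate_snps",
    "bootstrap_class_test",
    "tally_classes",
    "write_vcf",
]

MISSENSE = "missense"
NONSENSE = "nonsense"
SYNONYMOUS = "synonymous"
UPSTREAM = "upstream"
INTERGENIC = "intergenic"
# Reporting collapses the two non-coding labels into one fourth class.
UPSTREAM_INTERGENIC = "upstream_intergenic"
FOUR_CLASSES = (MISSENSE, NONSENSE, SYNONYMOUS, UPSTREAM_INTERGENIC)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def four_class(effect: str) -> str:
    """Collapse the fine-grained effect label onto the four-class scheme."""
    if effect in (UPSTREAM, INTERGENIC):
        return UPSTREAM_INTERGENIC
    if effect not in FOUR_CLASSES[:3]:
        raise ValueError(f"unknown effect label {effect!r}")
    return effect


@dataclass(frozen=True)
class SnpRecord:
    """A single classified SNP (1-based position)."""

    contig: str
    position: int
    ref: str
    alt: str
    effect: str  # fine-grained: missense/nonsense/synonymous/upstream/intergenic

    @property
    def effect_class(self) -> str:
        return four_class(self.effect)


def classify_snp(
    genome: AnnotatedGenome,
    contig: str,
    position: int,
    alt: str,
    ref: str | None = None,
    upstream_window: int | None = None,
) -> str:
    """Classify a point mutation by its coding effect.

    Inside a CDS the affected codon is translated before and after the change
    (reverse-complemented for minus-strand genes): same amino acid gives
    synonymous, a gained stop gives nonsense, and any other amino-acid change
    (including a lost stop) gives missense. Outside all CDS, positions within
    the strand-aware upstream window of a gene are ``upstream``; the rest are
    ``intergenic``.
    """
    genome_ref = genome.base_at(contig, position)
    if ref is not None and ref != genome_ref:
        raise ValueError(
            f"ref mismatch at {contig}:{position}: genome has {genome_ref}, got {ref}"
        )
    if alt == genome_ref:
        raise ValueError(f"alt equals ref ({alt}) at {contig}:{position}")
    if alt not in "ACGT":
        raise ValueError(f"alt must be one of ACGT, got {alt!r}")

    gene = genome.gene_at(contig, position)
    if gene is None:
        if genome.is_upstream(contig, position, upstream_window):
            return UPSTREAM
        return INTERGENIC

    seq = genome.contigs[contig]
    if gene.strand == "+":
        offset = position - gene.start
        codon_start = gene.start + 3 * (offset // 3)
        codon = seq[codon_start - 1 : codon_start + 2]
        within = offset % 3
        new_base = alt
    else:
        # Coding coordinates run from gene.end leftwards on the complement.
        offset = gene.end - position
        codon_hi = gene.end - 3 * (offset // 3)  # coding-frame codon, genomic coords
        codon = seq[codon_hi - 3 : codon_hi].translate(_COMPLEMENT)[::-1]
        within = offset % 3
        new_base = alt.translate(_COMPLEMENT)

    mutated = codon[:within] + new_base + codon[within + 1 :]
    aa_old = str(Seq(codon).translate())
    aa_new = str(Seq(mutated).translate())
    if aa_new == aa_old:
        return SYNONYMOUS
    if aa_new == "*":
        return NONSENSE
    return MISSENSE


def simulate_snps(genome: AnnotatedGenome, n: int, seed: int | None = None) -> list[SnpRecord]:
    """Draw ``n`` SNPs uniformly over the genome and classify each.

    Positions are uniform over all sites; the alternate base is uniform over
    the three non-reference bases.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    names = sorted(genome.contigs)
    lengths = np.array([len(genome.contigs[c]) for c in names])
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    sites = rng.integers(0, offsets[-1], size=n)
    alt_idx = rng.integers(0, 3, size=n)
    records = []
    for s, ai in zip(sites, alt_idx):
        ci = int(np.searchsorted(offsets, s, side="right") - 1)
        contig = names[ci]
        pos = int(s - offsets[ci]) + 1
        ref = genome.base_at(contig, pos)
        alt = [b for b in "ACGT" if b != ref][ai]
        effect = classify_snp(genome, contig, pos, alt)
        records.append(SnpRecord(contig, pos, ref, alt, effect))
    return records


def tally_classes(snps: Iterable[SnpRecord]) -> dict[str, int]:
    """Four-class counts of a SNP list (all classes present, possibly zero)."""
    counts = dict.fromkeys(FOUR_CLASSES, 0)
    for s in snps:
        counts[s.effect_class] += 1
    return counts


@dataclass(frozen=True)
class ClassTail:
    """Bootstrap tail summary for one mutation class."""

    observed: int
    null_mean: float
    p_ge: float  # P(simulated >= observed), ties included
    p_le: float  # P(simulated <= observed), ties included

    @property
    def mid_p_upper(self) -> float:
        """Tie-corrected upper tail, P(sim > obs) + P(sim == obs)/2."""
        p_eq = self.p_ge + self.p_le - 1.0
        return self.p_ge - 0.5 * p_eq


@dataclass(frozen=True)
class BootstrapResult:
    classes: dict[str, ClassTail]
    n_boot: int
    subsample_size: int
    seed: int | None = None


def bootstrap_class_test(
    null_snps: Sequence[SnpRecord] | Mapping[str, int],
    observed_counts: Mapping[str, int],
    n_boot: int = 1000,
    seed: int | None = None,
) -> BootstrapResult:
    """Compare observed class counts to bootstrap resamples of the null.

    Each bootstrap replicate resamples, with replacement, as many SNPs from
    the null distribution as were observed in total, and tallies the four
    classes. Resampling a SNP list with replacement and tallying classes is
    distributionally a multinomial draw over the null class proportions, which
    is how the replicates are generated. ``null_snps`` may be the simulated
    SNP list itself or a precomputed class tally.
    """
    if isinstance(null_snps, Mapping):
        null_counts = dict.fromkeys(FOUR_CLASSES, 0) | dict(null_snps)
    else:
        if len(null_snps) == 0:
            raise ValueError("null_snps must be non-empty")
        null_counts = tally_classes(null_snps)
    total_null = sum(null_counts.values())
    if total_null < 1:
        raise ValueError("null distribution is empty")
    for key in observed_counts:
        if key not in FOUR_CLASSES:
            raise ValueError(f"unknown class {key!r}; expected one of {FOUR_CLASSES}")
    obs = np.array([int(observed_counts.get(c, 0)) for c in FOUR_CLASSES])
    subsample = int(obs.sum())
    if subsample < 1:
        raise ValueError("observed counts must sum to >= 1")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    probs = np.array([null_counts[c] for c in FOUR_CLASSES], dtype=float) / total_null
    rng = np.random.default_rng(seed)
    sims = rng.multinomial(subsample, probs, size=n_boot)

    classes = {}
    for j, c in enumerate(FOUR_CLASSES):
        classes[c] = ClassTail(
            observed=int(obs[j]),
            null_mean=float(probs[j] * subsample),
            p_ge=float(np.mean(sims[:, j] >= obs[j])),
            p_le=float(np.mean(sims[:, j] <= obs[j])),
        )
    return BootstrapResult(
        classes=classes, n_boot=n_boot, subsample_size=subsample, seed=seed
    )


def write_vcf(snps: Iterable[SnpRecord], path: str | Path) -> None:
    """Write SNPs as a minimal VCF (CHROM, POS, REF, ALT, INFO=class)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="Effect class">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in snps:
            fh.write(
                f"{s.contig}\t{s.position}\t.\t{s.ref}\t{s.alt}\t.\t.\tCLASS={s.effect}\n"
            )
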