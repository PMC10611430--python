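"""Annotated toy genomes: contig sequences plus strand-aware single-CDS genes.

The container is deliberately minimal — named contigs over {A,C,G,T} and a
list of non-overlapping protein-coding gene models with 1-based inclusive
coordinates — which is all the SNP effect classifier needs. Sequences are
read and written as FASTA through Biopython; annotations as a small GFF3
subset (gene + CDS features).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["GeneModel", "AnnotatedGenome"]

_BASES = "ACGT"


@dataclass(frozen=True)
class GeneModel:
    """A single-CDS protein-coding gene, 1-based inclusive coordinates."""

    name: str
    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid gene interval [{self.start}, {self.end}] for {self.name}"
            )
        if len(self) < 6 or len(self) % 3:
            raise ValueError(
                f"CDS length must be >= 6 and divisible by 3, got {len(self)}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def upstream_interval(self, window: int) -> tuple[int, int]:
        """Strand-aware upstream window as a 1-based inclusive interval."""
        if self.strand == "+":
            return (max(1, self.start - window), self.start - 1)
        return (self.end + 1, self.end + window)


@dataclass
class AnnotatedGenome:
    """Contigs plus gene models; supports point lookups for SNP classification."""

    contigs: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)
    upstream_window: int = 1000

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("genome must contain at least one contig")
        for name, seq in self.contigs.items():
            if not seq or set(seq) - set(_BASES):
                raise ValueError(f"contig {name!r} is empty or has non-ACGT bases")
        by_contig: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            if g.contig not in self.contigs:
                raise ValueError(f"gene {g.name} references unknown contig {g.contig}")
            if g.end > len(self.contigs[g.contig]):
                raise ValueError(f"gene {g.name} extends past contig end")
            by_contig.setdefault(g.contig, []).append(g)
        self._index: dict[str, tuple[list[int], list[GeneModel]]] = {}
        for contig, gl in by_contig.items():
            gl.sort(key=lambda g: g.start)
            for a, b in zip(gl, gl[1:]):
                if b.start <= a.end:
                    raise ValueError(f"genes {a.name} and {b.name} overlap")
            self._index[contig] = ([g.start for g in gl], gl)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def base_at(self, contig: str, position: int) -> str:
        seq = self.contigs[contig]
        if not 1 <= position <= len(seq):
            raise ValueError(f"position {position} outside contig {contig}")
        return seq[position - 1]

    def gene_at(self, contig: str, position: int) -> GeneModel | None:
        """The gene whose CDS covers ``position``, or None."""
        starts, gl = self._index.get(contig, ([], []))
        i = bisect.bisect_right(starts, position) - 1
        if i >= 0 and gl[i].start <= position <= gl[i].end:
            return gl[i]
        return None

    def is_upstream(self, contig: str, position: int, window: int | None = None) -> bool:
        """True if ``position`` lies in the strand-aware upstream window of a gene."""
        w = self.upstream_window if window is None else window
        for g in self._index.get(contig, ([], []))[1]:
            lo, hi = g.upstream_interval(w)
            if lo <= position <= hi:
                return True
        return False

    # ---- IO --------------------------------------------------------------

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.contigs.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, seq in self.contigs.items():
                fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
            for g in self.genes:
                attrs = f"ID={g.name}"
                fh.write(
                    f"{g.contig}\tgroupsel\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
                fh.write(
                    f"{g.contig}\tgroupsel\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                    f"ID={g.name}.cds;Parent={g.name}\n"
                )

    @classmethod
    def read(
        cls, fasta: str | Path, gff3: str | Path, upstream_window: int = 1000
    ) -> "AnnotatedGenome":
        contigs = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")
        }
        genes = []
        with open(gff3) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 9 or cols[2] != "CDS":
                    continue
                name = dict(
                    kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
                ).get("Parent") or cols[8]
                genes.append(
                    GeneModel(
                        name=name,
                        contig=cols[0],
                        start=int(cols[3]),
                        end=int(cols[4]),
                        strand=cols[6],
                    )
                )
        return cls(contigs=contigs, genes=genes, upstream_window=upstream_window)
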