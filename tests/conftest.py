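import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from groupsel.genomes import AnnotatedGenome, GeneModel

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_genome():
    """Hand-built 60 bp genome: one forward gene, one reverse gene.

    gene_plus  (+, 11..22): ATG GGT TGG TAA
    gene_minus (-, 41..49): coding ATG CAA TAA, embedded as its reverse
    complement TTATTGCAT. Upstream windows are 5 bp (6..10 and 50..54).
    """
    seq = (
        "ACGTACGTAC"  # 1-10   intergenic / upstream of gene_plus
        "ATGGGTTGGTAA"  # 11-22  gene_plus CDS
        "ACGTACGTACGTACGTAC"  # 23-40  intergenic
        "TTATTGCAT"  # 41-49  gene_minus CDS (revcomp of ATGCAATAA)
        "ACGTACGTACG"  # 50-60  upstream of gene_minus / intergenic
    )
    return AnnotatedGenome(
        contigs={"chr1": seq},
        genes=[
            GeneModel("gene_plus", "chr1", 11, 22, "+"),
            GeneModel("gene_minus", "chr1", 41, 49, "-"),
        ],
        upstream_window=5,
    )
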