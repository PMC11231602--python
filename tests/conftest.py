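import numpy as np
import pytest

from malines.genome_io import (
    AnnotationSet,
    GenomicInterval,
    ReferenceGenome,
)
from malines.spectrum import MutationRecord


@pytest.fixture
def toy_genome():
    """Two small chromosomes with runs, both strands' contexts, and an N."""
    return ReferenceGenome(
        {
            "chr1": "ACGTACGTGCAACATTTCCTAAACCTGAAAAAAAAAAAG",
            "chr2": "TTTTTTTTTTTCGGATNATATATACCCGGG",
        }
    )


@pytest.fixture
def toy_annotation(toy_genome):
    mask = [
        GenomicInterval(c, 0, toy_genome.length(c))
        for c in toy_genome.chromosomes
    ]
    coding = [GenomicInterval("chr1", 0, 20), GenomicInterval("chr2", 10, 20)]
    return AnnotationSet.from_coding(coding, mask)


@pytest.fixture
def rng():
    return np.random.default_rng(20240521)


def make_mutation(
    chrom="chr1",
    pos=0,
    ref="A",
    alt="C",
    isolate="iso1",
    genotype="gt",
    mclass="substitution",
    indel_size=0,
):
    return MutationRecord(chrom, pos, ref, alt, isolate, genotype, mclass, indel_size)


@pytest.fixture
def mutation_factory():
    return make_mutation
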