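import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles importable as module

from mitocompare.mito_io import (
    GeneFeature,
    GenomeSequence,
    Interval,
    IntronFeature,
    MitogenomeAnnotation,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_annotation(residues, genes=(), introns=(), species="Testus testus",
                    circular=True):
    return MitogenomeAnnotation(
        genome=GenomeSequence(id="test", residues=residues, circular=circular),
        genes=tuple(genes),
        introns=tuple(introns),
        species=species,
    )


@pytest.fixture
def two_exon_plus_annotation():
    """10 kb genome: one 1 kb '+' CDS split by a 2 kb intron, one 500 bp rRNA.

    Gene exons: 1001..1500 and 3501..4000 (CDS 1000 bp); intron 1501..3500
    (2000 bp); rRNA 6001..6500.
    """
    rng = np.random.default_rng(5)
    residues = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 10_000)])
    gene = GeneFeature(
        name="cox2",
        feature_class="core_pcg",
        exons=(Interval(1001, 1500, "+"), Interval(3501, 4000, "+")),
    )
    intron = IntronFeature(host_gene="cox2", ordinal=1,
                           location=Interval(1501, 3500, "+"), group="I")
    rrna = GeneFeature(name="rns", feature_class="rrna",
                       exons=(Interval(6001, 6500, "+"),))
    return make_annotation(residues, [gene, rrna], [intron])
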