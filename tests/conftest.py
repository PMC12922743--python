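import numpy as np
import pytest

from enzfam.io import GeneModel, MutationEvent, Segment, SegmentProfile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_universe():
    """Ten genes on one chromosome with mixed family labels."""
    genes = []
    lengths = [1000, 1200, 900, 1100, 1000, 5000, 4800, 5200, 2000, 2100]
    fams = ["helicase"] * 3 + [None] * 3 + ["kinase"] * 2 + [None] * 2
    pos = 0
    for i, (ln, fam) in enumerate(zip(lengths, fams)):
        genes.append(
            GeneModel(f"G{i}", "chr1", pos, pos + ln, enzyme_family=fam)
        )
        pos += ln + 500
    return genes


def make_events(rows):
    """rows: (sample, gene, variant_class) triples."""
    return [MutationEvent(s, g, c) for s, g, c in rows]


@pytest.fixture
def diploid_profile():
    """One allele-specific diploid sample with a het loss on chr1."""
    return SegmentProfile(
        sample_id="S1",
        dialect="allele_specific",
        segments=[
            Segment("chr1", 0, 40_000, 2),
            Segment("chr1", 40_000, 60_000, 1),
            Segment("chr1", 60_000, 100_000, 2),
            Segment("chr2", 0, 50_000, 2),
        ],
        ploidy=2.0,
        chrom_lengths={"chr1": 100_000, "chr2": 50_000},
    )
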