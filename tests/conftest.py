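import numpy as np
import pytest

from panmod.genome_io import GeneModel, GenomicInterval, PeakSet


@pytest.fixture
def plus_gene() -> GeneModel:
    """The worked promoter/body example: a 20 kb plus-strand gene."""
    return GeneModel("gplus", GenomicInterval("chr1", 10_000, 30_000, "+"))


@pytest.fixture
def minus_gene() -> GeneModel:
    return GeneModel("gminus", GenomicInterval("chr1", 10_000, 30_000, "-"))


def make_peaks(mark: str, *spans: tuple[int, int], chrom: str = "chr1") -> PeakSet:
    return PeakSet(
        mark, [GenomicInterval(chrom, s, e) for s, e in spans]
    ).sorted()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_901)
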