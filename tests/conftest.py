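import numpy as np
import pytest

from ctcfevo.intervals import GenomicInterval, Karyotype


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def karyotype():
    return Karyotype({"chr1": 1_000_000, "chr2": 800_000, "chr3": 500_000})


def random_intervals(rng, n, karyotype, max_len=500):
    """Random valid intervals across the karyotype chromosomes."""
    chroms = list(karyotype)
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        size = karyotype[chrom]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, size - length))
        out.append(GenomicInterval(chrom, start, start + length, name=f"iv{i}"))
    return out
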