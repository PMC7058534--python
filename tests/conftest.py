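import numpy as np
import pytest

from chromoshatter import RunConfig, make_sv


@pytest.fixture
def cfg():
    return RunConfig()


def random_intra_svs(rng: np.random.Generator, n: int, chrom: str = "chr1",
                     lo: int = 1, hi: int = 1_000_000) -> list:
    """n random intrachromosomal SVs with random strand pairs."""
    strands = [("+", "-"), ("-", "+"), ("+", "+"), ("-", "-")]
    svs = []
    for k in range(n):
        a = int(rng.integers(lo, hi - 1))
        b = int(rng.integers(a + 1, hi))
        s1, s2 = strands[int(rng.integers(0, 4))]
        svs.append(make_sv(f"r{k}", chrom, a, s1, chrom, b, s2))
    return svs


def staggered_cluster(n: int, chrom: str = "chr1", start: int = 10_000,
                      step: int = 10_000, span: int = 60_000) -> list:
    """n pairwise-chained interleaved SVs with a balanced join spectrum."""
    strands = [("+", "-"), ("-", "+"), ("+", "+"), ("-", "-")]
    svs = []
    for i in range(n):
        s1, s2 = strands[i % 4]
        a = start + i * step
        svs.append(make_sv(f"{chrom}_{start}_c{i}", chrom, a, s1, chrom, a + span, s2))
    return svs
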