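import numpy as np
import pandas as pd
import pytest

from atacdyn.genome_io import GenomeLayout, GenomicInterval, PeakSet


@pytest.fixture
def genome() -> GenomeLayout:
    return GenomeLayout(("chr1", "chr2"), (100_000, 50_000))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_peaks(genome: GenomeLayout, spans, label="peaks") -> PeakSet:
    """Build a PeakSet from (chrom, start, end) tuples."""
    df = pd.DataFrame(spans, columns=["chrom", "start", "end"])
    return PeakSet(label, genome, df)


def random_intervals(rng, n, chrom="chr1", max_pos=10_000, max_width=200):
    """Random small intervals for oracle comparisons."""
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        width = int(rng.integers(1, max_width))
        out.append(GenomicInterval(chrom, start, start + width))
    return out
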