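import numpy as np
import pytest

from chromkd.genomic_io import GeneModel, GenomicInterval, Peak, SignalTrack
from chromkd.synthetic_data import ScenarioConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_config():
    """A fast scenario for unit-level end-to-end checks."""
    return ScenarioConfig(
        seed=7,
        n_chromosomes=2,
        chrom_length=400_000,
        n_genes=20,
        n_peaks=30,
        n_repression=5,
        n_recruitment=3,
        n_null_genes=200,
        n_pair_regions=30,
    )


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, 500))
        out.append(
            GenomicInterval(str(rng.choice(chroms)), start, start + length)
        )
    return out


def random_track(rng, chrom="chr1", n_runs=30, max_pos=5000):
    """Random non-overlapping runs with gaps, as a SignalTrack."""
    edges = np.sort(rng.choice(np.arange(max_pos), size=2 * n_runs, replace=False))
    runs = []
    for i in range(n_runs):
        s, e = int(edges[2 * i]), int(edges[2 * i + 1])
        if s < e:
            runs.append((s, e, float(rng.uniform(0, 10))))
    return SignalTrack({chrom: runs})


def random_genes(rng, n, chroms=("chr1", "chr2"), span=100_000):
    genes = []
    for i in range(n):
        start = int(rng.integers(0, span))
        body = int(rng.integers(1000, 10_000))
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, 4))
        cuts = np.sort(rng.choice(np.arange(1, body), size=2 * n_ex, replace=False))
        exons = tuple(
            (start + int(cuts[2 * j]), start + int(cuts[2 * j + 1]))
            for j in range(n_ex)
        )
        tss = start if strand == "+" else start + body
        genes.append(
            GeneModel(f"g{i:03d}", str(rng.choice(chroms)), strand, tss,
                      start, start + body, exons)
        )
    return genes


def random_peak(rng, chroms=("chr1", "chr2"), span=100_000):
    start = int(rng.integers(0, span))
    length = int(rng.integers(50, 1000))
    return Peak(
        GenomicInterval(str(rng.choice(chroms)), start, start + length),
        summit_offset=int(rng.integers(0, length)),
        name=f"p{start}",
    )
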