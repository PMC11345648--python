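import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from occutag.coverage import CoverageTrack
from occutag.genome import GeneModel, GenomeAnnotation
from occutag.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One full simulated dataset under default study conditions."""
    return simulate_dataset(SimulationConfig(seed=7))


@pytest.fixture
def toy_annotation():
    """Hand-built two-gene genome on one 50 kb chromosome.

    gplus:  +, [10000, 16000), exons [10000,12000) and [14000,16000)
    gminus: -, [30000, 36000), exons [30000,32000) and [34000,36000)
    One CGI over gplus's TSS, one intergenic CGI.
    """
    genes = [
        GeneModel("gplus", "chr1", "+", 10000, 16000,
                  [(10000, 12000), (14000, 16000)]),
        GeneModel("gminus", "chr1", "-", 30000, 36000,
                  [(30000, 32000), (34000, 36000)]),
    ]
    cgis = [("chr1", 9800, 10400), ("chr1", 44000, 44600)]
    return GenomeAnnotation(chrom_sizes={"chr1": 50000}, genes=genes, cgis=cgis)


def make_track(segments_by_chrom, **kwargs) -> CoverageTrack:
    """Build a CoverageTrack from {chrom: [(start, end, value), ...]}."""
    tr = CoverageTrack(**kwargs)
    for chrom, segs in segments_by_chrom.items():
        arr = np.array(segs, dtype=float)
        tr.add_chrom(chrom, arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])
    return tr


@pytest.fixture
def uniform_track(toy_annotation):
    return make_track({"chr1": [(0, 50000, 2.0)]})


def random_oracle_genome(rng, chrom_len=None):
    """Random small genome + peaks for brute-force comparisons."""
    chrom_len = chrom_len or int(rng.integers(20_000, 100_001))
    genes = []
    taken = []
    for i in range(int(rng.integers(2, 6))):
        for _ in range(50):
            length = int(rng.integers(1000, 5001))
            start = int(rng.integers(0, chrom_len - length))
            if all(start >= e or start + length <= s for s, e in taken):
                taken.append((start, start + length))
                break
        else:
            continue
        start, end = taken[-1]
        strand = "+" if rng.random() < 0.5 else "-"
        mid1 = start + int(rng.integers(200, (end - start) // 2))
        mid2 = mid1 + int(rng.integers(100, max(101, (end - mid1) // 2)))
        exons = [(start, mid1), (mid2, end)] if mid2 < end else [(start, end)]
        genes.append(GeneModel(f"g{i}", "chr1", strand, start, end, exons))
    peaks = []
    for _ in range(int(rng.integers(10, 40))):
        w = int(rng.integers(50, 800))
        s = int(rng.integers(0, chrom_len - w))
        peaks.append((s, s + w))
    return chrom_len, genes, peaks
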