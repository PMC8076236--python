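import numpy as np
import pytest

from peakscape.intervals import Genome, GenomicInterval, GenomicIntervalSet
from peakscape.simulate import SyntheticConfig, simulate


@pytest.fixture(scope="session")
def default_bundle():
    """The full synthetic bundle at default study conditions."""
    return simulate(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def small_bundle():
    """A lighter bundle for end-to-end/CLI tests."""
    return simulate(
        SyntheticConfig(seed=11, n_chrom=2, chrom_len=200_000, n_true_peaks=100,
                        n_genes=60, n_pioneer=8, n_nonpioneer=16)
    )


@pytest.fixture
def tiny_genome():
    return Genome([("chr1", 10_000), ("chr2", 8_000)])


def random_interval_set(genome, rng, n=50, max_len=400):
    ivs = []
    chroms = genome.chromosomes
    for _ in range(n):
        chrom, L = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, max(1, L - length)))
        ivs.append(GenomicInterval(chrom, start, min(start + length, L)))
    return GenomicIntervalSet(genome, ivs)


@pytest.fixture
def random_sets(tiny_genome):
    rng = np.random.default_rng(42)
    return (
        random_interval_set(tiny_genome, rng),
        random_interval_set(tiny_genome, rng),
    )
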