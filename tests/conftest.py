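import numpy as np
import pytest

from mossmap.genome import Chromosome, GenomicInterval, Marker, MarkerMap, ToyGenome


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_genome():
    """Two short named chromosomes without sequence."""
    return ToyGenome((Chromosome("chr1", 5_000_000),
                      Chromosome("chr2", 3_000_000)))


@pytest.fixture
def linear_markers(small_genome):
    """Eleven evenly spaced markers per chromosome, linear 100 cM map."""
    markers = []
    for chrom in small_genome:
        for i in range(11):
            pos = max(1, int(i * chrom.length / 10))
            markers.append(Marker(chrom.name, pos, pos / chrom.length * 100,
                                  f"{chrom.name}_m{i:02d}", "A", "C"))
    return MarkerMap(tuple(markers))
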