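import numpy as np
import pytest

from nucleofind.core_io import GenomeInfo, StrandCounts


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_genome():
    return GenomeInfo({"chr1": 10_000})


@pytest.fixture
def toy_counts(small_genome, rng):
    """Sparse random read-start counts on a 10 kb chromosome."""
    counts = StrandCounts(small_genome)
    counts.fwd["chr1"][:] = rng.poisson(0.05, 10_000)
    counts.rev["chr1"][:] = rng.poisson(0.05, 10_000)
    return counts
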