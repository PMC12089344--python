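import numpy as np
import pytest

from replikit import (
    FiringRateProfile,
    GenomeGrid,
    ModelConfig,
    SyntheticSpec,
    gen_firing_landscape,
)


@pytest.fixture
def config():
    return ModelConfig()


@pytest.fixture
def small_grid():
    return GenomeGrid.from_sizes({"chr1": 200})


def uniform_profile(f: float, n: int, name: str = "chr1") -> FiringRateProfile:
    grid = GenomeGrid.from_sizes({name: n})
    return FiringRateProfile(np.full(n, f), grid)


def single_origin_profile(
    n: int, origin: int, rate: float, background: float = 1e-10
) -> FiringRateProfile:
    grid = GenomeGrid.from_sizes({"chr1": n})
    r = np.full(n, background)
    r[origin] = rate
    return FiringRateProfile(r, grid)


@pytest.fixture
def sparse_landscape():
    """500-site landscape with 5 log-uniform origins (the Monte-Carlo testbed)."""
    return gen_firing_landscape(SyntheticSpec(n_sites=500, origin_count=5, seed=3))
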