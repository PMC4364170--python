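import numpy as np
import pytest

from cbfc.synthetic import CohortSpec, NetworkSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_net_spec():
    """Factory for a small two-network cohort spec (network 1 planted hypo)."""

    def make(**overrides):
        kw = dict(
            n_per_group=8,
            grid_shape=(20, 20, 12),
            n_volumes=120,
            networks=[
                NetworkSpec(1, cortical_size=80, cerebellar_size=60,
                            coupling_hc=0.6, coupling_sz=0.3),
                NetworkSpec(2, cortical_size=80, cerebellar_size=60,
                            coupling_hc=0.6, coupling_sz=0.6),
            ],
            rng_seed=7,
        )
        kw.update(overrides)
        return CohortSpec(**kw)

    return make


@pytest.fixture
def random_mask():
    def make(shape=(9, 9, 7), p=0.5, seed=0):
        return np.random.default_rng(seed).random(shape) < p

    return make
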