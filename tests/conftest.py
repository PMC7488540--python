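import numpy as np
import pytest

from snspmf import MultiTissueEffects, simulate_dataset


@pytest.fixture
def small_effects():
    """2 eQTLs x 3 tissues, fully observed, hand-set values."""
    return MultiTissueEffects(
        eqtl_ids=["g1:v1", "g2:v2"],
        tissue_ids=["liver", "heart", "lung"],
        X=np.array([[1.0, 2.0, 3.0], [0.5, -0.5, 1.5]]),
        SE=np.array([[1.0, 0.5, 1.0], [0.25, 1.0, 0.5]]),
        observed=np.ones((2, 3), dtype=bool),
    )


@pytest.fixture
def sim_low_noise():
    """Default-sized simulated dataset at the lowest noise level."""
    return simulate_dataset(N=100, T=10, K=5, sigma2=0.001, seed=7)


def random_effects_instance(rng, D=None, T=None, missing=0.0):
    """A random MultiTissueEffects instance for property tests."""
    D = D or int(rng.integers(3, 20))
    T = T or int(rng.integers(2, 8))
    X = rng.standard_normal((D, T))
    SE = rng.uniform(0.2, 2.0, size=(D, T))
    observed = rng.random((D, T)) >= missing
    # keep at least one observed cell per row
    for d in range(D):
        if not observed[d].any():
            observed[d, int(rng.integers(0, T))] = True
    return MultiTissueEffects(
        eqtl_ids=[f"g{d}:v{d}" for d in range(D)],
        tissue_ids=[f"t{t}" for t in range(T)],
        X=X,
        SE=SE,
        observed=observed,
    )
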