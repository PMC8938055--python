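import numpy as np
import pytest

from rankpls import RankedDataset, SimulationConfig, generate_simulation_data


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """Random 60 x 6 ordinal dataset with a planted signal."""
    cfg = SimulationConfig(
        n=60, p=6, levels_per_predictor=(3, 3, 3, 4, 4, 4),
        block_sizes=(3, 3), block_corr=0.3, n_informative=2,
        effect_size=0.8, seed=7,
    )
    data, _ = generate_simulation_data(cfg)
    return data


@pytest.fixture
def continuous_dataset(rng):
    """Well-conditioned continuous regression problem (for OLS comparisons)."""
    Z = rng.standard_normal((50, 8))
    beta = rng.standard_normal(8)
    y = Z @ beta + 0.2 * rng.standard_normal(50)
    return RankedDataset(Z=Z, y=y)
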