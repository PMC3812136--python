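import numpy as np
import pytest

from ffloops.synthetic_data import SimulationConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def default_sim():
    """One planted simulation at the default study conditions, shared."""
    return simulate(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def labeled_sim():
    """Two-class simulation at the prostate-cohort scale (111/28 split)."""
    from ffloops.synthetic_data import preset

    cfg = preset("prostate_like")
    cfg = SimulationConfig(**{**cfg.__dict__, "seed": 11})
    return simulate(cfg)
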