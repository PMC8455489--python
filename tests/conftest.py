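import numpy as np
import pytest

from prefdecode.simulate import SimulationConfig, simulate_dataset


def small_config(**kw) -> SimulationConfig:
    """Desk-scale configuration used across tests (12^3 grid, 8 trials)."""
    defaults = dict(
        n_subjects=4, grid_dims=(12, 12, 12), n_items=8, n_reps=1,
        roi_specs=(((6, 6, 6), 4.5),), seed=7,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_study():
    """Small fully simulated study shared by read-only tests."""
    return simulate_dataset(small_config(), keep_bold=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
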