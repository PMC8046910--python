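import numpy as np
import pytest

from ctpnet.synthetic import SyntheticSceneConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene():
    """Reduced-size scene for fast unit tests (same statistical structure)."""
    return SyntheticSceneConfig(grid_shape=(18, 20, 18), roi_n_voxels=100,
                                n_volumes_rest=80, event_times=(6, 21, 36, 51),
                                n_volumes_task=130, n_trials_task=6, seed=7)


@pytest.fixture(scope="session")
def default_rest_dataset():
    """One default-size resting subject, shared across tests."""
    from ctpnet.synthetic import generate_resting_run
    return generate_resting_run(SyntheticSceneConfig(seed=11))
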