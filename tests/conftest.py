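import numpy as np
import pytest

from bubbleflow import BolusParams, MicrographConfig, SceneConfig


@pytest.fixture
def default_bolus() -> BolusParams:
    return BolusParams(A=1.0, alpha=2.0, beta=5.0, t0=0.0, noise_sd=0.0, seed=0)


@pytest.fixture
def small_scene() -> SceneConfig:
    """A reduced scene for fast structural tests."""
    return SceneConfig(grid_shape=(24, 24), duration=60.0, seed=7)


@pytest.fixture
def micrograph_config() -> MicrographConfig:
    return MicrographConfig(n_bubbles=20, diameter_sd=0.0, seed=3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
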