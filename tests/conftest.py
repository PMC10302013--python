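import numpy as np
import pytest

from shootpheno.synth import StressModel, TrialConfig, generate_trial


@pytest.fixture(scope="session")
def small_trial():
    """A small rendered trial shared by segmentation/trait/pipeline tests."""
    cfg = TrialConfig(
        n_varieties=3,
        plots_unstressed=1,
        plots_treated=1,
        n_individuals=6,
        days=(-7, 14),
        views=("vertical", "horizontal"),
        seed=7,
    )
    return cfg, generate_trial(cfg)


@pytest.fixture(scope="session")
def noise_free_trial():
    """Noise-free trial: renders match latent state almost exactly."""
    cfg = TrialConfig(
        n_varieties=2,
        plots_unstressed=1,
        plots_treated=1,
        n_individuals=4,
        days=(0, 14),
        views=("vertical",),
        area_noise=0.0,
        vigor_noise=0.0,
        color_noise=0.0,
        seed=11,
    )
    return cfg, generate_trial(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
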