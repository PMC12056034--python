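import numpy as np
import pytest

import visforage as vf


@pytest.fixture(scope="session")
def noiseless_params() -> vf.ForagerParams:
    """A forager whose taps land exactly on the attended part's centroid."""
    return vf.ForagerParams(
        p_switch_att=0.41, motor_sigma_px=0.0, com_weight=0.0, error_rate=0.0
    )


@pytest.fixture(scope="session")
def small_experiment(noiseless_params):
    """3 participants x 4 trials, zero noise; returns (taplog, ground truth)."""
    return vf.simulate_experiment(
        3, 4, vf.PatchConfig(), [noiseless_params] * 3, seed=42
    )


@pytest.fixture(scope="session")
def small_labeled(small_experiment):
    taplog, truth = small_experiment
    return vf.preprocess.label_taps(taplog, truth["patches"])


@pytest.fixture(scope="session")
def default_patch() -> vf.Patch:
    return vf.generate_patch(vf.PatchConfig(), seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
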