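import numpy as np
import pytest

from facecode.synth import default_truth, downscale_dataset, generate_dataset


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def exact_truth():
    """Study truth with the within-subject nuisances switched off.

    In this configuration the shape/texture decoupling is exact: the two
    expressions of a subject share one texture draw and differ only in the
    mouth landmarks, with no pose or annotation jitter.
    """
    t = default_truth()
    t.texture_within_fraction = 0.0
    t.pose_translation_sd = 0.0
    t.pose_log_scale_sd = 0.0
    t.pose_rotation_sd = 0.0
    t.landmark_noise_sd = 0.0
    t.idiosyncratic_texture_sd = 0.0
    return t


@pytest.fixture(scope="session")
def bench100(truth):
    """The benchmark dataset: 50 subjects x 2 expressions at 100x120."""
    return generate_dataset(truth, 50, 2, seed=1)


@pytest.fixture(scope="session")
def bench50(bench100):
    return downscale_dataset(bench100, 50)


@pytest.fixture(scope="session")
def exact_bench(exact_truth):
    return generate_dataset(exact_truth, 20, 2, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
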