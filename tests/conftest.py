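import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def easy_indices():
    """Small train/val splits of easy synthetic scenes (session-cached)."""
    from tddet.synthetic import SceneConfig, generate_dataset

    cfg = SceneConfig.easy()
    train = generate_dataset(cfg, 20, None, seed=123)
    val = generate_dataset(cfg, 10, None, seed=999, split="test")
    return train, val


@pytest.fixture(scope="session")
def tiny_detector_factory():
    from tddet.detector import build_tiny_detector

    return build_tiny_detector
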