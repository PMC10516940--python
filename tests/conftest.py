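import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from iacsim import MixtureSpec, ScoreModel


@pytest.fixture
def two_class_model() -> ScoreModel:
    return ScoreModel(("background", "target"), separability=2.0)


@pytest.fixture
def sharp_model() -> ScoreModel:
    """Effectively perfect classifier: argmax equals the true label."""
    return ScoreModel(("background", "target"), separability=20.0)


@pytest.fixture
def quality_model() -> ScoreModel:
    return ScoreModel(
        ("background", "debris", "out_of_focus", "target"), separability=3.0
    )


@pytest.fixture
def rare_mixture() -> MixtureSpec:
    return MixtureSpec({"target": 1e-3, "background": 1 - 1e-3}, "target")


def brute_force_auc(target: np.ndarray, background: np.ndarray) -> float:
    """Mann-Whitney pair-ordering statistic: P(t > b) + P(t == b)/2."""
    t = np.asarray(target, dtype=float)[:, None]
    b = np.asarray(background, dtype=float)[None, :]
    n_pairs = t.size * b.size
    return float(((t > b).sum() + 0.5 * (t == b).sum()) / n_pairs)
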