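import numpy as np
import pytest

from plasmaselect.datamodel import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_expression(n_features=20, n_samples=10, seed=0, detected=None):
    rng = np.random.default_rng(seed)
    values = rng.normal(8.0, 1.0, size=(n_features, n_samples))
    if detected is None:
        detected = np.ones_like(values, dtype=bool)
    return ExpressionMatrix(
        feature_ids=[f"mir{i:03d}" for i in range(n_features)],
        sample_ids=[f"S{j:03d}" for j in range(n_samples)],
        values=values,
        detected=detected,
    )


def make_labeled_expression(n_features=50, n_case=13, n_control=26, seed=0,
                            spike=(), delta=0.0, noise_sd=1.0, baseline=8.0):
    """Expression matrix plus a case/control label dict; spiked features
    are shifted up in cases by delta."""
    rng = np.random.default_rng(seed)
    n = n_case + n_control
    values = rng.normal(baseline, noise_sd, size=(n_features, n))
    for f in spike:
        values[f, :n_case] += delta
    X = ExpressionMatrix(
        feature_ids=[f"mir{i:03d}" for i in range(n_features)],
        sample_ids=[f"S{j:03d}" for j in range(n)],
        values=values,
        detected=np.ones_like(values, dtype=bool),
    )
    labels = {
        s: ("case" if j < n_case else "control") for j, s in enumerate(X.sample_ids)
    }
    return X, labels


@pytest.fixture
def small_expression():
    return make_expression(n_features=20, n_samples=10, seed=42)
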