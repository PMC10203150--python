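import numpy as np
import pytest

from delmep.evaluation import split_train_test
from delmep.model import ModelSpec, fit_on_dataset
from delmep.synthetic import SyntheticConfig, generate_dataset


def make_trace_samples(rng, n=120):
    """A random MEP-like trimmed trace: noise plus an occasional deflection."""
    x = rng.normal(0.0, 3.0, size=n)
    if rng.random() < 0.8:
        onset = rng.integers(5, n - 30)
        width = rng.integers(10, 25)
        amp = rng.uniform(20.0, 400.0)
        t = np.arange(n - onset)
        x[onset:] += amp * (t / width) * np.exp(1 - t / width) * np.sin(
            2 * np.pi * t / (2.0 * width)
        )
    return x


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """Fast multi-subject dataset with short epochs (still covers 10-50 ms)."""
    cfg = SyntheticConfig(
        n_subjects=3, traces_per_subject=12, epoch_ms=(-50.0, 100.0), seed=42
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def recovery_setup():
    """The parameter-recovery study: 5004 default-condition traces,
    80/20 split, one model trained with the default recipe.

    Session-scoped because several checks (held-out accuracy, amplitude
    strata, estimator comparison) reuse the same trained model.
    """
    cfg = SyntheticConfig(n_subjects=9, traces_per_subject=556, seed=11)
    ds = generate_dataset(cfg)
    train_ds, test_ds = split_train_test(ds, ratio=0.8, seed=11)
    model = fit_on_dataset(train_ds, ModelSpec(seed=11))
    return ds, train_ds, test_ds, model
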