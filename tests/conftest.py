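import numpy as np
import pytest

from selstab.datasets import Dataset, SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_xy(rng):
    """n=60, p=8 with a clear sparse signal (coefficients 2, -1.5, 0.5)."""
    n, p = 60, 8
    X = rng.standard_normal((n, p))
    beta = np.array([2.0, 0, 0, -1.5, 0, 0, 0, 0.5])
    y = 1.0 + X @ beta + rng.normal(0, 0.5, n)
    return X, y


@pytest.fixture(scope="session")
def small_spec():
    """A fast small analogue of the study structure (n=150, p=24)."""
    return SyntheticSpec(
        n_subjects=150,
        n_covariates=24,
        block_sizes=(6, 6, 6, 1, 1, 1, 1, 1, 1),
        within_block_correlation=0.6,
        binary_fraction=0.2,
        true_support=(0, 6),
        true_coefficients=(8.0, 4.0),
        noise_sd=2.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_ds(small_spec):
    return generate_dataset(small_spec)


def make_dataset(X, y):
    p = X.shape[1]
    return Dataset(
        X=X,
        y=y,
        covariate_ids=[f"V{j + 1}" for j in range(p)],
        covariate_kind=["continuous"] * p,
    )
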