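import numpy as np
import pytest

import spmsens as sp


@pytest.fixture(scope="session")
def two_arm_cfg():
    return sp.two_arm_config(N=150, M=6, seed=42)


@pytest.fixture(scope="session")
def two_arm_data(two_arm_cfg):
    df, truth = sp.make_dataset(two_arm_cfg)
    return df, truth


@pytest.fixture(scope="session")
def two_arm_records(two_arm_data):
    return two_arm_data[1]["records"]


@pytest.fixture(scope="session")
def dropout_subject(two_arm_records):
    """A subject with interior dropout (1 < S < M)."""
    return next(r for r in two_arm_records if 1 < r.S < r.M)


@pytest.fixture(scope="session")
def true_params(two_arm_cfg):
    return two_arm_cfg.true_params


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_toy_subject(M=4, S=3, gamma=(0.23, 0.28), y=None, seed=0):
    """Small handmade subject for closed-form checks."""
    rng = np.random.default_rng(seed)
    times = np.arange(M) / (M - 1)
    X = np.column_stack([np.ones(M), times])
    Z = X.copy()
    Xh = np.column_stack([np.ones(M - 1), times[:-1]])
    if y is None:
        y = rng.standard_normal(M)
    observed = np.arange(1, M + 1) <= S
    return sp.SubjectRecord(
        id="toy",
        S=S,
        y=np.where(observed, y, np.nan),
        observed=observed,
        X_long=X,
        Z_long=Z,
        X_haz=Xh,
    )


def make_toy_params(beta=(0.0, 0.0), alpha=(0.5, -0.3), gamma=(0.23, 0.28),
                    delta=-0.2, sigma1=0.8, sigma2=1.0, sigma_eps=0.5):
    return sp.SPMParameters(
        beta=np.asarray(beta, float),
        alpha=np.asarray(alpha, float),
        gamma=np.asarray(gamma, float),
        re_cov=sp.RandomEffectsCov(delta=delta, sigma1=sigma1, sigma2=sigma2),
        sigma_eps=sigma_eps,
    )
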