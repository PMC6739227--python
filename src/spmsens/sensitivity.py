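"""Delta-based sensitivity model anchored at the default extrapolation.

After dropout at visit S < M the outcome is assumed piecewise linear:

    Y_ik = x_ik' beta + b_i1 + b_i2 t_k + Delta_i (t_k - t_S)_+ + eps_ik,

with b drawn from the *default* (closed skew-normal) conditional law, so
that Delta_i = 0 recovers the default extrapolation exactly.  The
per-subject slope deviation is

    Delta_i = a * (M - S_i)/(M - 1) * sigma_{b_i2},

where a is a single global sensitivity parameter with an informative
prior (triangular on [-2, 0] with mode -1 by default: at most a
two-standard-deviation extra decline for the earliest dropouts, centered
at one) and sigma_{b_i2} is the posterior SD of the random slope given
the subject's observed data.  Because a multiplies an unidentified
deviation, nothing here ever touches the observed-data fit.

Computing sigma_{b_i2} exactly needs high-dimensional Gaussian CDFs per
subject; :func:`sigma_b2_lookup` also offers the group-average
approximation (mean exact value within covariate groups).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import triang

from .csn import conditional_random_effects, csn_moments, default_extrapolation_sample
from .design import SPMParameters, SubjectRecord

__all__ = [
    "SensitivityConfig",
    "sample_a",
    "delta_i",
    "sensitivity_extrapolation_sample",
    "sigma_b2_lookup",
]


@dataclass(frozen=True)
class SensitivityConfig:
    """Prior for the global sensitivity parameter and sigma_{b2} mode.

    ``sigma_mode`` is "exact" (per-subject closed-form SD) or "group"
    (average exact SDs within covariate groups, the speed-up used at
    cohort scale).  ``group_cols`` names the grouping covariates.
    """

    prior_low: float = -2.0
    prior_mode: float = -1.0
    prior_high: float = 0.0
    sigma_mode: str = "group"
    group_cols: tuple = ()

    def __post_init__(self):
        if not self.prior_low <= self.prior_mode <= self.prior_high:
            raise ValueError("need prior_low <= prior_mode <= prior_high")
        if not self.prior_low < self.prior_high:
            raise ValueError("degenerate prior support")
        if self.sigma_mode not in ("exact", "group"):
            raise ValueError("sigma_mode must be 'exact' or 'group'")


def sample_a(config: SensitivityConfig, seed=None, size=None):
    """Draw from the triangular prior of the sensitivity parameter a."""
    rng = np.random.default_rng(seed)
    width = config.prior_high - config.prior_low
    c = (config.prior_mode - config.prior_low) / width
    draw = triang.rvs(c, loc=config.prior_low, scale=width, size=size, random_state=rng)
    return float(draw) if size is None else draw


def delta_i(a: float, S: int, M: int, sigma_b2: float) -> float:
    """Post-dropout slope deviation Delta_i = a (M - S)/(M - 1) sigma_{b_i2}.

    Zero for completers (S = M); largest (a * sigma) for dropout right
    after baseline (S = 1); a/(M-1) * sigma for dropout at the last
    pre-final visit.
    """
    if not 1 <= S <= M:
        raise ValueError("S must lie in 1..M")
    if sigma_b2 < 0:
        raise ValueError("sigma_b2 must be nonnegative")
    return a * (M - S) / (M - 1) * sigma_b2


def sensitivity_extrapolation_sample(
    subject: SubjectRecord,
    params: SPMParameters,
    a: float,
    sigma_b2: float,
    n: int,
    seed=None,
    *,
    visits=None,
    csn=None,
):
    """Draws of the missing outcomes under the piecewise-linear deviation.

    Shares the random streams of :func:`default_extrapolation_sample`, so
    a = 0 reproduces the default draws bit for bit under the same seed.
    The hinge (t_k - t_S)_+ uses the standardized visit times carried in
    the random-effects design, hence requires intercept+slope structure.
    """
    Z = subject.Z_long
    if Z.shape[1] != 2 or not np.allclose(Z[:, 0], 1.0):
        raise ValueError("sensitivity model requires z = (1, t) random-effect structure")
    if visits is None:
        visits = np.arange(subject.S + 1, subject.M + 1)
    visits = np.asarray(visits, dtype=int)
    base = default_extrapolation_sample(subject, params, n, seed, visits=visits, csn=csn)
    t_k = Z[visits - 1, 1]
    t_S = Z[subject.S - 1, 1]
    hinge = np.clip(t_k - t_S, 0.0, None)
    dlt = delta_i(a, subject.S, subject.M, sigma_b2)
    return base + dlt * hinge


def sigma_b2_lookup(
    records,
    params: SPMParameters,
    *,
    groups=None,
    abseps: float = 1e-6,
    min_group_size: int = 1,
):
    """Posterior SD of the random slope given each subject's observed data.

    With ``groups=None``: the exact per-subject value, the square root of
    the slope entry of the closed skew-normal covariance.  With a group
    label per subject: exact values are averaged within groups and the
    group mean assigned to every member (the cohort-scale approximation);
    a group smaller than ``min_group_size`` falls back to the exact
    per-subject values with a warning.
    """
    exact = np.array(
        [
            float(np.sqrt(csn_moments(conditional_random_effects(r, params), abseps=abseps)[1][1, 1]))
            for r in records
        ]
    )
    if groups is None:
        return exact
    groups = np.asarray(groups)
    if groups.shape[0] != len(records):
        raise ValueError("one group label per subject is required")
    out = exact.copy()
    for g in np.unique(groups):
        mask = groups == g
        if mask.sum() < min_group_size:
            warnings.warn(
                f"group {g!r} has fewer than {min_group_size} subjects; "
                "using exact per-subject values there"
            )
            continue
        out[mask] = exact[mask].mean()
    return out
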