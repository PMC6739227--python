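"""Observed-data likelihood components of the shared parameter model.

The joint model couples a Gaussian linear mixed model for the complete
longitudinal outcome,

    Y_ij = x_ij' beta + z_ij' b_i + eps_ij,   eps_ij ~ N(0, sigma_eps^2),

with a probit model for the discrete hazard of dropout at visit l,

    lambda_il = 1 - Phi( x_{S,il}' alpha + (W_il b_i)' gamma_l ),

linked through the shared random effects b_i ~ N(0, Sigma_b).  Given b_i
and covariates, outcome and dropout are conditionally independent; all
functions below therefore condition on b.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import multivariate_normal, norm

from .design import RandomEffectsCov, SPMParameters, SubjectRecord

__all__ = [
    "sigma_b_from_cholesky",
    "hazard_linear_predictors",
    "discrete_hazard",
    "dropout_loglik",
    "longitudinal_loglik",
    "joint_loglik_given_b",
]


def sigma_b_from_cholesky(re_cov: RandomEffectsCov) -> np.ndarray:
    """Random-effects covariance implied by (delta, sigma1, sigma2).

    Sigma_b = [[s1^2, d s1^2], [d s1^2, d^2 s1^2 + s2^2]]; positive
    definite for every finite delta and positive sigmas.
    """
    return re_cov.sigma_b


def hazard_linear_predictors(
    subject: SubjectRecord, b: np.ndarray, params: SPMParameters
) -> np.ndarray:
    """eta_l = x_{S,l}' alpha + (W_l b)' gamma_l for l = 1..M-1."""
    b = np.asarray(b, dtype=float).ravel()
    eta = subject.X_haz @ params.alpha
    Wb = subject.W @ b  # (M-1, q_S)
    if params.visit_specific_gamma:
        eta = eta + np.einsum("lk,lk->l", Wb, params.gamma)
    else:
        eta = eta + Wb @ params.gamma
    return eta


def discrete_hazard(
    subject: SubjectRecord, visit: int, b: np.ndarray, params: SPMParameters
) -> float:
    """Probability of dropping out at hazard index ``visit`` (1..M-1).

    lambda = 1 - Phi(eta) where eta is the probit linear predictor; the
    complement form is evaluated as the normal survival function for
    numerical accuracy in the tails.
    """
    if not 1 <= visit <= subject.M - 1:
        raise IndexError("hazard index must lie in 1..M-1")
    eta = hazard_linear_predictors(subject, b, params)[visit - 1]
    return float(norm.sf(eta))


def dropout_loglik(subject: SubjectRecord, b, params: SPMParameters) -> float:
    """Log-probability of the observed dropout visit S given b.

    Three cases: an event at visit 1; survival to S-1 followed by an
    event at S for interior dropout; pure survival through M-1 for a
    completer (administrative censoring).
    """
    eta = hazard_linear_predictors(subject, b, params)
    S, M = subject.S, subject.M
    # survival contributions: no event at hazard indices 1..S-1 (capped at M-1)
    n_surv = min(S - 1, M - 1) if S < M else M - 1
    ll = float(norm.logcdf(eta[:n_surv]).sum())
    if S < M:
        ll += float(norm.logcdf(-eta[S - 1]))  # event: lambda = Phi(-eta)
    return ll


def longitudinal_loglik(subject: SubjectRecord, b, params: SPMParameters) -> float:
    """Gaussian log-density of the observed outcome entries given b.

    Only rows with an observed outcome contribute; intermittent gaps are
    simply dropped (latent ignorability), so the value is invariant to
    the design rows of unobserved visits.
    """
    y_o, X_o, Z_o = subject.observed_rows()
    if y_o.size == 0:
        raise ValueError("subject has no observed outcomes")
    b = np.asarray(b, dtype=float).ravel()
    resid = y_o - X_o @ params.beta - Z_o @ b
    return float(norm.logpdf(resid, scale=params.sigma_eps).sum())


def joint_loglik_given_b(subject: SubjectRecord, b, params: SPMParameters) -> float:
    """Integrand of the observed-data likelihood: f(Y^o|b) f(S|b) f(b)."""
    b = np.asarray(b, dtype=float).ravel()
    lp_b = multivariate_normal.logpdf(b, mean=np.zeros(b.size), cov=params.re_cov.sigma_b)
    return longitudinal_loglik(subject, b, params) + dropout_loglik(subject, b, params) + float(lp_b)
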