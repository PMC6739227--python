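"""Gaussian orthant probabilities and one-sided truncated-normal moments.

These are the numerical primitives behind the closed skew-normal
conditional law of the random effects: its normalizing constant is an
orthant probability of a correlated Gaussian, and its exact moments
reduce to the mean and covariance of a multivariate normal truncated to
the positive orthant (Tallis-type formulas, requiring m- and
(m-1)/(m-2)-dimensional Gaussian CDF evaluations).

Orthant probabilities use scipy's quasi-Monte-Carlo integrator; a fixed
internal stream makes every evaluation deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import multivariate_normal, norm

__all__ = ["mvn_orthant_prob", "truncated_mvn_moments"]

_QMC_SEED = 20190401  # fixed stream: orthant probabilities are deterministic


def _mvncdf(upper: np.ndarray, cov: np.ndarray, abseps: float, releps: float = 0.0) -> float:
    """P(N(0, cov) <= upper), with fast exact paths for dims 0 and 1."""
    upper = np.atleast_1d(np.asarray(upper, dtype=float))
    d = upper.size
    if d == 0:
        return 1.0
    if d == 1:
        return float(norm.cdf(upper[0] / np.sqrt(float(np.atleast_2d(cov)[0, 0]))))
    return float(
        multivariate_normal.cdf(
            upper,
            mean=np.zeros(d),
            cov=cov,
            abseps=abseps,
            releps=releps,
            rng=np.random.default_rng(_QMC_SEED),
        )
    )


def mvn_orthant_prob(mean, cov, abseps: float = 1e-8, releps: float = 0.0) -> float:
    """P(V >= 0 componentwise) for V ~ N(mean, cov)."""
    return _mvncdf(
        np.asarray(mean, dtype=float), np.asarray(cov, dtype=float), abseps, releps
    )


def truncated_mvn_moments(mean, cov, abseps: float = 1e-7):
    """Exact mean and covariance of V ~ N(mean, cov) given V >= 0.

    Uses the Tallis first-moment identity and its second-moment
    extension for one-sided truncation.  Returns ``(tmean, tcov, p)``
    where ``p`` is the orthant probability.

    Raises
    ------
    FloatingPointError
        If the orthant probability is numerically zero, in which case
        the conditional moments are not recoverable at this tolerance.
    """
    m = np.asarray(mean, dtype=float).ravel()
    S = np.atleast_2d(np.asarray(cov, dtype=float))
    d = m.size
    a = -m  # truncation bounds of the centered variable W = V - mean >= a
    p = _mvncdf(m, S, abseps)
    if not np.isfinite(p) or p <= 1e-300:
        raise FloatingPointError(
            f"orthant probability underflow (p={p!r}, dim={d}); the truncation "
            "region carries no numerically resolvable mass"
        )
    if d == 1:
        s = float(np.sqrt(S[0, 0]))
        z = a[0] / s
        # standard one-sided truncated normal
        lam = float(norm.pdf(z) / norm.sf(z))
        tmean = float(m[0] + s * lam)
        tvar = S[0, 0] * (1.0 + z * lam - lam**2)
        return np.array([tmean]), np.array([[tvar]]), p

    idx = np.arange(d)
    F1 = np.zeros(d)
    for k in range(d):
        rest = idx[idx != k]
        fk = norm.pdf(a[k], scale=np.sqrt(S[k, k]))
        cm = S[rest, k] * (a[k] / S[k, k])
        cc = S[np.ix_(rest, rest)] - np.outer(S[rest, k], S[k, rest]) / S[k, k]
        F1[k] = fk * _mvncdf(cm - a[rest], cc, abseps)
    EW = S @ F1 / p

    M2 = p * S.copy()
    for k in range(d):
        M2 += np.outer(S[:, k], S[:, k]) * (a[k] * F1[k] / S[k, k])
    # bivariate-boundary terms; F_kq is symmetric in (k, q), so each pair
    # is evaluated once and reused for both orderings
    for k in range(d):
        for q in range(k + 1, d):
            kq = [k, q]
            rest = [r for r in range(d) if r not in kq]
            Skq = S[np.ix_(kq, kq)]
            f2 = multivariate_normal.pdf(a[kq], mean=np.zeros(2), cov=Skq)
            if rest and f2 > 0:
                B = S[np.ix_(rest, kq)] @ np.linalg.inv(Skq)
                cm = B @ a[kq]
                cc = S[np.ix_(rest, rest)] - B @ S[np.ix_(kq, rest)]
                f2 *= _mvncdf(cm - a[rest], cc, abseps)
            coef_q = S[:, q] - S[:, k] * (S[k, q] / S[k, k])
            coef_k = S[:, k] - S[:, q] * (S[k, q] / S[q, q])
            M2 += np.outer(S[:, k], coef_q) * f2
            M2 += np.outer(S[:, q], coef_k) * f2
    M2 /= p
    tcov = M2 - np.outer(EW, EW)
    tcov = 0.5 * (tcov + tcov.T)
    return m + EW, tcov, p
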