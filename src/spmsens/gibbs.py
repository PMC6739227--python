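"""Blocked Gibbs sampler for the shared parameter model.

The posterior is explored by data augmentation: the per-subject random
effects b_i and one latent Gaussian variable per hazard term (the
classical latent-normal representation of the probit link) are sampled
alongside the parameters, after which every conditional is conjugate:

* (alpha, gamma) — joint Gaussian regression of the latent hazard
  variables on the hazard covariates and the shared random effects;
* beta — Gaussian regression on the observed longitudinal rows;
* b_i — bivariate Gaussian combining the N(0, Sigma_b) prior, the
  subject's observed outcome rows and its latent hazard rows;
* delta — Gaussian regression of the random slopes on the intercepts;
* sigma1^2, sigma2^2 — inverse-gamma conditionals truncated by the
  Uniform(0, 5) prior on the standard deviations (inverse-CDF draw);
* sigma_eps^2 — inverse-gamma.

Everything is vectorized over subjects and hazard rows; only shared
(visit-constant) gamma is supported when fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import invgamma, norm, truncnorm

__all__ = ["PriorSpec", "MCMCConfig", "run_chain"]


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyper-parameters.

    Defaults: N(0, 100) on beta and delta, weakly informative N(0, 4) on
    alpha and gamma, Inverse-Gamma(0.001, 0.001) (shape/rate) on
    sigma_eps^2, and Uniform(0, 5) on each random-effects innovation SD.
    """

    beta_sd: float = 10.0
    delta_sd: float = 10.0
    alpha_gamma_sd: float = 2.0
    sigma_eps_shape: float = 0.001
    sigma_eps_rate: float = 0.001
    sigma_b_upper: float = 5.0

    def __post_init__(self):
        for v in (self.beta_sd, self.delta_sd, self.alpha_gamma_sd, self.sigma_b_upper):
            if v <= 0:
                raise ValueError("prior scales must be positive")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain settings: ``draws`` is the number of retained draws per chain
    after ``burn_in`` iterations and thinning by ``thin``."""

    chains: int = 3
    burn_in: int = 5000
    draws: int = 3000
    thin: int = 5
    seed: int = 0

    def __post_init__(self):
        if min(self.chains, self.burn_in, self.draws, self.thin) < 1:
            raise ValueError("chain settings must be positive integers")


class _Stacked:
    """Flat row-stacked views of the dataset used by the sampler."""

    def __init__(self, records):
        self.N = len(records)
        self.q = records[0].Z_long.shape[1]
        if self.q != 2:
            raise ValueError("the sampler requires intercept+slope random effects (q=2)")
        yo, Xo, Zo, subj_o = [], [], [], []
        Xh, subj_h, event = [], [], []
        for i, rec in enumerate(records):
            o = rec.observed
            yo.append(rec.y[o])
            Xo.append(rec.X_long[o])
            Zo.append(rec.Z_long[o])
            subj_o.append(np.full(int(o.sum()), i))
            L = rec.S if rec.S < rec.M else rec.M - 1
            Xh.append(rec.X_haz[:L])
            subj_h.append(np.full(L, i))
            ev = np.zeros(L, dtype=bool)
            if rec.S < rec.M:
                ev[L - 1] = True
            event.append(ev)
            if not np.allclose(rec.W, np.eye(self.q)):
                raise ValueError("fitting currently assumes W = identity")
        self.yo = np.concatenate(yo)
        self.Xo = np.vstack(Xo)
        self.Zo = np.vstack(Zo)
        self.subj_o = np.concatenate(subj_o)
        self.Xh = np.vstack(Xh)
        self.subj_h = np.concatenate(subj_h)
        self.event = np.concatenate(event)
        self.n_obs = self.yo.size
        self.n_haz = self.Xh.shape[0]
        self.p = self.Xo.shape[1]
        self.pS = self.Xh.shape[1]
        # per-subject Z'Z blocks (constant across iterations)
        self.ZtZ = np.zeros((self.N, 2, 2))
        for a in range(2):
            for bcol in range(2):
                self.ZtZ[:, a, bcol] = np.bincount(
                    self.subj_o, weights=self.Zo[:, a] * self.Zo[:, bcol], minlength=self.N
                )
        self.XtX = self.Xo.T @ self.Xo


def _segment_sum(values, subj, N):
    if values.ndim == 1:
        return np.bincount(subj, weights=values, minlength=N)
    return np.column_stack(
        [np.bincount(subj, weights=values[:, k], minlength=N) for k in range(values.shape[1])]
    )


def _draw_truncated_invgamma(rng, shape, rate, upper_sq):
    """sigma^2 ~ InvGamma(shape, rate) truncated to (0, upper_sq)."""
    cap = invgamma.cdf(upper_sq, shape, scale=rate)
    if cap <= 0:
        return upper_sq * 0.999  # all conditional mass above the prior bound
    u = rng.uniform(0.0, cap)
    return float(invgamma.ppf(u, shape, scale=rate))


def run_chain(
    stacked: _Stacked,
    priors: PriorSpec,
    n_iter: int,
    burn_in: int,
    thin: int,
    rng,
    *,
    gamma_zero: bool = False,
    init_scale: float = 0.0,
    store_b: bool = True,
):
    """Run one Gibbs chain; returns (draws matrix, parameter names, b draws).

    ``init_scale`` perturbs the starting point (used to overdisperse
    chains); ``gamma_zero`` fixes the association at zero, reducing the
    fit to an ignorable-dropout linear mixed model plus a free-standing
    probit dropout model.
    """
    st = stacked
    N, p, pS = st.N, st.p, st.pS
    q = 2
    beta = init_scale * rng.standard_normal(p)
    alpha = init_scale * rng.standard_normal(pS)
    gamma = np.zeros(q)
    delta = init_scale * rng.standard_normal()
    sig1_sq = float(np.exp(init_scale * rng.standard_normal())) if init_scale else 1.0
    sig2_sq = float(np.exp(init_scale * rng.standard_normal())) if init_scale else 1.0
    sig_eps_sq = float(np.exp(init_scale * rng.standard_normal())) if init_scale else 1.0
    b = np.zeros((N, q))

    n_keep = (n_iter - burn_in) // thin
    names = (
        [f"beta[{k}]" for k in range(p)]
        + [f"alpha[{k}]" for k in range(pS)]
        + ["gamma[1]", "gamma[2]"]
        + ["delta", "sigma1", "sigma2", "sigma_eps"]
    )
    out = np.empty((n_keep, len(names)))
    b_out = np.empty((n_keep, N, q)) if store_b else None

    prior_prec_ag = np.eye(pS + q) / priors.alpha_gamma_sd**2
    prior_prec_beta = np.eye(p) / priors.beta_sd**2
    kept = 0
    for it in range(n_iter):
        # --- latent probit variables for every at-risk visit ---------------
        bh = b[st.subj_h]
        eta = st.Xh @ alpha + bh @ gamma
        # survival rows: w > 0 (prob Phi(eta)); event rows: w <= 0
        lo = np.where(st.event, -np.inf, -eta)
        hi = np.where(st.event, -eta, np.inf)
        w = eta + truncnorm.rvs(lo, hi, random_state=rng)

        # --- (alpha, gamma) block ------------------------------------------
        if gamma_zero:
            Dh = st.Xh
            prec = Dh.T @ Dh + prior_prec_ag[:pS, :pS]
            mean = np.linalg.solve(prec, Dh.T @ w)
            alpha = mean + np.linalg.solve(np.linalg.cholesky(prec).T, rng.standard_normal(pS))
            gamma = np.zeros(q)
        else:
            Dh = np.hstack([st.Xh, bh])
            prec = Dh.T @ Dh + prior_prec_ag
            mean = np.linalg.solve(prec, Dh.T @ w)
            draw = mean + np.linalg.solve(
                np.linalg.cholesky(prec).T, rng.standard_normal(pS + q)
            )
            alpha, gamma = draw[:pS], draw[pS:]

        # --- beta -----------------------------------------------------------
        fitted_re = np.einsum("nq,nq->n", st.Zo, b[st.subj_o])
        prec = st.XtX / sig_eps_sq + prior_prec_beta
        rhs = st.Xo.T @ (st.yo - fitted_re) / sig_eps_sq
        mean = np.linalg.solve(prec, rhs)
        beta = mean + np.linalg.solve(np.linalg.cholesky(prec).T, rng.standard_normal(p))

        # --- random effects -------------------------------------------------
        v1 = sig1_sq
        sigma_b = np.array(
            [[v1, delta * v1], [delta * v1, delta**2 * v1 + sig2_sq]]
        )
        prec_b0 = np.linalg.inv(sigma_b)
        P = st.ZtZ / sig_eps_sq + prec_b0  # (N,2,2)
        resid_o = st.yo - st.Xo @ beta
        h = _segment_sum(st.Zo * resid_o[:, None], st.subj_o, N) / sig_eps_sq
        if not gamma_zero:
            wres = w - st.Xh @ alpha
            h += _segment_sum(gamma[None, :] * wres[:, None], st.subj_h, N)
            gg = np.outer(gamma, gamma)
            nh = np.bincount(st.subj_h, minlength=N).astype(float)
            P = P + nh[:, None, None] * gg
        # batched 2x2 solve and sampling
        a11, a12, a22 = P[:, 0, 0], P[:, 0, 1], P[:, 1, 1]
        det = a11 * a22 - a12**2
        m1 = (a22 * h[:, 0] - a12 * h[:, 1]) / det
        m2 = (-a12 * h[:, 0] + a11 * h[:, 1]) / det
        # Cholesky of the covariance P^{-1} = [[a22,-a12],[-a12,a11]]/det
        c11 = a22 / det
        c12 = -a12 / det
        c22 = a11 / det
        l11 = np.sqrt(c11)
        l21 = c12 / l11
        l22 = np.sqrt(c22 - l21**2)
        z = rng.standard_normal((N, 2))
        b = np.column_stack([m1 + l11 * z[:, 0], m2 + l21 * z[:, 0] + l22 * z[:, 1]])

        # --- random-effects covariance (modified Cholesky) ------------------
        b1, b2 = b[:, 0], b[:, 1]
        prec_d = (b1 @ b1) / sig2_sq + 1.0 / priors.delta_sd**2
        mean_d = (b1 @ b2) / sig2_sq / prec_d
        delta = mean_d + rng.standard_normal() / np.sqrt(prec_d)
        upper_sq = priors.sigma_b_upper**2
        sig1_sq = _draw_truncated_invgamma(rng, (N - 1) / 2.0, (b1 @ b1) / 2.0, upper_sq)
        e2 = b2 - delta * b1
        sig2_sq = _draw_truncated_invgamma(rng, (N - 1) / 2.0, (e2 @ e2) / 2.0, upper_sq)

        # --- residual variance ---------------------------------------------
        resid = resid_o - np.einsum("nq,nq->n", st.Zo, b[st.subj_o])
        sig_eps_sq = float(
            invgamma.rvs(
                priors.sigma_eps_shape + st.n_obs / 2.0,
                scale=priors.sigma_eps_rate + (resid @ resid) / 2.0,
                random_state=rng,
            )
        )

        if it >= burn_in and (it - burn_in) % thin == 0:
            out[kept] = np.concatenate(
                [
                    beta,
                    alpha,
                    gamma,
                    [delta, np.sqrt(sig1_sq), np.sqrt(sig2_sq), np.sqrt(sig_eps_sq)],
                ]
            )
            if store_b:
                b_out[kept] = b
            kept += 1
    return out[:kept], names, (b_out[:kept] if store_b else None)
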