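import numpy as np
import pytest
from scipy.stats import kstest, norm

import spmsens as sp
from spmsens.csn import (
    ClosedSkewNormal,
    conditional_random_effects,
    csn_marginal_moments_fd,
    csn_moments,
    default_extrapolation_sample,
    sample_csn,
)

from conftest import make_toy_params, make_toy_subject


def quadrature_checks(csn, n=161, half_width=7.0):
    """Integrate the returned density on a grid; return (mass, mean, cov)."""
    sds = np.sqrt(np.diag(csn.Omega))
    g1 = np.linspace(csn.mu[0] - half_width * sds[0], csn.mu[0] + half_width * sds[0], n)
    g2 = np.linspace(csn.mu[1] - half_width * sds[1], csn.mu[1] + half_width * sds[1], n)
    B1, B2 = np.meshgrid(g1, g2, indexing="ij")
    pts = np.column_stack([B1.ravel(), B2.ravel()])
    dens = csn.pdf(pts).reshape(n, n)
    w = np.outer(np.gradient(g1), np.gradient(g2))
    mass = float((dens * w).sum())
    mean = np.array([(B1 * dens * w).sum(), (B2 * dens * w).sum()]) / mass
    cm1, cm2 = B1 - mean[0], B2 - mean[1]
    cov = (
        np.array(
            [
                [(cm1 * cm1 * dens * w).sum(), (cm1 * cm2 * dens * w).sum()],
                [(cm1 * cm2 * dens * w).sum(), (cm2 * cm2 * dens * w).sum()],
            ]
        )
        / mass
    )
    return mass, mean, cov


class TestConditionalRandomEffects:
    def test_gamma_zero_is_conjugate_gaussian_update(self):
        """Sigma_b = I, one observation with z = (1, 0), sigma_eps = 1,
        residual 2 -> posterior mean (1, 0), variance (1/2, 1)."""
        p = make_toy_params(beta=(0.0, 0.0), gamma=(0.0, 0.0), delta=0.0,
                            sigma1=1.0, sigma2=1.0, sigma_eps=1.0)
        times = np.arange(3) / 2
        X = np.zeros((3, 2))
        Z = np.column_stack([np.ones(3), np.zeros(3)])  # z = (1, 0) rows
        observed = np.array([True, False, False])
        sub = sp.SubjectRecord("t", 1, np.where(observed, 2.0, np.nan), observed,
                               X, Z, np.ones((2, 2)))
        csn = conditional_random_effects(sub, p)
        assert np.all(csn.D == 0)
        assert csn.mu[0] == pytest.approx(1.0, abs=1e-12)
        assert csn.Omega[0, 0] == pytest.approx(0.5, abs=1e-12)
        assert csn.Omega[1, 1] == pytest.approx(1.0, abs=1e-12)

    def test_factor_count_matches_dropout_pattern(self, two_arm_records, true_params):
        for rec in two_arm_records[:25]:
            csn = conditional_random_effects(rec, true_params, compute_norm=False)
            assert csn.m == (rec.S if rec.S < rec.M else rec.M - 1)

    def test_density_normalized_and_consistent_with_quadrature(self, dropout_subject, true_params):
        csn = conditional_random_effects(dropout_subject, true_params)
        mass, _, _ = quadrature_checks(csn)
        assert mass == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_half_normalizer(self):
        """q = 1-like check embedded in 2-D: density ~ phi(b) Phi(b1) has mass 1/2
        before normalization."""
        p = make_toy_params(beta=(0.0, 0.0), gamma=(1.0, 0.0), delta=0.0,
                            sigma1=1.0, sigma2=1.0, sigma_eps=1e6)
        # one factor Phi(0 + b1): completer at M=2 with alpha = 0
        times = np.array([0.0, 1.0])
        sub = sp.SubjectRecord("h", 2, np.array([0.0, 0.0]), np.array([True, True]),
                               np.zeros((2, 2)), np.column_stack([np.ones(2), times]),
                               np.zeros((1, 2)))
        csn = conditional_random_effects(sub, p)
        assert csn.m == 1
        assert csn.log_norm == pytest.approx(np.log(0.5), abs=1e-7)


class TestCsnMoments:
    def test_univariate_skew_normal_mean(self):
        # density ~ phi(b) Phi(b): mean = 1/sqrt(pi)
        csn = ClosedSkewNormal(np.zeros(1), np.eye(1), np.ones((1, 1)), np.zeros(1), np.log(0.5))
        mean, cov = csn_moments(csn)
        assert mean[0] == pytest.approx(1 / np.sqrt(np.pi), abs=1e-10)

    def test_gaussian_case_returns_mu_omega(self):
        mu = np.array([0.3, -0.2])
        Om = np.array([[0.5, 0.1], [0.1, 0.8]])
        csn = ClosedSkewNormal(mu, Om, np.zeros((3, 2)), np.ones(3), 0.0)
        mean, cov = csn_moments(csn)
        assert np.allclose(mean, mu) and np.allclose(cov, Om)

    def test_matches_quadrature_and_sampling(self, dropout_subject, true_params):
        csn = conditional_random_effects(dropout_subject, true_params)
        mean, cov = csn_moments(csn)
        _, qmean, qcov = quadrature_checks(csn, n=221)
        assert np.allclose(mean, qmean, atol=1e-4)
        assert np.allclose(cov, qcov, atol=1e-4)
        draws = sample_csn(csn, 200_000, seed=11)
        se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert np.all(np.abs(mean - draws.mean(axis=0)) < 3 * se)

    def test_fast_marginal_route_agrees_with_exact(self, two_arm_records, true_params):
        rec = next(r for r in two_arm_records if 2 < r.S < r.M)
        csn = conditional_random_effects(rec, true_params)
        mean, cov = csn_moments(csn)
        for axis in (0, 1):
            m_fd, v_fd = csn_marginal_moments_fd(csn, axis)
            assert m_fd == pytest.approx(mean[axis], abs=2e-3)
            assert v_fd == pytest.approx(cov[axis, axis], rel=2e-3)


class TestSampleCsn:
    def test_gamma_zero_accepts_everything(self, two_arm_records):
        p = make_toy_params(beta=np.zeros(4), alpha=np.zeros(3), gamma=(0.0, 0.0))
        rec = two_arm_records[0]
        csn = conditional_random_effects(rec, p)
        _, rate = sample_csn(csn, 5000, seed=0, return_rate=True)
        assert rate == 1.0

    def test_seed_reproducibility(self, dropout_subject, true_params):
        csn = conditional_random_effects(dropout_subject, true_params)
        a = sample_csn(csn, 500, seed=7)
        b = sample_csn(csn, 500, seed=7)
        assert np.array_equal(a, b)

    def test_acceptance_floor_raises_with_advice(self):
        csn = ClosedSkewNormal(np.zeros(2), np.eye(2),
                               np.array([[1.0, 0.0]]), np.array([-30.0]),
                               float(norm.logcdf(-30 / np.sqrt(2))))
        with pytest.raises(RuntimeError, match="sequential"):
            sample_csn(csn, 10, seed=0)


class TestDefaultExtrapolation:
    def test_completer_has_nothing_to_extrapolate(self, two_arm_records, true_params):
        completer = next(r for r in two_arm_records if r.is_completer)
        with pytest.raises(ValueError):
            default_extrapolation_sample(completer, true_params, 10, seed=0)

    def test_mar_limit_matches_gaussian_predictive(self, dropout_subject):
        """gamma = 0: extrapolation law is the Gaussian LMM predictive."""
        p = make_toy_params(beta=np.zeros(4), alpha=(0.5, -0.3, 0.2), gamma=(0.0, 0.0))
        sub = dropout_subject
        csn = conditional_random_effects(sub, p)
        k = sub.S + 1  # first unobserved visit
        x, z = sub.X_long[k - 1], sub.Z_long[k - 1]
        pred_mean = x @ p.beta + z @ csn.mu
        pred_var = z @ csn.Omega @ z + p.sigma_eps**2
        draws = default_extrapolation_sample(sub, p, 50_000, seed=5, visits=[k])[:, 0]
        # exact moment match
        assert draws.mean() == pytest.approx(pred_mean, abs=4 * np.sqrt(pred_var / 50_000))
        # full-distribution match
        stat = kstest(draws, "norm", args=(pred_mean, np.sqrt(pred_var))).statistic
        assert stat < 1.63 / np.sqrt(50_000)  # 1% critical value

    def test_variance_at_least_residual(self, dropout_subject, true_params):
        draws = default_extrapolation_sample(dropout_subject, true_params, 20_000, seed=3)
        assert np.all(draws.var(axis=0) > true_params.sigma_eps**2 * 0.9)

    def test_informative_dropout_pulls_slope_down(self, two_arm_records):
        """Positive slope association + early dropout -> extrapolated mean at the
        final visit below the MAR prediction for the same subject."""
        rec = next(r for r in two_arm_records if r.S <= 3)
        p_inf = make_toy_params(beta=np.zeros(4), alpha=np.zeros(3), gamma=(0.0, 1.2))
        p_mar = make_toy_params(beta=np.zeros(4), alpha=np.zeros(3), gamma=(0.0, 0.0))
        last = [rec.M]
        inf = default_extrapolation_sample(rec, p_inf, 100_000, seed=1, visits=last).mean()
        mar = default_extrapolation_sample(rec, p_mar, 100_000, seed=1, visits=last).mean()
        assert inf < mar
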