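"""Synthetic longitudinal data with informative discrete-time dropout.

The generator emulates the structure of a multi-visit HIV cohort
(transformed CD4 outcome): M scheduled visits with standardized times
(j-1)/(M-1), baseline covariates (a 4-level viral-load group, binary
antiretroviral-treatment indicator, ordinal 0-5 symptom score), a random
intercept + slope linear mixed model for the complete outcome, a probit
discrete hazard of dropout sharing the random effects, and optional
intermittent (latently ignorable) missingness before dropout.  The
default truth values are the posterior means reported for such a cohort
analysis; they make the synthetic data realistic but carry no claim of
reproducing any particular dataset.

Per-subject random streams are spawned deterministically from the master
seed, so growing N leaves earlier subjects unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import DesignSpec, RandomEffectsCov, SPMParameters, StudyDesign, SubjectRecord

__all__ = [
    "CovariateScheme",
    "GeneratorConfig",
    "hers_like_params",
    "hers_like_config",
    "two_arm_params",
    "two_arm_config",
    "simulate_subject",
    "make_dataset",
]

VL_COLS = ("vl_0_500", "vl_500_5k", "vl_5k_30k")  # reference: >30k copies/ml


@dataclass(frozen=True)
class CovariateScheme:
    """Sampling law of the independent baseline covariates.

    ``vl_probs`` orders the viral-load groups (0,500], (500,5000],
    (5000,30000], >30000 (the reference, most severe, group).
    """

    vl_probs: tuple = (0.25, 0.30, 0.20, 0.25)
    art_prob: float = 0.35
    symptom_probs: tuple = (0.35, 0.25, 0.16, 0.10, 0.08, 0.06)

    def __post_init__(self):
        for p in (*self.vl_probs, self.art_prob, *self.symptom_probs):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.vl_probs) - 1) > 1e-9 or abs(sum(self.symptom_probs) - 1) > 1e-9:
            raise ValueError("category probabilities must sum to 1")

    def draw(self, rng) -> dict:
        vl = rng.choice(4, p=self.vl_probs)
        covs = {col: float(vl == k) for k, col in enumerate(VL_COLS)}
        covs["art"] = float(rng.random() < self.art_prob)
        covs["symptoms"] = float(rng.choice(len(self.symptom_probs), p=self.symptom_probs))
        return covs


@dataclass
class GeneratorConfig:
    N: int
    design: StudyDesign
    true_params: SPMParameters
    long_spec: DesignSpec
    haz_spec: DesignSpec
    scheme: CovariateScheme = field(default_factory=CovariateScheme)
    intermittent_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0.0 <= self.intermittent_rate < 1.0:
            raise ValueError("intermittent_rate must lie in [0, 1)")


def hers_like_params() -> SPMParameters:
    """Truth values patterned on a fitted 12-visit HIV cohort model."""
    beta = np.array(
        [-0.55, 1.52, 1.02, 0.47, -0.02, -0.65, -1.21, 0.59, 0.53, 0.37, -0.06, 0.21]
    )
    alpha = np.array([1.11, 0.75, 0.63, 0.26, -0.01, -0.22, 1.67, -2.79, 0.37])
    gamma = np.array([0.23, 0.28])
    re_cov = RandomEffectsCov.from_sigma_b(
        np.array([[0.56, -0.20 * np.sqrt(0.56 * 1.24)], [-0.20 * np.sqrt(0.56 * 1.24), 1.24]])
    )
    return SPMParameters(
        beta=beta, alpha=alpha, gamma=gamma, re_cov=re_cov, sigma_eps=float(np.sqrt(0.15))
    )


def hers_like_specs() -> tuple[DesignSpec, DesignSpec]:
    long_spec = DesignSpec(
        [
            "1",
            *VL_COLS,
            "symptoms",
            "art",
            "t",
            *(f"{c}:t" for c in VL_COLS),
            "symptoms:t",
            "art:t",
        ]
    )
    haz_spec = DesignSpec(["1", *VL_COLS, "symptoms", "art", "t", "t2", "art:t"])
    return long_spec, haz_spec


def hers_like_config(
    N: int = 827, M: int = 12, *, intermittent_rate: float = 0.076, seed: int = 0
) -> GeneratorConfig:
    """Full-structure cohort emulation: 12 visits, 4-level viral load,
    treatment, symptoms, informative dropout, intermittent gaps."""
    long_spec, haz_spec = hers_like_specs()
    return GeneratorConfig(
        N=N,
        design=StudyDesign(M),
        true_params=hers_like_params(),
        long_spec=long_spec,
        haz_spec=haz_spec,
        intermittent_rate=intermittent_rate,
        seed=seed,
    )


@dataclass(frozen=True)
class _TwoArmScheme(CovariateScheme):
    """Single binary-treatment covariate, used for compact studies."""

    def draw(self, rng) -> dict:
        return {"trt": float(rng.random() < 0.5)}


def two_arm_params(gamma=(0.23, 0.28)) -> SPMParameters:
    """Compact truth for a two-arm study: outcome declines over follow-up,
    treatment slows the decline, dropout hazard falls over time."""
    return SPMParameters(
        beta=np.array([-0.5, 0.3, -1.2, 0.4]),  # 1, trt, t, trt:t
        alpha=np.array([1.1, -0.2, 0.8]),  # 1, trt, t
        gamma=np.asarray(gamma, dtype=float),
        re_cov=RandomEffectsCov(delta=-0.3, sigma1=0.75, sigma2=1.05),
        sigma_eps=0.4,
    )


def two_arm_config(
    N: int = 300,
    M: int = 8,
    *,
    params: SPMParameters | None = None,
    intermittent_rate: float = 0.0,
    seed: int = 0,
) -> GeneratorConfig:
    return GeneratorConfig(
        N=N,
        design=StudyDesign(M),
        true_params=params if params is not None else two_arm_params(),
        long_spec=DesignSpec(["1", "trt", "t", "trt:t"]),
        haz_spec=DesignSpec(["1", "trt", "t"]),
        scheme=_TwoArmScheme(),
        intermittent_rate=intermittent_rate,
        seed=seed,
    )


def _subject_rng(config: GeneratorConfig, index: int):
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(index,))
    )


def simulate_subject(config: GeneratorConfig, index: int):
    """Simulate one subject; returns (complete outcome vector, SubjectRecord).

    Draws b ~ N(0, Sigma_b), the complete outcome at all M visits, the
    dropout visit by sequential Bernoulli trials on the probit hazard,
    then truncates and applies intermittent masking (never at visit 1).
    """
    rng = _subject_rng(config, index)
    p = config.true_params
    design = config.design
    M, times = design.M, design.visit_times
    covs = config.scheme.draw(rng)
    X = config.long_spec.build(covs, times)
    Z = np.column_stack([np.ones(M), times])
    X_haz = config.haz_spec.build(covs, times[:-1])

    b = np.linalg.cholesky(p.re_cov.sigma_b) @ rng.standard_normal(2)
    y_complete = X @ p.beta + Z @ b + rng.standard_normal(M) * p.sigma_eps

    S = M
    for l in range(1, M):  # hazard index l = 1..M-1
        eta = X_haz[l - 1] @ p.alpha + b @ p.gamma_at(l)
        lam = norm.sf(eta)
        if rng.random() < lam:
            S = l
            break

    observed = np.arange(1, M + 1) <= S
    if config.intermittent_rate > 0:
        gaps = rng.random(M) < config.intermittent_rate
        gaps[0] = False  # the baseline outcome is always observed
        observed &= ~gaps
    y_obs = np.where(observed, y_complete, np.nan)
    record = SubjectRecord(
        id=index,
        S=S,
        y=y_obs,
        observed=observed,
        X_long=X,
        Z_long=Z,
        X_haz=X_haz,
    )
    record.covariates = covs  # kept for grouping in sensitivity lookups
    record.b_true = b
    return y_complete, record


def make_dataset(config: GeneratorConfig, path: str | Path | None = None):
    """Simulate the full study; returns ``(df, truth)`` and optionally writes CSV.

    ``df`` is the long-format observed table (one row per subject-visit,
    empty y where unobserved) with a ``dropout_visit`` column.  ``truth``
    holds the generating parameters, per-subject random effects, and the
    complete outcomes — for recovery tests only; nothing in ``df`` leaks
    the truth.
    """
    rows = []
    b_all = np.empty((config.N, 2))
    y_complete_all = np.empty((config.N, config.design.M))
    records = []
    for i in range(config.N):
        y_complete, rec = simulate_subject(config, i)
        b_all[i] = rec.b_true
        y_complete_all[i] = y_complete
        records.append(rec)
        for j in range(config.design.M):
            row = {
                "id": i,
                "visit": j + 1,
                "time": config.design.visit_times[j],
                "y": rec.y[j],
                "dropout_visit": rec.S,
            }
            row.update(rec.covariates)
            rows.append(row)
    df = pd.DataFrame(rows)
    p = config.true_params
    truth = {
        "params": {
            "beta": p.beta.tolist(),
            "alpha": p.alpha.tolist(),
            "gamma": p.gamma.tolist(),
            "delta": p.re_cov.delta,
            "sigma1": p.re_cov.sigma1,
            "sigma2": p.re_cov.sigma2,
            "sigma_eps": p.sigma_eps,
        },
        "b": b_all,
        "y_complete": y_complete_all,
        "records": records,
    }
    if path is not None:
        path = Path(path)
        df.to_csv(path, index=False, float_format="%.10g")
        truth_path = path.with_name(path.stem + "_truth.json")
        with open(truth_path, "w") as fh:
            json.dump(
                {
                    "params": truth["params"],
                    "b": b_all.tolist(),
                    "y_complete": y_complete_all.tolist(),
                    "seed": config.seed,
                },
                fh,
                indent=1,
            )
    return df, truth
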