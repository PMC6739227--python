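"""Model and results objects: the user-facing estimation surface.

``SharedParameterModel`` wraps a dataset of :class:`SubjectRecord` (or a
long-format DataFrame) and ``fit()`` runs the blocked Gibbs sampler,
returning an :class:`SPMResults` with the pooled posterior draws, a
Table-style ``summary()``, convergence diagnostics, posterior-predictive
checks, extrapolation and G-computation entry points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import (
    DesignSpec,
    RandomEffectsCov,
    SPMParameters,
    StudyDesign,
    SubjectRecord,
    records_from_dataframe,
)
from .gibbs import MCMCConfig, PriorSpec, _Stacked, run_chain

__all__ = ["SharedParameterModel", "SPMResults", "ConvergenceReport"]

SCALAR_PARAMS = ("delta", "sigma1", "sigma2", "sigma_eps")


class SharedParameterModel:
    """Joint model for a continuous longitudinal outcome and discrete dropout.

    Parameters
    ----------
    records : list of SubjectRecord
    design : StudyDesign
    param_names : optional mapping for pretty summary labels, keyed by the
        internal names ``beta[k]`` / ``alpha[k]``.
    """

    def __init__(self, records, design: StudyDesign, param_names: dict | None = None):
        if not records:
            raise ValueError("no subjects")
        for rec in records:
            if rec.n_obs < 1:
                raise ValueError(f"subject {rec.id!r} has no observed outcomes")
            if rec.M != design.M:
                raise ValueError("record/design visit-count mismatch")
        self.records = list(records)
        self.design = design
        self.param_names = dict(param_names or {})

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        design: StudyDesign,
        long_spec: DesignSpec,
        haz_spec: DesignSpec,
        **column_kwargs,
    ) -> "SharedParameterModel":
        records = records_from_dataframe(df, design, long_spec, haz_spec, **column_kwargs)
        labels = {f"beta[{k}]": f"beta[{t}]" for k, t in enumerate(long_spec.terms)}
        labels.update({f"alpha[{k}]": f"alpha[{t}]" for k, t in enumerate(haz_spec.terms)})
        model = cls(records, design, param_names=labels)
        model.long_spec = long_spec
        model.haz_spec = haz_spec
        return model

    @property
    def n_subjects(self) -> int:
        return len(self.records)

    def fit(
        self,
        priors: PriorSpec | None = None,
        mcmc: MCMCConfig | None = None,
        *,
        gamma_zero: bool = False,
        store_random_effects: bool = True,
    ) -> "SPMResults":
        """Posterior sampling by blocked Gibbs with data augmentation.

        ``gamma_zero=True`` fixes the association at zero — the
        ignorable-dropout (plain linear mixed model) comparator.
        """
        priors = priors or PriorSpec()
        mcmc = mcmc or MCMCConfig()
        stacked = _Stacked(self.records)
        n_iter = mcmc.burn_in + mcmc.draws * mcmc.thin
        frames, b_parts = [], []
        names = None
        for chain in range(mcmc.chains):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=mcmc.seed, spawn_key=(chain,))
            )
            draws, names, b_draws = run_chain(
                stacked,
                priors,
                n_iter,
                mcmc.burn_in,
                mcmc.thin,
                rng,
                gamma_zero=gamma_zero,
                init_scale=0.5 * chain,  # chain 0 starts at the origin, later chains overdispersed
                store_b=store_random_effects,
            )
            frame = pd.DataFrame(draws, columns=names)
            frame.insert(0, "chain", chain)
            frame.insert(1, "draw", np.arange(len(frame)))
            frames.append(frame)
            if store_random_effects:
                b_parts.append(b_draws)
        draws_df = pd.concat(frames, ignore_index=True)
        b_all = np.concatenate(b_parts, axis=0) if store_random_effects else None
        return SPMResults(self, draws_df, b_all, priors, mcmc, gamma_zero)


@dataclass
class ConvergenceReport:
    table: pd.DataFrame
    passed: bool
    threshold: float = 1.1

    def __repr__(self):
        worst = self.table["rhat"].max()
        return (
            f"<ConvergenceReport passed={self.passed} max_rhat={worst:.4f} "
            f"threshold={self.threshold}>"
        )


class SPMResults:
    """Posterior draws and everything computed from them."""

    def __init__(self, model, draws: pd.DataFrame, b_draws, priors, mcmc, gamma_zero=False):
        self.model = model
        self.draws = draws
        self.b_draws = b_draws
        self.priors = priors
        self.mcmc = mcmc
        self.gamma_zero = gamma_zero

    # -- access -------------------------------------------------------------
    @property
    def param_columns(self) -> list[str]:
        return [c for c in self.draws.columns if c not in ("chain", "draw")]

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    def params_at(self, idx: int) -> SPMParameters:
        """Materialize the idx-th pooled draw as an SPMParameters."""
        row = self.draws.iloc[idx]
        p = sum(c.startswith("beta[") for c in self.draws.columns)
        pS = sum(c.startswith("alpha[") for c in self.draws.columns)
        beta = row[[f"beta[{k}]" for k in range(p)]].to_numpy(dtype=float)
        alpha = row[[f"alpha[{k}]" for k in range(pS)]].to_numpy(dtype=float)
        gamma = row[["gamma[1]", "gamma[2]"]].to_numpy(dtype=float)
        return SPMParameters(
            beta=beta,
            alpha=alpha,
            gamma=gamma,
            re_cov=RandomEffectsCov(
                delta=float(row["delta"]),
                sigma1=float(row["sigma1"]),
                sigma2=float(row["sigma2"]),
            ),
            sigma_eps=float(row["sigma_eps"]),
        )

    def thin_indices(self, n: int) -> np.ndarray:
        """Evenly spaced pooled-draw indices (posterior subsampling)."""
        n = min(n, self.n_draws)
        return np.unique(np.linspace(0, self.n_draws - 1, n).astype(int))

    # -- summaries ----------------------------------------------------------
    def summary(self, *, ci: float = 0.95) -> pd.DataFrame:
        """Posterior mean, SD and central credible interval per parameter."""
        lo = (1 - ci) / 2
        rows = []
        for col in self.param_columns:
            x = self.draws[col].to_numpy()
            rows.append(
                {
                    "parameter": self.model.param_names.get(col, col),
                    "mean": x.mean(),
                    "sd": x.std(ddof=1),
                    f"{100 * lo:g}%": np.quantile(x, lo),
                    f"{100 * (1 - lo):g}%": np.quantile(x, 1 - lo),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def check_convergence(self, threshold: float = 1.1) -> ConvergenceReport:
        """Potential scale reduction factor and effective sample size for
        every scalar parameter (requires >= 2 chains).

        The PSRF is the classic between/within-chain variance ratio,
        sqrt(((n-1)/n W + B/n) / W), floored at 1 (identical chains give
        exactly 1); the effective sample size is arviz's.
        """
        import arviz as az

        n_chains = self.draws["chain"].nunique()
        if n_chains < 2:
            raise ValueError("convergence diagnostics need at least 2 chains")
        per_chain = min(
            (self.draws["chain"] == c).sum() for c in self.draws["chain"].unique()
        )
        data = {}
        for col in self.param_columns:
            arr = np.stack(
                [
                    self.draws.loc[self.draws["chain"] == c, col].to_numpy()[:per_chain]
                    for c in sorted(self.draws["chain"].unique())
                ]
            )
            data[col] = arr
        ess = az.ess(az.from_dict(posterior=data))
        rows = []
        for col in self.param_columns:
            arr = data[col]
            n = arr.shape[1]
            W = arr.var(axis=1, ddof=1).mean()
            B_over_n = arr.mean(axis=1).var(ddof=1)
            var_plus = (n - 1) / n * W + B_over_n
            rhat = float(np.sqrt(max(1.0, var_plus / W))) if W > 0 else 1.0
            rows.append({"parameter": col, "rhat": rhat, "ess": float(ess[col].values)})
        table = pd.DataFrame(rows).set_index("parameter")
        passed = bool((table["rhat"] < threshold).all())
        return ConvergenceReport(table=table, passed=passed, threshold=threshold)

    # -- downstream stages ---------------------------------------------------
    def extrapolate(self, subject: SubjectRecord, draw_idx: int, n: int, seed=None, **kw):
        from .csn import default_extrapolation_sample

        return default_extrapolation_sample(subject, self.params_at(draw_idx), n, seed, **kw)

    def ppc(self, n_draws: int = 100, seed: int = 0, **kw):
        from .diagnostics import ppc_pvalue

        return ppc_pvalue(self.model.records, self, n_draws=n_draws, seed=seed, **kw)

    def gcompute(self, profiles, sens_config=None, **kw):
        from .gcomputation import gcompute

        return gcompute(self, profiles, sens_config=sens_config, **kw)

    def save_draws(self, path):
        self.draws.to_csv(path, index=False)
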