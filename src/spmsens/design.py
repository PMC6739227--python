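"""Study design, per-subject data containers, and model parameters.

Conventions used throughout the package:

* Visits are 1-based, ``j = 1..M``; visit times ``t_j`` live on a
  standardized scale in ``[0, 1]`` with ``t_1 = 0`` (default
  ``t_j = (j-1)/(M-1)``).
* ``S`` is the last attended visit.  ``S = M`` marks a completer whose
  dropout time is administratively censored at the final visit.
* The discrete hazard is indexed by the visit at risk of being the last,
  ``l = 1..M-1``; a subject with ``S = s < M`` contributes ``s-1``
  survival terms and one event term, a completer contributes ``M-1``
  survival terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "DesignSpec",
    "SubjectRecord",
    "RandomEffectsCov",
    "SPMParameters",
    "records_from_dataframe",
]


@dataclass(frozen=True)
class StudyDesign:
    """Schedule of follow-up visits.

    Parameters
    ----------
    M : int
        Number of scheduled visits (>= 2).
    visit_times : ndarray, optional
        Strictly increasing times in [0, 1] with ``visit_times[0] == 0``.
        Defaults to the equally spaced ``(j - 1)/(M - 1)``.
    """

    M: int
    visit_times: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.M < 2:
            raise ValueError("a study design needs at least two visits")
        times = self.visit_times
        if times is None:
            times = np.arange(self.M) / (self.M - 1)
        times = np.asarray(times, dtype=float)
        if times.shape != (self.M,):
            raise ValueError("visit_times must have length M")
        if times[0] != 0.0:
            raise ValueError("the first visit time must be 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError("visit_times must be strictly increasing")
        object.__setattr__(self, "visit_times", times)


class DesignSpec:
    """Maps named covariates to fixed-effect / hazard design columns.

    Terms are strings: ``"1"`` (intercept), ``"t"`` (standardized visit
    time), ``"t2"`` (its square), a covariate column name, or
    ``"<name>:t"`` for a covariate-by-time interaction.  The longitudinal
    design evaluates ``t`` at the visit's own time; the hazard design at
    the time of the visit at risk (visits ``1..M-1``).
    """

    def __init__(self, terms):
        self.terms = list(terms)
        if not self.terms:
            raise ValueError("at least one design term is required")

    def __len__(self):
        return len(self.terms)

    @property
    def names(self):
        return list(self.terms)

    def build(self, covariates, times) -> np.ndarray:
        """Design matrix for one subject.

        Parameters
        ----------
        covariates : mapping
            Covariate name -> scalar value (baseline covariates).
        times : ndarray
            Times at which rows are evaluated, one row per time.
        """
        times = np.asarray(times, dtype=float)
        cols = []
        for term in self.terms:
            if term == "1":
                cols.append(np.ones_like(times))
            elif term == "t":
                cols.append(times)
            elif term == "t2":
                cols.append(times**2)
            elif term.endswith(":t"):
                name = term[:-2]
                cols.append(float(covariates[name]) * times)
            else:
                cols.append(np.full_like(times, float(covariates[term])))
        return np.column_stack(cols)


@dataclass
class SubjectRecord:
    """One subject's observed data and design rows for all scheduled visits.

    ``y`` has length M with NaN at unobserved visits; ``observed`` is the
    boolean availability mask (False after ``S`` and at intermittent
    gaps).  Design rows are kept for every scheduled visit so that
    post-dropout outcomes can be extrapolated.
    """

    id: object
    S: int
    y: np.ndarray
    observed: np.ndarray
    X_long: np.ndarray
    Z_long: np.ndarray
    X_haz: np.ndarray
    W: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        self.X_long = np.atleast_2d(np.asarray(self.X_long, dtype=float))
        self.Z_long = np.atleast_2d(np.asarray(self.Z_long, dtype=float))
        self.X_haz = np.atleast_2d(np.asarray(self.X_haz, dtype=float))
        M = self.y.shape[0]
        if self.X_long.shape[0] != M or self.Z_long.shape[0] != M:
            raise ValueError("design rows must cover all M scheduled visits")
        if self.X_haz.shape[0] != M - 1:
            raise ValueError("hazard design must have M-1 rows")
        if not 1 <= self.S <= M:
            raise ValueError("dropout visit S must lie in 1..M")
        if not self.observed[0]:
            raise ValueError("the visit-1 outcome must be observed")
        if self.observed[self.S:].any():
            raise ValueError("observed flags must be False after visit S")
        if np.isnan(self.y[self.observed]).any():
            raise ValueError("observed outcomes may not be NaN")
        q = self.Z_long.shape[1]
        if self.W is None:
            self.W = np.broadcast_to(np.eye(q), (M - 1, q, q)).copy()
        else:
            self.W = np.asarray(self.W, dtype=float)
            if self.W.shape[0] != M - 1 or self.W.shape[2] != q:
                raise ValueError("W must have shape (M-1, q_S, q)")

    @property
    def M(self) -> int:
        return self.y.shape[0]

    @property
    def n_obs(self) -> int:
        return int(self.observed.sum())

    @property
    def is_completer(self) -> bool:
        return self.S == self.M

    def observed_rows(self):
        """(y_obs, X_obs, Z_obs) restricted to observed visits."""
        o = self.observed
        return self.y[o], self.X_long[o], self.Z_long[o]


@dataclass(frozen=True)
class RandomEffectsCov:
    """Modified-Cholesky parameterization of the 2x2 random-effects covariance.

    The random intercept is ``b1 = e1`` and the random slope regresses on
    it, ``b2 = delta * b1 + e2``, with innovation standard deviations
    ``sigma1`` and ``sigma2``.  Any finite ``delta`` with positive sigmas
    yields a positive-definite covariance.
    """

    delta: float
    sigma1: float
    sigma2: float

    def __post_init__(self):
        if not (self.sigma1 > 0 and self.sigma2 > 0):
            raise ValueError("innovation standard deviations must be positive")

    @property
    def sigma_b(self) -> np.ndarray:
        d, s1, s2 = self.delta, self.sigma1, self.sigma2
        v1 = s1**2
        return np.array([[v1, d * v1], [d * v1, d**2 * v1 + s2**2]])

    @classmethod
    def from_sigma_b(cls, sigma_b) -> "RandomEffectsCov":
        S = np.asarray(sigma_b, dtype=float)
        if S.shape != (2, 2) or not np.allclose(S, S.T):
            raise ValueError("sigma_b must be a symmetric 2x2 matrix")
        if S[0, 0] <= 0 or np.linalg.det(S) <= 0:
            raise ValueError("sigma_b must be positive definite")
        v1 = S[0, 0]
        delta = S[0, 1] / v1
        v2 = S[1, 1] - delta**2 * v1
        return cls(delta=delta, sigma1=float(np.sqrt(v1)), sigma2=float(np.sqrt(v2)))


@dataclass
class SPMParameters:
    """Full parameter vector theta of the shared parameter model.

    ``gamma`` is either one shared association vector of length q_S
    (default; used in the data application) or an (M-1, q_S) array with
    one row per hazard index.
    """

    beta: np.ndarray
    alpha: np.ndarray
    gamma: np.ndarray
    re_cov: RandomEffectsCov
    sigma_eps: float

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.sigma_eps <= 0:
            raise ValueError("sigma_eps must be positive")

    def gamma_at(self, hazard_index: int) -> np.ndarray:
        """Association vector at 1-based hazard index ``l`` in 1..M-1."""
        if self.gamma.ndim == 1:
            return self.gamma
        return self.gamma[hazard_index - 1]

    @property
    def visit_specific_gamma(self) -> bool:
        return self.gamma.ndim == 2


def records_from_dataframe(
    df: pd.DataFrame,
    design: StudyDesign,
    long_spec: DesignSpec,
    haz_spec: DesignSpec,
    *,
    id_col: str = "id",
    visit_col: str = "visit",
    y_col: str = "y",
    dropout_col: str = "dropout_visit",
) -> list[SubjectRecord]:
    """Build SubjectRecords from a long-format table.

    The table must contain one row per subject-visit for all M scheduled
    visits (missing outcomes as NaN / empty).  Baseline covariates are
    taken from the subject's first row.  If ``dropout_col`` is absent,
    S defaults to the last visit with a non-missing outcome.
    """
    records = []
    times = design.visit_times
    for sid, g in df.groupby(id_col, sort=False):
        g = g.sort_values(visit_col)
        visits = g[visit_col].to_numpy()
        if len(visits) != design.M or not np.array_equal(visits, np.arange(1, design.M + 1)):
            raise ValueError(f"subject {sid!r}: need one row per visit 1..M")
        y = g[y_col].to_numpy(dtype=float)
        covs = g.iloc[0].to_dict()
        if dropout_col in g.columns:
            S = int(g[dropout_col].iloc[0])
        else:
            S = int(np.max(np.where(~np.isnan(y))[0]) + 1)
        observed = ~np.isnan(y)
        observed[S:] = False
        records.append(
            SubjectRecord(
                id=sid,
                S=S,
                y=np.where(observed, y, np.nan),
                observed=observed,
                X_long=long_spec.build(covs, times),
                Z_long=np.column_stack([np.ones(design.M), times]),
                X_haz=haz_spec.build(covs, times[:-1]),
            )
        )
    return records
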