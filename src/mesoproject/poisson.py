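"""Exposure-driven Poisson regression of age-specific incident counts.

Models annual incident case counts M_{a,Y} (not rates: there is no
person-years offset by default) as

    log E[M_{a,Y}] = b0 + b1 * X_{a,Y} + b2 * Sex
                     + sum_i b_i1 * Age_i + sum_i b_i2 * Sex*Age_i

where X_{a,Y} is the latency-lagged cumulative per-capita asbestos exposure
covariate (shared across sexes), Sex is 0 for women / 1 for men, and the
age dummies use the youngest group as baseline.  Fitting is a standard
Poisson GLM with log link (delegated to statsmodels' IRLS); prediction is
``exp(X beta)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .exposure import ExposureMatrix
from .registry import AgeGroup, IncidenceTable, Period, normalize_sex

__all__ = [
    "PoissonDesign",
    "PoissonFit",
    "ExposurePoissonModel",
    "build_design",
    "fit_poisson",
    "predict_poisson",
]

SEX_CODE = {"female": 0, "male": 1}


@dataclass
class PoissonDesign:
    """Design matrix with rows indexed by (sex, age group, year).

    ``X`` has columns ``const, exposure, sex, age_<label>..., sexage_<label>...``
    (baseline age group contributes no dummy); ``y`` holds observed counts
    and may be None for a prediction-only design.
    """

    X: pd.DataFrame
    y: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.y is not None and len(self.y) != len(self.X):
            raise ValueError("response length does not match design")
        if "exposure" in self.X.columns and (self.X["exposure"] < 0).any():
            raise ValueError("exposure column must be non-negative")

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.X.columns)


def build_design(exposure: ExposureMatrix, counts: IncidenceTable | None,
                 age_groups: Sequence[AgeGroup], years: Sequence[int],
                 sexes: Sequence[str] = ("female", "male")) -> PoissonDesign:
    """Assemble the Poisson design over (sex, age group, year) cells.

    ``counts`` supplies the response (annual records are required); pass
    None for a future/prediction design.  Exposure values come from the
    (sex-shared) exposure matrix.  A missing count cell is an error.
    """
    age_groups = list(age_groups)
    years = [int(y) for y in years]
    sexes = [normalize_sex(s) for s in sexes]
    baseline = age_groups[0]
    dummy_groups = age_groups[1:]

    count_map = {}
    if counts is not None:
        for _, r in counts.data.iterrows():
            per = r["period"]
            if not per.is_annual:
                raise ValueError("Poisson model requires annual count data")
            count_map[(r["sex"], r["age_group"], per.start)] = int(r["cases"])

    rows, index, yvals = [], [], []
    for sex in sexes:
        sex_code = SEX_CODE[sex]
        for g in age_groups:
            for year in years:
                x = {"const": 1.0,
                     "exposure": exposure.lookup(g, year),
                     "sex": float(sex_code)}
                for dg in dummy_groups:
                    on = 1.0 if dg == g else 0.0
                    x[f"age_{dg.label}"] = on
                    x[f"sexage_{dg.label}"] = on * sex_code
                rows.append(x)
                index.append((sex, g.label, year))
                if counts is not None:
                    key = (sex, g, year)
                    if key not in count_map:
                        raise ValueError(f"missing count cell (sex={sex}, "
                                         f"age_group={g.label}, year={year})")
                    yvals.append(count_map[key])
    cols = (["const", "exposure", "sex"]
            + [f"age_{dg.label}" for dg in dummy_groups]
            + [f"sexage_{dg.label}" for dg in dummy_groups])
    X = pd.DataFrame(rows, columns=cols,
                     index=pd.MultiIndex.from_tuples(index,
                                                     names=["sex", "age_group", "year"]))
    y = pd.Series(yvals, index=X.index, name="cases") if counts is not None else None
    return PoissonDesign(X, y)


@dataclass
class PoissonFit:
    """Fitted Poisson GLM: coefficients, covariance, deviance."""

    params: pd.Series
    cov: pd.DataFrame
    deviance: float
    converged: bool

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.params.index)

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())),
                         index=self.params.index)


class ExposurePoissonModel(BaseEstimator):
    """Poisson GLM estimator over a :class:`PoissonDesign`.

    ``offset_person_years`` switches on a log person-years offset (rate
    modelling); off by default because the reference formulation models raw
    counts.  Fitted attributes: ``coef_``, ``cov_``, ``deviance_``,
    ``result_`` (a :class:`PoissonFit`).
    """

    def __init__(self, offset_person_years: bool = False, maxiter: int = 200,
                 tol: float = 1e-8):
        self.offset_person_years = offset_person_years
        self.maxiter = maxiter
        self.tol = tol

    def fit(self, design: PoissonDesign, person_years: pd.Series | None = None
            ) -> "ExposurePoissonModel":
        if design.y is None:
            raise ValueError("design has no response; cannot fit")
        X = design.X.to_numpy(dtype=float)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        if (design.y > 0).sum() < 1:
            raise ValueError("need at least one positive count")
        offset = None
        if self.offset_person_years:
            if person_years is None:
                raise ValueError("offset_person_years=True requires person_years")
            offset = np.log(person_years.reindex(design.X.index).to_numpy(dtype=float))
        model = sm.GLM(design.y.to_numpy(dtype=float), X,
                       family=sm.families.Poisson(), offset=offset)
        res = model.fit(maxiter=self.maxiter, tol=self.tol)
        if not res.converged:
            raise RuntimeError("Poisson IRLS did not converge")
        cols = list(design.X.columns)
        self.coef_ = pd.Series(res.params, index=cols)
        self.cov_ = pd.DataFrame(res.cov_params(), index=cols, columns=cols)
        self.deviance_ = float(res.deviance)
        self.columns_ = tuple(cols)
        self.result_ = PoissonFit(self.coef_, self.cov_, self.deviance_, True)
        return self

    def predict(self, design: PoissonDesign) -> pd.Series:
        if tuple(design.X.columns) != self.columns_:
            raise ValueError(f"design columns {tuple(design.X.columns)} do not match "
                             f"fitted columns {self.columns_}")
        mu = np.exp(design.X.to_numpy(dtype=float) @ self.coef_.to_numpy())
        return pd.Series(mu, index=design.X.index, name="expected")


def fit_poisson(design: PoissonDesign) -> PoissonFit:
    """Maximum-likelihood Poisson fit; thin wrapper over the estimator."""
    est = ExposurePoissonModel()
    est.fit(design)
    return est.result_


def predict_poisson(fit: PoissonFit, design: PoissonDesign) -> pd.Series:
    """Expected counts ``exp(X beta)`` for a (future) design."""
    if tuple(design.X.columns) != fit.columns:
        raise ValueError("design column structure does not match the fit")
    mu = np.exp(design.X.to_numpy(dtype=float) @ fit.params.to_numpy())
    return pd.Series(mu, index=design.X.index, name="expected")
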