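"""Power-link age-period-cohort (APC) incidence model.

The model decomposes the incidence rate for age group ``a`` in calendar
period ``p`` as

    R_ap = (A_a + D*p + P_p + C_c)^5,      c = A - a + p,

i.e. the fifth power of a linear predictor built from age components
``A_a``, a common linear drift ``D``, and non-linear period (``P_p``) and
cohort (``C_c``) components.  The fifth-root link moderates the exponential
extrapolation a log link would produce, which is why it is the standard
choice for long-range cancer-incidence projection.  Identifiability follows
the NORDPRED convention: ``P`` and ``C`` are constrained to zero sum and
zero linear slope, so the drift ``D`` carries the entire linear time trend
and is the only trend extrapolated into the future.  Projection damps the
drift with a "cut trend" attenuation schedule (defaults 1, 0.75, 0.5, 0.25
cumulatively over four 5-year projection periods), freezes the period
effect at its last level, and extends unseen cohorts at the last estimated
cohort level.

Fitting is iteratively reweighted least squares on the fifth-root scale
with Poisson weights, started from the age-only model, with step-halving to
keep the deviance monotone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.special import xlogy
from sklearn.base import BaseEstimator

from .registry import AgeGroup, BinSpec, IncidenceTable, Period, PopulationTable

__all__ = [
    "LexisGrid",
    "APCConfig",
    "APCFit",
    "ProjectionResult",
    "PowerLinkAPC",
    "build_lexis",
    "fit_apc",
    "project_apc",
    "predicted_counts",
    "poisson_deviance",
    "apc_linear_predictor",
]

_ETA_FLOOR = 1e-4  # linear predictor floor during fitting (rate 1e-20)


@dataclass
class LexisGrid:
    """Age × period grid of case counts and person-years.

    Rows are age groups (youngest first), columns calendar periods
    (earliest first).  Cohorts run along the diagonals: with 1-based
    indices, cohort ``c = A - a + p`` ranges over ``1 .. A + P - 1`` from
    the oldest cohort (oldest age group, first period) to the youngest.
    """

    ages: tuple[AgeGroup, ...]
    periods: tuple[Period, ...]
    cases: np.ndarray
    person_years: np.ndarray

    def __post_init__(self) -> None:
        self.ages = tuple(self.ages)
        self.periods = tuple(self.periods)
        self.cases = np.asarray(self.cases, dtype=float)
        self.person_years = np.asarray(self.person_years, dtype=float)
        shape = (len(self.ages), len(self.periods))
        if self.cases.shape != shape or self.person_years.shape != shape:
            raise ValueError(f"matrix shapes must be {shape}; got cases "
                             f"{self.cases.shape}, person_years {self.person_years.shape}")
        if (self.cases < 0).any():
            raise ValueError("case counts must be non-negative")
        if (self.person_years <= 0).any():
            a, p = np.argwhere(self.person_years <= 0)[0]
            raise ValueError(f"person-years must be positive; cell "
                             f"({self.ages[a].label}, {self.periods[p].label}) is not")

    @property
    def n_ages(self) -> int:
        return len(self.ages)

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    @property
    def n_cohorts(self) -> int:
        return self.n_ages + self.n_periods - 1

    def cohort_index(self, a: int, p: int) -> int:
        """1-based cohort index for 1-based age index ``a`` and period ``p``."""
        if not (1 <= a <= self.n_ages and 1 <= p <= self.n_periods):
            raise IndexError(f"(a={a}, p={p}) outside grid")
        return self.n_ages - a + p

    @property
    def rates(self) -> np.ndarray:
        return self.cases / self.person_years


def build_lexis(incidence: IncidenceTable, population: PopulationTable,
                sex: str, spec: BinSpec | None = None) -> LexisGrid:
    """Assemble the Lexis grid for one sex from matching binned tables.

    If ``spec`` is given both tables are re-binned onto it first.  The full
    age × period rectangle must be present in both tables.
    """
    if spec is not None:
        incidence = incidence.aggregate(spec)
        population = population.aggregate(spec)
    from .registry import normalize_sex
    sex = normalize_sex(sex)
    inc = incidence.data[incidence.data["sex"] == sex]
    pop = population.data[population.data["sex"] == sex]
    if inc.empty:
        raise ValueError(f"no incidence rows for sex={sex}")
    ages = sorted(set(inc["age_group"]), key=lambda g: g.lower)
    periods = sorted(set(inc["period"]))
    if set(pop["age_group"]) != set(ages) or set(pop["period"]) != set(periods):
        raise ValueError("incidence and population tables are binned differently")
    A, P = len(ages), len(periods)
    cases = np.zeros((A, P))
    py = np.zeros((A, P))
    inc_map = {(r["age_group"], r["period"]): r["cases"] for _, r in inc.iterrows()}
    pop_map = {(r["age_group"], r["period"]): r["person_years"] for _, r in pop.iterrows()}
    for i, g in enumerate(ages):
        for j, per in enumerate(periods):
            if (g, per) not in inc_map:
                raise ValueError(f"missing incidence cell ({g.label}, {per.label})")
            if (g, per) not in pop_map:
                raise ValueError(f"missing population cell ({g.label}, {per.label})")
            cases[i, j] = inc_map[(g, per)]
            py[i, j] = pop_map[(g, per)]
    return LexisGrid(tuple(ages), tuple(periods), cases, py)


@dataclass
class APCConfig:
    """Tunables of the power-link APC fit and projection."""

    power: float = 5.0
    drift_mode: str = "average"           # or "recent": slope of last two periods
    attenuation: tuple[float, ...] = (1.0, 0.75, 0.5, 0.25)
    min_periods: int = 3
    max_iter: int = 100
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise ValueError("power must be positive")
        if self.drift_mode not in ("average", "recent"):
            raise ValueError(f"unknown drift_mode {self.drift_mode!r}")
        att = tuple(float(x) for x in self.attenuation)
        if any(not (0.0 <= x <= 1.0) for x in att):
            raise ValueError("attenuation multipliers must lie in [0, 1]")
        if any(b > a for a, b in zip(att, att[1:])):
            raise ValueError("attenuation multipliers must be non-increasing")
        self.attenuation = att


@dataclass
class APCFit:
    """Fitted components of the power-link APC model."""

    age_labels: tuple[str, ...]
    period_labels: tuple[str, ...]
    age: np.ndarray          # A_a on the fifth-root (rate^{1/power}) scale
    drift: float             # D, per period
    period: np.ndarray       # P_p, zero-sum / zero-slope
    cohort: np.ndarray       # C_c, zero-sum / zero-slope, length A+P-1
    deviance: float
    power: float = 5.0
    converged: bool = True
    n_iter: int = 0
    constraints: str = "zero-sum and zero-slope on period and cohort; drift carries trend"

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("age", "period", "cohort"):
            d[k] = list(np.asarray(d[k], dtype=float))
        d["age_labels"] = list(self.age_labels)
        d["period_labels"] = list(self.period_labels)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "APCFit":
        d = dict(d)
        for k in ("age", "period", "cohort"):
            d[k] = np.asarray(d[k], dtype=float)
        d["age_labels"] = tuple(d["age_labels"])
        d["period_labels"] = tuple(d["period_labels"])
        return cls(**d)


def poisson_deviance(counts: np.ndarray, mu: np.ndarray) -> float:
    """Poisson deviance 2*sum[y log(y/mu) - (y - mu)] (0 log 0 = 0)."""
    counts = np.asarray(counts, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return float(2.0 * np.sum(xlogy(counts, counts) - xlogy(counts, mu)
                              - (counts - mu)))


def apc_linear_predictor(age: np.ndarray, drift: float, period: np.ndarray,
                         cohort: np.ndarray) -> np.ndarray:
    """Linear predictor eta_ap = A_a + D*p + P_p + C_{A-a+p} on the full grid."""
    age = np.asarray(age, dtype=float)
    period = np.asarray(period, dtype=float)
    cohort = np.asarray(cohort, dtype=float)
    A, P = len(age), len(period)
    if len(cohort) != A + P - 1:
        raise ValueError("cohort vector must have length A + P - 1")
    eta = np.empty((A, P))
    for i in range(A):
        for j in range(P):
            c = A - (i + 1) + (j + 1)  # 1-based cohort index
            eta[i, j] = age[i] + drift * (j + 1) + period[j] + cohort[c - 1]
    return eta


def _detrended_basis(n: int) -> np.ndarray:
    """Orthonormal basis (n × (n-2)) of vectors with zero sum and zero slope."""
    constraints = np.vstack([np.ones(n), np.arange(1, n + 1, dtype=float)])
    return null_space(constraints)


class PowerLinkAPC(BaseEstimator):
    """Power-link APC estimator with NORDPRED-style constraints and projection.

    Parameters
    ----------
    power : link exponent (rate = eta**power); 5 is the standard choice.
    drift_mode : ``"average"`` extrapolates the fitted common drift;
        ``"recent"`` uses the slope of the last two observed periods
        (drift plus the last non-linear period step).
    attenuation : cumulative "cut trend" drift multipliers for successive
        projection periods.
    min_periods : minimum number of observed periods required to fit.
    max_iter, tol : IRLS iteration cap and deviance-change convergence
        tolerance.

    Fitted attributes (after :meth:`fit`): ``age_``, ``drift_``,
    ``period_``, ``cohort_``, ``deviance_``, ``n_iter_``, ``converged_``,
    ``result_`` (an :class:`APCFit`), ``grid_``.
    """

    def __init__(self, power: float = 5.0, drift_mode: str = "average",
                 attenuation: Sequence[float] = (1.0, 0.75, 0.5, 0.25),
                 min_periods: int = 3, max_iter: int = 100, tol: float = 1e-8):
        self.power = power
        self.drift_mode = drift_mode
        self.attenuation = attenuation
        self.min_periods = min_periods
        self.max_iter = max_iter
        self.tol = tol

    # -- internals ---------------------------------------------------------

    def _config(self) -> APCConfig:
        return APCConfig(power=self.power, drift_mode=self.drift_mode,
                         attenuation=tuple(self.attenuation),
                         min_periods=self.min_periods,
                         max_iter=self.max_iter, tol=self.tol)

    @staticmethod
    def _design(A: int, P: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Cellwise design matrix in the constrained parametrisation.

        Columns: A age indicators | 1 drift (period index) | P-2 detrended
        period basis | A+P-3 detrended cohort basis.
        """
        basis_p = _detrended_basis(P)
        basis_c = _detrended_basis(A + P - 1)
        n_cells = A * P
        X = np.zeros((n_cells, A + 1 + basis_p.shape[1] + basis_c.shape[1]))
        rows = 0
        for i in range(A):
            for j in range(P):
                c = A - (i + 1) + (j + 1)
                col = 0
                X[rows, i] = 1.0
                col = A
                X[rows, col] = j + 1
                col += 1
                X[rows, col:col + basis_p.shape[1]] = basis_p[j]
                col += basis_p.shape[1]
                X[rows, col:] = basis_c[c - 1]
                rows += 1
        return X, basis_p, basis_c

    def _unpack(self, theta: np.ndarray, A: int, P: int,
                basis_p: np.ndarray, basis_c: np.ndarray):
        age = theta[:A]
        drift = theta[A]
        period = basis_p @ theta[A + 1:A + 1 + basis_p.shape[1]]
        cohort = basis_c @ theta[A + 1 + basis_p.shape[1]:]
        return age, float(drift), period, cohort

    # -- estimator API -----------------------------------------------------

    def fit(self, grid: LexisGrid, y=None) -> "PowerLinkAPC":
        cfg = self._config()
        A, P = grid.n_ages, grid.n_periods
        if P < cfg.min_periods:
            raise ValueError(f"need at least {cfg.min_periods} observed periods, "
                             f"got {P}")
        X, basis_p, basis_c = self._design(A, P)
        y_cnt = grid.cases.ravel()
        n_py = grid.person_years.ravel()
        rate_obs = y_cnt / n_py
        pw = cfg.power

        # start from the age-only model (pooled age-specific rates)
        pooled = grid.cases.sum(axis=1) / grid.person_years.sum(axis=1)
        floor_rate = 0.5 / grid.person_years.sum()
        theta = np.zeros(X.shape[1])
        theta[:A] = np.maximum(pooled, floor_rate) ** (1.0 / pw)

        def dev_at(th: np.ndarray) -> float:
            eta = np.maximum(X @ th, _ETA_FLOOR)
            return poisson_deviance(y_cnt, n_py * eta ** pw)

        dev = dev_at(theta)
        n_iter = 0
        converged = False
        for n_iter in range(1, cfg.max_iter + 1):
            eta = np.maximum(X @ theta, _ETA_FLOOR)
            rate = eta ** pw
            deriv = pw * eta ** (pw - 1.0)          # d(rate)/d(eta)
            z = eta + (rate_obs - rate) / deriv      # working response
            w = n_py * deriv ** 2 / rate             # Poisson weights on rate scale
            sw = np.sqrt(w)
            theta_new, *_ = np.linalg.lstsq(sw[:, None] * X, sw * z, rcond=None)
            # step-halving keeps the deviance monotone
            step = 1.0
            dev_new = dev_at(theta_new)
            while dev_new > dev + 1e-12 and step > 1e-4:
                step *= 0.5
                dev_new = dev_at(theta + step * (theta_new - theta))
            if dev_new > dev + 1e-12:
                raise RuntimeError(
                    f"IRLS failed to reduce the deviance at iteration {n_iter} "
                    f"(deviance {dev:.6g})")
            theta = theta + step * (theta_new - theta)
            if abs(dev - dev_new) < cfg.tol:
                dev = dev_new
                converged = True
                break
            dev = dev_new
        age, drift, period, cohort = self._unpack(theta, A, P, basis_p, basis_c)
        self.age_ = age
        self.drift_ = drift
        self.period_ = period
        self.cohort_ = cohort
        self.deviance_ = dev
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.grid_ = grid
        self.result_ = APCFit(
            age_labels=tuple(g.label for g in grid.ages),
            period_labels=tuple(p.label for p in grid.periods),
            age=age, drift=drift, period=period, cohort=cohort,
            deviance=dev, power=pw, converged=converged, n_iter=n_iter)
        return self

    def fitted_rates(self) -> np.ndarray:
        """Fitted rates per person-year on the observed grid."""
        eta = apc_linear_predictor(self.age_, self.drift_, self.period_, self.cohort_)
        return np.maximum(eta, 0.0) ** self.power

    def project(self, future_person_years: np.ndarray,
                n_future: int | None = None) -> "ProjectionResult":
        """Project rates and expected counts onto future person-years.

        ``future_person_years`` is an (A, K) array, K = number of future
        periods.  The drift increment beyond the last observed period is
        accumulated through the attenuation schedule; a negative linear
        predictor truncates the rate to zero.
        """
        fit = self.result_
        return project_apc(fit, future_person_years, n_future, self._config(),
                           last_period=self.grid_.periods[-1])


def fit_apc(grid: LexisGrid, config: APCConfig | None = None) -> APCFit:
    """Fit the power-link APC model; thin wrapper over :class:`PowerLinkAPC`."""
    cfg = config or APCConfig()
    est = PowerLinkAPC(power=cfg.power, drift_mode=cfg.drift_mode,
                       attenuation=cfg.attenuation, min_periods=cfg.min_periods,
                       max_iter=cfg.max_iter, tol=cfg.tol)
    est.fit(grid)
    return est.result_


@dataclass
class ProjectionResult:
    """Projected age-specific rates and expected counts for future periods."""

    age_labels: tuple[str, ...]
    periods: tuple[Period, ...]
    rates: np.ndarray          # (A, K) per person-year
    person_years: np.ndarray   # (A, K)
    expected: np.ndarray       # (A, K) expected case counts

    @property
    def crude_rates_per_100k(self) -> np.ndarray:
        return self.expected.sum(axis=0) / self.person_years.sum(axis=0) * 1e5

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.age_labels):
            for j, per in enumerate(self.periods):
                rows.append((g, per.start, per.end,
                             self.rates[i, j] * 1e5, self.expected[i, j]))
        return pd.DataFrame(rows, columns=["age_group", "period_start", "period_end",
                                           "rate_per_100k", "expected_cases"])


def project_apc(fit: APCFit, future_person_years, n_future: int | None = None,
                config: APCConfig | None = None,
                last_period: Period | None = None) -> ProjectionResult:
    """Project an :class:`APCFit` forward over ``n_future`` periods.

    ``future_person_years``: (A, K) array, or a :class:`PopulationTable`
    together with periods inferred from its contents is not supported here —
    the pipeline layer handles tables; this operation takes the matrix.
    """
    cfg = config or APCConfig()
    py = np.asarray(future_person_years, dtype=float)
    if py.ndim != 2 or py.shape[0] != len(fit.age_labels):
        raise ValueError(f"future person-years must be (A, K) with A = "
                         f"{len(fit.age_labels)}; got {py.shape}")
    K = py.shape[1] if n_future is None else int(n_future)
    if K > py.shape[1]:
        raise ValueError("future person-years cover fewer periods than requested")
    if K > len(cfg.attenuation):
        raise ValueError(f"projection horizon {K} exceeds attenuation schedule "
                         f"of length {len(cfg.attenuation)}")
    if (py[:, :K] <= 0).any():
        raise ValueError("future person-years must be positive")
    A = len(fit.age_labels)
    P = len(fit.period_labels)
    if cfg.drift_mode == "recent" and P >= 2:
        drift_step = fit.drift + (fit.period[-1] - fit.period[-2])
    else:
        drift_step = fit.drift
    cum_att = np.cumsum(cfg.attenuation[:K])
    rates = np.empty((A, K))
    for k in range(1, K + 1):
        for i in range(A):
            c = A - (i + 1) + (P + k)  # 1-based cohort index of the future cell
            cohort = fit.cohort[c - 1] if c <= len(fit.cohort) else fit.cohort[-1]
            eta = (fit.age[i] + fit.drift * P + drift_step * cum_att[k - 1]
                   + fit.period[-1] + cohort)
            rates[i, k - 1] = max(eta, 0.0) ** fit.power
    if last_period is None:
        last = Period.parse(fit.period_labels[-1])
    else:
        last = last_period
    width = last.n_years
    periods = tuple(Period(last.end + 1 + (k - 1) * width, last.end + k * width)
                    for k in range(1, K + 1))
    expected = rates * py[:, :K]
    return ProjectionResult(tuple(fit.age_labels), periods, rates, py[:, :K], expected)


def predicted_counts(result: ProjectionResult, by: str = "period") -> pd.Series:
    """Marginal sums of projected expected counts (unrounded).

    ``by`` is one of ``"period"``, ``"age"``, ``"total"``.
    """
    if by == "period":
        return pd.Series(result.expected.sum(axis=0),
                         index=[p.label for p in result.periods], name="expected")
    if by == "age":
        return pd.Series(result.expected.sum(axis=1),
                         index=list(result.age_labels), name="expected")
    if by == "total":
        return pd.Series({"total": result.expected.sum()}, name="expected")
    raise ValueError(f"unknown margin {by!r}")
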