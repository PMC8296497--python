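"""Synthetic registry worlds with known ground truth.

Real mesothelioma inputs (registry counts, population pyramids, asbestos
trade records) are not redistributable, so every stage of the pipeline is
exercised on generated stand-ins instead:

* :func:`simulate_apc_counts` draws Poisson counts from a power-link APC
  rate surface on a Lexis grid (18 five-year age groups by default, sized
  like a mid-size national registry: ~50M population, a few hundred male
  cases per 5-year period, counts roughly tripling over 20 years);
* :func:`simulate_consumption` produces a rise-peak-ban trade trajectory
  (default: linear rise from 1940 to a 95 kt peak in 1992, decline to zero
  at a 2009 ban), optionally thinned to sparse checkpoints to exercise the
  interpolation step;
* :func:`simulate_exposure_counts` draws Poisson counts from the
  exposure-driven log-linear model with a known coefficient vector.

Every generator is a pure function of (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exposure import (ConsumptionSeries, ExposureMatrix, TradeSeries,
                       build_exposure_matrix, net_consumption, per_capita)
from .registry import AgeGroup, BinSpec, IncidenceTable, Period, PopulationTable

__all__ = [
    "APCScenario",
    "ExposureScenario",
    "simulate_apc_counts",
    "simulate_consumption",
    "simulate_exposure_counts",
    "population_series",
    "per_capita_series",
]

# Plausible mesothelioma-like age-specific rates per 100,000 person-years
# for 5-year age groups 0-4 .. 85+ (near zero until mid-life, rising to a
# few per 100k at old ages).
_DEFAULT_RATES_PER_100K = np.array([
    0.01, 0.01, 0.01, 0.02, 0.03, 0.05, 0.08, 0.12, 0.20,
    0.35, 0.60, 0.90, 1.30, 1.80, 2.20, 2.50, 2.60, 2.40])

# Smooth population pyramid weights for the same 18 groups (middle-heavy,
# thinning at old ages), normalised at use time.
_DEFAULT_PYRAMID = np.array([
    0.045, 0.050, 0.060, 0.065, 0.070, 0.075, 0.080, 0.085, 0.085,
    0.080, 0.070, 0.060, 0.050, 0.040, 0.030, 0.025, 0.018, 0.012])


def _project_detrended(v: np.ndarray) -> np.ndarray:
    """Remove the mean and linear trend so v satisfies the APC constraints."""
    v = np.asarray(v, dtype=float)
    n = len(v)
    B = np.column_stack([np.ones(n), np.arange(1, n + 1, dtype=float)])
    coef, *_ = np.linalg.lstsq(B, v, rcond=None)
    return v - B @ coef


@dataclass
class APCScenario:
    """Ground-truth power-link APC world.

    ``age_curve`` is on the fifth-root (eta) scale; ``drift`` is per
    period.  Raw ``period_effects`` / ``cohort_effects`` are detrended
    (zero sum, zero slope) before use so the stored truth matches the
    fitter's identifiable parametrisation.  ``female_scale`` multiplies the
    female age curve (0.87^5 ~ 0.5: women at about half the male rate).
    """

    seed: int
    age_breaks: tuple[int, ...] = tuple(range(0, 90, 5))
    n_periods: int = 4
    first_year: int = 1994
    period_width: int = 5
    total_population: float = 50e6
    age_curve: np.ndarray | None = None
    drift: float = 0.008
    period_effects: np.ndarray | None = None
    cohort_effects: np.ndarray | None = None
    person_years: np.ndarray | None = None
    female_scale: float = 0.87
    power: float = 5.0

    def __post_init__(self) -> None:
        self.age_breaks = tuple(int(b) for b in self.age_breaks)
        A, P = self.n_ages, self.n_periods
        if self.age_curve is None:
            if A != len(_DEFAULT_RATES_PER_100K):
                raise ValueError("default age curve needs 18 five-year groups; "
                                 "supply age_curve explicitly")
            self.age_curve = (_DEFAULT_RATES_PER_100K / 1e5) ** (1.0 / self.power)
        self.age_curve = np.asarray(self.age_curve, dtype=float)
        if len(self.age_curve) != A:
            raise ValueError(f"age_curve must have length {A}")
        self.period_effects = (np.zeros(P) if self.period_effects is None
                               else _project_detrended(self.period_effects))
        if len(self.period_effects) != P:
            raise ValueError(f"period_effects must have length {P}")
        self.cohort_effects = (np.zeros(A + P - 1) if self.cohort_effects is None
                               else _project_detrended(self.cohort_effects))
        if len(self.cohort_effects) != A + P - 1:
            raise ValueError(f"cohort_effects must have length {A + P - 1}")
        if self.person_years is None:
            w = _DEFAULT_PYRAMID / _DEFAULT_PYRAMID.sum()
            per_cell = self.total_population / 2.0 * self.period_width
            self.person_years = np.tile((w * per_cell)[:, None], (1, P))
        self.person_years = np.asarray(self.person_years, dtype=float)
        if self.person_years.shape != (A, P):
            raise ValueError(f"person_years must be shaped ({A}, {P})")
        for sex in ("male", "female"):
            if (self.eta(sex) < 0).any():
                raise ValueError(f"scenario implies negative linear predictor "
                                 f"({sex}); rates would be undefined")

    @property
    def n_ages(self) -> int:
        return len(self.age_breaks)

    @property
    def age_groups(self) -> list[AgeGroup]:
        b = self.age_breaks
        return [AgeGroup(lo, hi) for lo, hi in zip(b[:-1], b[1:])] + [AgeGroup(b[-1])]

    @property
    def periods(self) -> list[Period]:
        w = self.period_width
        return [Period(self.first_year + k * w, self.first_year + (k + 1) * w - 1)
                for k in range(self.n_periods)]

    def eta(self, sex: str) -> np.ndarray:
        """True linear predictor grid for one sex."""
        A, P = self.n_ages, self.n_periods
        curve = self.age_curve * (self.female_scale if sex == "female" else 1.0)
        eta = np.empty((A, P))
        for i in range(A):
            for j in range(P):
                c = A - (i + 1) + (j + 1)
                eta[i, j] = (curve[i] + self.drift * (j + 1)
                             + self.period_effects[j] + self.cohort_effects[c - 1])
        return eta

    def rates(self, sex: str) -> np.ndarray:
        return self.eta(sex) ** self.power

    def means(self, sex: str) -> np.ndarray:
        return self.rates(sex) * self.person_years


def simulate_apc_counts(scenario: APCScenario, annual: bool = False
                        ) -> tuple[IncidenceTable, PopulationTable, dict]:
    """Draw a registry world from an APC scenario.

    Counts are independent Poisson draws per cell with mean
    person-years * (A_a + D*p + P_p + C_c)^power.  With ``annual=True``
    each 5-year period is split into years (person-years divided evenly,
    the period's rate applied to each year) so the binning step can be
    exercised; binning the annual output back recovers the period world in
    expectation.
    """
    rng = np.random.default_rng(scenario.seed)
    groups = scenario.age_groups
    periods = scenario.periods
    inc_rows, pop_rows = [], []
    truth: dict = {"scenario": scenario, "means": {}, "rates": {}}
    for sex in ("male", "female"):
        rates = scenario.rates(sex)
        means = scenario.means(sex)
        truth["rates"][sex] = rates
        truth["means"][sex] = means
        for i, g in enumerate(groups):
            for j, per in enumerate(periods):
                if annual:
                    py_year = scenario.person_years[i, j] / per.n_years
                    for year in range(per.start, per.end + 1):
                        mean = rates[i, j] * py_year
                        cnt = int(rng.poisson(mean)) if mean > 0 else 0
                        yp = Period(year, year)
                        inc_rows.append((sex, g, yp, cnt))
                        pop_rows.append((sex, g, yp, py_year))
                else:
                    mean = means[i, j]
                    cnt = int(rng.poisson(mean)) if mean > 0 else 0
                    inc_rows.append((sex, g, per, cnt))
                    pop_rows.append((sex, g, per, scenario.person_years[i, j]))
    incidence = IncidenceTable.from_records(inc_rows)
    population = PopulationTable.from_records(pop_rows)
    return incidence, population, truth


@dataclass
class ExposureScenario:
    """Ground-truth exposure-driven Poisson world.

    The consumption trajectory rises linearly from zero at ``start_year``
    to ``peak_tonnes`` at ``peak_year``, declines linearly to zero at
    ``ban_year`` and stays zero after.  ``beta`` entries follow the design
    column order (const, exposure, sex, age dummies, sex*age interactions).
    """

    seed: int
    age_breaks: tuple[int, ...] = (0, 40, 50, 60, 70, 80)
    first_year: int = 1994
    last_year: int = 2018
    start_year: int = 1940
    peak_year: int = 1992
    peak_tonnes: float = 95_000.0
    ban_year: int = 2009
    latency_years: float = 40.0
    population_checkpoints: tuple[tuple[int, float], ...] = (
        (1900, 10e6), (1940, 16e6), (1960, 25e6), (1980, 38e6),
        (2000, 47e6), (2020, 51.8e6))
    beta_const: float = 0.5
    beta_exposure: float = 0.05
    beta_sex: float = 0.7
    beta_age: tuple[float, ...] = (1.0, 1.8, 2.3, 2.5, 2.0)
    beta_sexage: tuple[float, ...] = (0.3, 0.5, 0.6, 0.5, 0.3)

    def __post_init__(self) -> None:
        if not self.start_year < self.peak_year < self.ban_year:
            raise ValueError("need start_year < peak_year < ban_year")
        if len(self.beta_age) != len(self.age_breaks) - 1:
            raise ValueError("beta_age must cover all non-baseline age groups")
        if len(self.beta_sexage) != len(self.beta_age):
            raise ValueError("beta_sexage must match beta_age in length")

    @property
    def age_groups(self) -> list[AgeGroup]:
        b = self.age_breaks
        return [AgeGroup(lo, hi) for lo, hi in zip(b[:-1], b[1:])] + [AgeGroup(b[-1])]

    @property
    def years(self) -> list[int]:
        return list(range(self.first_year, self.last_year + 1))

    def beta_vector(self, columns: Sequence[str]) -> pd.Series:
        groups = self.age_groups
        values = {"const": self.beta_const, "exposure": self.beta_exposure,
                  "sex": self.beta_sex}
        for g, b_a, b_sa in zip(groups[1:], self.beta_age, self.beta_sexage):
            values[f"age_{g.label}"] = b_a
            values[f"sexage_{g.label}"] = b_sa
        return pd.Series([values[c] for c in columns], index=list(columns))


def _trajectory(scenario: ExposureScenario) -> pd.Series:
    years = np.arange(scenario.start_year, scenario.last_year + 1)
    vals = np.interp(years,
                     [scenario.start_year, scenario.peak_year, scenario.ban_year],
                     [0.0, scenario.peak_tonnes, 0.0])
    vals[years > scenario.ban_year] = 0.0
    return pd.Series(vals, index=years)


def simulate_consumption(scenario: ExposureScenario,
                         checkpoints: Sequence[int] | None = None) -> TradeSeries:
    """Rise-peak-ban import trajectory as a trade series.

    With ``checkpoints`` the series is thinned to those years only, to
    exercise checkpoint interpolation downstream.  The trajectory is
    piecewise linear with kinks at the peak and ban years, so thinning to
    checkpoints containing those years followed by linear interpolation
    recovers it exactly.
    """
    traj = _trajectory(scenario)
    if checkpoints is not None:
        missing = [int(c) for c in checkpoints if int(c) not in traj.index]
        if missing:
            raise ValueError(f"checkpoint year(s) {missing} outside the trajectory")
        traj = traj.loc[sorted(int(c) for c in checkpoints)]
    df = pd.DataFrame({"production_t": 0.0, "imports_t": traj, "exports_t": 0.0},
                      index=traj.index)
    return TradeSeries(df)


def population_series(scenario: ExposureScenario) -> pd.Series:
    """Annual total population from the scenario's checkpoints."""
    yrs, vals = zip(*scenario.population_checkpoints)
    years = np.arange(min(yrs), scenario.last_year + 1)
    return pd.Series(np.interp(years, yrs, vals), index=years)


def per_capita_series(scenario: ExposureScenario) -> pd.Series:
    """Annual per-capita consumption C(t) in kg/person."""
    cons = net_consumption(simulate_consumption(scenario))
    return per_capita(cons, population_series(scenario)).per_capita_kg


def scenario_exposure_matrix(scenario: ExposureScenario) -> ExposureMatrix:
    """Cumulative exposure matrix over the scenario's groups and years."""
    return build_exposure_matrix(scenario.age_groups, scenario.years,
                                 per_capita_series(scenario),
                                 scenario.latency_years,
                                 assume_zero_before=scenario.start_year)


def simulate_exposure_counts(scenario: ExposureScenario
                             ) -> tuple[IncidenceTable, dict]:
    """Draw annual counts from the exposure-driven log-linear model."""
    from .poisson import build_design  # local import avoids a cycle
    rng = np.random.default_rng(scenario.seed)
    exposure = scenario_exposure_matrix(scenario)
    design = build_design(exposure, None, scenario.age_groups, scenario.years)
    beta = scenario.beta_vector(design.columns)
    mu = pd.Series(np.exp(design.X.to_numpy() @ beta.to_numpy()),
                   index=design.X.index)
    counts = rng.poisson(mu.to_numpy())
    rows = []
    lookup = {g.label: g for g in scenario.age_groups}
    for (sex, label, year), cnt in zip(design.X.index, counts):
        rows.append((sex, lookup[label], Period(int(year), int(year)), int(cnt)))
    incidence = IncidenceTable.from_records(rows)
    truth = {"scenario": scenario, "beta": beta, "mu": mu,
             "design": design, "exposure": exposure}
    return incidence, truth
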