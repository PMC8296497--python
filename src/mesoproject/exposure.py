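"""Asbestos consumption reconstruction and the cumulative exposure covariate.

National asbestos trade records are sparse in the early decades (mineral
yearbooks report production/import/export only at 5- or 10-year
checkpoints).  This module linearly interpolates those checkpoints to an
annual series, forms net consumption (production + imports - exports,
clamped at zero), converts it to per-capita kilograms, and builds the
latency-lagged cumulative exposure covariate used by the Poisson incidence
model: for an age group with representative age ``a`` observed in year
``Y`` and a latent period ``L_t`` (default 40 years), exposure accumulates
per-capita consumption ``C(t)`` over the birth-to-latency window
``t in [Y - a, Y - L_t]``.  Years in the window without consumption data
are mean-imputed through the ``e/d`` rescaling factor (``e`` = window
length in years, ``d`` = years with data); a group entirely younger than
the latent period has zero exposure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .registry import AgeGroup, PopulationTable

__all__ = [
    "TradeSeries",
    "ConsumptionSeries",
    "ExposureMatrix",
    "interpolate_checkpoints",
    "net_consumption",
    "per_capita",
    "cumulative_exposure",
    "build_exposure_matrix",
]

logger = logging.getLogger(__name__)

_COMPONENTS = ("production_t", "imports_t", "exports_t")


@dataclass
class TradeSeries:
    """Annual production/import/export tonnages with per-cell provenance.

    ``values`` is indexed by calendar year with float columns
    ``production_t, imports_t, exports_t`` (NaN = not recorded);
    ``provenance`` mirrors it with ``"observed"`` / ``"interpolated"`` /
    ``"missing"`` labels.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        missing = set(_COMPONENTS) - set(self.values.columns)
        if missing:
            raise ValueError(f"trade series missing column(s) {sorted(missing)}")
        self.values = self.values.loc[:, list(_COMPONENTS)].astype(float).sort_index()
        self.values.index = self.values.index.astype(int)
        if (self.values.stack() < 0).any():
            raise ValueError("trade tonnages must be non-negative")
        if self.provenance is None:
            prov = pd.DataFrame(
                np.where(self.values.notna(), "observed", "missing"),
                index=self.values.index, columns=self.values.columns)
            self.provenance = prov
        else:
            self.provenance = self.provenance.loc[self.values.index, list(_COMPONENTS)]

    @classmethod
    def from_dict(cls, data: Mapping[int, tuple]) -> "TradeSeries":
        """Build from ``{year: (production, imports, exports)}`` (None = missing)."""
        df = pd.DataFrame.from_dict(
            {y: [np.nan if v is None else float(v) for v in vals]
             for y, vals in data.items()},
            orient="index", columns=list(_COMPONENTS))
        return cls(df)

    @classmethod
    def read_csv(cls, path) -> "TradeSeries":
        df = pd.read_csv(path)
        if "year" not in df.columns:
            raise ValueError(f"{path}: trade CSV needs a 'year' column")
        return cls(df.set_index("year"))

    def to_csv(self, path) -> None:
        self.values.rename_axis("year").to_csv(path)

    @property
    def years(self) -> np.ndarray:
        return self.values.index.to_numpy()


@dataclass
class ConsumptionSeries:
    """Annual net asbestos consumption (tonnes), optionally per-capita (kg)."""

    net_t: pd.Series
    per_capita_kg: pd.Series | None = None

    def __post_init__(self) -> None:
        self.net_t = self.net_t.astype(float).sort_index()
        self.net_t.index = self.net_t.index.astype(int)
        if (self.net_t < 0).any():
            raise ValueError("net consumption must be non-negative")
        if self.per_capita_kg is not None:
            self.per_capita_kg = self.per_capita_kg.astype(float).sort_index()
            self.per_capita_kg.index = self.per_capita_kg.index.astype(int)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"net_t": self.net_t})
        if self.per_capita_kg is not None:
            df["per_capita_kg"] = self.per_capita_kg
        df.rename_axis("year").to_csv(path)


def interpolate_checkpoints(series: TradeSeries,
                            years: Sequence[int] | None = None) -> TradeSeries:
    """Fill a sparse trade series to annual resolution by linear interpolation.

    Each component is interpolated independently between its observed
    checkpoint years; observed values are never modified.  Requesting a year
    outside a component's checkpoint span raises (no extrapolation).
    """
    obs = series.values
    if years is None:
        years = np.arange(int(obs.index.min()), int(obs.index.max()) + 1)
    years = np.asarray(sorted(int(y) for y in years))
    filled = pd.DataFrame(index=years, columns=list(_COMPONENTS), dtype=float)
    prov = pd.DataFrame("missing", index=years, columns=list(_COMPONENTS))
    for comp in _COMPONENTS:
        col = obs[comp].dropna()
        if len(col) < 2:
            raise ValueError(f"{comp}: need at least 2 observed checkpoints, "
                             f"got {len(col)}")
        lo, hi = int(col.index.min()), int(col.index.max())
        out_of_span = [int(y) for y in years if y < lo or y > hi]
        if out_of_span:
            raise ValueError(
                f"{comp}: year(s) {out_of_span} outside checkpoint span "
                f"[{lo}, {hi}]; refusing to extrapolate")
        filled[comp] = np.interp(years, col.index.to_numpy(), col.to_numpy())
        is_obs = pd.Index(years).isin(col.index)
        filled.loc[is_obs, comp] = col.reindex(years[is_obs]).to_numpy()
        prov[comp] = np.where(is_obs, "observed", "interpolated")
    return TradeSeries(filled, prov)


def net_consumption(series: TradeSeries) -> ConsumptionSeries:
    """Net consumption = production + imports - exports, per year.

    Negative net (exports drawn from stockpiles) clamps to zero with a
    warning: consumption cannot be negative.
    """
    vals = series.values
    if vals.isna().any().any():
        year = int(vals[vals.isna().any(axis=1)].index[0])
        raise ValueError(f"trade components missing for year {year}; "
                         "interpolate before computing net consumption")
    net = vals["production_t"] + vals["imports_t"] - vals["exports_t"]
    neg = net < 0
    if neg.any():
        yrs = [int(y) for y in net.index[neg]]
        warnings.warn(f"negative net consumption clamped to 0 in years {yrs}",
                      stacklevel=2)
        net = net.clip(lower=0.0)
    return ConsumptionSeries(net)


def _total_population(population: PopulationTable | pd.Series) -> pd.Series:
    if isinstance(population, pd.Series):
        pop = population.astype(float)
        pop.index = pop.index.astype(int)
        return pop.sort_index()
    df = population.data
    totals: dict[int, float] = {}
    for _, r in df.iterrows():
        p = r["period"]
        if not p.is_annual:
            raise ValueError("per-capita conversion needs annual population data")
        totals[p.start] = totals.get(p.start, 0.0) + float(r["person_years"])
    return pd.Series(totals).sort_index()


def per_capita(consumption: ConsumptionSeries,
               population: PopulationTable | pd.Series) -> ConsumptionSeries:
    """Convert tonnes/year to kg per person per year.

    ``population`` is either an annual :class:`PopulationTable` (summed over
    sex and age) or a ready ``pd.Series`` of total persons indexed by year.
    """
    pop = _total_population(population)
    missing = [int(y) for y in consumption.net_t.index if y not in pop.index]
    if missing:
        raise ValueError(f"population missing for consumption year(s) {missing}")
    pop = pop.reindex(consumption.net_t.index)
    if (pop <= 0).any():
        raise ValueError("population must be positive for per-capita conversion")
    kg = consumption.net_t * 1000.0 / pop
    return ConsumptionSeries(consumption.net_t, kg)


def cumulative_exposure(age: float, year: int, per_capita_kg: pd.Series,
                        latency_years: float = 40.0,
                        return_diagnostics: bool = False):
    """Latency-lagged cumulative per-capita exposure for one (age, year) cell.

    Sums ``C(t)`` over ``t in [year - age, year - latency_years]`` (the years
    the cohort could have been exposed and still clear the latent period),
    then rescales by ``e/d`` where ``e`` is the window length in years and
    ``d`` the number of window years with data — i.e. missing years are
    imputed at the window mean.  ``age < latency_years`` gives 0.
    """
    if age < latency_years:
        return (0.0, 0, 0) if return_diagnostics else 0.0
    lo = int(np.ceil(year - age))
    hi = int(np.floor(year - latency_years))
    window = np.arange(lo, hi + 1)
    e = len(window)
    inside = per_capita_kg.reindex(window)
    available = inside.notna().to_numpy()
    d = int(available.sum())
    if d == 0:
        raise ValueError(
            f"no consumption data anywhere in window [{lo}, {hi}] "
            f"for age {age}, year {year}; cannot rescale")
    raw = float(inside[available].sum())
    value = raw * e / d
    return (value, e, d) if return_diagnostics else value


@dataclass
class ExposureMatrix:
    """Cumulative exposure on an age-group × year grid (kg·years/person).

    ``values`` is indexed by age-group label with year columns; ``e`` and
    ``d`` hold the window-length and data-available-years diagnostics used
    by the rescaling.
    """

    values: pd.DataFrame
    e: pd.DataFrame
    d: pd.DataFrame
    latency_years: float
    representative_ages: dict[str, float]

    def lookup(self, age_group: AgeGroup | str, year: int) -> float:
        label = age_group.label if isinstance(age_group, AgeGroup) else str(age_group)
        return float(self.values.loc[label, int(year)])


def build_exposure_matrix(age_groups: Sequence[AgeGroup], years: Sequence[int],
                          per_capita_kg: pd.Series, latency_years: float = 40.0,
                          representative_ages: Mapping[str, float] | None = None,
                          assume_zero_before: int | None = None) -> ExposureMatrix:
    """Cumulative exposure for every (age group, occurrence year) cell.

    ``representative_ages`` overrides the default group-midpoint mapping.
    ``assume_zero_before`` treats all years strictly before the given year as
    zero consumption (pre-industrial-use assumption) instead of missing.
    """
    C = per_capita_kg.astype(float).copy()
    C.index = C.index.astype(int)
    years = [int(y) for y in years]
    reps = {g.label: g.representative_age for g in age_groups}
    if representative_ages:
        reps.update({str(k): float(v) for k, v in representative_ages.items()})
    if assume_zero_before is not None:
        earliest = min(int(np.ceil(y - reps[g.label])) for g in age_groups
                       for y in years)
        pad = np.arange(earliest, assume_zero_before)
        pad = pad[~np.isin(pad, C.index)]
        if len(pad):
            logger.info("assuming zero consumption for %d year(s) before %d",
                        len(pad), assume_zero_before)
            C = pd.concat([pd.Series(0.0, index=pad), C]).sort_index()
    labels = [g.label for g in age_groups]
    vals = pd.DataFrame(0.0, index=labels, columns=years)
    e_df = pd.DataFrame(0, index=labels, columns=years)
    d_df = pd.DataFrame(0, index=labels, columns=years)
    for g in age_groups:
        a = reps[g.label]
        for y in years:
            v, e, d = cumulative_exposure(a, y, C, latency_years,
                                          return_diagnostics=True)
            vals.loc[g.label, y] = v
            e_df.loc[g.label, y] = e
            d_df.loc[g.label, y] = d
    return ExposureMatrix(vals, e_df, d_df, latency_years, reps)
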