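"""End-to-end orchestration: exposure -> both fits -> validation -> projection.

Two entry points mirror how the analysis is actually run:

* :func:`run_validation_pipeline` fits the power-link APC model and the
  exposure Poisson model on the fit window only, predicts the holdout
  window, and reports E/O ratios with CIs per sex and per age group plus
  the model-selection outcome.
* :func:`run_projection_pipeline` refits the chosen model on the projection
  fit window (by default the last 20 observed years) and emits per-period
  expected cases by sex and a crude-rate series over the observed +
  projected span.

Everything is deterministic given the config and inputs; report CSVs round
only at write time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .apc import APCConfig, APCFit, ProjectionResult, build_lexis, fit_apc, project_apc
from .exposure import ConsumptionSeries, build_exposure_matrix
from .poisson import build_design, fit_poisson, predict_poisson
from .registry import (AgeGroup, BinSpec, IncidenceTable, Period,
                       PopulationTable, read_incidence_table,
                       read_population_table)
from .validation import EOResult, SelectionOutcome, eo_table, evaluate_eo, select_model

__all__ = ["RunConfig", "ValidationReport", "ProjectionReport",
           "run_validation_pipeline", "run_projection_pipeline"]


@dataclass
class RunConfig:
    """Inputs and knobs for a full run.

    ``incidence`` / ``population`` are annual tables (or CSV paths);
    ``per_capita_consumption`` is the annual C(t) series in kg/person (or a
    CSV path with ``year,per_capita_kg`` columns).  The holdout window must
    be disjoint from and later than the fit window.
    """

    incidence: IncidenceTable | str
    population: PopulationTable | str
    per_capita_consumption: pd.Series | ConsumptionSeries | str
    fit_years: tuple[int, int] = (1994, 2013)
    holdout_years: tuple[int, int] = (2014, 2018)
    projection_fit_years: tuple[int, int] | None = None   # default: last 20 observed
    horizon: int = 4
    period_width: int = 5
    apc: APCConfig = field(default_factory=APCConfig)
    latency_years: float = 40.0
    apc_age_breaks: tuple[int, ...] = tuple(range(0, 90, 5))
    poisson_age_breaks: tuple[int, ...] = (0, 40, 50, 60, 70, 80)
    future_population: PopulationTable | str | None = None
    selection_scale: str = "natural"
    outdir: str | None = None

    def __post_init__(self) -> None:
        f0, f1 = self.fit_years
        h0, h1 = self.holdout_years
        if f1 < f0 or h1 < h0:
            raise ValueError("year windows must be (start, end) with start <= end")
        if h0 <= f1:
            raise ValueError(
                f"holdout window {self.holdout_years} must be disjoint from and "
                f"later than the fit window {self.fit_years}")
        if (f1 - f0 + 1) % self.period_width:
            raise ValueError("fit window length must be a multiple of period_width")
        if self.horizon > len(self.apc.attenuation):
            raise ValueError(f"projection horizon {self.horizon} exceeds the "
                             f"attenuation schedule ({len(self.apc.attenuation)})")

    # -- input resolution --------------------------------------------------

    def load_incidence(self) -> IncidenceTable:
        if isinstance(self.incidence, IncidenceTable):
            return self.incidence
        return read_incidence_table(self.incidence)

    def load_population(self) -> PopulationTable:
        if isinstance(self.population, PopulationTable):
            return self.population
        return read_population_table(self.population)

    def load_consumption(self) -> pd.Series:
        c = self.per_capita_consumption
        if isinstance(c, ConsumptionSeries):
            if c.per_capita_kg is None:
                raise ValueError("consumption series lacks the per-capita form")
            return c.per_capita_kg
        if isinstance(c, pd.Series):
            s = c.astype(float)
            s.index = s.index.astype(int)
            return s.sort_index()
        df = pd.read_csv(c)
        return pd.Series(df["per_capita_kg"].to_numpy(),
                         index=df["year"].astype(int).to_numpy()).sort_index()

    def load_future_population(self) -> PopulationTable | None:
        fp = self.future_population
        if fp is None or isinstance(fp, PopulationTable):
            return fp
        return read_population_table(fp)

    def knobs(self) -> dict:
        return {
            "fit_years": list(self.fit_years),
            "holdout_years": list(self.holdout_years),
            "projection_fit_years": (list(self.projection_fit_years)
                                     if self.projection_fit_years else None),
            "horizon": self.horizon,
            "period_width": self.period_width,
            "apc": {"power": self.apc.power, "drift_mode": self.apc.drift_mode,
                    "attenuation": list(self.apc.attenuation),
                    "min_periods": self.apc.min_periods},
            "latency_years": self.latency_years,
            "apc_age_breaks": list(self.apc_age_breaks),
            "poisson_age_breaks": list(self.poisson_age_breaks),
            "selection_scale": self.selection_scale,
        }


def _filter_years(table, lo: int, hi: int):
    df = table.data
    keep = df["period"].map(lambda p: lo <= p.start and p.end <= hi)
    sub = df[keep]
    if sub.empty:
        raise ValueError(f"no records in year window [{lo}, {hi}]")
    return type(table)(sub)


def _coarse_bin_of(group: AgeGroup, coarse: list[AgeGroup]) -> AgeGroup:
    for cg in coarse:
        if cg.contains(group):
            return cg
    raise ValueError(f"age group {group.label} fits no coarse bin")


def _py_matrix(population: PopulationTable, sex: str, ages: tuple, period: Period
               ) -> np.ndarray:
    return np.array([[population.value(sex, g, period)] for g in ages])


@dataclass
class ValidationReport:
    """E/O validation outputs: per-sex and per-age tables plus selection."""

    eo_sex: dict            # {(sex, model): EOResult}
    eo_age: dict            # {(sex, age_label, model): EOResult}
    selection: SelectionOutcome
    per_sex_selection: dict
    table1: pd.DataFrame
    table2: pd.DataFrame
    knobs: dict

    @property
    def chosen(self) -> str:
        return self.selection.chosen

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.table1.to_csv(out / "table1.csv", index=False)
        self.table2.to_csv(out / "table2.csv", index=False)
        log = dict(self.knobs)
        log["chosen_model"] = self.chosen
        log["tie"] = self.selection.tie
        (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")


def run_validation_pipeline(config: RunConfig) -> ValidationReport:
    """Fit both models on the fit window, score both on the holdout window."""
    incidence = config.load_incidence()
    population = config.load_population()
    C = config.load_consumption()
    f0, f1 = config.fit_years
    h0, h1 = config.holdout_years
    sexes = incidence.sexes

    # --- APC candidate ----------------------------------------------------
    apc_spec = BinSpec(config.apc_age_breaks,
                       list(range(f0, f1 + 2, config.period_width)))
    hold_spec = BinSpec(config.apc_age_breaks, [h0, h1 + 1])
    inc_fit = _filter_years(incidence, f0, f1).aggregate(apc_spec)
    pop_fit = _filter_years(population, f0, f1).aggregate(apc_spec)
    inc_hold = _filter_years(incidence, h0, h1).aggregate(hold_spec)
    pop_hold = _filter_years(population, h0, h1).aggregate(hold_spec)
    hold_period = Period(h0, h1)

    coarse_groups = BinSpec(config.poisson_age_breaks, [f0, f1 + 1]).age_bins()
    E_apc: dict[str, float] = {}
    E_apc_age: dict[tuple[str, str], float] = {}
    for sex in sexes:
        grid = build_lexis(inc_fit, pop_fit, sex)
        fit = fit_apc(grid, config.apc)
        py = _py_matrix(pop_hold, sex, grid.ages, hold_period)
        proj = project_apc(fit, py, 1, config.apc, last_period=grid.periods[-1])
        E_apc[sex] = float(proj.expected.sum())
        for g, e in zip(grid.ages, proj.expected[:, 0]):
            cg = _coarse_bin_of(g, coarse_groups)
            E_apc_age[(sex, cg.label)] = E_apc_age.get((sex, cg.label), 0.0) + float(e)

    # --- Poisson candidate ------------------------------------------------
    years_all = list(range(f0, h1 + 1))
    coarse_spec = BinSpec(config.poisson_age_breaks, list(range(f0, h1 + 2)))
    inc_coarse = incidence.aggregate(coarse_spec)
    expo = build_exposure_matrix(coarse_groups, years_all, C, config.latency_years,
                                 assume_zero_before=int(C.index.min()))
    design_fit = build_design(expo, _filter_years(inc_coarse, f0, f1),
                              coarse_groups, list(range(f0, f1 + 1)), sexes)
    pfit = fit_poisson(design_fit)
    design_hold = build_design(expo, None, coarse_groups,
                               list(range(h0, h1 + 1)), sexes)
    mu = predict_poisson(pfit, design_hold)
    E_pois = mu.groupby(level="sex").sum().to_dict()
    E_pois_age = mu.groupby(level=["sex", "age_group"]).sum().to_dict()

    # --- observed holdout -------------------------------------------------
    O_sex = {sex: int(inc_hold.total(sex=sex)) for sex in sexes}
    inc_hold_coarse = _filter_years(inc_coarse, h0, h1)
    O_age = {}
    for _, r in inc_hold_coarse.data.iterrows():
        key = (r["sex"], r["age_group"].label)
        O_age[key] = O_age.get(key, 0) + int(r["cases"])

    # --- E/O and selection ------------------------------------------------
    eo_sex, eo_age = {}, {}
    rows1 = []
    for sex in sexes:
        for model, E in (("apc", E_apc[sex]), ("poisson", E_pois[sex])):
            res = evaluate_eo(E, O_sex[sex], label=f"{sex}/{model}")
            eo_sex[(sex, model)] = res
            rows1.append(res)
    rows2 = []
    for sex in sexes:
        for cg in coarse_groups:
            O = O_age.get((sex, cg.label), 0)
            if O == 0:
                continue   # no observed cases: the ratio is undefined
            for model, Emap in (("apc", E_apc_age), ("poisson", E_pois_age)):
                res = evaluate_eo(Emap.get((sex, cg.label), 0.0), O,
                                  label=f"{sex}/{cg.label}/{model}")
                eo_age[(sex, cg.label, model)] = res
                rows2.append(res)
    pooled = {
        model: evaluate_eo(sum(E[s] for s in sexes), sum(O_sex[s] for s in sexes),
                           label=f"pooled/{model}")
        for model, E in (("apc", E_apc), ("poisson", E_pois))}
    selection = select_model({m: r for m, r in pooled.items()},
                             scale=config.selection_scale)
    per_sex_selection = {
        sex: select_model({m: eo_sex[(sex, m)] for m in ("apc", "poisson")},
                          scale=config.selection_scale)
        for sex in sexes}
    report = ValidationReport(eo_sex=eo_sex, eo_age=eo_age, selection=selection,
                              per_sex_selection=per_sex_selection,
                              table1=eo_table(rows1), table2=eo_table(rows2),
                              knobs=config.knobs())
    if config.outdir:
        report.write(config.outdir)
    return report


@dataclass
class ProjectionReport:
    """Projection outputs: per-period expected cases and crude rates."""

    model: str
    table3: pd.DataFrame        # sex x period expected cases (+ grand total)
    crude_rates: pd.DataFrame   # sex, period, observed/projected, rate per 100k
    projections: dict           # {sex: ProjectionResult} for the APC model
    knobs: dict

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        t3 = self.table3.copy()
        t3["expected_cases"] = t3["expected_cases"].round().astype(int)
        t3.to_csv(out / "table3.csv", index=False)
        self.crude_rates.to_csv(out / "crude_rates.csv", index=False)
        log = dict(self.knobs)
        log["projection_model"] = self.model
        (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")


def run_projection_pipeline(config: RunConfig, model: str = "apc"
                            ) -> ProjectionReport:
    """Refit the chosen model on the projection window and project forward."""
    if model not in ("apc", "poisson"):
        raise ValueError(f"unknown projection model {model!r}")
    incidence = config.load_incidence()
    population = config.load_population()
    h1 = config.holdout_years[1]
    if config.projection_fit_years is None:
        span = 4 * config.period_width
        p0, p1 = h1 - span + 1, h1
    else:
        p0, p1 = config.projection_fit_years
    if (p1 - p0 + 1) % config.period_width:
        raise ValueError("projection fit window must be a multiple of period_width")
    w = config.period_width
    K = config.horizon
    future_periods = [Period(p1 + 1 + k * w, p1 + (k + 1) * w) for k in range(K)]
    future_pop = config.load_future_population()

    spec = BinSpec(config.apc_age_breaks, list(range(p0, p1 + 2, w)))
    inc_fit = _filter_years(incidence, p0, p1).aggregate(spec)
    pop_fit = _filter_years(population, p0, p1).aggregate(spec)
    sexes = incidence.sexes

    rows3, rate_rows = [], []
    projections: dict[str, ProjectionResult] = {}
    for sex in sexes:
        grid = build_lexis(inc_fit, pop_fit, sex)
        # observed side of the report
        for j, per in enumerate(grid.periods):
            obs = grid.cases[:, j].sum()
            py = grid.person_years[:, j].sum()
            rate_rows.append((sex, per.label, "observed", obs / py * 1e5))
        if future_pop is not None:
            fspec = BinSpec(config.apc_age_breaks,
                            [fp.start for fp in future_periods] + [future_periods[-1].end + 1])
            fpop = _filter_years(future_pop, future_periods[0].start,
                                 future_periods[-1].end).aggregate(fspec)
            py_future = np.column_stack(
                [[fpop.value(sex, g, per) for g in grid.ages]
                 for per in future_periods])
        else:
            py_future = np.tile(grid.person_years[:, -1][:, None], (1, K))
        if model == "apc":
            fit = fit_apc(grid, config.apc)
            proj = project_apc(fit, py_future, K, config.apc,
                               last_period=grid.periods[-1])
            projections[sex] = proj
            per_period = proj.expected.sum(axis=0)
        else:
            per_period = _poisson_projection(config, incidence, p0, p1,
                                             future_periods, sex)
            proj = None
        for per, e in zip(future_periods, per_period):
            rows3.append((sex, per.start, per.end, float(e)))
        if proj is not None:
            for j, per in enumerate(future_periods):
                rate_rows.append((sex, per.label, "projected",
                                  float(proj.crude_rates_per_100k[j])))
        else:
            for j, per in enumerate(future_periods):
                rate_rows.append((sex, per.label, "projected",
                                  float(per_period[j] / py_future[:, j].sum() * 1e5)))
    table3 = pd.DataFrame(rows3, columns=["sex", "period_start", "period_end",
                                          "expected_cases"])
    crude = pd.DataFrame(rate_rows, columns=["sex", "period", "kind",
                                             "rate_per_100k"])
    knobs = config.knobs()
    knobs["projection_fit_years"] = [p0, p1]
    report = ProjectionReport(model=model, table3=table3, crude_rates=crude,
                              projections=projections, knobs=knobs)
    if config.outdir:
        report.write(config.outdir)
    return report


def _poisson_projection(config: RunConfig, incidence: IncidenceTable,
                        p0: int, p1: int, future_periods: list[Period],
                        sex: str) -> np.ndarray:
    """Per-period expected counts from the exposure Poisson model."""
    C = config.load_consumption()
    coarse_groups = BinSpec(config.poisson_age_breaks, [p0, p1 + 1]).age_bins()
    last_future = future_periods[-1].end
    coarse_spec = BinSpec(config.poisson_age_breaks, list(range(p0, p1 + 2)))
    inc_coarse = _filter_years(incidence, p0, p1).aggregate(coarse_spec)
    all_years = list(range(p0, last_future + 1))
    expo = build_exposure_matrix(coarse_groups, all_years, C, config.latency_years,
                                 assume_zero_before=int(C.index.min()))
    sexes = incidence.sexes
    design_fit = build_design(expo, inc_coarse, coarse_groups,
                              list(range(p0, p1 + 1)), sexes)
    pfit = fit_poisson(design_fit)
    out = []
    for per in future_periods:
        design_f = build_design(expo, None, coarse_groups,
                                list(range(per.start, per.end + 1)), sexes)
        mu = predict_poisson(pfit, design_f)
        out.append(float(mu.xs(sex, level="sex").sum()))
    return np.asarray(out)
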