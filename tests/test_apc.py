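"""Power-link APC model: Lexis assembly, fitting, projection."""

import numpy as np
import pytest

from mesoproject.apc import (APCConfig, APCFit, LexisGrid, PowerLinkAPC,
                             apc_linear_predictor, build_lexis, fit_apc,
                             poisson_deviance, predicted_counts, project_apc)
from mesoproject.registry import AgeGroup, IncidenceTable, Period, PopulationTable


def toy_grid(cases, py):
    A, P = np.asarray(cases).shape
    ages = tuple(AgeGroup(10 * i, 10 * i + 10) for i in range(A))
    periods = tuple(Period(2000 + 5 * j, 2004 + 5 * j) for j in range(P))
    return LexisGrid(ages, periods, np.asarray(cases, float),
                     np.asarray(py, float))


class TestLexis:
    def test_cohort_index_formula(self):
        grid = toy_grid(np.ones((3, 3)), np.full((3, 3), 1e5))
        assert grid.cohort_index(1, 2) == 4  # c = A - a + p = 3 - 1 + 2
        assert grid.cohort_index(3, 1) == 1
        assert grid.n_cohorts == 5

    def test_build_from_tables_conserves_totals(self, apc_world):
        _, incidence, population, _ = apc_world
        grid = build_lexis(incidence, population, "male")
        assert grid.cases.sum() == incidence.total(sex="male")
        assert grid.person_years.sum() == pytest.approx(
            population.total(sex="male"))

    def test_incomplete_rectangle_errors(self):
        inc = IncidenceTable.from_records([
            ("male", AgeGroup(0, 40), Period(2000, 2004), 5),
            ("male", AgeGroup(40, 50), Period(2000, 2004), 5),
            ("male", AgeGroup(0, 40), Period(2005, 2009), 5)])
        pop = PopulationTable.from_records([
            ("male", g, p, 1e5)
            for g in (AgeGroup(0, 40), AgeGroup(40, 50))
            for p in (Period(2000, 2004), Period(2005, 2009))])
        with pytest.raises(ValueError, match="missing incidence cell"):
            build_lexis(inc, pop, "male")

    def test_zero_person_years_rejected(self):
        with pytest.raises(ValueError, match="person-years"):
            toy_grid(np.ones((2, 3)), [[1e5, 0.0, 1e5]] * 2)


class TestFit:
    def test_constant_rate_grid_gives_flat_components(self):
        rate = 2e-5
        py = np.full((4, 4), 1e6)
        grid = toy_grid(rate * py, py)
        fit = fit_apc(grid)
        assert np.allclose(fit.age, rate ** 0.2, atol=1e-6)
        assert fit.drift == pytest.approx(0.0, abs=1e-7)
        assert np.allclose(fit.period, 0.0, atol=1e-7)
        assert np.allclose(fit.cohort, 0.0, atol=1e-7)
        assert fit.deviance == pytest.approx(0.0, abs=1e-8)

    def test_age_drift_grid_reproduced_exactly(self):
        # counts equal to the model means: the fit should reach ~zero
        # deviance and reproduce observed period totals
        A_true = np.array([0.05, 0.08, 0.11])
        D_true = 0.004
        py = np.full((3, 4), 1e6)
        eta = apc_linear_predictor(A_true, D_true, np.zeros(4), np.zeros(6))
        grid = toy_grid(py * eta ** 5, py)
        est = PowerLinkAPC().fit(grid)
        assert est.deviance_ == pytest.approx(0.0, abs=1e-6)
        fitted = est.fitted_rates() * py
        assert np.allclose(fitted.sum(axis=0), grid.cases.sum(axis=0),
                           rtol=1e-6)
        assert est.drift_ == pytest.approx(D_true, abs=1e-5)

    def test_matches_statsmodels_power_link_glm(self, apc_world):
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.genmod.families import links
        _, incidence, population, _ = apc_world
        grid = build_lexis(incidence, population, "female")
        est = PowerLinkAPC().fit(grid)
        X, _, _ = PowerLinkAPC._design(grid.n_ages, grid.n_periods)
        if links.Power not in sm.families.Poisson.links:
            sm.families.Poisson.links.append(links.Power)
        glm = sm.GLM(grid.rates.ravel(), X,
                     family=sm.families.Poisson(link=links.Power(0.2)),
                     var_weights=grid.person_years.ravel())
        res = glm.fit()
        assert est.deviance_ == pytest.approx(res.deviance, abs=1e-6)
        assert est.drift_ == pytest.approx(res.params[grid.n_ages], abs=1e-8)

    def test_identifiability_constraints_hold(self, apc_world):
        _, incidence, population, _ = apc_world
        grid = build_lexis(incidence, population, "male")
        fit = fit_apc(grid)
        for comp in (fit.period, fit.cohort):
            idx = np.arange(1, len(comp) + 1)
            assert comp.sum() == pytest.approx(0.0, abs=1e-10)
            assert (comp * idx).sum() == pytest.approx(0.0, abs=1e-9)

    def test_too_few_periods_rejected(self):
        grid = toy_grid(np.ones((3, 2)), np.full((3, 2), 1e5))
        with pytest.raises(ValueError, match="at least 3"):
            fit_apc(grid)


def test_gauge_invariance_of_linear_predictor():
    """Moving a linear-in-p trend between P and (D, A) leaves rates fixed."""
    rng = np.random.default_rng(0)
    A, D = rng.uniform(0.05, 0.15, 5), 0.006
    Pv, Cv = rng.normal(0, 0.002, 4), rng.normal(0, 0.002, 8)
    alpha = 0.003
    p_idx = np.arange(1, 5)
    eta1 = apc_linear_predictor(A, D, Pv, Cv)
    eta2 = apc_linear_predictor(A + alpha * p_idx.mean(), D - alpha,
                                Pv + alpha * (p_idx - p_idx.mean()), Cv)
    assert np.allclose(eta1, eta2)


def make_fit(age, drift, n_periods, n_ages=None):
    n_ages = n_ages or len(age)
    return APCFit(age_labels=tuple(f"g{i}" for i in range(n_ages)),
                  period_labels=tuple(f"{2000 + 5 * j}-{2004 + 5 * j}"
                                      for j in range(n_periods)),
                  age=np.asarray(age, float), drift=drift,
                  period=np.zeros(n_periods),
                  cohort=np.zeros(n_ages + n_periods - 1), deviance=0.0)


class TestProjection:
    def test_no_trend_repeats_last_observed_rates(self):
        fit = make_fit([0.06, 0.1], drift=0.0, n_periods=4)
        py = np.full((2, 3), 1e6)
        proj = project_apc(fit, py, 3)
        last = np.array([0.06, 0.1]) ** 5
        for k in range(3):
            assert np.allclose(proj.rates[:, k], last)

    def test_hand_computed_attenuated_drift(self):
        # single age group, attenuation (1, 0.75): second projected period
        # rate is (A + D*(P + 1 + 0.75))^5
        A, D, P = 0.08, 0.005, 4
        fit = make_fit([A], drift=D, n_periods=P)
        cfg = APCConfig(attenuation=(1.0, 0.75))
        proj = project_apc(fit, np.full((1, 2), 1e6), 2, cfg)
        assert proj.rates[0, 0] == pytest.approx((A + D * (P + 1.0)) ** 5)
        assert proj.rates[0, 1] == pytest.approx((A + D * (P + 1.75)) ** 5)

    def test_counts_linear_in_person_years(self):
        fit = make_fit([0.06, 0.1], drift=0.004, n_periods=4)
        py = np.full((2, 2), 1e6)
        p1 = project_apc(fit, py, 2)
        p2 = project_apc(fit, 2 * py, 2)
        assert np.allclose(p2.expected, 2 * p1.expected)
        assert np.allclose(p2.rates, p1.rates)

    def test_zero_attenuation_equals_zero_drift(self):
        fit = make_fit([0.06, 0.1], drift=0.004, n_periods=4)
        fit0 = make_fit([0.06, 0.1], drift=0.0, n_periods=4)
        py = np.full((2, 2), 1e6)
        cfg = APCConfig(attenuation=(0.0, 0.0))
        proj = project_apc(fit, py, 2, cfg)
        base = project_apc(fit0, py, 2)
        # beyond the last observed period no drift accumulates, but the
        # within-observation drift D*P stays in the linear predictor
        ref = (np.array([[0.06], [0.1]]) + 0.004 * 4) ** 5
        assert np.allclose(proj.rates, ref)
        assert np.allclose(base.rates, np.array([[0.06], [0.1]]) ** 5)

    def test_negative_linear_predictor_truncates_to_zero(self):
        fit = make_fit([0.02], drift=-0.01, n_periods=4)
        proj = project_apc(fit, np.full((1, 2), 1e6), 2,
                           APCConfig(attenuation=(1.0, 1.0)))
        assert proj.rates[0, 1] == 0.0

    def test_horizon_beyond_attenuation_errors(self):
        fit = make_fit([0.06], drift=0.004, n_periods=4)
        with pytest.raises(ValueError, match="attenuation"):
            project_apc(fit, np.full((1, 5), 1e6), 5)


class TestPredictedCounts:
    def test_margins_sum_to_grand_total(self):
        fit = make_fit([0.06, 0.1, 0.12], drift=0.004, n_periods=4)
        proj = project_apc(fit, np.full((3, 4), 1e6), 4)
        total = predicted_counts(proj, "total").iloc[0]
        assert predicted_counts(proj, "period").sum() == pytest.approx(total)
        assert predicted_counts(proj, "age").sum() == pytest.approx(total)

    def test_single_cell(self):
        fit = make_fit([0.06], drift=0.0, n_periods=4)
        proj = project_apc(fit, np.full((1, 1), 1e6), 1)
        assert predicted_counts(proj, "period").iloc[0] == pytest.approx(
            proj.expected[0, 0])


def test_deviance_zero_at_equal_counts():
    y = np.array([0.0, 3.0, 10.0])
    assert poisson_deviance(y, np.maximum(y, 1e-300)) <= 1e-6
    assert poisson_deviance(y, y + 1.0) > 0
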