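"""Exposure-driven Poisson regression: design, fit, predict."""

import numpy as np
import pandas as pd
import pytest

from mesoproject.poisson import (PoissonDesign, PoissonFit, build_design,
                                 fit_poisson, predict_poisson)
from mesoproject.synthetic import ExposureScenario, simulate_exposure_counts


def poisson_loglik(y, mu):
    return float(np.sum(y * np.log(mu) - mu))


class TestDesign:
    def test_column_structure(self, exposure_world):
        scenario, incidence, truth = exposure_world
        design = build_design(truth["exposure"], incidence,
                              scenario.age_groups, scenario.years)
        # 6 age groups: const + exposure + sex + 5 age dummies + 5 interactions
        assert len(design.columns) == 13
        assert design.columns[:3] == ("const", "exposure", "sex")

    def test_baseline_male_row(self, exposure_world):
        scenario, incidence, truth = exposure_world
        design = build_design(truth["exposure"], incidence,
                              scenario.age_groups, scenario.years)
        row = design.X.loc[("male", "0-39", 2000)]
        assert row["sex"] == 1.0
        assert (row.filter(like="age_") == 0.0).all()

    def test_exposure_zero_below_latency(self, exposure_world):
        scenario, incidence, truth = exposure_world
        design = build_design(truth["exposure"], incidence,
                              scenario.age_groups, scenario.years)
        assert (design.X.xs("0-39", level="age_group")["exposure"] == 0.0).all()

    def test_exposure_shared_across_sexes(self, exposure_world):
        scenario, incidence, truth = exposure_world
        design = build_design(truth["exposure"], incidence,
                              scenario.age_groups, scenario.years)
        male = design.X.xs("male", level="sex")["exposure"]
        female = design.X.xs("female", level="sex")["exposure"]
        pd.testing.assert_series_equal(male, female)

    def test_missing_count_cell_errors(self, exposure_world):
        scenario, incidence, truth = exposure_world
        trimmed = type(incidence)(incidence.data.iloc[1:])
        with pytest.raises(ValueError, match="missing count cell"):
            build_design(truth["exposure"], trimmed,
                         scenario.age_groups, scenario.years)


class TestFit:
    def test_intercept_only_saturated(self):
        design = PoissonDesign(pd.DataFrame({"const": [1.0]}),
                               pd.Series([7]))
        fit = fit_poisson(design)
        assert fit.params["const"] == pytest.approx(np.log(7))

    def test_rank_deficiency_rejected(self):
        X = pd.DataFrame({"const": [1.0, 1.0], "dup": [1.0, 1.0]})
        with pytest.raises(ValueError, match="rank deficient"):
            fit_poisson(PoissonDesign(X, pd.Series([1, 2])))

    def test_score_equation_total_counts_match(self, exposure_world):
        scenario, incidence, truth = exposure_world
        design = build_design(truth["exposure"], incidence,
                              scenario.age_groups, scenario.years)
        fit = fit_poisson(design)
        mu = predict_poisson(fit, design)
        assert mu.sum() == pytest.approx(design.y.sum(), rel=1e-8)

    def test_recovers_beta1_within_3se(self, exposure_world):
        scenario, incidence, truth = exposure_world
        design = build_design(truth["exposure"], incidence,
                              scenario.age_groups, scenario.years)
        fit = fit_poisson(design)
        err = abs(fit.params["exposure"] - scenario.beta_exposure)
        assert err < 3 * fit.se()["exposure"]

    def test_optimum_dominates_generating_beta(self, exposure_world):
        scenario, incidence, truth = exposure_world
        design = build_design(truth["exposure"], incidence,
                              scenario.age_groups, scenario.years)
        fit = fit_poisson(design)
        y = design.y.to_numpy(float)
        X = design.X.to_numpy(float)
        ll_hat = poisson_loglik(y, np.exp(X @ fit.params.to_numpy()))
        ll_true = poisson_loglik(y, truth["mu"].to_numpy())
        assert ll_hat >= ll_true - 1e-8

    def test_rmse_of_beta1_decreases_with_information(self):
        """Consistency: scaling all means up shrinks the beta1 error."""
        rmse = []
        for extra in (0.0, np.log(100.0)):
            errs = []
            for seed in range(4):
                sc = ExposureScenario(seed=200 + seed,
                                      beta_const=0.5 + extra)
                inc, truth = simulate_exposure_counts(sc)
                design = build_design(truth["exposure"], inc,
                                      sc.age_groups, sc.years)
                fit = fit_poisson(design)
                errs.append(fit.params["exposure"] - sc.beta_exposure)
            rmse.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert rmse[1] < rmse[0]


class TestPredict:
    def test_constant_model_predicts_constant(self, exposure_world):
        scenario, incidence, truth = exposure_world
        design = build_design(truth["exposure"], None,
                              scenario.age_groups, scenario.years)
        params = pd.Series(0.0, index=list(design.columns))
        params["const"] = np.log(5.0)
        fit = PoissonFit(params, pd.DataFrame(np.eye(len(params)),
                                              index=params.index,
                                              columns=params.index), 0.0, True)
        mu = predict_poisson(fit, design)
        assert np.allclose(mu.to_numpy(), 5.0)

    def test_beta1_zero_ignores_exposure(self, exposure_world):
        scenario, incidence, truth = exposure_world
        design = build_design(truth["exposure"], None,
                              scenario.age_groups, scenario.years)
        params = pd.Series(0.1, index=list(design.columns))
        params["exposure"] = 0.0
        fit = PoissonFit(params, pd.DataFrame(np.eye(len(params)),
                                              index=params.index,
                                              columns=params.index), 0.0, True)
        bumped = PoissonDesign(design.X.assign(exposure=design.X["exposure"] + 7.0))
        assert np.allclose(predict_poisson(fit, design).to_numpy(),
                           predict_poisson(fit, bumped).to_numpy())

    def test_affine_exposure_recoding_gauge(self, exposure_world):
        scenario, incidence, truth = exposure_world
        design = build_design(truth["exposure"], incidence,
                              scenario.age_groups, scenario.years)
        fit = fit_poisson(design)
        c, s = 3.0, 2.0   # x = s*x' - c with x' = (x + c)/s, keeping x' >= 0
        recoded = PoissonDesign(
            design.X.assign(exposure=(design.X["exposure"] + c) / s))
        params = fit.params.copy()
        params["exposure"] = fit.params["exposure"] * s
        params["const"] = fit.params["const"] - fit.params["exposure"] * c
        adj = PoissonFit(params, fit.cov, fit.deviance, True)
        assert np.allclose(predict_poisson(adj, recoded).to_numpy(),
                           predict_poisson(fit, design).to_numpy())

    def test_structure_mismatch_errors(self, exposure_world):
        scenario, incidence, truth = exposure_world
        design = build_design(truth["exposure"], incidence,
                              scenario.age_groups, scenario.years)
        fit = fit_poisson(design)
        shuffled = PoissonDesign(design.X[list(design.X.columns[::-1])])
        with pytest.raises(ValueError, match="structure"):
            predict_poisson(fit, shuffled)

    def test_annual_predictions_aggregate_to_period(self, exposure_world):
        scenario, incidence, truth = exposure_world
        design = build_design(truth["exposure"], incidence,
                              scenario.age_groups, scenario.years)
        fit = fit_poisson(design)
        mu = predict_poisson(fit, design)
        male = mu.xs("male", level="sex")
        window = [y for y in scenario.years if 2009 <= y <= 2013]
        annual_sum = sum(male.xs(y, level="year").sum() for y in window)
        block = male[male.index.get_level_values("year").isin(window)].sum()
        assert block == pytest.approx(annual_sum)
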