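import math

import numpy as np
import pytest

from radrisk import (BaselineModel, DoseResponse, PersonYearTable,
                     PoissonRiskModel, RiskModel, deviance_decomposition,
                     fit, poisson_deviance)
from radrisk.model import EvaluationError

from conftest import lnt_spec, make_cell


def _flat_model(h0, err=0.0, transfer="ERR", free=()):
    return RiskModel(transfer, BaselineModel(intercept=math.log(h0),
                                             free=[f for f in free
                                                   if f == "intercept"]),
                     DoseResponse("lnt", err=err,
                                  free={f for f in free if f == "err"}))


class TestDeviance:
    def test_saturated_model_gives_zero(self):
        # lambda = deaths in every cell
        cells = [make_cell(dose_cat=i, mean_dose=0.1 * i,
                           person_years=1000.0, deaths={"cvd": 3})
                 for i in range(3)]
        table = PersonYearTable(cells, causes=["cvd"])
        model = _flat_model(3.0 / 1000.0)
        assert poisson_deviance(table, model, "cvd") == \
            pytest.approx(0.0, abs=1e-10)

    def test_single_cell_closed_form(self):
        # d = 2, lambda = 1: dev = 2 (2 ln 2 - 1)
        table = PersonYearTable([make_cell(person_years=1000.0,
                                           deaths={"cvd": 2})],
                                causes=["cvd"])
        model = _flat_model(1.0 / 1000.0)
        assert poisson_deviance(table, model, "cvd") == \
            pytest.approx(2 * (2 * math.log(2) - 1))

    def test_empty_cell_reduces_to_two_lambda(self):
        table = PersonYearTable([make_cell(person_years=1000.0,
                                           deaths={"cvd": 0})],
                                causes=["cvd"])
        model = _flat_model(3.0 / 1000.0)
        assert poisson_deviance(table, model, "cvd") == pytest.approx(6.0)

    def test_inadmissible_model_raises(self):
        table = PersonYearTable([make_cell(mean_dose=1.0,
                                           deaths={"cvd": 1})],
                                causes=["cvd"])
        model = _flat_model(1e-3, err=-1.5)
        with pytest.raises(EvaluationError):
            poisson_deviance(table, model, "cvd")


class TestFit:
    def test_all_parameters_fixed_returns_evaluated_deviance(
            self, tiny_table):
        model = _flat_model(2e-3)
        res = fit(tiny_table, model, "cvd")
        assert res.n_par == 0
        assert res.deviance == pytest.approx(
            poisson_deviance(tiny_table, model, "cvd"))
        assert res.converged

    def test_intercept_only_matches_analytic_mle(self, default_table):
        # with a single flat rate the Poisson MLE is total deaths over
        # total person-years
        table, _ = default_table
        res = fit(table, _flat_model(1e-3, free=("intercept",)), "cvd",
                  n_restarts=1)
        rate = table.total_deaths("cvd") / table.total_person_years
        assert res.params["bl.intercept"] == \
            pytest.approx(math.log(rate), abs=1e-4)

    def test_matches_poisson_glm_oracle(self, default_table):
        # zero-dose log-linear model: independent GLM fit with
        # log person-years offset must agree on estimates and deviance
        statsmodels = pytest.importorskip("statsmodels.api")
        table, _ = default_table
        bl = BaselineModel(intercept=-5.5, log_age=4.0, sex=0.0,
                           free=("intercept", "log_age", "sex"))
        model = RiskModel("ERR", bl, DoseResponse("lnt", err=0.0))
        res = fit(table, model, "cvd", n_restarts=1)

        _, sex, a, _, _, pyr, deaths = table.arrays("cvd")
        X = np.column_stack([np.ones(len(a)), np.log(a / 70),
                             (sex == "female").astype(float)])
        glm = statsmodels.GLM(deaths, X,
                              family=statsmodels.families.Poisson(),
                              offset=np.log(pyr)).fit()
        assert res.params["bl.intercept"] == \
            pytest.approx(glm.params[0], abs=2e-3)
        assert res.params["bl.log_age"] == \
            pytest.approx(glm.params[1], abs=2e-3)
        assert res.params["bl.sex"] == pytest.approx(glm.params[2],
                                                     abs=2e-3)
        assert res.deviance == pytest.approx(glm.deviance, abs=0.01)
        # Wald uncertainties agree with the GLM information matrix
        se = res.wald_se
        assert se["bl.intercept"] == pytest.approx(glm.bse[0], rel=0.05)
        assert se["bl.log_age"] == pytest.approx(glm.bse[1], rel=0.05)

    def test_recovers_true_slope_within_three_se(self, default_table):
        table, truth = default_table
        res = fit(table, lnt_spec(), "cvd", n_restarts=1)
        err_true = truth["dose_response"]["err"]
        assert res.converged
        assert abs(res.params["dr.err"] - err_true) < \
            3 * res.wald_se["dr.err"]

    def test_quadratic_toy_problem_matches_analytic_minimum(self):
        # one cell, free err on a quadratic shape: the deviance is
        # minimised where expected deaths equal observed deaths, i.e.
        # 1.12 err D^2 = d/(h0 pyr) - 1
        d, pyr, h0, D = 12, 1000.0, 8.0 / 1000.0, 1.5
        table = PersonYearTable([make_cell(mean_dose=D, person_years=pyr,
                                           deaths={"cvd": d})],
                                causes=["cvd"])
        model = RiskModel("ERR", BaselineModel(intercept=math.log(h0)),
                          DoseResponse("quadratic", err=0.1, free={"err"}))
        res = fit(table, model, "cvd", n_restarts=1)
        analytic = (d / (h0 * pyr) - 1) / (1.12 * D ** 2)
        assert res.params["dr.err"] == pytest.approx(analytic, rel=1e-4)

    def test_restarts_keep_best_optimum(self, tiny_table):
        model = _flat_model(1e-3, free=("intercept",))
        res0 = fit(tiny_table, model, "cvd", n_restarts=0)
        res3 = fit(tiny_table, model, "cvd", n_restarts=3)
        assert res3.deviance <= res0.deviance + 1e-6

    def test_unknown_cause_rejected(self, tiny_table):
        with pytest.raises(ValueError, match="cause"):
            PoissonRiskModel(tiny_table, _flat_model(1e-3), "leukemia")


class TestNestedMonotonicity:
    def test_larger_model_never_fits_worse(self, default_table):
        table, _ = default_table
        small = lnt_spec()
        res_small = fit(table, small, "cvd", n_restarts=1)

        bl = BaselineModel(intercept=-5.7, log_age=4.0, sex=0.0,
                           free=("intercept", "log_age", "sex"))
        large = RiskModel("ERR", bl,
                          DoseResponse("linear-quadratic", err1=0.1,
                                       err2=0.0, free={"err1", "err2"}))
        res_large = fit(table, large, "cvd", n_restarts=1)
        assert res_large.deviance <= res_small.deviance + 0.05


class TestWaldScaling:
    def test_se_shrinks_with_cohort_scale(self):
        from radrisk import SyntheticConfig, generate_table
        scale = 4.0
        base = SyntheticConfig(seed=3)
        big = SyntheticConfig(seed=3,
                              total_person_years=base.total_person_years
                              * scale,
                              target_deaths=base.target_deaths * scale)
        se = {}
        for name, cfg in (("base", base), ("big", big)):
            table, _ = generate_table(cfg)
            res = fit(table, lnt_spec(), "cvd", n_restarts=1)
            se[name] = res.wald_se["dr.err"]
        ratio = se["base"] / se["big"]
        assert ratio == pytest.approx(math.sqrt(scale), rel=0.25)


class TestDevianceDecomposition:
    def test_groups_sum_to_total_deviance(self, default_table):
        table, _ = default_table
        model = lnt_spec()
        out = deviance_decomposition(table, model, "cvd",
                                     [0, 0.1, 0.5, 1.0, 5.0],
                                     [30, 60, 75, 100])
        assert out["deviance"].sum() == pytest.approx(
            poisson_deviance(table, model, "cvd"), rel=1e-12)

    def test_single_group_equals_total(self, tiny_table):
        model = _flat_model(2e-3)
        out = deviance_decomposition(tiny_table, model, "cvd",
                                     [0, 10], [0, 120])
        assert len(out) == 1
        assert out["deviance"].iloc[0] == pytest.approx(
            poisson_deviance(tiny_table, model, "cvd"))

    def test_saturated_model_all_groups_zero(self):
        cells = [make_cell(dose_cat=i, mean_dose=0.2 * i, age_cat=i,
                           mean_age=50.0 + 10 * i, person_years=1000.0,
                           deaths={"cvd": 4}) for i in range(3)]
        table = PersonYearTable(cells, causes=["cvd"])
        model = _flat_model(4.0 / 1000.0)
        out = deviance_decomposition(table, model, "cvd", [0, 1],
                                     [40, 90])
        assert np.allclose(out["deviance"], 0.0, atol=1e-10)

    def test_matches_per_cell_accumulation(self, default_table):
        from scipy.special import xlogy
        table, _ = default_table
        model = lnt_spec()
        dose_bins, age_bins = [0, 0.3, 5.0], [30, 70, 100]
        out = deviance_decomposition(table, model, "cvd", dose_bins,
                                     age_bins)
        # brute force
        acc = {}
        for c in table:
            lam = float(model.hazard(c.city, c.sex, c.mean_age,
                                     c.mean_agex, c.mean_dose)
                        * c.person_years)
            d = c.deaths["cvd"]
            term = 2 * (xlogy(d, d / lam) - (d - lam))
            i = 0 if c.mean_dose < 0.3 else 1
            j = 0 if c.mean_age < 70 else 1
            acc[(i, j)] = acc.get((i, j), 0.0) + term
        for i in range(2):
            for j in range(2):
                assert out["deviance"].iloc[i * 2 + j] == \
                    pytest.approx(acc[(i, j)], rel=1e-10)
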