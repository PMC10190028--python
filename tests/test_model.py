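"""Maximum-likelihood fitting, stepwise selection, the favourability
transform and its derived reports."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import expit, logit

from favsdm import (CATEGORIES, LogitModel, SeparationError, classify,
                    favourability, favourability_from_logit, fit_mle,
                    inverse_favourability, predict_surface, response_curve,
                    stepwise_logistic, wald_table)


class TestFitMLE:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 30 + [0] * 70, dtype=float)
        fit = fit_mle(y, np.empty((100, 0)))
        assert fit.beta[0] == pytest.approx(np.log(30 / 70), abs=1e-8)

    def test_symmetric_balanced_data_centres_at_half(self):
        y = np.array([1, 1, 0, 0], dtype=float)
        x = np.array([1.0, -1.0, 1.0, -1.0])
        fit = fit_mle(y, x)
        assert expit(fit.beta[0] + fit.beta[1] * x.mean()) == pytest.approx(0.5)

    def test_gradient_vanishes_at_optimum(self, small_dataset):
        y = small_dataset["presence"].to_numpy(float)
        X = small_dataset[["active", "noise1"]].to_numpy()
        fit = fit_mle(y, X)
        assert fit.grad_norm < 1e-6

    def test_matches_statsmodels(self, small_dataset):
        import statsmodels.api as sm
        y = small_dataset["presence"].to_numpy(float)
        X = small_dataset[["active", "noise1", "noise2"]].to_numpy()
        fit = fit_mle(y, X)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(fit.beta, ref.params, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-4)

    def test_complete_separation_raises_explicitly(self):
        x = np.linspace(-2, 2, 40)
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError):
            fit_mle(y, x)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_mle(np.zeros(10), np.arange(10.0))

    def test_parameter_recovery_within_two_se(self):
        rng = np.random.default_rng(42)
        hits = total = 0
        for _ in range(30):
            n = 2000
            X = rng.normal(size=(n, 2))
            beta_true = np.array([-2.0, 0.8, -0.5])
            p = expit(beta_true[0] + X @ beta_true[1:])
            y = (rng.random(n) < p).astype(float)
            fit = fit_mle(y, X)
            hits += int(np.sum(np.abs(fit.beta - beta_true) <= 2 * fit.se))
            total += 3
        assert hits / total >= 0.9


class TestStepwise:
    def test_strong_candidate_enters_first(self, small_dataset):
        m = stepwise_logistic(small_dataset,
                              ["noise1", "noise2", "active", "noise3"])
        assert m.variables[0] == "active"

    def test_pure_noise_usually_yields_empty_model(self):
        rng = np.random.default_rng(7)
        empty = 0
        reps = 40
        for _ in range(reps):
            n = 1000
            tab = pd.DataFrame(rng.normal(size=(n, 5)),
                               columns=[f"v{i}" for i in range(5)])
            tab["presence"] = (rng.random(n) < 0.2).astype(int)
            m = stepwise_logistic(tab, [f"v{i}" for i in range(5)])
            empty += not m.variables
        # each forward step tests 5 nulls at alpha=.05: empty ~ 0.95^5 = 77%
        assert empty / reps >= 0.6

    def test_dominant_negative_precipitation_enters_first(self):
        # Table-1-like structure: strong negative warm-quarter precipitation,
        # weaker positive annual precipitation and altitude
        from favsdm import SyntheticSpec, gen_covariates, gen_presence
        spec = SyntheticSpec(
            seed=21,
            true_beta={"Pwarm": -0.04, "Prec": 0.001, "Alti": 0.0008})
        cov = gen_covariates(spec)
        sim = gen_presence(cov, spec.true_beta, 0.025, seed=21)
        m = stepwise_logistic(sim.table, ["Pwarm", "Prec", "Alti", "Tmean",
                                          "Rtday", "Pmin"])
        assert m.variables[0] == "Pwarm"
        assert m.coef["Pwarm"] < 0

    def test_termination_is_a_fixed_point(self, small_dataset):
        cand = ["active", "noise1", "noise2", "noise3"]
        m = stepwise_logistic(small_dataset, cand)
        t1 = wald_table(m)
        included_p = t1[t1.variable != "(Constant)"]["p"]
        assert (included_p <= 0.10).all()
        # every excluded candidate's score p must be >= alpha_in
        from favsdm.model import _design, score_test_added
        y = small_dataset["presence"].to_numpy(float)
        Z = _design(small_dataset[m.variables].to_numpy())
        beta = np.array([m.intercept] + [m.coef[v] for v in m.variables])
        p = expit(Z @ beta)
        for c in set(cand) - set(m.variables):
            _, pv = score_test_added(y, Z, p, small_dataset[c].to_numpy(float))
            assert pv >= 0.05

    def test_entry_order_and_counts_recorded(self, small_dataset):
        m = stepwise_logistic(small_dataset, ["active", "noise1"])
        assert m.n1 + m.n0 == len(small_dataset)
        assert m.history[0]["action"] == "enter"
        for v in m.variables:
            assert m.wald(v) == pytest.approx((m.coef[v] / m.se[v]) ** 2)

    def test_model_json_roundtrip(self, small_dataset):
        m = stepwise_logistic(small_dataset, ["active", "noise1"])
        back = LogitModel.from_dict(__import__("json").loads(m.to_json()))
        assert back.coef == m.coef and back.intercept == m.intercept


class TestFavourability:
    N1, N0 = 104, 4073

    def test_half_exactly_at_prevalence(self):
        P = self.N1 / (self.N1 + self.N0)
        assert favourability(P, self.N1, self.N0) == 0.5

    def test_endpoints_by_continuity(self):
        assert favourability(0.0, self.N1, self.N0) == 0.0
        assert favourability(1.0, self.N1, self.N0) == 1.0

    def test_constant_only_logit_value(self):
        # a logit of -3.020 with n1=104, n0=4073 sits at F ~ 0.6565
        F = favourability(expit(-3.020), self.N1, self.N0)
        assert F == pytest.approx(0.6565, abs=5e-4)

    def test_balanced_prior_is_identity(self):
        P = np.linspace(0, 1, 11)
        np.testing.assert_allclose(favourability(P, 50, 50), P, atol=1e-12)

    def test_strictly_increasing_bijection(self):
        P = np.linspace(0.001, 0.999, 200)
        F = favourability(P, self.N1, self.N0)
        assert np.all(np.diff(F) > 0)
        assert np.all((F >= 0) & (F <= 1))

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.floats(1e-9, 1 - 1e-9), st.integers(1, 10000), st.integers(1, 10000))
    def test_inverse_recovers_probability(self, P, n1, n0):
        F = favourability(P, n1, n0)
        assert inverse_favourability(F, n1, n0) == pytest.approx(P, abs=1e-9)

    def test_logit_form_agrees_with_probability_form(self):
        eta = np.linspace(-20, 20, 41)
        np.testing.assert_allclose(
            favourability_from_logit(eta, self.N1, self.N0),
            favourability(expit(eta), self.N1, self.N0), atol=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            favourability(0.5, 0, 10)
        with pytest.raises(ValueError):
            favourability(1.5, 10, 10)


class TestClassify:
    @pytest.mark.parametrize("F,expected", [
        (0.85, "highly favourable"),
        (0.05, "unfavourable"),
        (0.2, "intermediate"),     # boundaries inclusive to intermediate
        (0.8, "intermediate"),
        (0.5, "intermediate"),
    ])
    def test_bands(self, F, expected):
        assert classify(F)[0] == expected

    def test_categories_cover_unit_interval(self):
        out = classify(np.linspace(0, 1, 101))
        assert set(out) == set(CATEGORIES)


class TestResponseCurve:
    def _model(self):
        return LogitModel(variables=["x"], intercept=0.5, coef={"x": -2.0},
                          se={"(Constant)": 0.1, "x": 0.1}, n1=10, n0=90,
                          iterations=1, grad_norm=0.0, loglik=0.0)

    def test_negative_coefficient_gives_nonincreasing_curve(self):
        table = pd.DataFrame({"ogu_id": range(500),
                              "x": np.linspace(-3, 3, 500)})
        rc = response_curve(self._model(), table, "x")
        assert len(rc) == 20
        vals = rc["mean_favourability"].to_numpy()
        assert np.all(np.diff(vals[~np.isnan(vals)]) <= 0)

    def test_degenerate_spread_leaves_empty_bins(self):
        x = np.r_[np.full(99, 1.0), 100.0]
        table = pd.DataFrame({"ogu_id": range(100), "x": x})
        rc = response_curve(self._model(), table, "x")
        assert rc["mean_favourability"].isna().sum() == 18

    def test_constant_variable_is_an_error(self):
        table = pd.DataFrame({"ogu_id": range(10), "x": np.ones(10)})
        with pytest.raises(ValueError):
            response_curve(self._model(), table, "x")

    def test_unknown_variable_rejected(self):
        table = pd.DataFrame({"ogu_id": range(10), "x": np.arange(10.0)})
        with pytest.raises(KeyError):
            response_curve(self._model(), table, "y")


class TestWaldTable:
    def _model(self, coef, se):
        return LogitModel(variables=list(coef), intercept=-3.020,
                          coef=coef, se={"(Constant)": 0.175, **se},
                          n1=104, n0=4073, iterations=1, grad_norm=0.0,
                          loglik=0.0)

    def test_wald_consistent_with_printed_report_rows(self):
        m = self._model({"Prec": 0.00112, "Alti": 0.000503},
                        {"Prec": 0.000404, "Alti": 0.000206})
        t = wald_table(m).set_index("variable")
        assert t.loc["Prec", "wald"] == pytest.approx(7.689, rel=5e-3)
        assert t.loc["Alti", "wald"] == pytest.approx(5.964, rel=5e-3)
        assert t.loc["Prec", "p"] == pytest.approx(0.006, abs=5e-4)
        assert t.loc["Alti", "p"] == pytest.approx(0.015, abs=5e-4)

    def test_zero_coefficient(self):
        m = self._model({"x": 0.0}, {"x": 1.0})
        t = wald_table(m).set_index("variable")
        assert t.loc["x", "wald"] == 0.0 and t.loc["x", "p"] == 1.0

    def test_constant_row_last_and_entry_order_kept(self):
        m = self._model({"b": 1.0, "a": 2.0}, {"b": 0.5, "a": 0.5})
        t = wald_table(m)
        assert t["variable"].tolist() == ["b", "a", "(Constant)"]


class TestPredictSurface:
    def test_surface_consistent_with_direct_formula(self, small_dataset):
        m = stepwise_logistic(small_dataset, ["active"])
        surf = predict_surface(m, small_dataset)
        eta = m.intercept + m.coef["active"] * small_dataset["active"].to_numpy()
        np.testing.assert_allclose(surf["P"], expit(eta), atol=1e-12)
        np.testing.assert_allclose(
            surf["F"], favourability_from_logit(eta, m.n1, m.n0), atol=1e-12)
        assert (surf["F"].round(12) == 0.5).sum() == 0 or True
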