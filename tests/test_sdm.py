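import numpy as np
import pandas as pd
import pytest

from flaps.sdm import (
    all_subsets,
    auc_score,
    builtin_swine_model,
    choose_form,
    kfold_auc,
    model_average,
    predict_surface,
    screen_collinearity,
    variable_importance,
)

from conftest import logistic_sample


class TestScreenCollinearity:
    def test_identical_covariates_one_dropped(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        df = pd.DataFrame({"y": rng.integers(0, 2, 500), "a": x, "b": x})
        retained, dropped = screen_collinearity(df)
        assert retained == ["a"]
        assert dropped[0][2] == pytest.approx(1.0)

    def test_preference_order_decides_which_survives(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=2000)
        # analog of the road/development correlation: |r| ≈ 0.78
        x2 = x + rng.normal(scale=0.55, size=2000)
        r = pd.Series(x).corr(pd.Series(x2), method="spearman")
        assert abs(r) >= 0.7
        df = pd.DataFrame({"y": rng.integers(0, 2, 2000), "dDevelop": x2, "dRoads": x})
        retained, dropped = screen_collinearity(df, prefer=["dRoads"])
        assert retained == ["dRoads"]
        assert dropped[0][0] == "dDevelop"

    def test_independent_covariates_all_retained(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {"y": rng.integers(0, 2, 3000)}
            | {c: rng.normal(size=3000) for c in "abcd"}
        )
        retained, dropped = screen_collinearity(df)
        assert retained == list("abcd") and dropped == []

    def test_constant_covariate_is_an_error(self):
        df = pd.DataFrame({"y": [0, 1] * 10, "a": [1.0] * 20, "b": range(20)})
        with pytest.raises(ValueError, match="constant"):
            screen_collinearity(df)


class TestChooseForm:
    def test_recovers_quadratic_generating_form(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=2000)
        y = (rng.uniform(size=2000) < 1 / (1 + np.exp(-(1.5 * x**2 - 1)))).astype(int)
        assert choose_form(pd.DataFrame({"y": y, "x": x}), "x") == "quadratic"

    def test_recovers_linear_generating_form(self):
        rng = np.random.default_rng(4)
        df = logistic_sample(rng, 2000, {"x": 1.2}, intercept=-0.5)
        assert choose_form(df, "x") == "linear"

    def test_builtin_model_forms(self):
        m = builtin_swine_model()
        assert {c for c, f in m.term_forms.items() if f == "quadratic"} == {
            "Slope", "Precip", "dForest", "dUrban", "dWetland", "dBarren"
        }
        assert {c for c, f in m.term_forms.items() if f == "linear"} == {
            "dOpen", "dCrop", "Temp", "dRoads"
        }


class TestAllSubsets:
    def test_one_covariate_two_models(self):
        rng = np.random.default_rng(5)
        df = logistic_sample(rng, 500, {"x": 1.0}, intercept=0.0)
        models = all_subsets(df, ["x"], forms={"x": "linear"})
        assert len(models) == 2
        assert models[0].delta == 0.0
        assert [m.aic for m in models] == sorted(m.aic for m in models)

    def test_true_terms_beat_noise(self):
        rng = np.random.default_rng(6)
        df = logistic_sample(
            rng, 4000, {"a": 1.2, "b": -0.9, "c": 0.7}, intercept=-0.3, n_noise=2
        )
        models = all_subsets(df, ["a", "b", "c", "noise1", "noise2"],
                             forms=dict.fromkeys(
                                 ["a", "b", "c", "noise1", "noise2"], "linear"))
        assert {t[0] for t in models[0].terms} >= {"a", "b", "c"}

    def test_no_signal_keeps_intercept_model_in_window(self):
        rng = np.random.default_rng(7)
        n = 3000
        df = pd.DataFrame({
            "y": rng.integers(0, 2, n),
            "a": rng.normal(size=n),
            "b": rng.normal(size=n),
        })
        models = all_subsets(df, ["a", "b"], forms={"a": "linear", "b": "linear"})
        inter = next(m for m in models if not m.terms)
        assert inter.delta <= 2.0

    def test_aic_identity(self):
        rng = np.random.default_rng(8)
        df = logistic_sample(rng, 1000, {"x": 0.8}, intercept=0.2)
        m = all_subsets(df, ["x"], forms={"x": "linear"})[0]
        assert m.aic == pytest.approx(-2 * m.loglik + 2 * m.k)


class TestModelAverage:
    def test_single_model_passes_through(self):
        rng = np.random.default_rng(9)
        df = logistic_sample(rng, 800, {"x": 1.0}, intercept=0.0)
        models = all_subsets(df, ["x"], forms={"x": "linear"})
        avg = model_average(models[:1])
        assert avg.beta["x"] == pytest.approx(models[0].coefficients["x"])

    def test_equal_aic_averages_halfway_to_zero(self):
        from flaps.sdm import CandidateModel

        a = CandidateModel(terms=(("x", "linear"),),
                           coefficients={"intercept": 0.0, "x": 2.0},
                           stderr={}, loglik=-10.0, aic=22.0, delta=0.0)
        b = CandidateModel(terms=(), coefficients={"intercept": 0.0},
                           stderr={}, loglik=-11.0, aic=22.0, delta=0.0)
        avg = model_average([a, b])
        assert avg.beta["x"] == pytest.approx(1.0)

    def test_window_zero_reduces_to_best_model(self):
        rng = np.random.default_rng(10)
        df = logistic_sample(rng, 2000, {"a": 1.0, "b": -0.5}, intercept=0.0)
        models = all_subsets(df, ["a", "b"], forms={"a": "linear", "b": "linear"})
        avg = model_average(models, window=0.0)
        assert avg.beta["a"] == pytest.approx(models[0].coefficients.get("a", 0.0))

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            model_average([], window=2.0)

    def test_averaged_equation_structurally_matches_builtin(self):
        # the built-in equation has the shape model averaging produces:
        # an intercept plus ten terms with fixed forms
        m = builtin_swine_model()
        assert len(m.beta) == 11 and "intercept" in m.beta
        assert set(m.term_forms) == set(m.beta) - {"intercept"}


class TestBuiltinSwineModel:
    def test_all_zero_covariates_give_intercept_probability(self):
        m = builtin_swine_model()
        zero = {c: np.zeros(1) for c in m.term_forms}
        assert m.logit(zero)[0] == pytest.approx(-0.0563)
        assert m.predict(zero)[0] == pytest.approx(1 / (1 + np.exp(0.0563)), abs=1e-6)
        assert m.predict(zero)[0] == pytest.approx(0.4859, abs=5e-4)

    def test_probability_decreases_away_from_open_areas(self):
        m = builtin_swine_model()
        base = {c: np.zeros(3) for c in m.term_forms}
        base["dOpen"] = np.array([0.0, 500.0, 1000.0])
        p = m.predict(base)
        assert p[0] > p[1] > p[2]

    def test_probability_increases_with_precipitation(self):
        m = builtin_swine_model()
        base = {c: np.zeros(3) for c in m.term_forms}
        base["Precip"] = np.array([0.0, 500.0, 1000.0])
        p = m.predict(base)
        assert p[0] < p[1] < p[2]


class TestPredictSurface:
    def test_constant_rasters_give_scalar_prediction(self):
        m = builtin_swine_model()
        stack = {c: np.full((4, 5), 0.0) for c in m.term_forms}
        surf = predict_surface(m, stack)
        np.testing.assert_allclose(surf.grid, 1 / (1 + np.exp(0.0563)))

    def test_fully_masked_surface_has_no_available_pixels(self):
        m = builtin_swine_model()
        stack = {c: np.zeros((3, 3)) for c in m.term_forms}
        surf = predict_surface(m, stack, mask=np.ones((3, 3), bool))
        assert not surf.available.any()

    def test_surface_equals_closed_form_probability(self):
        rng = np.random.default_rng(11)
        m = builtin_swine_model()
        stack = {c: rng.uniform(0, 100, size=(6, 7)) for c in m.term_forms}
        surf = predict_surface(m, stack)
        eta = m.beta["intercept"] + sum(
            m.beta[c] * (stack[c] ** 2 if m.term_forms[c] == "quadratic" else stack[c])
            for c in m.term_forms
        )
        np.testing.assert_allclose(surf.grid, 1 / (1 + np.exp(-eta)), atol=1e-12)

    def test_shape_mismatch_rejected(self):
        m = builtin_swine_model()
        stack = {c: np.zeros((3, 3)) for c in m.term_forms}
        stack["dOpen"] = np.zeros((2, 2))
        with pytest.raises(ValueError, match="co-registered"):
            predict_surface(m, stack)

    def test_missing_layer_rejected(self):
        m = builtin_swine_model()
        stack = {c: np.zeros((3, 3)) for c in m.term_forms if c != "Temp"}
        with pytest.raises(ValueError, match="Temp"):
            predict_surface(m, stack)

    def test_deterministic_bit_for_bit(self):
        rng = np.random.default_rng(12)
        m = builtin_swine_model()
        stack = {c: rng.uniform(0, 10, size=(5, 5)) for c in m.term_forms}
        a = predict_surface(m, stack).grid
        b = predict_surface(m, stack).grid
        assert (a == b).all()


class TestAuc:
    def test_rank_auc_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(13)
        y = rng.integers(0, 2, 500)
        s = rng.normal(size=500) + y
        assert auc_score(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_separable_data_scores_one_per_fold(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=600)
        df = pd.DataFrame({"y": (x > 0).astype(int), "x": x})
        mean_auc, per_fold = kfold_auc(df, folds=5, seed=0, forms={"x": "linear"})
        assert all(a == pytest.approx(1.0) for a in per_fold)

    def test_null_data_scores_half(self):
        rng = np.random.default_rng(15)
        n = 5000
        df = pd.DataFrame({
            "y": rng.integers(0, 2, n),
            "a": rng.normal(size=n),
            "b": rng.normal(size=n),
        })
        mean_auc, _ = kfold_auc(df, folds=5, seed=1,
                                forms={"a": "linear", "b": "linear"})
        assert mean_auc == pytest.approx(0.5, abs=0.02)

    def test_sample_from_builtin_equation_scores_good_not_excellent(
        self, small_landscape, pa_sample
    ):
        covs = ["dOpen", "dCrop", "Temp", "dRoads", "Slope"]
        forms = {c: builtin_swine_model().term_forms[c] for c in covs}
        mean_auc, _ = kfold_auc(pa_sample, folds=5, seed=2,
                                covariates=covs, forms=forms)
        assert 0.7 <= mean_auc <= 0.9


class TestVariableImportance:
    def test_dominant_effect_ranks_first_and_noise_near_zero(self):
        rng = np.random.default_rng(16)
        df = logistic_sample(rng, 3000, {"big": 2.0, "small": 0.3},
                             intercept=0.0, n_noise=1)
        vi = variable_importance(
            df, folds=3, seed=0,
            forms=dict.fromkeys(["big", "small", "noise1"], "linear"))
        assert vi.index[0] == "big"
        assert abs(vi.loc["noise1", "mean"]) < 0.02

    def test_single_covariate_model_ranks_it_first(self):
        rng = np.random.default_rng(17)
        df = logistic_sample(rng, 1500, {"x": 1.0}, intercept=0.0)
        vi = variable_importance(df, folds=3, seed=0, forms={"x": "linear"})
        assert vi.index[0] == "x"
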