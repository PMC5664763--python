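"""The supervised selection pipeline: stages, trace, estimator interface."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from noiselur.regression import (
    LURRegressor,
    RankDeficiencyError,
    UnivariateResult,
    backward_prune,
    build_lur,
    challenge_variables,
    exhaustive_subset_search,
    final_augment,
    fit_ols,
    forward_selection,
    replay_trace,
    select_best_buffer,
    univariate_screen,
)
from noiselur.variables import CandidateVariable

from conftest import toy_feature_matrix


def var(name, buffer_m=None, sign=0, var_type=None):
    return CandidateVariable(name, var_type or name, "generic", buffer_m, sign, "")


class TestFitOls:
    def test_exact_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        fm = toy_feature_matrix({"x": x})
        y = 3.0 + 2.5 * x
        fit = fit_ols(fm.df, y)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.coefficients["x"] == pytest.approx(2.5, abs=1e-10)
        assert fit.intercept == pytest.approx(3.0, abs=1e-10)
        assert fit.residuals.sum() == pytest.approx(0, abs=1e-8)

    def test_pure_noise(self):
        rng = np.random.default_rng(1)
        fm = toy_feature_matrix({"x": rng.normal(size=1000)})
        y = rng.normal(size=1000)
        fit = fit_ols(fm.df, y)
        assert fit.r2 < 0.02
        assert abs(fit.coefficients["x"]) < 3 * fit.standard_errors["x"]

    def test_duplicate_columns_rank_deficient(self):
        x = np.arange(20.0)
        fm = toy_feature_matrix({"a": x, "b": x})
        with pytest.raises(RankDeficiencyError):
            fit_ols(fm.df, x + 1)

    def test_adjusted_below_r2(self):
        rng = np.random.default_rng(2)
        fm = toy_feature_matrix({f"x{i}": rng.normal(size=30) for i in range(4)})
        y = fm.df["x0"] + rng.normal(0, 1, 30)
        fit = fit_ols(fm.df, y)
        assert fit.adjusted_r2 <= fit.r2
        assert np.var(fit.fitted) <= np.var(np.asarray(y))

    def test_needs_more_sites_than_predictors(self):
        fm = toy_feature_matrix({f"x{i}": np.random.default_rng(i).normal(size=4) for i in range(4)})
        with pytest.raises(ValueError):
            fit_ols(fm.df, np.ones(4))


class TestUnivariateScreen:
    def test_perfect_and_negated(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        fm = toy_feature_matrix({"good": x, "flipped": -x}, signs={"good": +1, "flipped": +1})
        y = pd.Series(x, index=fm.df.index)
        res = {r.variable.name: r for r in univariate_screen(fm, y)}
        assert res["good"].r2 == pytest.approx(1.0)
        assert res["good"].sign_ok
        assert res["flipped"].r2 == pytest.approx(1.0)
        assert not res["flipped"].sign_ok

    def test_uncorrelated(self):
        rng = np.random.default_rng(4)
        fm = toy_feature_matrix({"x": rng.normal(size=2000)})
        y = rng.normal(size=2000)
        (r,) = univariate_screen(fm, y)
        assert r.r2 < 0.01


class TestSelectBestBuffer:
    def _res(self, name, buffer_m, r2, sign_ok, var_type):
        return UnivariateResult(var(name, buffer_m, +1, var_type), 1.0 if sign_ok else -1.0, r2, sign_ok)

    def test_sign_constrained_max_r2(self):
        results = [
            self._res("t_25m", 25, 0.05, True, "t"),
            self._res("t_200m", 200, 0.12, True, "t"),
            self._res("t_500m", 500, 0.30, False, "t"),  # wrong sign, ignored
        ]
        chosen, _ = select_best_buffer(results)
        assert [c.variable.name for c in chosen] == ["t_200m"]

    def test_all_wrong_sign_drops_type(self):
        results = [self._res("t_25m", 25, 0.4, False, "t")]
        chosen, trace = select_best_buffer(results)
        assert chosen == []
        assert trace[0].action == "type_dropped"

    def test_tie_takes_smaller_buffer(self):
        results = [
            self._res("t_100m", 100, 0.2, True, "t"),
            self._res("t_50m", 50, 0.2, True, "t"),
        ]
        chosen, _ = select_best_buffer(results)
        assert chosen[0].variable.name == "t_50m"


def _screened(fm, y):
    return select_best_buffer(univariate_screen(fm, y))[0]


class TestForwardSelection:
    def test_near_duplicate_rejected_by_gate(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=80)
        fm = toy_feature_matrix({"a": x, "b": x + rng.normal(0, 0.1, 80)})
        y = pd.Series(x + rng.normal(0, 0.3, 80), index=fm.df.index)
        fit, trace = forward_selection(_screened(fm, y), fm, y)
        actions = {e.variable: e.action for e in trace}
        assert len(fit.variables) == 1
        assert "rejected_correlation" in actions.values()

    def test_noise_candidate_rejected_no_gain(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=15)
        noise = rng.normal(size=15) * 0.01
        fm = toy_feature_matrix({"signal": x, "noise": noise})
        y = pd.Series(x, index=fm.df.index)  # exact fit: no noise column can help
        fit, trace = forward_selection(_screened(fm, y), fm, y)
        assert fit.variables == ["signal"]
        assert any(e.action == "rejected_no_gain" and e.variable == "noise" for e in trace)

    def test_independent_strong_predictors_all_added(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(200, 3))
        fm = toy_feature_matrix({f"x{i}": X[:, i] for i in range(3)})
        y = pd.Series(X @ [3, 2, 1.5] + rng.normal(0, 0.5, 200), index=fm.df.index)
        fit, trace = forward_selection(_screened(fm, y), fm, y)
        assert sorted(fit.variables) == ["x0", "x1", "x2"]
        accepted = [e for e in trace if e.action == "added"]
        assert all(e.adj_r2_after > e.adj_r2_before for e in accepted)


class TestBackwardPrune:
    def test_all_significant_unchanged(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(100, 2))
        fm = toy_feature_matrix({"a": X[:, 0], "b": X[:, 1]})
        y = pd.Series(X @ [2, 2] + rng.normal(0, 0.5, 100), index=fm.df.index)
        fit = fit_ols(fm.df, y)
        pruned, trace = backward_prune(fit, fm, y)
        assert pruned.variables == fit.variables
        assert trace == []

    def test_noise_variable_removed(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(100, 3))
        fm = toy_feature_matrix({"a": X[:, 0], "b": X[:, 1], "junk": X[:, 2]})
        # junk has no effect: its p-value is ~Uniform; draw a seed where p > 0.2
        y = pd.Series(X[:, :2] @ [3, 2] + rng.normal(0, 0.5, 100), index=fm.df.index)
        fit = fit_ols(fm.df, y)
        assert float(fit.p_values["junk"]) > 0.2
        pruned, trace = backward_prune(fit, fm, y)
        assert pruned.variables == ["a", "b"]
        assert [e.variable for e in trace] == ["junk"]
        assert (pruned.p_values <= 0.2).all()


class TestChallenge:
    def test_swaps_in_generating_buffer(self):
        rng = np.random.default_rng(10)
        true = rng.normal(size=120)
        proxy = true + rng.normal(0, 0.6, 120)  # correlated, weaker carrier
        fm = toy_feature_matrix(
            {"t_200m": true, "t_50m": proxy},
            signs={"t_200m": +1, "t_50m": +1},
        )
        y = pd.Series(2 * true + rng.normal(0, 0.3, 120), index=fm.df.index)
        seeded = fit_ols(fm.df[["t_50m"]], y)
        out, trace = challenge_variables(seeded, fm, y)
        assert out.variables == ["t_200m"]
        assert trace[0].action == "challenged_swap"
        assert trace[0].replaced == "t_50m"
        assert trace[0].adj_r2_after > trace[0].adj_r2_before

    def test_no_improvement_unchanged(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=60)
        fm = toy_feature_matrix({"a": x, "weak": rng.normal(size=60)})
        y = pd.Series(3 * x + rng.normal(0, 0.2, 60), index=fm.df.index)
        fit = fit_ols(fm.df[["a"]], y)
        out, trace = challenge_variables(fit, fm, y)
        assert out.variables == ["a"]
        assert trace == []

    def test_collinear_challenger_blocked(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=100)
        z = rng.normal(size=100)
        strong_but_collinear = z + rng.normal(0, 0.05, 100)
        fm = toy_feature_matrix({"keep": z, "weak": x + rng.normal(0, 1.0, 100), "best": strong_but_collinear})
        y = pd.Series(2 * z + x + rng.normal(0, 0.2, 100), index=fm.df.index)
        fit = fit_ols(fm.df[["keep", "weak"]], y)
        out, _ = challenge_variables(fit, fm, y)
        # "best" (r ~ 1 with "keep") must not replace "weak"
        assert "best" not in out.variables or "keep" not in out.variables


class TestFinalAugment:
    def test_held_out_predictor_added(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(150, 2))
        fm = toy_feature_matrix({"a": X[:, 0], "b": X[:, 1]})
        y = pd.Series(X @ [3, 2] + rng.normal(0, 0.5, 150), index=fm.df.index)
        fit = fit_ols(fm.df[["a"]], y)
        out, trace = final_augment(fit, fm, y)
        assert out.variables == ["a", "b"]
        assert trace[0].action == "augmented"

    def test_high_pvalue_not_kept(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(40, 2))
        fm = toy_feature_matrix({"a": X[:, 0], "b": X[:, 1]})
        y = pd.Series(3 * X[:, 0] + rng.normal(0, 0.5, 40), index=fm.df.index)
        fit = fit_ols(fm.df[["a"]], y)
        out, trace = final_augment(fit, fm, y)
        if trace and trace[0].action == "not_augmented":
            assert out.variables == ["a"]
        else:  # the addition that was kept must satisfy the p-gate
            assert float(out.p_values[out.variables[-1]]) <= 0.2

    def test_at_most_one_addition(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(150, 3))
        fm = toy_feature_matrix({f"x{i}": X[:, i] for i in range(3)})
        y = pd.Series(X @ [3, 2, 2] + rng.normal(0, 0.5, 150), index=fm.df.index)
        fit = fit_ols(fm.df[["x0"]], y)
        out, _ = final_augment(fit, fm, y)
        assert len(out.variables) == 2


class TestBuildLur:
    def _study(self, seed=0, n=150, sigma=0.5):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 5))
        fm = toy_feature_matrix(
            {f"x{i}": X[:, i] for i in range(5)},
            signs={f"x{i}": +1 for i in range(5)},
        )
        y = pd.Series(60 + X[:, :3] @ [3, 2, 1.5] + rng.normal(0, sigma, n), index=fm.df.index)
        return fm, y

    def test_deterministic(self):
        fm, y = self._study()
        m1, m2 = build_lur(fm, y), build_lur(fm, y)
        assert m1.fit.variables == m2.fit.variables
        assert m1.trace == m2.trace
        assert np.allclose(m1.fit.coefficients, m2.fit.coefficients)

    def test_pure_noise_response(self):
        rng = np.random.default_rng(15)
        fm = toy_feature_matrix({f"x{i}": rng.normal(size=100) for i in range(4)})
        y = pd.Series(rng.normal(size=100), index=fm.df.index)
        model = build_lur(fm, y)
        assert model.fit.adjusted_r2 < 0.15
        assert len(model.fit.variables) <= 2

    def test_trace_replay_reproduces_model(self):
        fm, y = self._study(seed=21)
        model = build_lur(fm, y)
        replayed = replay_trace(model.trace, fm, y)
        assert replayed.variables == model.fit.variables
        assert np.allclose(replayed.coefficients, model.fit.coefficients)
        assert replayed.adjusted_r2 == pytest.approx(model.fit.adjusted_r2, abs=1e-12)

    def test_final_model_invariants(self):
        fm, y = self._study(seed=22)
        model = build_lur(fm, y)
        cols = model.fit.variables
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                r = abs(np.corrcoef(fm.df[a], fm.df[b])[0, 1])
                assert r < model.config.corr_threshold
        accepted = [e for e in model.trace if e.action in ("added", "challenged_swap", "augmented")]
        assert all(e.adj_r2_after > e.adj_r2_before for e in accepted)


class TestExhaustiveOracle:
    def test_matches_known_best_subset(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(60, 4))
        fm = toy_feature_matrix({f"x{i}": X[:, i] for i in range(4)})
        y = pd.Series(X[:, 0] * 3 + X[:, 1] * 2, index=fm.df.index)  # noiseless
        best = exhaustive_subset_search(fm, y)
        assert set(best) == {"x0", "x1"}

    def test_correlation_gate_respected(self):
        rng = np.random.default_rng(18)
        x = rng.normal(size=60)
        fm = toy_feature_matrix({"a": x, "b": x + rng.normal(0, 0.05, 60)})
        y = pd.Series(x, index=fm.df.index)
        best = exhaustive_subset_search(fm, y, corr_threshold=0.7)
        assert len(best) == 1


class TestLURRegressorEstimator:
    def test_sklearn_protocol(self):
        est = LURRegressor(corr_threshold=0.65)
        assert est.get_params()["corr_threshold"] == 0.65
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_fit_predict_ndarray(self):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(120, 4))
        y = 50 + X[:, 0] * 3 + rng.normal(0, 0.3, 120)
        est = LURRegressor().fit(X, y)
        assert "x0" in est.variables_
        pred = est.predict(X)
        assert pred.shape == (120,)
        assert np.corrcoef(pred, y)[0, 1] ** 2 > 0.9

    def test_predictions_equal_fitted_on_train(self):
        rng = np.random.default_rng(20)
        X = pd.DataFrame(rng.normal(size=(80, 3)), columns=["a", "b", "c"])
        y = 10 + 2 * X["a"] + rng.normal(0, 0.2, 80)
        est = LURRegressor().fit(X, y)
        assert np.allclose(est.predict(X), est.model_.fit.fitted.to_numpy())

    def test_feature_matrix_input(self, small_feature_matrix):
        rng = np.random.default_rng(23)
        fm = small_feature_matrix
        y = 60 + 5000 * fm.df["hh_density_100m"] + rng.normal(0, 0.5, len(fm.df))
        est = LURRegressor().fit(fm, pd.Series(y, index=fm.df.index))
        assert est.adj_r2_ > 0.5
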