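"""Cox fitting, Kaplan-Meier, log-rank and time-dependent AUC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from tiics.survival_stats import (
    SurvivalData,
    fit_cox,
    km_curve,
    logrank_test,
    predict_survival,
    time_dependent_auc,
)

from conftest import logrank_oe_oracle, make_survival


class TestFitCox:
    def test_null_covariate_estimate_within_two_se(self):
        # |beta| < 2 se holds ~95% of the time under the null; check the
        # rate over replicates rather than trusting one draw
        rng = np.random.default_rng(7)
        n = 2000
        within = 0
        for _ in range(20):
            x = rng.normal(0, 1, n)
            t = rng.exponential(1 / 0.02, n)
            surv = make_survival(t, np.ones(n, dtype=int))
            r = fit_cox(pd.DataFrame({"x": x}, index=surv.time.index), surv)["x"]
            within += abs(r.beta) < 2 * r.se_beta
        assert within >= 16

    def test_matches_brute_force_partial_likelihood_maximizer(self):
        # 6 subjects, distinct times, binary covariate, no ties: compare
        # against a grid search over the written-out partial likelihood
        times = np.array([2.0, 5.0, 7.0, 11.0, 13.0, 17.0])
        events = np.array([1, 1, 0, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0])

        def neg_pl(beta):
            ll = 0.0
            for i in range(6):
                if events[i] == 0:
                    continue
                risk = times >= times[i]
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return -ll

        grid = np.linspace(-4, 4, 160_001)
        beta_grid = grid[np.argmin([neg_pl(b) for b in grid])]
        surv = make_survival(times, events)
        fit = fit_cox(pd.DataFrame({"x": x}, index=surv.time.index), surv)
        assert fit["x"].beta == pytest.approx(beta_grid, abs=1e-4)

    def test_all_censored_rejected(self):
        surv = make_survival([3.0, 5.0, 8.0], [0, 0, 0])
        with pytest.raises(ValueError, match="events"):
            fit_cox(pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=surv.time.index), surv)

    def test_separation_flagged_not_converged(self):
        # covariate perfectly ordered with event times: monotone likelihood
        times = np.arange(1.0, 11.0)
        x = -times
        surv = make_survival(times, np.ones(10, dtype=int))
        fit = fit_cox(pd.DataFrame({"x": x}, index=surv.time.index), surv)
        assert not fit.converged
        assert not fit["x"].converged

    def test_agrees_with_lifelines_on_tied_data(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        n = 300
        X = pd.DataFrame(
            {"a": rng.normal(0, 1, n), "b": rng.binomial(1, 0.4, n).astype(float)},
            index=[f"s{i}" for i in range(n)],
        )
        t = np.round(rng.exponential(1 / (0.02 * np.exp(0.5 * X["a"] - 0.8 * X["b"])))) + 0.5
        e = (t < rng.exponential(60, n)).astype(int)
        surv = SurvivalData(pd.Series(t, index=X.index), pd.Series(e, index=X.index))
        fit = fit_cox(X, surv)
        df = X.copy()
        df["T"], df["E"] = surv.time, surv.event
        cph = lifelines.CoxPHFitter()
        cph.fit(df, "T", "E")
        assert np.abs(fit.beta - cph.params_.to_numpy()).max() < 1e-4
        ses = np.array([fit["a"].se_beta, fit["b"].se_beta])
        assert np.abs(ses - cph.summary["se(coef)"].to_numpy()).max() < 1e-4

    def test_se_hr_is_delta_method(self):
        rng = np.random.default_rng(1)
        n = 100
        surv = make_survival(rng.exponential(50, n), np.ones(n, dtype=int))
        fit = fit_cox(pd.DataFrame({"x": rng.normal(0, 1, n)}, index=surv.time.index), surv)
        r = fit["x"]
        assert r.se_hr == pytest.approx(r.hr * r.se_beta, abs=1e-12)


class TestKmCurve:
    def test_no_events_stays_at_one(self):
        surv = make_survival([4.0, 9.0, 12.0], [0, 0, 0])
        labels = pd.Series(["g"] * 3, index=surv.time.index)
        _, probs = km_curve(surv, labels)["g"]
        assert np.all(probs == 1.0)

    def test_four_distinct_events_step_by_quarters(self):
        surv = make_survival([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        labels = pd.Series(["g"] * 4, index=surv.time.index)
        times, probs = km_curve(surv, labels)["g"]
        steps = dict(zip(times, probs))
        for t, s in [(1.0, 0.75), (2.0, 0.5), (3.0, 0.25), (4.0, 0.0)]:
            assert steps[t] == pytest.approx(s, abs=1e-12)

    def test_censored_subject_leaves_risk_set(self):
        # censoring at t=2 between events at 1 and 3: S(3) = 0.75 * (1 - 1/2)
        surv = make_survival([1.0, 2.0, 3.0, 5.0], [1, 0, 1, 0])
        labels = pd.Series(["g"] * 4, index=surv.time.index)
        times, probs = km_curve(surv, labels)["g"]
        steps = dict(zip(times, probs))
        assert steps[3.0] == pytest.approx(0.75 * 0.5)


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        times = [2.0, 4.0, 6.0, 9.0]
        events = [1, 0, 1, 1]
        surv = make_survival(times + times, events + events)
        labels = pd.Series([0] * 4 + [1] * 4, index=surv.time.index)
        chi2, p = logrank_test(surv, labels)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_tabulated_oe_oracle(self):
        times = [3.0, 5.0, 6.0, 8.0, 10.0, 12.0, 14.0, 15.0]
        events = [1, 1, 0, 1, 1, 0, 1, 1]
        group = [1, 1, 1, 1, 0, 0, 0, 0]
        surv = make_survival(times, events)
        labels = pd.Series(group, index=surv.time.index)
        chi2, p = logrank_test(surv, labels)
        chi2_ref, p_ref = logrank_oe_oracle(times, events, group)
        assert chi2 == pytest.approx(chi2_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_logrank_and_cox_wald_p_same_order_of_magnitude(self):
        rng = np.random.default_rng(3)
        n = 400
        g = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(1 / (0.02 * np.exp(0.6 * g)))
        surv = make_survival(t, np.ones(n, dtype=int))
        labels = pd.Series(g, index=surv.time.index)
        _, p_lr = logrank_test(surv, labels)
        p_cox = fit_cox(pd.DataFrame({"g": g}, index=surv.time.index), surv)["g"].p_value
        assert abs(np.log10(p_lr) - np.log10(p_cox)) < 1.0


class TestTimeDependentAuc:
    def test_perfect_risk_ranking_gives_unit_auc(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(50, 300)
        surv = make_survival(t, np.ones(300, dtype=int))
        score = pd.Series(-t, index=surv.time.index)
        auc = time_dependent_auc(score, surv, horizons=[np.median(t)])
        assert auc.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_reduces_to_binary_roc_auc_without_censoring(self):
        rng = np.random.default_rng(1)
        n = 200
        t = rng.exponential(40, n)
        score = pd.Series(rng.normal(0, 1, n), index=[f"s{i}" for i in range(n)])
        surv = make_survival(t, np.ones(n, dtype=int))
        horizon = float(np.quantile(t, 0.6))
        auc = time_dependent_auc(score, surv, horizons=[horizon]).iloc[0]
        ref = roc_auc_score((t <= horizon).astype(int), score)
        assert auc == pytest.approx(ref, abs=1e-10)

    def test_random_score_mean_auc_near_half(self):
        rng = np.random.default_rng(2)
        aucs = []
        for _ in range(200):
            t = rng.exponential(50, 500)
            e = (rng.random(500) > 0.25).astype(int)
            surv = make_survival(t, e)
            score = pd.Series(rng.normal(0, 1, 500), index=surv.time.index)
            aucs.append(time_dependent_auc(score, surv, horizons=[40.0]).iloc[0])
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_horizon_beyond_follow_up_rejected(self):
        surv = make_survival([5.0, 10.0, 15.0], [1, 1, 1])
        score = pd.Series([1.0, 2.0, 3.0], index=surv.time.index)
        with pytest.raises(ValueError, match="horizon"):
            time_dependent_auc(score, surv, horizons=[20.0])


class TestPredictSurvival:
    def test_time_zero_probability_is_one(self):
        rng = np.random.default_rng(4)
        n = 100
        x = pd.DataFrame({"x": rng.normal(0, 1, n)}, index=[f"s{i}" for i in range(n)])
        surv = make_survival(rng.exponential(60, n), np.ones(n, dtype=int))
        fit = fit_cox(x, surv)
        sp = predict_survival(fit, x.iloc[:5], horizons=[0.0, 30.0])
        assert np.allclose(sp[0.0], 1.0)
        assert (sp[30.0] < 1.0).all()
        assert (sp[30.0] > 0.0).all()

    def test_null_model_baseline_matches_km(self):
        rng = np.random.default_rng(6)
        n = 500
        t = rng.exponential(50, n)
        e = (rng.random(n) > 0.2).astype(int)
        surv = make_survival(t, e)
        noise = pd.DataFrame({"z": rng.normal(0, 1e-8, n)}, index=surv.time.index)
        fit = fit_cox(noise, surv)
        grid = np.quantile(t, np.linspace(0.05, 0.9, 20))
        pred = predict_survival(fit, noise.iloc[:1], horizons=grid).iloc[0].to_numpy()
        labels = pd.Series(["all"] * n, index=surv.time.index)
        km_t, km_s = km_curve(surv, labels)["all"]
        km_interp = np.array([km_s[km_t <= g][-1] for g in grid])
        assert np.abs(pred - km_interp).max() < 0.02
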