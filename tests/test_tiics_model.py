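"""Weight formula, composite score, median split and external validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import tiics as T
from tiics.ssgsea import EnrichmentMatrix
from tiics.survival_stats import CoxResult
from tiics.tiics_model import TiicsScores, validate_external

from conftest import make_survival


def cox_result(cell, hr, se_hr, p=0.01):
    """Build a CoxResult whose delta-method SE(HR) equals ``se_hr``."""
    return CoxResult(
        term=cell, beta=float(np.log(hr)), se_beta=se_hr / hr,
        p_value=p, n_events=50, converged=True,
    )


def enrichment(values, cells):
    cols = [f"s{j}" for j in range(np.asarray(values).shape[1])]
    return EnrichmentMatrix(
        pd.DataFrame(np.asarray(values, dtype=float), index=cells, columns=cols),
        alpha=0.25, normalized=True,
    )


class TestComputeWeights:
    @pytest.mark.parametrize(
        "hr, se_hr, expected",
        [
            (1.0, 0.3, 0.0),     # neutral cell carries no weight
            (0.5, 0.25, 2.0),    # protective cell, positive weight
            (2.0, 0.5, -2.0),    # harmful cell, negative weight
        ],
    )
    def test_weight_formula(self, hr, se_hr, expected):
        w = T.compute_weights({"c": cox_result("c", hr, se_hr)})
        assert w.table.loc["c", "weight"] == pytest.approx(expected, abs=1e-12)
        assert w.table.loc["c", "se_HR"] == pytest.approx(se_hr, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        hr=st.floats(0.05, 20.0),
        se_hr=st.floats(0.01, 5.0),
    )
    def test_weight_sign_equals_sign_of_one_minus_hr(self, hr, se_hr):
        w = T.compute_weights({"c": cox_result("c", hr, se_hr)})
        assert np.sign(w.table.loc["c", "weight"]) == np.sign(1.0 - hr)

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError, match="zero SE"):
            T.compute_weights({"c": cox_result("c", 0.8, 0.0)})

    def test_se_beta_mode_changes_scale_not_sign(self):
        res = {"c": cox_result("c", 0.5, 0.25)}
        w_hr = T.compute_weights(res, se_mode="hr").table.loc["c", "weight"]
        w_beta = T.compute_weights(res, se_mode="beta").table.loc["c", "weight"]
        assert w_hr != w_beta
        assert np.sign(w_hr) == np.sign(w_beta)


class TestComputeTiics:
    def test_unit_weight_single_cell_is_identity(self):
        enr = enrichment([[0.1, 0.5, -0.2]], ["c"])
        w = T.compute_weights({"c": cox_result("c", 0.5, 0.5)})  # weight 1.0
        scores = T.compute_tiics(enr, w)
        assert np.allclose(scores.score.to_numpy(), [0.1, 0.5, -0.2])

    def test_zero_weights_zero_scores(self):
        enr = enrichment([[0.4, 0.2], [0.1, 0.9]], ["a", "b"])
        w = T.compute_weights(
            {"a": cox_result("a", 1.0, 0.3), "b": cox_result("b", 1.0, 0.2)}
        )
        assert np.allclose(T.compute_tiics(enr, w).score.to_numpy(), 0.0)

    def test_linear_in_weights(self):
        rng = np.random.default_rng(0)
        enr = enrichment(rng.normal(0, 1, (2, 5)), ["a", "b"])
        w1 = T.compute_weights(
            {"a": cox_result("a", 0.5, 0.5), "b": cox_result("b", 2.0, 1.0)}
        )
        w2 = T.compute_weights(
            {"a": cox_result("a", 0.5, 0.25), "b": cox_result("b", 2.0, 0.5)}
        )  # both weights doubled
        s1 = T.compute_tiics(enr, w1).score
        s2 = T.compute_tiics(enr, w2).score
        assert np.allclose(2 * s1.to_numpy(), s2.to_numpy())

    def test_invariant_to_cell_ordering(self):
        rng = np.random.default_rng(1)
        enr = enrichment(rng.normal(0, 1, (3, 6)), ["a", "b", "c"])
        res = {
            "a": cox_result("a", 0.5, 0.5),
            "b": cox_result("b", 0.7, 0.2),
            "c": cox_result("c", 1.4, 0.3),
        }
        fwd = T.compute_tiics(enr, T.compute_weights(res)).score
        rev = T.compute_tiics(
            enr, T.compute_weights(dict(reversed(res.items())))
        ).score
        assert np.allclose(fwd.to_numpy(), rev.to_numpy())

    def test_missing_cell_row_rejected(self):
        enr = enrichment([[0.1, 0.2]], ["a"])
        w = T.compute_weights({"ghost": cox_result("ghost", 0.5, 0.5)})
        with pytest.raises(KeyError, match="ghost"):
            T.compute_tiics(enr, w)


class TestAssignGroups:
    def test_even_count_median_split(self):
        scores = TiicsScores(pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd")))
        out = T.assign_groups(scores)
        assert out.cutoff == 2.5
        assert set(out.group[out.group == "high"].index) == {"c", "d"}

    def test_odd_count_tie_at_median_goes_low(self):
        scores = TiicsScores(pd.Series([1.0, 2.0, 3.0], index=list("abc")))
        out = T.assign_groups(scores)
        assert out.cutoff == 2.0
        assert out.group.tolist() == ["low", "low", "high"]

    def test_tie_high_convention(self):
        scores = TiicsScores(pd.Series([1.0, 2.0, 3.0], index=list("abc")))
        out = T.assign_groups(scores, ties="high")
        assert out.group.tolist() == ["low", "high", "high"]

    def test_constant_scores_rejected(self):
        scores = TiicsScores(pd.Series([2.0, 2.0, 2.0], index=list("abc")))
        with pytest.raises(ValueError, match="identical"):
            T.assign_groups(scores)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(-5, 5), min_size=2, max_size=25))
    def test_group_size_gap_bounded_by_median_ties(self, values):
        scores = TiicsScores(
            pd.Series([float(v) for v in values],
                      index=[f"s{i}" for i in range(len(values))])
        )
        if scores.score.nunique() == 1:
            return
        out = T.assign_groups(scores)
        n_high = (out.group == "high").sum()
        n_low = (out.group == "low").sum()
        n_tied = (out.score == out.cutoff).sum()
        assert abs(n_high - n_low) <= n_tied + 1


class TestScreenCells:
    def test_selection_obeys_threshold_and_ordering(self, protective_enrichment):
        enrich, surv, truth = protective_enrichment
        results, selected = T.screen_cells(enrich, surv, p_threshold=0.05)
        assert set(results) == set(enrich.cell_types)
        ps = [results[c].p_value for c in selected]
        assert ps == sorted(ps)
        assert all(p < 0.05 for p in ps)
        # the two strongly planted protective cells must be found
        assert {"cell_01", "cell_02"} <= set(selected)
        assert results["cell_01"].hr < 1 and results["cell_02"].hr < 1

    def test_no_cell_passing_is_informative_error(self):
        rng = np.random.default_rng(0)
        enr = enrichment(rng.normal(0, 1, (3, 40)), ["a", "b", "c"])
        surv = make_survival(rng.exponential(50, 40), np.ones(40, dtype=int))
        with pytest.raises(ValueError, match="threshold"):
            T.screen_cells(enr, surv, p_threshold=1e-12)


class TestEndToEndSign:
    def test_protective_cells_give_high_group_better_survival(self, protective_enrichment):
        enrich, surv, _ = protective_enrichment
        results, selected = T.screen_cells(enrich, surv)
        weights = T.compute_weights({c: results[c] for c in selected})
        scores = T.assign_groups(T.compute_tiics(enrich, weights))
        chi2, p = T.logrank_test(surv, scores.group)
        assert p < 0.05
        curves = T.km_curve(surv, scores.group)
        t_star = float(surv.time.median())
        surv_at = {
            g: probs[times <= t_star][-1] for g, (times, probs) in curves.items()
        }
        assert surv_at["high"] > surv_at["low"]

    def test_transfer_and_refit_validation(self, protective_enrichment):
        enrich, surv, _ = protective_enrichment
        results, selected = T.screen_cells(enrich, surv)
        weights = T.compute_weights({c: results[c] for c in selected})
        # independently simulated validation cohort, same generative law
        config = T.SimulationConfig(
            n_genes=800, n_samples=240, n_cell_types=8, genes_per_set=25,
            signal_strength=2.0, noise_sd=1.0,
            prognostic_cells={1: -0.8, 2: -0.6}, censor_rate=0.25,
            batch_shift=0.0, batch_scale=1.0, seed=77,
        )
        expr_v, surv_v, sets_v, _ = T.generate_cohort(config)
        restricted, _ = T.restrict_to_matrix(sets_v, expr_v.gene_ids)
        enrich_v = T.ssgsea_score(expr_v, restricted)
        transfer = validate_external(
            enrich_v, surv_v, mode="transfer", training_weights=weights
        )
        assert transfer.p_value < 0.05
        refit = validate_external(enrich_v, surv_v, mode="refit")
        assert {"cell_01", "cell_02"} <= set(refit.weights.cell_types)
        assert refit.p_value < 0.05
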