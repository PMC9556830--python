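"""Validation measurements: oracle comparisons and operating characteristics.

Each function re-derives a statistical property of the pipeline from
scratch — against an independent reference implementation, a closed
form, or a seeded simulation with known ground truth — and returns the
measured quantity. They back both the acceptance test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

import tiics as T
from tiics.preprocess import ExpressionMatrix, batch_adjust
from tiics.ssgsea import SsgseaParams, ssgsea_score
from tiics.survival_stats import SurvivalData, fit_cox, km_curve, logrank_test


# ---------------------------------------------------------------------------
# reference implementations (deliberately naive, independent of the pipeline)

def naive_ssgsea_es(expr_col, gene_ids, set_genes, alpha) -> float:
    """Literal double-loop single-sample enrichment score."""
    N = len(gene_ids)
    ranks = stats.rankdata(expr_col)
    order = sorted(range(N), key=lambda i: (-ranks[i], gene_ids[i]))
    in_set = [gene_ids[i] in set_genes for i in order]
    w = [ranks[order[i]] ** alpha for i in range(N)]
    denom_in = sum(w[i] for i in range(N) if in_set[i])
    s = sum(in_set)
    es = 0.0
    for i in range(N):
        p_in = sum(w[j] for j in range(i + 1) if in_set[j]) / denom_in
        p_out = sum(1 for j in range(i + 1) if not in_set[j]) / (N - s)
        es += p_in - p_out
    return es


def logrank_oe_tabulation(time, event, group) -> tuple[float, float]:
    """Observed/expected/variance log-rank tabulation over event times."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    O = E = V = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (O - E) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# measurements

def ssgsea_oracle_max_abs_diff(n_matrices: int = 100, seed: int = 0) -> float:
    """Max |pipeline ES - naive ES| over random small matrices with ties."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_matrices):
        N = int(rng.integers(3, 9))
        nsamp = int(rng.integers(1, 4))
        ssize = int(rng.integers(1, min(4, N)))
        X = np.round(rng.normal(0, 1, (N, nsamp)), 1)
        for j in range(nsamp):
            if X[:, j].max() == X[:, j].min():
                X[0, j] += 1.0
        genes = [f"g{i}" for i in range(N)]
        samples = [f"s{j}" for j in range(nsamp)]
        sgenes = list(rng.choice(genes, size=ssize, replace=False))
        alpha = float(rng.choice([0.0, 0.25, 1.0]))
        enr = ssgsea_score(
            ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples)),
            T.GeneSetCollection.from_dict({"S": sgenes}),
            SsgseaParams(alpha=alpha, normalize=False),
        )
        for j in range(nsamp):
            ref = naive_ssgsea_es(X[:, j], genes, set(sgenes), alpha)
            worst = max(worst, abs(float(enr.scores.iloc[0, j]) - ref))
    return worst


def cox_recovery(
    betas=(-0.5, 0.0, 0.5), n: int = 1000, reps: int = 100, seed: int = 0
) -> dict:
    """Bias and 95% Wald CI coverage of the Cox estimator per true beta."""
    rng = np.random.default_rng(seed)
    out = {"bias": {}, "coverage": None}
    covered = total = 0
    for beta_true in betas:
        estimates = []
        for _ in range(reps):
            x = rng.normal(0, 1, n)
            t = rng.exponential(1 / (0.01 * np.exp(beta_true * x)))
            idx = pd.RangeIndex(n)
            surv = SurvivalData(pd.Series(t, index=idx), pd.Series(np.ones(n, int), index=idx))
            r = fit_cox(pd.DataFrame({"x": x}, index=idx), surv)["x"]
            estimates.append(r.beta)
            covered += abs(r.beta - beta_true) < 1.96 * r.se_beta
            total += 1
        out["bias"][beta_true] = float(np.mean(estimates) - beta_true)
    out["coverage"] = covered / total
    return out


def logrank_null_uniformity(reps: int = 1000, n: int = 100, seed: int = 0) -> float:
    """KS p-value for uniformity of null log-rank p-values."""
    rng = np.random.default_rng(seed)
    pvals = []
    for _ in range(reps):
        t = rng.exponential(50, n)
        e = (rng.random(n) > 0.3).astype(int)
        if e.sum() == 0:
            continue
        idx = pd.RangeIndex(n)
        surv = SurvivalData(pd.Series(t, index=idx), pd.Series(e, index=idx))
        labels = pd.Series(rng.permutation(np.repeat([0, 1], n // 2)), index=idx)
        pvals.append(logrank_test(surv, labels)[1])
    return float(stats.kstest(pvals, "uniform").pvalue)


def _score_cohort(config: T.SimulationConfig):
    expr, surv, sets, truth = T.generate_cohort(config)
    restricted, _ = T.restrict_to_matrix(sets, expr.gene_ids)
    enrich = T.ssgsea_score(expr, restricted)
    return enrich, surv, truth


def tiics_sign_recovery(reps: int = 100, n: int = 800, seed: int = 0) -> dict:
    """Fraction of cohorts with planted protective cells where the
    high-score group separates favorably (log-rank p < 0.05 and the high
    group's KM curve above the low group's at the median follow-up)."""
    successes = 0
    for rep in range(reps):
        config = T.SimulationConfig(
            n_genes=1000, n_samples=n, n_cell_types=10, genes_per_set=25,
            signal_strength=2.0, noise_sd=1.0,
            prognostic_cells={1: -0.7, 2: -0.7, 3: -0.7}, censor_rate=0.3,
            batch_shift=0.0, batch_scale=1.0, seed=seed + rep,
        )
        enrich, surv, _ = _score_cohort(config)
        try:
            results, selected = T.screen_cells(enrich, surv)
        except ValueError:
            continue
        weights = T.compute_weights({c: results[c] for c in selected})
        scores = T.assign_groups(T.compute_tiics(enrich, weights))
        _, p = logrank_test(surv, scores.group)
        curves = km_curve(surv, scores.group)
        t_star = float(surv.time.median())
        s_at = {
            g: probs[times <= t_star][-1] if (times <= t_star).any() else 1.0
            for g, (times, probs) in curves.items()
        }
        if p < 0.05 and s_at["high"] > s_at["low"]:
            successes += 1
    return {"success_fraction": successes / reps, "reps": reps, "n": n}


def screening_power(reps: int = 100, n: int = 800, seed: int = 0) -> dict:
    """Detection rate of a single planted prognostic cell (beta = -0.7)
    among 28 cell types, and the false-selection count among the 27
    null cells."""
    hits = 0
    false_counts = []
    for rep in range(reps):
        config = T.SimulationConfig(
            n_genes=1500, n_samples=n, n_cell_types=28, genes_per_set=30,
            signal_strength=2.0, noise_sd=1.0,
            prognostic_cells={5: -0.7}, censor_rate=0.3,
            batch_shift=0.0, batch_scale=1.0, seed=seed + rep,
        )
        enrich, surv, _ = _score_cohort(config)
        try:
            _, selected = T.screen_cells(enrich, surv)
        except ValueError:
            selected = []
        hits += "cell_05" in selected
        false_counts.append(len([c for c in selected if c != "cell_05"]))
    return {
        "hit_fraction": hits / reps,
        "mean_false_selections": float(np.mean(false_counts)),
        "reps": reps,
        "n": n,
    }


def screening_null_size(reps: int = 60, n: int = 800, seed: int = 0) -> dict:
    """Mean number of cells selected at p < 0.05 when no cell is
    prognostic (nominal expectation: 28 x 0.05 = 1.4)."""
    counts = []
    for rep in range(reps):
        config = T.SimulationConfig(
            n_genes=1500, n_samples=n, n_cell_types=28, genes_per_set=30,
            signal_strength=2.0, noise_sd=1.0,
            prognostic_cells={}, censor_rate=0.3,
            batch_shift=0.0, batch_scale=1.0, seed=seed + rep,
        )
        enrich, surv, _ = _score_cohort(config)
        try:
            _, selected = T.screen_cells(enrich, surv)
        except ValueError:
            selected = []
        counts.append(len(selected))
    return {"mean_selections": float(np.mean(counts)), "reps": reps, "n": n}


def moderated_t_null_type1(n_genes: int = 2000, n_per_group: int = 50, seed: int = 0) -> float:
    """Fraction of null genes with raw p < 0.05."""
    rng = np.random.default_rng(seed)
    X = rng.normal(6, 1, (n_genes, 2 * n_per_group))
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(2 * n_per_group)]
    m = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples))
    labels = pd.Series(["high"] * n_per_group + ["low"] * n_per_group, index=samples)
    deg = T.moderated_t_deg(m, labels)
    return float((deg["p_value"] < 0.05).mean())


def moderated_t_pooled_limit(n_genes: int = 500, n_per_group: int = 200, seed: int = 0) -> float:
    """Max |moderated t - pooled two-sample t| at large per-gene df,
    under heteroscedastic gene variances (finite prior df)."""
    rng = np.random.default_rng(seed)
    s2 = 8.0 / rng.chisquare(8.0, n_genes)
    X = rng.normal(0, 1, (n_genes, 2 * n_per_group)) * np.sqrt(s2)[:, None] + 6
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(2 * n_per_group)]
    m = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples))
    labels = pd.Series(["high"] * n_per_group + ["low"] * n_per_group, index=samples)
    deg = T.moderated_t_deg(m, labels)
    n = n_per_group
    hi, lo = X[:, :n], X[:, n:]
    sp = np.sqrt(((n - 1) * hi.var(1, ddof=1) + (n - 1) * lo.var(1, ddof=1)) / (2 * n - 2))
    pooled_t = (hi.mean(1) - lo.mean(1)) / (sp * np.sqrt(2 / n))
    return float(np.abs(deg["moderated_t"].to_numpy() - pooled_t).max())


def batch_shift_equalization(n_per_batch: int = 100, n_genes: int = 200, seed: int = 0) -> float:
    """Max per-gene batch-mean gap after adjusting a pure mean shift
    (second batch duplicates the first batch's structure plus 2.0)."""
    rng = np.random.default_rng(seed)
    base = rng.normal(0, 1, (n_genes, n_per_batch))
    base = (base - base.mean(1, keepdims=True)) / base.std(1, ddof=1, keepdims=True) + 6
    X = np.concatenate([base, base + 2.0], axis=1)
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(2 * n_per_batch)]
    m = ExpressionMatrix(
        pd.DataFrame(X, index=genes, columns=samples),
        pd.Series(["b1"] * n_per_batch + ["b2"] * n_per_batch, index=samples),
    )
    A = batch_adjust(m).values.to_numpy()
    gap = np.abs(A[:, :n_per_batch].mean(1) - A[:, n_per_batch:].mean(1))
    return float(gap.max())


def batch_biology_preservation(seed: int = 0) -> float:
    """Relative change of a batch-orthogonal two-group expression gap
    through batch adjustment (planted biology balanced across batches)."""
    rng = np.random.default_rng(seed)
    G, n = 300, 200
    X = rng.normal(6, 1, (G, n))
    batch = np.array(([0] * 50 + [1] * 50) * 2)
    bio = np.repeat([0, 1], 100)
    X[:40, bio == 1] += 1.0
    X[:, batch == 1] += 1.5
    genes = [f"g{i}" for i in range(G)]
    samples = [f"s{j}" for j in range(n)]
    m = ExpressionMatrix(
        pd.DataFrame(X, index=genes, columns=samples),
        pd.Series([f"b{b}" for b in batch], index=samples),
    )
    before = X[:40][:, bio == 1].mean() - X[:40][:, bio == 0].mean()
    A = batch_adjust(m).values.to_numpy()
    after = A[:40][:, bio == 1].mean() - A[:40][:, bio == 0].mean()
    return float(abs(after - before) / abs(before))
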