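"""Shared fixtures and independent reference implementations (oracles)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tiics as T


def naive_ssgsea_es(expr_col, gene_ids, set_genes, alpha):
    """Double-loop reference for the single-sample enrichment score.

    Ranks ascending with average ties, positions by descending rank with
    lexicographic tie-break, then accumulates the weighted in-set vs
    unweighted out-of-set ECDF difference literally, term by term.
    """
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


def logrank_oe_oracle(time, event, group):
    """Hand-tabulated observed/expected/variance log-rank statistic.

    At each distinct event time t: n1, n at risk, d events, d1 in group 1;
    E = d*n1/n, V = d*(n1/n)*(1-n1/n)*(n-d)/(n-1). Chi-square =
    (sum(d1) - sum(E))^2 / sum(V).
    """
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
    return chi2, float(stats.chi2.sf(chi2, df=1))


def make_expression(values, genes=None, samples=None, batch=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    b = pd.Series(batch, index=samples) if batch is not None else None
    return T.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), b)


def make_survival(times, events):
    idx = [f"s{j}" for j in range(len(times))]
    return T.SurvivalData(pd.Series(times, index=idx, dtype=float),
                          pd.Series(events, index=idx))


@pytest.fixture(scope="session")
def protective_cohort():
    """Small cohort with two strongly protective cell types."""
    config = T.SimulationConfig(
        n_genes=800, n_samples=240, n_cell_types=8, genes_per_set=25,
        signal_strength=2.0, noise_sd=1.0,
        prognostic_cells={1: -0.8, 2: -0.6}, censor_rate=0.25,
        batch_shift=0.0, batch_scale=1.0, seed=11,
    )
    return config, T.generate_cohort(config)


@pytest.fixture(scope="session")
def protective_enrichment(protective_cohort):
    """ssGSEA scores and survival for the protective cohort."""
    _, (expr, surv, sets, truth) = protective_cohort
    restricted, _ = T.restrict_to_matrix(sets, expr.gene_ids)
    enrich = T.ssgsea_score(expr, restricted)
    return enrich, surv, truth
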