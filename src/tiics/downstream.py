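"""Group-comparison analytics between score strata.

Microenvironment scoring (ESTIMATE-style stromal/immune enrichment with
the published cosine purity transform), empirical-Bayes moderated-t
differential expression, preranked permutation set enrichment, and
Wilcoxon rank-sum feature comparisons.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from tiics.gene_sets_io import GeneSetCollection, restrict_to_matrix
from tiics.preprocess import ExpressionMatrix
from tiics.ssgsea import SsgseaParams, ssgsea_score

logger = logging.getLogger(__name__)

# Published ESTIMATE purity transform, calibrated on Affymetrix-scale scores.
_PURITY_INTERCEPT = 0.6049872018
_PURITY_SLOPE = 0.0001467884


def estimate_scores(
    matrix: ExpressionMatrix,
    stromal_set: Iterable[str],
    immune_set: Iterable[str],
) -> pd.DataFrame:
    """Stromal/immune/combined microenvironment scores and tumor purity.

    Stromal and immune scores are unnormalized ssGSEA (alpha = 0.25) of
    the two signatures; their sum is the combined score, and purity is
    cos(0.6049872018 + 0.0001467884 * combined) — a transform calibrated
    for Affymetrix-scale scores (a warning is logged when the combined
    scores look far from that scale). Purity is clipped to [0, 1] for
    reporting.
    """
    coll = GeneSetCollection.from_dict(
        {"stromal": list(stromal_set), "immune": list(immune_set)}
    )
    restricted, dropped = restrict_to_matrix(coll, matrix.gene_ids, min_size=1)
    if dropped or len(restricted) < 2:
        raise ValueError(f"signature empty after restriction to matrix: {sorted(dropped)}")
    enrich = ssgsea_score(matrix, restricted, SsgseaParams(alpha=0.25, normalize=False))
    stromal = enrich.scores.loc["stromal"]
    immune = enrich.scores.loc["immune"]
    combined = stromal + immune
    if combined.abs().max() > (np.pi - _PURITY_INTERCEPT) / _PURITY_SLOPE:
        logger.warning(
            "combined scores exceed the purity transform's calibrated range; "
            "purity values are extrapolated"
        )
    purity_raw = np.cos(_PURITY_INTERCEPT + _PURITY_SLOPE * combined)
    out = pd.DataFrame(
        {
            "stromal_score": stromal,
            "immune_score": immune,
            "estimate_score": combined,
            "tumor_purity": np.clip(purity_raw, 0.0, 1.0),
        }
    )
    out.index.name = "sample_id"
    return out


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve polygamma(1, x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        step = tri * (1.0 - tri / y) / polygamma(2, x)
        x += step
        if abs(step) < tol * x:
            break
    return float(x)


def moderated_t_deg(
    matrix: ExpressionMatrix,
    groups: pd.Series,
    lfc_threshold: float = 0.5,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Two-group moderated-t differential expression (high vs low).

    Per gene, the log fold change is the high-group mean minus the
    low-group mean; residual variances are shrunk toward a common prior
    estimated by moment matching of log-variances (digamma/trigamma
    relations give the prior degrees of freedom d0 and scale s0^2), and
    the moderated t has d0 + d_g degrees of freedom. Significance is the
    raw-p rule |logFC| > lfc_threshold and p < p_threshold (defaults 0.5
    and 0.05); BH-adjusted p-values are reported alongside but never
    filter. Genes with zero variance in both groups are excluded with a
    warning.
    """
    groups = pd.Series(groups).reindex(matrix.sample_ids)
    levels = set(groups.dropna().unique())
    if levels != {"high", "low"}:
        raise ValueError(f"groups must be 'high'/'low', got {sorted(levels)}")
    hi = groups.index[groups == "high"]
    lo = groups.index[groups == "low"]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("need >=2 samples per group")

    Xh = matrix.values[hi].to_numpy(dtype=float)
    Xl = matrix.values[lo].to_numpy(dtype=float)
    n1, n2 = Xh.shape[1], Xl.shape[1]
    d_g = n1 + n2 - 2
    logfc = Xh.mean(axis=1) - Xl.mean(axis=1)
    ss = Xh.var(axis=1, ddof=1) * (n1 - 1) + Xl.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / d_g

    keep = s2 > 0
    if not keep.all():
        excluded = matrix.values.index[~keep].tolist()
        logger.warning("excluding %d zero-variance genes: %s...", len(excluded), excluded[:5])
    s2k = s2[keep]
    lfck = logfc[keep]

    # empirical-Bayes shrinkage of log-variances
    e = np.log(s2k) - digamma(d_g / 2.0) + np.log(d_g / 2.0)
    mean_e = float(e.mean())
    var_e = float(e.var(ddof=1))
    excess = var_e - float(polygamma(1, d_g / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = np.exp(mean_e + digamma(d0 / 2.0) - np.log(d0 / 2.0))
        s2_post = (d0 * s0_sq + d_g * s2k) / (d0 + d_g)
        df_total = d0 + d_g
    else:  # no evidence of variance heterogeneity: complete shrinkage
        d0 = np.inf
        s0_sq = np.exp(mean_e)
        s2_post = np.full_like(s2k, s0_sq)
        df_total = np.inf
    t = lfck / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    p = 2 * stats.t.sf(np.abs(t), df=df_total)
    adj_p = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "logFC": lfck,
            "moderated_t": t,
            "p_value": p,
            "bh_adjusted_p": adj_p,
        },
        index=matrix.values.index[keep],
    )
    table["significant"] = (table["logFC"].abs() > lfc_threshold) & (
        table["p_value"] < p_threshold
    )
    table.index.name = "gene_id"
    table.attrs["prior_df"] = d0
    table.attrs["prior_var"] = float(s0_sq)
    return table


def ranked_enrichment(
    gene_stat: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked permutation set enrichment over a gene-level statistic.

    Genes are ordered by decreasing statistic; the running sum gains
    |stat|-weighted mass at in-set genes and loses 1/(N-|S|) at others,
    and the enrichment score is the maximum signed deviation. The null
    is gene-label permutation: NES divides the score by the mean |null
    score| of the same sign, and the two-sided permutation p carries a
    +1 pseudo-count. Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    stat = pd.Series(gene_stat).astype(float).dropna()
    restricted, _ = restrict_to_matrix(sets, stat.index, min_size=1)
    order = stat.sort_values(ascending=False, kind="mergesort")
    genes = order.index.to_numpy(dtype=object)
    absstat = np.abs(order.to_numpy())
    N = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    def score_positions(pos: np.ndarray) -> float:
        member = np.zeros(N, dtype=bool)
        member[pos] = True
        w = np.where(member, absstat, 0.0)
        total = w.sum()
        if total == 0:
            w = member.astype(float)
            total = w.sum()
        running = np.cumsum(w / total - (~member) / (N - member.sum()))
        return float(running[np.argmax(np.abs(running))])

    rows = []
    for name in restricted.names():
        pos = np.array([gene_pos[g] for g in restricted.genes(name)])
        s = len(pos)
        if s >= N:
            raise ValueError(f"set {name!r} covers all ranked genes")
        es = score_positions(pos)
        null = np.array(
            [score_positions(rng.choice(N, size=s, replace=False)) for _ in range(n_perm)]
        )
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.abs(same_sign).mean() if len(same_sign) else np.abs(null).mean()
        nes = es / denom if denom > 0 else 0.0
        p = (1.0 + np.sum(np.abs(null) >= abs(es))) / (n_perm + 1.0)
        rows.append((name, s, es, nes, p))
    out = pd.DataFrame(rows, columns=["set", "size", "ES", "NES", "p"]).set_index("set")
    return out


def group_compare(values: pd.Series, groups: pd.Series) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of a feature across groups.

    Uses exact enumeration when the combined sample size is <= 12 (and
    the data are tie-free), otherwise the tie-corrected normal
    approximation. Returns (U statistic for the high group, p).
    """
    values = pd.Series(values)
    groups = pd.Series(groups).reindex(values.index)
    hi = values[groups == "high"].to_numpy(dtype=float)
    lo = values[groups == "low"].to_numpy(dtype=float)
    if len(hi) == 0 or len(lo) == 0:
        raise ValueError("both groups must be non-empty")
    n = len(hi) + len(lo)
    if n < 4:
        raise ValueError("need combined n >= 4")
    ties = len(np.unique(np.concatenate([hi, lo]))) < n
    method = "exact" if (n <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(hi, lo, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
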