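"""Single-sample gene-set enrichment (ssGSEA) and cell-level structure.

Per sample, genes are ranked by expression and each gene set's enrichment
score is the integrated difference between the rank-weighted in-set
cumulative distribution and the unweighted out-of-set cumulative
distribution along the ranked list:

    ES(S, j) = sum_i [ P_in(i) - P_out(i) ]
    P_in(i)  = sum_{g in S, pos(g)<=i} r_g^alpha / sum_{g in S} r_g^alpha
    P_out(i) = |{g not in S, pos(g)<=i}| / (N - |S|)

with ranks 1..N ascending in expression (ties averaged) and list
positions in descending rank (ties broken lexicographically by gene id,
so scores are deterministic on discrete data). The resulting cell-type x
sample matrix feeds pairwise cell correlations and hierarchical
clustering of cell profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from tiics.gene_sets_io import GeneSetCollection
from tiics.preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class SsgseaParams:
    """Scoring parameters: rank-weight exponent and normalization flag.

    ``alpha`` is the exponent applied to absolute ranks when weighting
    in-set genes (0.25 by ssGSEA convention; 0 gives uniform weights).
    ``normalize`` rescales the whole score matrix by its global
    max - min range, GSVA's "ssgsea.norm" behaviour.
    """

    alpha: float = 0.25
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass
class EnrichmentMatrix:
    """Cell types x samples enrichment scores."""

    scores: pd.DataFrame
    alpha: float
    normalized: bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("enrichment scores must be finite")

    @property
    def cell_types(self) -> list[str]:
        return self.scores.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.scores.columns.tolist()

    def to_tsv(self, path) -> None:
        out = self.scores.copy()
        out.index.name = "cell_type"
        out.to_csv(path, sep="\t")


@dataclass
class CorrelationNetwork:
    """Significant pairwise Pearson correlations between cell profiles.

    ``edges`` has columns cell_a, cell_b, r, p with cell_a < cell_b and
    every retained edge satisfying p < ``p_threshold``.
    """

    edges: pd.DataFrame
    p_threshold: float
    excluded_cells: list[str] = field(default_factory=list)


def ssgsea_score(
    matrix: ExpressionMatrix,
    sets: GeneSetCollection,
    params: SsgseaParams | None = None,
) -> EnrichmentMatrix:
    """Score every gene set in every sample.

    Sets must be pre-restricted to the matrix genes and strictly smaller
    than the gene universe (P_out is undefined for an all-gene set). A
    constant-expression sample is an error naming the sample. Scores are
    invariant to gene-row and sample-column ordering of the input, and
    to any strictly monotone transform of a sample's expression.
    """
    params = params or SsgseaParams()
    X = matrix.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    gene_index = {g: i for i, g in enumerate(matrix.values.index)}

    memberships = {}
    for name in sets.names():
        genes = sets.genes(name)
        missing = [g for g in genes if g not in gene_index]
        if missing:
            raise KeyError(
                f"set {name!r} has genes absent from matrix (restrict first): {missing[:5]}"
            )
        if len(genes) >= n_genes:
            raise ValueError(f"set {name!r} covers all {n_genes} genes; P_out undefined")
        m = np.zeros(n_genes, dtype=bool)
        m[[gene_index[g] for g in genes]] = True
        memberships[name] = m

    const = (X.max(axis=0) - X.min(axis=0)) == 0
    if const.any():
        bad = [matrix.values.columns[i] for i in np.flatnonzero(const)]
        raise ValueError(f"constant-expression samples cannot be ranked: {bad[:5]}")

    ranks = stats.rankdata(X, axis=0)  # ascending, ties averaged
    # Deterministic list positions: descending rank, ties by gene id.
    gene_ids = matrix.values.index.to_numpy(dtype=object)
    lex_rank = np.argsort(np.argsort(gene_ids))  # lexicographic rank of each gene id
    pos = np.empty((n_genes, n_samples), dtype=np.intp)
    seq = np.arange(1, n_genes + 1, dtype=np.intp)[:, None]
    for j in range(n_samples):
        order = np.lexsort((lex_rank, -ranks[:, j]))
        pos[order, j] = seq[:, 0]

    # The integrated in/out difference collapses to sums over set genes:
    #   sum_i P_in(i)  = sum_{g in S} w_g (N - pos_g + 1) / W
    #   sum_i P_out(i) = [N(N+1)/2 - sum_{g in S}(N - pos_g + 1)] / (N - |S|)
    coverage = (n_genes - pos + 1).astype(float)  # positions at/after each gene
    rank_w = ranks**params.alpha
    total_coverage = n_genes * (n_genes + 1) / 2.0
    es = np.empty((len(memberships), n_samples))
    for k, (name, m) in enumerate(memberships.items()):
        rows = np.flatnonzero(m)
        w = rank_w[rows]
        cov = coverage[rows]
        in_sum = (w * cov).sum(axis=0) / w.sum(axis=0)
        out_sum = (total_coverage - cov.sum(axis=0)) / (n_genes - len(rows))
        es[k] = in_sum - out_sum

    scores = pd.DataFrame(es, index=list(memberships), columns=matrix.values.columns)
    normalized = False
    if params.normalize:
        span = float(es.max() - es.min())
        if span == 0:
            logger.warning("constant enrichment matrix; skipping normalization")
        else:
            scores = scores / span
            normalized = True
    return EnrichmentMatrix(scores, alpha=params.alpha, normalized=normalized)


def cell_correlations(
    enrich: EnrichmentMatrix, p_threshold: float = 1e-4
) -> CorrelationNetwork:
    """All-pairs Pearson correlations between cell profiles, thresholded.

    p-values come from the t transform of r with n-2 degrees of freedom
    (two-sided); edges with p < ``p_threshold`` (default 1e-4) are kept.
    Constant cell rows are excluded with a warning.
    """
    S = enrich.scores
    if S.shape[1] < 3:
        raise ValueError("need >=3 samples for correlation p-values")
    sds = S.std(axis=1, ddof=1)
    excluded = sds.index[sds == 0].tolist()
    if excluded:
        logger.warning("excluding constant cell profiles: %s", excluded)
        S = S.drop(index=excluded)
    cells = S.index.tolist()
    n = S.shape[1]
    R = np.corrcoef(S.to_numpy())
    rows = []
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            r = float(np.clip(R[i, j], -1.0, 1.0))
            if abs(r) == 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n - 2) / (1 - r**2))
                p = float(2 * stats.t.sf(abs(t), df=n - 2))
            if p < p_threshold:
                a, b = sorted((cells[i], cells[j]))
                rows.append((a, b, r, p))
    edges = pd.DataFrame(rows, columns=["cell_a", "cell_b", "r", "p"])
    return CorrelationNetwork(edges, p_threshold, excluded)


def cluster_cells(enrich: EnrichmentMatrix, k: int = 4) -> dict[str, int]:
    """Ward hierarchical clustering of row-standardized cell profiles.

    Profiles are z-scored per cell, clustered with Euclidean distance and
    Ward linkage, and the tree is cut at ``k`` clusters (default 4).
    Labels are deterministic (1..k in scipy's maxclust convention).
    """
    cells = enrich.cell_types
    if not 1 <= k <= len(cells):
        raise ValueError(f"k must be in [1, {len(cells)}], got {k}")
    X = enrich.scores.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    if k == 1:
        return {c: 1 for c in cells}
    tree = linkage(Z, method="ward", metric="euclidean")
    labels = fcluster(tree, t=k, criterion="maxclust")
    return dict(zip(cells, (int(l) for l in labels)))
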