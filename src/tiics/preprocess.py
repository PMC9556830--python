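"""Probe-to-gene collapse and empirical-Bayes batch adjustment.

Expression is carried as a genes x samples matrix of log-scale values
(:class:`ExpressionMatrix`). Probe-level arrays are collapsed to gene
level by the per-gene median, and additive/multiplicative batch effects
across cohorts are removed with a parametric empirical-Bayes
location/scale adjustment (ComBat-style).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x samples log-scale expression with optional batch labels.

    ``values`` is a DataFrame indexed by gene id with sample-id columns;
    ids must be unique and values finite. ``batch``, if given, is a
    Series indexed by the same sample ids.
    """

    values: pd.DataFrame
    batch: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        if self.batch is not None:
            self.batch = self.batch.reindex(self.values.columns)
            if self.batch.isna().any():
                missing = self.batch.index[self.batch.isna()].tolist()
                raise ValueError(f"batch labels missing for samples: {missing[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls, path: str | Path, batch_path: str | Path | None = None
    ) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        batch = None
        if batch_path is not None:
            tbl = pd.read_csv(batch_path, sep="\t", index_col=0)
            batch = tbl.iloc[:, 0]
            batch.index = batch.index.astype(str)
        return cls(values, batch)


def collapse_probes(
    probe_matrix: pd.DataFrame, probe_map: Mapping[str, str | None]
) -> ExpressionMatrix:
    """Collapse a probes x samples matrix to gene level.

    Probes mapped to ``None`` (or an empty string / NaN) are dropped;
    each gene's value is the median across its probes, per sample, with
    even probe counts resolved as the mean of the two central order
    statistics. Every probe in the matrix must appear in ``probe_map``.
    """
    mapped = pd.Series({p: probe_map[p] for p in probe_matrix.index if p in probe_map})
    missing = [p for p in probe_matrix.index if p not in probe_map]
    if missing:
        raise KeyError(f"probes absent from probe map: {missing[:10]}")
    mapped = mapped.replace("", np.nan)
    n_empty = int(mapped.isna().sum())
    if n_empty:
        logger.info("dropping %d unmapped probes", n_empty)
    kept = mapped.dropna()
    collapsed = probe_matrix.loc[kept.index].groupby(kept).median()
    collapsed.index = collapsed.index.astype(str)
    return ExpressionMatrix(collapsed)


def _trim_batch_design(batch: pd.Series) -> tuple[np.ndarray, list]:
    codes, levels = pd.factorize(batch, sort=True)
    return codes, list(levels)


def batch_adjust(matrix: ExpressionMatrix, max_iter: int = 100, tol: float = 1e-4) -> ExpressionMatrix:
    """Remove additive and multiplicative batch effects (parametric EB).

    Each gene is standardized against its fitted overall mean and pooled
    variance; per batch, additive (gamma) and multiplicative (delta^2)
    effects are estimated and shrunk toward common priors (normal for
    gamma, inverse-gamma for delta^2, hyperparameters by method of
    moments across genes, iterated to a joint fixed point); the data are
    adjusted and de-standardized. Shape and orderings are preserved.

    A single batch returns the input unchanged with a warning; a batch
    with one sample is an error (its variance is inestimable).
    """
    if matrix.batch is None:
        raise ValueError("batch_adjust requires batch labels on the matrix")
    codes, levels = _trim_batch_design(matrix.batch)
    n_batches = len(levels)
    if n_batches < 2:
        logger.warning("single batch; returning input unchanged")
        return ExpressionMatrix(matrix.values.copy(), matrix.batch)
    counts = np.bincount(codes, minlength=n_batches)
    if (counts < 2).any():
        bad = [levels[i] for i in np.flatnonzero(counts < 2)]
        raise ValueError(f"batches with <2 samples (variance inestimable): {bad}")

    X = matrix.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    design = np.zeros((n_samples, n_batches))
    design[np.arange(n_samples), codes] = 1.0

    # per-gene batch means via least squares; grand mean weighted by batch size
    batch_means = np.stack([X[:, codes == b].mean(axis=1) for b in range(n_batches)], axis=1)
    grand_mean = batch_means @ (counts / n_samples)
    fitted = batch_means[:, codes]
    var_pooled = ((X - fitted) ** 2).mean(axis=1)
    if (var_pooled <= 0).any():
        var_pooled = np.maximum(var_pooled, 1e-12)

    stand_mean = grand_mean[:, None]
    sd = np.sqrt(var_pooled)[:, None]
    Z = (X - stand_mean) / sd

    gamma_hat = np.stack([Z[:, codes == b].mean(axis=1) for b in range(n_batches)], axis=1)
    delta_hat = np.stack([Z[:, codes == b].var(axis=1, ddof=1) for b in range(n_batches)], axis=1)

    # hyperpriors by method of moments per batch
    gamma_bar = gamma_hat.mean(axis=0)
    tau2 = gamma_hat.var(axis=0, ddof=1)
    d_mean = delta_hat.mean(axis=0)
    d_var = np.maximum(delta_hat.var(axis=0, ddof=1), 1e-12)
    a_prior = (2 * d_var + d_mean**2) / d_var
    b_prior = (d_mean * d_var + d_mean**3) / d_var

    Z_adj = np.empty_like(Z)
    for b in range(n_batches):
        idx = codes == b
        n_b = counts[b]
        g_star = gamma_hat[:, b].copy()
        d_star = delta_hat[:, b].copy()
        Zb = Z[:, idx]
        # joint EB fixed point for gamma* (posterior mean) and delta* (posterior
        # expectation of the inverse-gamma scale)
        for _ in range(max_iter):
            g_new = (n_b * tau2[b] * gamma_hat[:, b] + d_star * gamma_bar[b]) / (
                n_b * tau2[b] + d_star
            )
            sse = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sse + b_prior[b]) / (n_b / 2 + a_prior[b] - 1)
            change = max(
                np.abs(g_new - g_star).max() / max(np.abs(g_star).max(), 1e-12),
                np.abs(d_new - d_star).max() / max(np.abs(d_star).max(), 1e-12),
            )
            g_star, d_star = g_new, d_new
            if change < tol:
                break
        Z_adj[:, idx] = (Zb - g_star[:, None]) / np.sqrt(d_star)[:, None]

    adjusted = Z_adj * sd + stand_mean
    out = pd.DataFrame(adjusted, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(out, matrix.batch)
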