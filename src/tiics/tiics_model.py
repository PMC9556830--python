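"""The TIICs composite prognostic score.

The tumor immune-cell infiltration score for sample j is

    TIICs_j = sum_i  (1 - HR_i) / SE(HR_i)  x  ES_{i,j}

over the cell types whose univariate Cox regression on their enrichment
profile is prognostic (Wald p below a screening threshold, 0.05 by
default). HR_i = exp(beta_i) is the cell's hazard ratio and SE(HR_i) its
delta-method standard error (HR * se_beta), so protective cells
(HR < 1) receive positive weights and harmful cells negative ones.
Samples are stratified at the median score: high means strictly above
the cutoff (ties fall low by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from tiics.ssgsea import EnrichmentMatrix
from tiics.survival_stats import CoxResult, SurvivalData, fit_cox, logrank_test

logger = logging.getLogger(__name__)


@dataclass
class TiicsWeights:
    """Selected cells with their hazard ratios and TIICs weights.

    ``table`` has one row per retained cell: HR, se_HR, p, weight with
    weight = (1 - HR)/se_HR; every retained cell satisfies
    p < ``p_threshold``. Weight sign always equals sign(1 - HR).
    """

    table: pd.DataFrame
    p_threshold: float
    se_mode: str = "hr"

    def __post_init__(self) -> None:
        required = {"HR", "se_HR", "p", "weight"}
        if not required <= set(self.table.columns):
            raise ValueError(f"weights table must have columns {sorted(required)}")
        if (self.table["p"] >= self.p_threshold).any():
            raise ValueError("retained cell with p >= p_threshold")

    @property
    def cell_types(self) -> list[str]:
        return self.table.index.tolist()

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "cell_type"
        out.to_csv(path, sep="\t")


@dataclass
class TiicsScores:
    """Per-sample composite scores with high/low labels at the median."""

    score: pd.Series
    cutoff: float | None = None
    group: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"score": self.score})
        if self.group is not None:
            out["group"] = self.group
        return out

    def to_tsv(self, path) -> None:
        out = self.to_frame()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


def screen_cells(
    enrich: EnrichmentMatrix,
    surv: SurvivalData,
    p_threshold: float = 0.05,
) -> tuple[dict[str, CoxResult], list[str]]:
    """Univariate Cox screening of cell types on their enrichment rows.

    Returns (all per-cell Cox results, cells with Wald p < p_threshold
    ordered by ascending p). Raises if no cell passes — the composite
    score is undefined on an empty selection; review the threshold or
    cohort size.
    """
    common = [s for s in enrich.sample_ids if s in set(surv.sample_ids)]
    if len(common) < len(enrich.sample_ids):
        logger.info(
            "screening on %d/%d samples shared with survival", len(common), len(enrich.sample_ids)
        )
    if not common:
        raise ValueError("no samples shared between enrichment and survival")
    surv_c = surv.subset(common)
    results: dict[str, CoxResult] = {}
    for cell in enrich.cell_types:
        cov = enrich.scores.loc[[cell], common].T
        fit = fit_cox(cov, surv_c)
        results[cell] = fit[cell]
    selected = sorted(
        (c for c, r in results.items() if r.p_value < p_threshold),
        key=lambda c: results[c].p_value,
    )
    if not selected:
        raise ValueError(
            f"no cell type passed the screen at p < {p_threshold}; "
            "review the threshold or the cohort (TIICs is undefined on an empty set)"
        )
    return results, selected


def compute_weights(
    selected: dict[str, CoxResult],
    p_threshold: float = 0.05,
    se_mode: Literal["hr", "beta"] = "hr",
) -> TiicsWeights:
    """Turn screened Cox results into TIICs weights w = (1 - HR)/SE(HR).

    ``se_mode='hr'`` (default) uses the delta-method SE(HR) = HR*se_beta;
    ``'beta'`` divides by se_beta instead (same sign, different scale).
    """
    if not selected:
        raise ValueError("no selected cells")
    rows = []
    for cell, r in selected.items():
        se = r.se_hr if se_mode == "hr" else r.se_beta
        if not (np.isfinite(r.hr) and np.isfinite(se)) or r.hr <= 0:
            raise ValueError(f"non-finite or non-positive HR/SE for cell {cell!r}")
        if se == 0:
            raise ValueError(f"zero SE for cell {cell!r}; weight undefined")
        rows.append((cell, r.hr, r.se_hr, r.p_value, (1.0 - r.hr) / se))
    table = pd.DataFrame(
        rows, columns=["cell_type", "HR", "se_HR", "p", "weight"]
    ).set_index("cell_type")
    return TiicsWeights(table, p_threshold=p_threshold, se_mode=se_mode)


def compute_tiics(enrich: EnrichmentMatrix, weights: TiicsWeights) -> TiicsScores:
    """Weighted sum of enrichment rows: score_j = sum_i w_i * ES_{i,j}."""
    missing = [c for c in weights.cell_types if c not in set(enrich.cell_types)]
    if missing:
        raise KeyError(f"weighted cells absent from enrichment matrix: {missing}")
    w = weights.table["weight"]
    score = enrich.scores.loc[w.index].T @ w
    score.name = "score"
    return TiicsScores(score=score)


def assign_groups(
    scores: TiicsScores, ties: Literal["low", "high"] = "low"
) -> TiicsScores:
    """Median-cutoff stratification into high and low groups.

    The cutoff is the median score; a sample is high iff its score is
    strictly above the cutoff (``ties='low'``, default) or at/above it
    (``ties='high'``). All-identical scores cannot be stratified.
    """
    s = scores.score
    if len(s) < 2:
        raise ValueError("need >=2 samples to stratify")
    if s.nunique() == 1:
        raise ValueError("all scores identical; no stratification possible")
    cutoff = float(s.median())
    if ties == "low":
        high = s > cutoff
    elif ties == "high":
        high = s >= cutoff
    else:
        raise ValueError(f"unknown tie convention {ties!r}")
    group = pd.Series(np.where(high, "high", "low"), index=s.index, name="group")
    return TiicsScores(score=s, cutoff=cutoff, group=group)


@dataclass
class ValidationResult:
    """External-cohort validation: scores, groups and the log-rank test."""

    scores: TiicsScores
    weights: TiicsWeights
    chi_square: float
    p_value: float
    mode: str


def validate_external(
    enrich_val: EnrichmentMatrix,
    surv_val: SurvivalData,
    mode: Literal["refit", "transfer"] = "refit",
    training_weights: TiicsWeights | None = None,
    p_threshold: float = 0.05,
    ties: Literal["low", "high"] = "low",
) -> ValidationResult:
    """Score an external cohort and test high-vs-low survival separation.

    ``refit`` (default) repeats the whole construction on the validation
    cohort — screen, weights, score; ``transfer`` reuses the training
    weights. Either way samples are split at the validation median and
    compared by log-rank.
    """
    if mode == "refit":
        results, selected = screen_cells(enrich_val, surv_val, p_threshold)
        weights = compute_weights({c: results[c] for c in selected}, p_threshold)
    elif mode == "transfer":
        if training_weights is None:
            raise ValueError("transfer mode requires training_weights")
        weights = training_weights
    else:
        raise ValueError(f"unknown mode {mode!r}")
    scores = assign_groups(compute_tiics(enrich_val, weights), ties=ties)
    common = [s for s in scores.score.index if s in set(surv_val.sample_ids)]
    chi2, p = logrank_test(surv_val.subset(common), scores.group.loc[common])
    return ValidationResult(scores, weights, chi2, p, mode)
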