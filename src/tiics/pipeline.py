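"""End-to-end orchestration of the infiltration-scoring analysis.

Chains preprocessing (optional batch adjustment), ssGSEA scoring,
prognostic-cell screening, the composite TIICs score, median
stratification, survival comparisons (Kaplan-Meier, log-rank,
time-dependent AUC) and the downstream group analytics, writing every
stage output as TSV plus a checksum manifest. Fully deterministic given
the configured seed, which fans out to per-stage seeds by stable
derivation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml

from tiics.downstream import estimate_scores, group_compare, moderated_t_deg, ranked_enrichment
from tiics.gene_sets_io import read_gmt, restrict_to_matrix
from tiics.preprocess import ExpressionMatrix, batch_adjust
from tiics.ssgsea import EnrichmentMatrix, SsgseaParams, cell_correlations, cluster_cells, ssgsea_score
from tiics.survival_stats import (
    DEFAULT_HORIZONS,
    SurvivalData,
    fit_cox,
    km_curve,
    logrank_test,
    time_dependent_auc,
)
from tiics.tiics_model import assign_groups, compute_tiics, compute_weights, screen_cells

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and options for an end-to-end run."""

    expression: str
    survival: str
    signatures: str
    out_dir: str
    batches: str | None = None
    estimate_signatures: str | None = None  # GMT with sets named 'stromal'/'immune'
    batch_correct: bool = False
    min_set_size: int = 5
    alpha: float = 0.25
    normalize: bool = True
    screening_p: float = 0.05
    correlation_p: float = 1e-4
    n_cell_clusters: int = 4
    median_ties: str = "low"
    horizons: tuple[float, ...] = DEFAULT_HORIZONS
    lfc_threshold: float = 0.5
    deg_p: float = 0.05
    n_perm: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        for name in ("screening_p", "correlation_p", "deg_p"):
            v = getattr(cfg, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if any(h <= 0 for h in cfg.horizons):
            raise ValueError("horizons must be positive")
        return cfg

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage seed derived from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def compare_auc(
    tiics_scores,
    enrich: EnrichmentMatrix,
    surv: SurvivalData,
    horizons=DEFAULT_HORIZONS,
    cells: list[str] | None = None,
) -> pd.DataFrame:
    """Time-dependent AUC of the composite score and single cell types.

    Each marker is oriented as a risk before scoring: the composite
    TIICs is protective-positive by construction so its risk is the
    negated score, and each cell's enrichment row is oriented by the
    sign of its own univariate Cox coefficient. Returns a markers x
    horizons AUC table (first row 'TIICs').
    """
    cells = cells if cells is not None else enrich.cell_types
    ids = tiics_scores.score.index
    surv_c = surv.subset([s for s in ids if s in set(surv.sample_ids)])
    rows = {}
    rows["TIICs"] = time_dependent_auc(
        -tiics_scores.score.loc[surv_c.sample_ids], surv_c, horizons
    )
    for cell in cells:
        es = enrich.scores.loc[cell, surv_c.sample_ids]
        beta = fit_cox(es.to_frame(cell), surv_c)[cell].beta
        orient = -1.0 if beta < 0 else 1.0
        rows[cell] = time_dependent_auc(orient * es, surv_c, horizons)
    return pd.DataFrame(rows).T


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write outputs plus a checksum manifest.

    Sample ids are reconciled by inner join between expression and
    survival, with mismatch counts logged; any stage error propagates as
    :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    results: dict = {"config": asdict(config)}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc
        return deco

    def load_inputs():
        expr = ExpressionMatrix.from_tsv(config.expression, batch_path=config.batches)
        surv = SurvivalData.from_tsv(config.survival)
        sets = read_gmt(config.signatures)
        common = [s for s in expr.sample_ids if s in set(surv.sample_ids)]
        n_expr_only = len(expr.sample_ids) - len(common)
        n_surv_only = len(surv.sample_ids) - len(common)
        if n_expr_only or n_surv_only:
            logger.warning(
                "sample reconciliation: %d shared, %d expression-only, %d survival-only",
                len(common), n_expr_only, n_surv_only,
            )
        if not common:
            raise ValueError("no samples shared between expression and survival")
        batch = expr.batch.loc[common] if expr.batch is not None else None
        expr = ExpressionMatrix(expr.values[common], batch)
        return expr, surv.subset(common), sets

    expr, surv, sets = stage("load_inputs")(load_inputs)
    results["n_samples"] = len(expr.sample_ids)
    results["n_genes"] = len(expr.gene_ids)

    if config.batch_correct and expr.batch is not None:
        expr = stage("batch_adjust")(lambda: batch_adjust(expr))

    def score_cells():
        restricted, dropped = restrict_to_matrix(sets, expr.gene_ids, config.min_set_size)
        enrich = ssgsea_score(
            expr, restricted, SsgseaParams(alpha=config.alpha, normalize=config.normalize)
        )
        return enrich, dropped

    enrich, dropped_sets = stage("ssgsea")(score_cells)
    enrich.to_tsv(out / "enrichment.tsv")
    written["enrichment"] = out / "enrichment.tsv"
    results["n_cell_types"] = len(enrich.cell_types)
    results["dropped_sets"] = sorted(dropped_sets)

    def correlations():
        net = cell_correlations(enrich, config.correlation_p)
        net.edges.to_csv(out / "cell_correlations.tsv", sep="\t", index=False)
        labels = cluster_cells(enrich, min(config.n_cell_clusters, len(enrich.cell_types)))
        pd.Series(labels, name="cluster").rename_axis("cell_type").to_csv(
            out / "cell_clusters.tsv", sep="\t"
        )
        return net

    net = stage("cell_structure")(correlations)
    written["cell_correlations"] = out / "cell_correlations.tsv"
    written["cell_clusters"] = out / "cell_clusters.tsv"
    results["n_correlation_edges"] = len(net.edges)

    def build_score():
        cox_results, selected = screen_cells(enrich, surv, config.screening_p)
        weights = compute_weights(
            {c: cox_results[c] for c in selected}, config.screening_p
        )
        scores = assign_groups(compute_tiics(enrich, weights), ties=config.median_ties)
        screen_tbl = pd.DataFrame(
            {
                "beta": {c: r.beta for c, r in cox_results.items()},
                "HR": {c: r.hr for c, r in cox_results.items()},
                "se_HR": {c: r.se_hr for c, r in cox_results.items()},
                "p": {c: r.p_value for c, r in cox_results.items()},
                "selected": {c: c in selected for c in cox_results},
            }
        ).rename_axis("cell_type")
        screen_tbl.to_csv(out / "cox_screen.tsv", sep="\t")
        weights.to_tsv(out / "tiics_weights.tsv")
        scores.to_tsv(out / "tiics_scores.tsv")
        return weights, scores, selected

    weights, scores, selected = stage("tiics")(build_score)
    for key in ("cox_screen", "tiics_weights", "tiics_scores"):
        written[key] = out / f"{key}.tsv"
    results["selected_cells"] = selected
    results["median_cutoff"] = scores.cutoff

    def survival_comparisons():
        curves = km_curve(surv, scores.group)
        km_rows = []
        for g, (t, s) in curves.items():
            for ti, si in zip(t, s):
                km_rows.append((g, ti, si))
        pd.DataFrame(km_rows, columns=["group", "time_months", "survival"]).to_csv(
            out / "km_curves.tsv", sep="\t", index=False
        )
        chi2, p = logrank_test(surv, scores.group)
        usable = [h for h in config.horizons if h < surv.time.max()]
        auc_tbl = compare_auc(scores, enrich, surv, usable, cells=selected)
        auc_tbl.rename_axis("marker").to_csv(out / "auc.tsv", sep="\t")
        return chi2, p, auc_tbl

    chi2, logrank_p, auc_tbl = stage("survival")(survival_comparisons)
    written["km_curves"] = out / "km_curves.tsv"
    written["auc"] = out / "auc.tsv"
    results["logrank_chi_square"] = chi2
    results["logrank_p"] = logrank_p
    results["tiics_auc"] = auc_tbl.loc["TIICs"].to_dict()

    def downstream_stage():
        deg = moderated_t_deg(expr, scores.group, config.lfc_threshold, config.deg_p)
        deg.to_csv(out / "deg.tsv", sep="\t")
        enr = ranked_enrichment(
            deg["moderated_t"], sets, n_perm=config.n_perm,
            seed=config.stage_seed("ranked_enrichment"),
        )
        enr.to_csv(out / "ranked_enrichment.tsv", sep="\t")
        comp_rows = []
        for cell in selected:
            u, p_w = group_compare(enrich.scores.loc[cell], scores.group)
            comp_rows.append((cell, u, p_w))
        comp = pd.DataFrame(comp_rows, columns=["cell_type", "U", "p"]).set_index("cell_type")
        est = None
        if config.estimate_signatures:
            est_sets = read_gmt(config.estimate_signatures)
            est = estimate_scores(
                expr, est_sets.genes("stromal"), est_sets.genes("immune")
            )
            est.to_csv(out / "estimate_scores.tsv", sep="\t")
            for col in ("stromal_score", "immune_score", "tumor_purity"):
                u, p_w = group_compare(est[col], scores.group)
                comp_rows.append((col, u, p_w))
            comp = pd.DataFrame(
                comp_rows, columns=["feature", "U", "p"]
            ).set_index("feature")
        comp.to_csv(out / "group_comparisons.tsv", sep="\t")
        return deg, est

    deg, est = stage("downstream")(downstream_stage)
    written["deg"] = out / "deg.tsv"
    written["ranked_enrichment"] = out / "ranked_enrichment.tsv"
    written["group_comparisons"] = out / "group_comparisons.tsv"
    if est is not None:
        written["estimate_scores"] = out / "estimate_scores.tsv"
    results["n_significant_degs"] = int(deg["significant"].sum())

    manifest = {
        "results": results,
        "files": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in written.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
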