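"""Synthetic cohorts with planted infiltration signal and known truth.

Emulates the statistical structure the scoring pipeline assumes: a
genes x samples log-expression matrix in which each cell type's
signature genes co-vary with a per-sample latent infiltration level,
additive/multiplicative batch effects across pseudo-cohorts, and
proportional-hazards survival whose log-hazard is a linear function of
chosen latent infiltration levels (negative coefficients protective),
with independent exponential censoring calibrated to a target censored
fraction.

Generative model, per sample j and cell type k:

    a_{k,j} ~ N(0, 1)                               (latent infiltration)
    x_{g,j} = mu_g + lambda * a_{k(g),j} + batch + eps   (signature gene)
    x_{g,j} = mu_g + batch + eps                         (background gene)
    T_j ~ Exponential(h0 * exp(sum_k beta_k a_{k,j}))    (event time)
    C_j ~ Exponential(c),  c chosen so E[fraction censored] ~ censor_rate

with mu_g ~ N(6, 1) (log2-microarray-like scale), eps ~ N(0, sigma_b^2)
where sigma_b scales with batch, and batch b shifted by batch_shift * b.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from tiics.gene_sets_io import GeneSetCollection, write_gmt
from tiics.preprocess import ExpressionMatrix
from tiics.survival_stats import SurvivalData


@dataclass
class SimulationConfig:
    """Cohort-generator parameters.

    Defaults emulate a two-cohort microarray study of 28 immune cell
    signatures: 400 samples, 5000 genes with 30-gene signatures, unit
    signal loading against unit noise, baseline hazard 0.01 events per
    month and 30% censoring, with a one-unit additive batch shift and a
    20% wider noise scale in the second pseudo-cohort.
    """

    n_genes: int = 5000
    n_samples: int = 400
    n_cell_types: int = 28
    genes_per_set: int = 30
    signal_strength: float = 1.0  # lambda: loading of latent level on set genes
    noise_sd: float = 1.0  # sigma
    prognostic_cells: dict[int, float] = field(default_factory=dict)  # 1-based index -> beta
    baseline_hazard: float = 0.01  # h0, events per month
    censor_rate: float = 0.3
    n_batches: int = 2
    batch_shift: float = 1.0
    batch_scale: float = 1.2
    overlap_fraction: float = 0.0  # fraction of each set shared with the next set
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genes, self.n_samples, self.n_cell_types, self.genes_per_set) < 1:
            raise ValueError("dimensions must be positive")
        if self.n_cell_types * self.genes_per_set > self.n_genes:
            raise ValueError(
                f"{self.n_cell_types} sets x {self.genes_per_set} genes "
                f"exceed the {self.n_genes}-gene universe"
            )
        bad = [k for k in self.prognostic_cells if not 1 <= k <= self.n_cell_types]
        if bad:
            raise ValueError(f"prognostic cell indices out of range: {bad}")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.noise_sd <= 0 or self.baseline_hazard <= 0 or self.batch_scale <= 0:
            raise ValueError("noise_sd, baseline_hazard, batch_scale must be positive")
        if self.signal_strength < 0 or not 0 <= self.overlap_fraction < 1:
            raise ValueError("signal_strength >= 0 and overlap_fraction in [0, 1) required")
        if self.n_batches < 1 or self.n_batches > self.n_samples:
            raise ValueError("n_batches must be in [1, n_samples]")


@dataclass
class SimulationTruth:
    """Ground truth for parameter-recovery tests."""

    latent_infiltration: pd.DataFrame  # cell types x samples
    betas: pd.Series  # per cell type log-hazard coefficient
    batch_labels: pd.Series  # per sample batch id
    set_assignment: pd.Series  # gene -> owning cell type ('' = background)


def _censoring_rate_constant(hazards: np.ndarray, target: float) -> float:
    """Solve for exponential censoring rate c with E[P(C < T)] = target.

    For independent exponentials, P(censored | hazard l) = c / (c + l).
    """
    if target <= 0:
        return 0.0

    def expected_censored(c: float) -> float:
        return float(np.mean(c / (c + hazards)))

    lo, hi = 1e-12, float(hazards.max()) * 1e6
    return brentq(lambda c: expected_censored(c) - target, lo, hi, xtol=1e-12, rtol=1e-10)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SurvivalData, GeneSetCollection, SimulationTruth]:
    """Draw one cohort; bit-identical for a given config (seeded)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, n, K, m = config.n_genes, config.n_samples, config.n_cell_types, config.genes_per_set

    genes = np.array([f"G{i:05d}" for i in range(1, G + 1)], dtype=object)
    samples = [f"S{j:04d}" for j in range(1, n + 1)]
    cells = [f"cell_{k:02d}" for k in range(1, K + 1)]

    batch = np.repeat(np.arange(config.n_batches), int(np.ceil(n / config.n_batches)))[:n]
    mu = rng.normal(6.0, 1.0, size=G)
    latent = rng.normal(0.0, 1.0, size=(K, n))

    # disjoint ownership blocks; optional overlap borrows genes from the next set
    owner = np.full(G, "", dtype=object)
    membership: dict[str, list[str]] = {}
    for k in range(K):
        block = np.arange(k * m, (k + 1) * m)
        owner[block] = cells[k]
        membership[cells[k]] = list(genes[block])
    if config.overlap_fraction > 0:
        n_shared = int(round(config.overlap_fraction * m))
        for k in range(K):
            nxt = (k + 1) % K
            borrowed = genes[np.arange(nxt * m, nxt * m + n_shared)]
            membership[cells[k]] = list(
                dict.fromkeys(membership[cells[k]] + list(borrowed))
            )

    noise_scale = (config.batch_scale ** batch) * config.noise_sd
    X = mu[:, None] + rng.normal(0.0, 1.0, size=(G, n)) * noise_scale[None, :]
    X += config.batch_shift * batch[None, :]
    for k in range(K):
        block = slice(k * m, (k + 1) * m)
        X[block, :] += config.signal_strength * latent[k][None, :]

    betas = np.zeros(K)
    for idx, beta in config.prognostic_cells.items():
        betas[idx - 1] = beta
    hazards = config.baseline_hazard * np.exp(betas @ latent)
    event_time = rng.exponential(1.0 / hazards)
    if config.censor_rate > 0:
        c = _censoring_rate_constant(hazards, config.censor_rate)
        censor_time = rng.exponential(1.0 / c, size=n)
    else:
        censor_time = np.full(n, np.inf)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    observed = np.maximum(observed, 1e-6)  # guard against zero times

    expr = ExpressionMatrix(
        pd.DataFrame(X, index=list(genes), columns=samples),
        batch=pd.Series([f"batch_{b + 1}" for b in batch], index=samples),
    )
    surv = SurvivalData(
        pd.Series(observed, index=samples), pd.Series(event, index=samples)
    )
    sets = GeneSetCollection(
        {c: (f"synthetic signature for {c}", tuple(g)) for c, g in membership.items()}
    )
    truth = SimulationTruth(
        latent_infiltration=pd.DataFrame(latent, index=cells, columns=samples),
        betas=pd.Series(betas, index=cells),
        batch_labels=expr.batch,
        set_assignment=pd.Series(owner, index=list(genes)),
    )
    return expr, surv, sets, truth


def write_cohort(
    cohort: tuple[ExpressionMatrix, SurvivalData, GeneSetCollection, SimulationTruth],
    out_dir: str | Path,
    config: SimulationConfig | None = None,
) -> dict[str, str]:
    """Write a cohort to TSV/GMT files re-readable by the pipeline.

    Returns a manifest of logical name -> file path.
    """
    expr, surv, sets, truth = cohort
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    expr.to_tsv(out / "expression.tsv")
    manifest["expression"] = str(out / "expression.tsv")
    batch = expr.batch.to_frame(name="batch")
    batch.index.name = "sample_id"
    batch.to_csv(out / "batches.tsv", sep="\t")
    manifest["batches"] = str(out / "batches.tsv")
    surv.to_tsv(out / "survival.tsv")
    manifest["survival"] = str(out / "survival.tsv")
    write_gmt(sets, out / "signatures.gmt")
    manifest["signatures"] = str(out / "signatures.gmt")

    latent = truth.latent_infiltration.copy()
    latent.index.name = "cell_type"
    latent.to_csv(out / "truth_latent.tsv", sep="\t")
    manifest["truth_latent"] = str(out / "truth_latent.tsv")
    betas = truth.betas.to_frame(name="beta")
    betas.index.name = "cell_type"
    betas.to_csv(out / "truth_betas.tsv", sep="\t")
    manifest["truth_betas"] = str(out / "truth_betas.tsv")
    assign = truth.set_assignment.to_frame(name="cell_type")
    assign.index.name = "gene_id"
    assign.to_csv(out / "truth_set_assignment.tsv", sep="\t")
    manifest["truth_set_assignment"] = str(out / "truth_set_assignment.tsv")

    if config is not None:
        cfg = asdict(config)
        cfg["prognostic_cells"] = {str(k): v for k, v in cfg["prognostic_cells"].items()}
        (out / "config.json").write_text(json.dumps(cfg, indent=2) + "\n")
        manifest["config"] = str(out / "config.json")
    return manifest
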