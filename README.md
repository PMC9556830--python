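# tiics

Tumor immune-cell infiltration scoring for survival cohorts.

`tiics` builds and evaluates a composite prognostic score from the
inferred infiltration of immune cell types in bulk expression data —
the setting is multiple myeloma-style cohorts with overall-survival
follow-up, scored against a panel of immune-cell gene signatures (28
cell types by convention). It is aimed at computational biologists who
want the whole construction — enrichment, screening, scoring,
stratification, downstream comparisons — as a tested, deterministic
pipeline that also ships a synthetic-cohort generator with known ground
truth, so every stage can be validated without any data download.

## The score

For each sample *j*, single-sample GSEA turns the expression profile
into an enrichment score ES(*i*, *j*) per immune cell type *i* (rank
weights r^α, α = 0.25). Each cell type is screened by univariate Cox
regression of survival on its enrichment (Efron ties, Wald p < 0.05),
and the retained cells form the weighted sum

```
TIICs_j = Σ_i  (1 − HR_i) / SE(HR_i) × ES(i, j)
```

where HR_i = exp(β_i) is the cell's hazard ratio and SE(HR_i) its
delta-method standard error. Protective cells (HR < 1) get positive
weights, harmful ones negative, so a higher score is constructed to be
favorable. Samples split at the median score into high/low groups,
which are compared by Kaplan–Meier curves, the log-rank test and
IPCW time-dependent AUC at 6/8/10-year horizons; downstream analytics
(stromal/immune microenvironment scores with the cosine purity
transform, moderated-t differential expression at |logFC| > 0.5 and
p < 0.05, preranked permutation set enrichment, Wilcoxon feature
comparisons) contrast the two groups. See `docs/methods.md` for the
full model description and the design choices.

## Worked example

Simulate a cohort in which cell types 1 and 2 are truly protective
(log-hazard −0.7 and −0.5 per unit latent infiltration), then run the
construction:

```python
import tiics as T

config = T.SimulationConfig(
    n_genes=1000, n_samples=300, n_cell_types=10, genes_per_set=25,
    signal_strength=2.0, prognostic_cells={1: -0.7, 2: -0.5},
    censor_rate=0.3, batch_shift=0.0, batch_scale=1.0, seed=1,
)
expr, surv, sets, truth = T.generate_cohort(config)
restricted, _ = T.restrict_to_matrix(sets, expr.gene_ids)
enrich = T.ssgsea_score(expr, restricted)

results, selected = T.screen_cells(enrich, surv)          # Cox p < 0.05
weights = T.compute_weights({c: results[c] for c in selected})
print(weights.table.round(4))

scores = T.assign_groups(T.compute_tiics(enrich, weights))  # median split
chi2, p = T.logrank_test(surv, scores.group)
print(f"cutoff = {scores.cutoff:.4f}")
print(f"log-rank chi-square = {chi2:.2f}, p = {p:.3g}")
print(T.compare_auc(scores, enrich, surv, horizons=[72.0], cells=selected).round(3))
```

Output:

```
               HR   se_HR    p   weight
cell_type
cell_01    0.1306  0.0337  0.0  25.7932
cell_02    0.3154  0.0744  0.0   9.2052
cutoff = 1.5915
log-rank chi-square = 48.42, p = 3.43e-12
          72.0
TIICs    0.742
cell_01  0.710
cell_02  0.617
```

The screen recovers exactly the two planted protective cells with
HR < 1, hence positive weights. The high-score half of the cohort has
markedly better survival (log-rank p ≈ 3e-12), and the composite score
discriminates 6-year outcomes better (AUC 0.74) than either cell alone
(0.71, 0.62) — the composite pools partial signals.

The same flow is available from the shell:

```
tiics simulate --seed 1 --out cohort/ --prognostic "1:-0.7,2:-0.5"
tiics run --config config.yaml        # end-to-end with checksum manifest
```

(`simulate`, `preprocess`, `score`, `tiics`, `survival`, `downstream`,
`run` are the subcommands; `run` takes a YAML config naming the
expression/survival/signature inputs and thresholds.)

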