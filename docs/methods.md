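# Methods

## The model

This package builds a composite prognostic score from the inferred
infiltration of immune cell types in bulk tumor expression data, in the
setting of multiple myeloma-like cohorts: log-scale expression profiles
with survival follow-up, scored against a panel of immune-cell gene
signatures (28 cell types by default).

The construction has four stages.

**1. Per-sample enrichment (ssGSEA).** For sample *j* and signature *S*,
genes are ranked by expression ascending (ranks 1..N, ties averaged) and
laid out in descending-rank order, ties broken lexicographically by gene
id so that scores are reproducible on discrete data. The enrichment
score is the integrated difference between the rank-weighted in-set and
unweighted out-of-set cumulative distributions,

    ES(S, j) = Σ_i [ P_in(i) − P_out(i) ],
    P_in(i)  = Σ_{g∈S, pos(g)≤i} r_g^α / Σ_{g∈S} r_g^α,
    P_out(i) = |{g∉S, pos(g)≤i}| / (N − |S|),

with α = 0.25 (the usual ssGSEA weighting; α = 0 gives uniform in-set
weights). Absolute ranks, not centered ranks, are used as weights. The
implementation evaluates the algebraically equivalent closed form
`ES = Σ_{g∈S} w_g (N − pos_g + 1)/W − [N(N+1)/2 − Σ_{g∈S}(N − pos_g + 1)]/(N−|S|)`,
which needs only the positions of set genes; a literal double-loop
reference implementation is kept in `tiics.evaluation` and the two are
compared to 1e-9 in the acceptance suite. By default the score matrix is
rescaled by its global max − min range (GSVA's "ssgsea.norm"
convention), and the normalized scores feed the survival modelling;
`SsgseaParams(normalize=False)` disables this.

**2. Prognostic screening.** Each cell type's enrichment row enters a
univariate Cox proportional-hazards regression against overall survival.
Cells with two-sided Wald p < 0.05 are retained. The Cox fit maximizes
the Efron-tie-corrected partial likelihood by Newton–Raphson with step
halving (|Δβ| < 1e-9, ≤ 50 iterations); standard errors come from the
inverse observed information. Monotone likelihoods (perfect separation)
are flagged `converged=False` rather than raised. The fit is written
natively because the screen runs thousands of univariate models;
lifelines' `CoxPHFitter` serves as an independent cross-check in the
tests (agreement to 1e-4, which is lifelines' own convergence scale).

**3. The composite score.** Each retained cell *i* contributes weight

    w_i = (1 − HR_i) / SE(HR_i),     TIICs_j = Σ_i w_i · ES_{i,j},

with HR = exp(β) and, by the delta method, SE(HR) = HR·se_β. Protective
cells (HR < 1) therefore carry positive weight and harmful ones
negative, so higher scores are constructed to be favorable. The
denominator is ambiguous in principle (SE of the hazard ratio vs SE of
the log hazard ratio); the delta-method reading is the default and
`se_mode="beta"` is exposed — the choice rescales weights but never
changes their sign.

**4. Stratification and comparison.** Samples split at the median score:
"high" means strictly above the cutoff, with ties at the median assigned
low (deterministic; `ties="high"` is available). Groups are compared by
Kaplan–Meier curves, the log-rank test, and IPCW cumulative/dynamic
time-dependent AUC (scikit-survival) at 72/96/120-month horizons
(6/8/10 years; the package works in months throughout). When the
composite is compared against single cell types, every marker is
oriented as a risk first — the composite by negating it (it is
protective-positive by construction), each cell row by the sign of its
own univariate Cox coefficient — since an AUC below 0.5 for a
protective marker measures the same discrimination. External validation
defaults to refitting the weights on the validation cohort (`refit`),
with `transfer` reusing training weights.

## Supporting analytics

**Batch adjustment** is a parametric empirical-Bayes location/scale
(ComBat-style) correction: genes are standardized against fitted batch
means and pooled variances; per-batch additive (γ) and multiplicative
(δ²) effects are shrunk toward normal and inverse-gamma priors whose
hyperparameters are moment-matched across genes, iterated to a joint
fixed point (relative tolerance 1e-4). No covariate matrix is used;
biological groups are assumed batch-balanced. The parametric variant
was chosen for determinism and speed; scanpy's ComBat — an independent
implementation — agrees to ~1e-3 on simulated data and is kept as a
test oracle. Note what shrinkage implies: a shift shared by all genes
is removed essentially exactly, but per-gene deviations of the batch
means (sampling noise) are only partially removed — this is the
intended empirical-Bayes behaviour, not a defect.

**Differential expression** is a two-group moderated t: per-gene pooled
variances are shrunk toward a common prior via the standard
log-variance moment relations (digamma/trigamma, with a Newton
trigamma inverse), giving prior df d₀ and scale s₀²; the moderated t
has d₀ + d_g df. When the observed log-variances show no excess
dispersion (d₀ → ∞) all genes share s₀². Significance is the raw-p
conjunction |logFC| > 0.5 and p < 0.05, with logFC defined as
high-group minus low-group mean; Benjamini–Hochberg values are reported
alongside but deliberately never filter, preserving the stated decision
rule while making the multiplicity information available.

**Microenvironment scores** are unnormalized ssGSEA (α = 0.25) of
stromal and immune signatures; their sum is the combined score and
purity = cos(0.6049872018 + 0.0001467884 × combined), the published
transform of the ESTIMATE method. Those constants are calibrated to
Affymetrix-scale scores; out-of-range combined scores trigger a logged
warning and purity is clipped to [0, 1] for reporting.

**Preranked enrichment** orders genes by a statistic, accumulates
|stat|-weighted mass at in-set genes and −1/(N−|S|) elsewhere, and takes
the maximum signed deviation. The null is gene-label permutation; NES
divides by the mean |null| of matching sign and the two-sided p carries
a +1 pseudo-count (minimum p = 1/(n_perm+1)). Because weights are
|stat|, the score is intentionally not invariant to monotone rescaling
of the statistic — a regression test asserts this.

**Rank-sum comparisons** use exact enumeration for combined n ≤ 12
(tie-free) and the tie-corrected normal approximation otherwise.

## The synthetic cohort generator

`generate_cohort` emulates the statistical structure the analysis
assumes, not any particular platform. Per sample j and cell type k:

- latent infiltration a_{k,j} ~ N(0,1), i.i.d.;
- signature genes: x = μ_g + λ·a_{k,j} + batch + ε, background genes
  omit the λ term; μ_g ~ N(6,1) (log2-microarray-like scale),
  ε ~ N(0, σ_b²) with σ_b = batch_scale^b·σ, and batch b shifted by
  batch_shift·b;
- survival: event time ~ Exponential(h₀·exp(Σ_k β_k a_{k,j})) —
  proportional hazards in the latent levels with negative β protective —
  censored by an independent exponential whose rate solves
  E[c/(c+λ_j)] = censor_rate.

Defaults: 28 cell types × 30-gene disjoint signatures in 5000 genes,
400 samples, λ = σ = 1, h₀ = 0.01 events/month, 30% censoring, two
batches (shift 1.0, scale 1.2), no prognostic cells unless requested.
An `overlap_fraction` lets consecutive signatures share genes, since
real immune signatures overlap. Exponential event and censoring times
are the simplest PH-consistent choice; the generator does not emulate
probe structure, heavy-tailed expression noise, correlated background
genes, non-proportional hazards, or informative censoring — so passing
tests demonstrate correctness of the machinery under the assumed model,
not robustness to violations real cohorts will show.

A closed form ties the generator to its tests: the correlation between
a signature gene and its latent level is λ/√(λ²+σ²), checked at
n = 5000 within ±0.03.

## Numerical and design notes

- Probe collapse uses the per-gene median across probes (mean of the
  two central order statistics for even counts); unmapped probes are
  dropped, unknown probes are an error.
- Signature sets are intersected with the matrix and dropped below 5
  surviving genes (enrichment on tiny sets is noise-dominated); gene
  matching is exact and case-sensitive, no symbol aliasing.
- Cell-cell correlation edges use Pearson r with the t transform
  (n−2 df) and threshold p < 1e-4; cell clustering is Ward linkage on
  row-standardized profiles cut at k = 4.
- The pipeline reconciles expression and survival samples by inner
  join with logged counts; silent drops are forbidden. A single global
  seed fans out to per-stage seeds via SHA-256 of "seed:stage".
- Degenerate inputs fail loudly: constant-expression samples, all-gene
  sets, all-censored cohorts, constant composite scores, singleton
  batches.

## Problem sizes in the validation suite

The acceptance measurements run at: 100 random small matrices for the
enrichment oracle; 100 Cox replicates of n = 1000 per true β; 1000
log-rank null replicates of n = 100; 100 cohorts of n = 800 (10 cell
types) for sign recovery; 100 + 60 cohorts of n = 800 (28 cell types)
for screening power and null size; 2000 genes at n = 50/50 for the
type-I rate; n = 200/group for the pooled-t limit. The reproduction
script additionally simulates one training cohort of n = 1281 and one
validation cohort of n = 426 with 28 signatures (6000 genes, 100 genes
per signature, five protective and two harmful cell types) — sizes
chosen to mirror the cohort scale the score was designed for while
keeping a full run in the low minutes on one core.

## Known limitations

- The generator's independence and exponential-time assumptions are
  idealized (above); parameter-recovery results do not transfer
  automatically to real arrays.
- The purity transform is platform-calibrated; on scores far from the
  Affymetrix scale it extrapolates (warned, clipped).
- Screening is univariate by design — correlated protective cells are
  all selected and their weights double-count shared signal; no
  penalized multivariable selection is offered.
- The time-dependent AUC estimator is the IPCW cumulative/dynamic
  variant; other estimators (incident/dynamic) would give different
  absolute values.
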