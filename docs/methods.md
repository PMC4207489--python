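# Methods

## The model

Gene expression in a tumour cohort is modelled as an additive function of
four regulatory inputs: copy number, promoter methylation, transcription
factor (TF) occupancy, and miRNA-mediated repression.  Let `y_gs` be the
(log-scale) expression of gene `g` in sample `s`, `c_gs` the gene's
copy-number segment mean, `d_gs` its methylation beta average, `b_tg` the
ChIP-seq binding score of TF `t` at the gene's promoter (measured once, in
a related cell line), `s_mg` the number of conserved seed-match sites of
miRNA `m` in the gene's 3'UTR, and `x_ms` the miRNA's expression.

**Stage 1** fits, independently for every sample `s`, the gene-wise model

    y_gs = alpha_s + phi_s c_gs + psi_s d_gs
           + sum_t w_ts b_tg + sum_m u_ms (s_mg x_ms) + eps_gs

The coefficients `w_ts` and `u_ms` are the *sample-specific regulatory
activities* of each TF and miRNA: a latent per-sample scalar that scales
the regulator's static binding/seed profile into the sample's expression
state.  This is how static cell-line ChIP data is married to per-patient
omics: the binding profile is shared; only its per-sample weight is free.

**Stage 2** re-uses the activity matrices `W` (T x N) and `U` (M x N) as
predictors, fitting independently for every gene `g` the sample-wise model

    y_gs = beta0_g + beta_c,g c_gs + beta_d,g d_gs
           + sum_{t in TF(g)} theta_gt w_ts
           + sum_{m in miR(g)} theta_gm u~_ms + eps_gs

where `TF(g) = {t : b_tg > 0}` and `miR(g) = {m : s_mg > 0}` are the
candidate regulators with nonzero binding signal / seed-site counts, and
`u~_ms = u_ms * mean_s(u_ms)` is the activity weighted by its cross-sample
mean.  The weighting serves two purposes: it damps miRNAs whose average
activity is negligible, and — because mean miRNA activity is negative
(repression) — it flips the predictor so that a *repressive* regulator-gene
interaction receives a *negative* score `theta_gm`.  The matrices
`Theta_TF` (G x T) and `Theta_miR` (G x M) are the interaction scores used
for target prediction; entries off the candidate support are identically
zero by construction.

Both stages use the same fitting contract: least squares with an L1
penalty (lasso).  Predictors are standardised to unit variance internally;
the intercept is unpenalised; coefficients are reported on the original
predictor scale.  The penalty weight is chosen per regression by k-fold
(default 10) cross-validation over a 100-point log-spaced path from
`lambda_max = max|X'y|/n` down to `1e-3 * lambda_max`, at the minimum of
mean CV squared error (not the one-standard-error rule: the model
comparison rewards minimum-error predictive fits; the 1-SE alternative
can be had by passing an explicit `lam`).  Fold assignment is fixed by the
seed, making every fit bit-reproducible.  `lam=0` is solved as exact OLS.
Zero-variance predictor columns (e.g. an unexpressed miRNA) are dropped to
coefficient zero.

## Downstream procedures

**Model comparison.**  10-fold cross-validation per sample over genes
(stage 1) or per gene over samples (stage 2), scoring held-out predictions
by Spearman correlation and out-of-sample R^2 (`1 - SS_res/SS_tot`, which
may be negative; no clipping).  Variants exclude one factor at a time
(implemented by zeroing the factor's matrix, which the fitting contract
reduces to dropping the column), replace ChIP scores with motif counts,
drop the expression weighting of seed counts (`x := 1`), or permute gene
labels as a negative control.  The penalty is re-selected inside every
training fold, so no information leaks from held-out units.  Variants are
compared by paired Wilcoxon signed-rank tests (exact null for n <= 25
nonzero differences, normal approximation with continuity correction
above).  An undefined Spearman value (constant vector) is recorded as 0
and flagged, keeping metric vectors full-length for the paired tests.

**Feature selection.**  Each regulator is scored by a leave-one-out nested
F-test on the stage-1 regressions: the per-sample fits are recomputed with
the regulator's predictor column removed, and

    F = ((RSS_reduced - RSS_full) / df_num) / (RSS_full / df_den)

with `df_num = N` (one activity parameter removed per sample) and
`df_den = N (G - T - M - 3)` (per-sample residual degrees of freedom,
pooled), both configurable.  By default both models are refitted by OLS on
the full candidate set (`refit_ols`), which guarantees exact nesting and
an exact F null under Gaussian errors — penalised fits are not nested, so
in `lasso` mode a negative numerator is clipped to F = 0, p = 1.
p-values are Benjamini-Hochberg adjusted over the T + M regulators;
regulators with FDR below the threshold (default 0.1) are selected.

**Target evaluation.**  miRNA-gene interactions are ranked most-negative
first (repression semantics); TF-gene interactions by absolute score,
since activation and repression both count.  Ties break lexicographically
by (regulator, gene) so rankings are reproducible.  Validated-overlap
curves count known interactions among the top k = 1000..5000 (step 200 by
default) predictions.  Precision-recall curves enumerate thresholds
between distinct scores (tied scores are never split), anchor the curve at
(recall 0, first precision), and integrate precision over recall by
trapezoid.  Baselines: Pearson correlation of miRNA and gene expression
(most-negative first), a per-gene lasso of expression on seed-matched
miRNA expression, and raw peak scores for TF-gene pairs.

**Phenotype analyses.**  Samples are clustered on selected-regulator
activities by average-linkage agglomeration on `1 - Pearson` distance,
with the dendrogram cut into k = 4 groups; agreement with cytogenetic risk
groups is quantified by the unadjusted Rand index (pair-agreement
fraction), with the adjusted Rand reported alongside.  Constant sample
columns have undefined correlation; their distance is set to the maximum
(2).  Survival is tested per feature by splitting samples at the
arithmetic mean of the feature (the "sample average"), comparing the two
groups by the standard hypergeometric-variance log-rank statistic
(chi-square with 1 df), and BH-adjusting across the feature panel; a split
leaving fewer than two samples on either side is flagged degenerate with
p = 1.  Target-set enrichment uses the upper-tail hypergeometric test over
a stated gene background, dropping sets with fewer than 5 genes after
background intersection.  Regulator network layers are assigned from
regulator-regulator edges: *top* regulates another regulator and is
regulated by none (isolated regulators are top); *middle* both regulates
and is regulated (cycles land here); *bottom* is regulated but regulates
only non-regulator targets.

## The synthetic cohort generator

`racer.synthetic.generate_bundle` draws a complete aligned bundle plus
planted truth from a single seeded generator (per-matrix sub-streams are
spawned deterministically, so identical configs are bitwise-identical).
Defaults: G = 500 genes, M = 15 miRNAs, T = 10 TFs, N = 40 samples,
edge density 0.05 for both binding and seed supports, expression noise sd
0.1, 4 risk groups, unit activity group shift.

* **Binding scores** are nonzero with probability `edge_density` with
  magnitudes `|t(3)|` — heavy-tailed, mimicking ChIP signal skew.
* **Seed counts** are `1 + Poisson(0.25)` on their own support: mostly 1,
  occasionally 2-3, like conserved-site counts.
* **miRNA expression** is lognormal(0, 0.25): nonnegative, right-skewed,
  with modest cross-sample spread.  This encodes the regime the method
  presumes: the sample-specific repression signal is carried by activity
  heterogeneity, not by abundance fluctuations.  When expression CV
  dominates activity CV, plain expression-expression correlation is
  provably the better target statistic and the activity model has nothing
  to add; the generator plants the regime where activity inference is the
  right tool, and the baseline comparisons test exactly that claim.
* **CNV** is standard normal (centred log segment means); **methylation**
  is Beta(2, 2) in [0, 1].
* **Activities**: per regulator, a fixed baseline plus a per-(regulator,
  risk-group) shift scaled by `activity_group_shift` plus within-group
  noise.  TF baselines are N(0, 1); miRNA baselines are strictly negative
  (mean about -1.6), so mean miRNA activity — and with it the sign
  convention of repressive interaction scores — is well defined.
  Regulators outside the active set (default: all are active) have
  identically zero activity and no functional edges; such nulls are
  planted explicitly in the feature-selection calibration configs.
* **Functional edges**: every binding event of an active TF drives
  expression, but only `effect_fraction` (default 0.5) of seed-match
  candidate pairs are functional — most predicted miRNA sites are
  non-functional in vivo, and these non-functional candidates are the
  negatives for edge-recovery evaluation.
* **Expression** is assembled from the additive model plus Gaussian noise
  and left on the model scale.  It is deliberately *not* per-gene
  mean-centred: with each gene's cross-sample mean removed, only activity
  *deviations* remain identifiable — the cross-sample mean activity is
  absorbed into the removed gene means, the mean-activity weighting
  becomes degenerate, and the sign of repressive interaction scores flips.
  Real preprocessing centres log expression to strip baseline abundance;
  in the generator there is no nuisance baseline to strip, so leaving the
  model-scale means in place is what makes the planted activities the
  identifiable quantities.  (The `normalize_expression` preprocessing op
  still centres per gene, and its behaviour is tested independently.)
* **Clinical data**: exponential survival, with the hazard scaled by
  `exp(z)` of the standardised linked-regulator activity when
  `survival_link_feature` is set, under independent exponential censoring
  calibrated to roughly 25%.  Risk labels are a near-balanced random
  assignment into `risk_groups` groups.

What the generator does **not** emulate: read-level count noise,
gene-gene co-expression beyond shared regulators, non-linear or
combinatorial regulation, batch effects, missing data, and realistic
genome geometry (genes sit on one synthetic chromosome at fixed spacing).
Passing tests therefore demonstrate correctness of the machinery and of
the statistical procedures under the model's own assumptions — not
performance on real tumour cohorts.

`write_fixture_dir` inverts the preprocessing: it emits BED annotation,
narrowPeak peaks, segment/probe/site tables and raw expression
(`2^(E + o_g) - 0.05` with per-gene positivity offsets) in exactly the
dialects the readers consume, so the command-line pipeline can run
end-to-end from files alone.

## Numerical and design choices

* Coordinate-descent tolerance is scikit-learn's default with
  `max_iter = 5000`; the solver is validated against the closed-form
  soft-threshold solution on orthonormal designs to 1e-6.
* Sub-seeds passed to per-unit fits are `seed + unit_index` (and
  `seed + 31*unit + fold` inside CV), keeping every fold assignment
  deterministic and distinct.
* Promoters are `[tss - flank, tss + flank + 1)` — an inclusive +/-flank
  window of width `2*flank + 1`; any >= 1 bp overlap counts.
* Genes with no overlapping copy-number segment get 0, i.e. neutral on
  the log segment-mean scale.
* Transcript choice for seed counts: longest 3'UTR, ties to the
  lexicographically smallest transcript id.
* All internal coordinates are 0-based half-open; GTF (1-based inclusive)
  and BED inputs are converted at parse time only.
* Duplicate gene-set names in GMT input are an error, not a merge.
* The narrowPeak binding score is signalValue (column 7) by default;
  column 5 is a capped display score and available as an option.
* Simulation-study sizes (500x40 for recovery, 250x40 for the CV
  comparison, 200-replicate calibration) were chosen as the smallest
  scales at which the statistics of interest are stable across seeds.

## Known limitations

* Stage-2 interaction scores are reported on the original activity scale;
  regulators whose estimated activities are nearly constant yield
  ill-conditioned predictors, which is why evaluation restricts to
  candidate pairs and the generator plants activity for every expressed
  regulator.
* The F-test degrees of freedom follow the pooled-OLS reading above;
  other conventions are possible and both `df_num` and `df_den` are
  exposed as parameters.
* `refit_ols` feature selection requires `G > T + M + 3`; very small
  cohorts must fall back to `lasso` mode, whose F values are heuristic.
* Survival analysis implements only the two-group mean-split log-rank
  design; no proportional-hazards regression.
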