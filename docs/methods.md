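# Methods

`splsero` implements a discovery → replication analysis of targeted serum
proteomics panels (Olink-style NPX data, i.e. relative protein quantities on
a log2 scale) for case/control and subphenotype comparisons in inflammatory
bowel disease: Crohn's disease (CD), ulcerative colitis (UC) and healthy
controls (HC). This note records the statistical model, the choices made
where the design was genuinely open, and what the synthetic benchmark does
and does not establish.

## Preprocessing

**LOD-prevalence exclusion.** A protein is excluded when (a) its signal is
below the limit of detection (LOD) in strictly more than 80% of samples and
(b) the remaining detections are evenly distributed between the groups, so
the sparse signal carries no group information. "Evenly distributed" is
operationalized as a Fisher–Freeman–Halton exact test of the detected /
censored × group contingency table with p ≥ 0.05 (both thresholds
configurable). The exact test enumerates all 2×k tables with the observed
margins; its p-values match R's `fisher.test` to ten digits on reference
tables. Exclusion depends only on the censoring mask and the group labels,
never on the measured values, so it is invariant under monotone transforms
and sample reordering.

**Quantile normalization and reference projection.** The discovery cohort is
quantile-normalized as a whole: every sample's sorted value vector is
replaced by the mean of all samples' sorted vectors (the *reference
distribution*). Ties within a sample receive the mean of the reference
values their sorted positions span. Each replication sample is then
projected *independently* onto the frozen discovery reference — the
projection of a single new sample never sees other replication samples,
mimicking how a diagnostic model would be applied to newly measured
patients. The projection is idempotent and its output's sorted vector equals
the reference exactly.

**Below-LOD reset.** Censored cells keep their instrument values through
normalization (they carry rank information) and are reset to zero
afterwards. The order matters and is guarded by a regression test: resetting
before normalization changes the reference and the downstream results.
Zeros produced by the reset enter the t-tests as values; excluding them
would silently change per-protein group sizes.

## Univariate screening

Per protein and contrast: Welch's unequal-variance t-test on the log2
values; the fold change is the ratio of geometric means, `FC = 2^Δ` with
`Δ = mean(A) − mean(B)`, and its 95% CI is `2^(Δ ± t_{0.975,ν}·SE)` with the
Welch–Satterthwaite degrees of freedom ν — symmetric on the log scale, so
`FC(A,B)·FC(B,A) = 1`. Multiple testing uses Storey q-values computed per
contrast: π0 is estimated on the grid λ = 0.05, …, 0.95 with a cubic
polynomial smoother read off at λ = 0.95 and clipped to (0, 1]; with π0
forced to 1 the q-values equal Benjamini–Hochberg adjusted p-values exactly.
A protein is *significant* when |FC| exceeds 1.2-fold in either direction
**and** q < 0.05.

**Replication validation.** A discovery-significant protein is *validated*
when its replication fold change has the same direction and a magnitude at
least as large as the discovery CI bound nearer to 1 — the weakest fold
change still consistent with the discovery estimate ("similar or larger
fold change of identical direction"). Proteins absent from the replication
panel, or not significant in discovery, are marked not-assessed.

## Sparse PLS-DA

The classifier is a NIPALS-style sparse partial least-squares discriminant
analysis written from scratch:

- Predictors are auto-scaled (column-centered, unit variance, ddof = 1); the
  class response is dummy-coded (one column per class), centered and scaled.
- Per component h: v is initialized as the leading right singular direction
  of `M = Xᵀ_h Y_h`; then iterate `u ← soft_threshold(M v, keepX_h)`,
  `v ← Mᵀu / ‖Mᵀu‖` until the change in u falls below 1e-6 (at most 500
  iterations; non-convergence keeps the last iterate with a warning).
- The soft threshold keeps at most `keepX` nonzero weights: with λ the
  (keep+1)-th largest |w|, each entry becomes `sign(w)·max(|w|−λ, 0)` and
  the vector is renormalized. Ties at λ resolve in stable index order; a
  complete tie keeps the first index so the result is never the zero vector.
- Both blocks are deflated by regression on the score `ξ_h = X_h u_h`
  (regression mode), which makes successive scores exactly orthogonal.
- The sign of each weight vector is fixed by making its largest-magnitude
  entry positive, so fits are deterministic and invariant to sample order.
- Prediction is `Ŷ = X_std W(PᵀW)⁻¹Qᵀ`, rescaled to the dummy coding; the
  predicted class is the argmax column ("max.dist"), ties resolving to the
  first class in level order. In the dense limit (`keepX = p`) the weights
  coincide with SVD-based PLS-DA.

**VIP.** Variable importance in the projection is
`VIP_j = sqrt(p · Σ_h SSY_h u_{hj}² / Σ_h SSY_h)` with `SSY_h` the response
sum of squares explained by component h; mean(VIP²) = 1 by construction and
predictors zeroed in every component score exactly 0.

Open design points resolved here (the source procedure does not pin them
down): auto-scaling of predictors (required for VIP comparability across
proteins of different dynamic range), the max.dist prediction rule (the
simplest), and regression-mode deflation (the standard sPLS formulation).
Either choice can move error rates by a few samples on small cohorts.

## Model selection and significance

**Double (nested) cross-validation.** The outer loop is leave-one-out; for
each outer fold an inner stratified K-fold CV (default 7-fold, capped at the
smallest class size; inner LOO available) grid-searches the number of
components {1, 2, 3} and the VIP cutoff {0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.5}.
Variable selection is *VIP-based*: fit a dense model, keep proteins with
VIP ≥ cutoff (falling back to the single top-VIP protein if none), refit on
the subset. Ties in inner misclassification break toward fewer selected
proteins, then fewer components — a deliberate parsimony bias. The winning
pair is refit on the n−1 training samples and predicts the held-out sample;
the LOO error rate is misclassifications over n. Everything is
deterministic given the data and one integer seed (all internal seeds are
derived via `numpy.random.SeedSequence`).

**Permutation significance.** The class labels are permuted B = 40 times
(matching a p-value resolution of 0.025) and the *entire* double CV is
re-run per permutation; `p = #{err_perm ≤ err_obs}/B`, reported as the bound
`< 1/B` when no permutation matches. Because the error rate is discrete,
this p-value is conservative (slightly super-uniform) under the null —
visible in the null calibration test as a mean somewhat above 0.5.

**Replication transfer.** For the final model the hyperparameters are
re-selected by a single-level stratified CV on the full discovery cohort
(one model, not one per outer fold), the model is fitted on all discovery
samples and applied to the projected replication cohort. Reported: the
misclassification rate, the ROC curve over the positive class's continuous
dummy-response score, and the AUC by the rank (Mann–Whitney) formula with
tie correction — invariant under monotone score transforms.

## Synthetic study conditions

The generator emulates the designed experiment: 54/54/54 (CD/UC/HC)
discovery and 30/30/30 replication samples, 91 panel proteins. Values are
`baseline_j + shift_{g,j} + f_sᵀ λ_j + ε`, with per-protein baselines
uniform on [0, 10] log2 units, two latent "inflammation factors" (scores
N(0,1), loadings N(0, 0.3²)) inducing inter-protein correlation, Gaussian
noise with sd 0.5 log2 units, and additive group shifts whose default
magnitudes span |log2 FC| ≈ 0.26–1.25 (17 CD-vs-HC effects, 12 UC-vs-HC
effects sharing 8 proteins, plus a weak UC shift of FGF-19 placing CD vs UC
at ≈ 0.51). Four designated assays (IL-13, IL-33, IL-1α, TSLP) are censored
at the 0.9 quantile — emulating proteins that fail in serum — and all others
at the 0.02 quantile of their empirical marginal. Clinical strata (Montreal
location 15/13/22/4 for discovery CD, remission fractions ≈ 0.69–0.78,
prior resection enriched in ileal disease) reproduce the default cohort mix
exactly at the default sizes. Structural parameters are shared between
cohorts; sample noise is cohort-specific, so the replication behaves like an
independent re-measurement.

What the emulation does *not* contain: between-plate or between-batch
shifts (the real replication cohort was assayed separately, so transferred
error rates on synthetic data are optimistic), heavy-tailed or skewed
abundance distributions, the empirical correlation structure of real
inflammation markers (two factors is a deliberate simplification — real
panels are more strongly co-regulated, which raises the number of
univariate discoveries at fixed effect sizes via a lower estimated π0), and
effects tied to resection or disease activity. Passing tests therefore
establish the correctness and calibration of the machinery at realistic
signal-to-noise, not the clinical numbers themselves.

## Numerical choices and problem sizes

- NIPALS tolerance 1e-6 on the weight vector, max 500 iterations; for
  two-class problems the centered dummy response has rank 1 and the
  iteration converges in one step.
- Constant predictor columns are dropped with a warning before a public
  fit; inside cross-validation loops they are neutralized (scale set to 1;
  their centered column is zero, so their weight is exactly 0) to keep
  column indexing stable across folds.
- Zero-variance t-tests: equal means give t = 0, p = 1; unequal means give
  p = 0 with a warning.
- The acceptance script and the classification tests use a compact search
  grid (components {1, 2}, VIP cutoffs {0.8, 1.0, 1.2}, inner 5-fold) so
  that a full 40-permutation resampling run per contrast completes quickly
  on one CPU; the selected models on the default synthetic study are
  insensitive to the finer default grid.
- The null calibration of the permutation test uses 20 meta-replicates of a
  15+15-sample, 20-protein pure-noise design with B = 20 — small enough to
  be fast, large enough that the discrete error distribution spreads over
  many levels.

## Known limitations

- π0 estimation via a cubic polynomial is one of several smoothers in use;
  borderline q-values can shift between implementations.
- With ~90 tests per contrast the q < 0.05 + |FC| > 1.2 rule admits rare
  false positives (FDR is an expectation bound, not a guarantee of zero);
  the recovery benchmark shows ≈ 0.4 false positives per 87-protein screen
  on average.
- The CI-based validation rule uses the discovery CI bound nearer to 1;
  other readings of "similar fold change" (e.g. overlap of CIs) would be
  stricter.
- Leave-one-out error on small balanced cohorts is slightly pessimistic
  under the null (the held-out sample's class is always the training
  minority), which the permutation test absorbs by construction.
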