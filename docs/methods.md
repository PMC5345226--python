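# Methods

`mesnet` implements a pipeline for asking how the regulatory machinery of a
tumor cohort with high expression of a mesenchymal signature (MS) differs
from that of a low-MS cohort, and which of the rewired genes carry
prognostic information. This note documents the models, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer should know about.

## Pipeline model

1. **Cohort stratification.** Each sample's *metagene score* is the
   unweighted mean of its normalized log-scale expression over a fixed
   signature gene list. With tail fraction `f` (default 0.25), the
   `k = ceil(f·N)` lowest-scoring samples form the low-MS cohort and the
   `k` highest the high-MS cohort; the rest are excluded. Ties at a
   boundary are broken by sample id, so membership is invariant to input
   order and cohort sizes are fixed (275 samples at `f = 0.25` gives 69
   per cohort).

2. **Differential expression.** Genes are ranked by a per-gene Welch
   (unequal-variance) t-test between cohorts on the normalized values; the
   effect size is the difference of cohort means, which is a log2 fold
   change on log2-scale data. Benjamini–Hochberg adjustment runs over all
   genes, and the selection rule is `|log2FC| >= 1` (inclusive) with
   `q <= 0.05`. This is a rank-and-threshold stage: downstream consumers
   need a gene list, not a count model, so a negative-binomial Wald test
   is deliberately out of scope and the package operates on normalized
   matrices throughout. When raw counts are supplied, `normalize_counts`
   applies median-of-ratios size factors followed by `log2(x/s + 1)` — a
   deterministic variance-flattening transform that preserves the rank
   structure the later stages consume (it is not a full variance-stabilizing
   transform; no dispersion estimation is performed).

3. **Network inference by message passing.** For each cohort a TF→gene
   network `W` is seeded from a sequence-motif prior and refined by
   passing messages between three evidence layers: TF–TF cooperativity
   `P` (PPI), the network itself, and gene–gene co-expression `C`
   (Pearson, computed over the motif prior's gene axis). Each round
   computes a *responsibility* `R = T(P, W)` and an *availability*
   `A = T(W, C)`, where

       T(x, y) = x·y / sqrt(‖x‖² + ‖y‖² − |x·y|)

   is a continuous Tanimoto similarity applied row-against-column, and
   updates `W ← (1−α)W + α(R+A)/2` with learning rate `α = 0.1`. `P` and
   `C` are in turn pulled toward the self-similarity of `W`'s rows and
   columns, with the diagonal of each self-similarity matrix replaced by
   `sd(off-diagonal of the row) × dim × exp(2αt)` at step `t` — a
   stabilization that keeps self-edges from dominating; it is the least
   certain detail of the update and is isolated in one function
   (`panda._stabilized`) so alternatives can be swapped in. All three
   input layers are first z-scored jointly by rows and columns
   (`out_ij = (rowz_ij + colz_ij)/2`, with a whole-matrix fallback for
   zero-sd rows/columns). Iteration stops when `mean|W_t − W_{t−1}| <
   tol` (default `1e-3`; typically 25–40 rounds on desk-scale inputs) and
   non-convergence is flagged, never silent. Edge weights are z-score-like
   confidences: positive for evidence an edge exists, negative for
   evidence it does not. The PPI is optional (identity when absent).

4. **Differential network.** Each cohort gets a leave-one-out jackknife
   ensemble (one network per left-out sample, so 69 replicates per cohort
   at the default study size). Ensembles are aggregated by the
   element-wise mean, and each edge is compared between conditions with a
   Welch t-test across replicate weights, BH-adjusted over all TF×gene
   edges. Edges pass the filter when `|Δweight| >= min_delta_w` and
   `−log10(FDR) > min_neglog10_fdr` (strictly), and are then partitioned
   by *existence* (aggregated weight above `existence_tau = 0`): unique to
   low, unique to high, or shared; a filtered edge below the existence
   threshold in both conditions is set aside in an `absent` frame rather
   than attributed to either phenotype. Gene-level rewiring is scored by
   *differential indegree*: per replicate, a gene's indegree is the sum of
   positive weights of its retained incoming edges; a Welch test across
   replicates flags genes at raw `p <= 0.05`. A weighted indegree is used
   rather than a binary edge count because it is stable at desk scale; the
   unfiltered variant is available via `filtered=None`.

   **Caveat, by construction:** jackknife replicates are treated as
   independent observations in these t-tests, as in the source procedure.
   Replicates are strongly dependent, so the p-values are not calibrated
   error rates; they are a ranking device, and the magnitude filter on
   `Δweight` is what carries the discrimination.

5. **Threshold calibration.** The weight-difference scale of a
   message-passing network depends on the problem size, so fixed edge
   cutoffs do not transfer across scales; the filter thresholds are
   data-dependent choices made from the observed weight and FDR
   distributions. `calibrate_min_delta_w` makes that choice reproducible:
   it permutes the gene labels of both expression matrices (several
   times; default 3), reruns the full jackknife comparison on each, and
   sets the cutoff at the 0.99 quantile of `|Δweight|` over permuted
   edges that exist in at least one condition. This sits the cutoff at
   the top of what label-scrambled data can produce, so a permuted-both
   rerun retains essentially nothing — the behavior the filter is
   designed to have. `RunConfig` defaults (`min_delta_w = 1`,
   `min_neglog10_fdr = 25`) are the operating point published for the
   full-size study; `calibrate=True` in `run_differential_network`
   replaces the delta cutoff with the calibrated one. The FDR cutoff is
   left as configured: genuinely rewired edges clear it by two orders of
   magnitude at desk scale.

6. **Enrichment and candidate assembly.** Differentially regulated genes
   are tested for over-representation in user-supplied gene sets (GMT)
   with the hypergeometric upper tail `P[X >= k]`; the universe is the
   set of genes that entered the network stage, not the whole genome,
   conditioning on what was testable. "Top" pathways use raw
   `p <= 0.005` as printed for the full-size analysis, with BH q reported
   alongside. The prognostic candidate set is a pathway's genes plus
   every TF with at least one retained edge into them in either
   phenotype, deduplicated (pathway genes first, then TFs, each block
   alphabetical).

7. **Prognostic signature and risk stratification.** An L1-penalized Cox
   proportional-hazards model is fit on the candidate genes with age and
   tumor type as unpenalized covariates (penalty factor 0, so the penalty
   can never exclude them). Gene covariates are standardized before
   penalization and coefficients reported on the original scale. The
   penalty weight λ is chosen by 5-fold cross-validated held-out partial
   likelihood with seeded folds, then the model is refit on all samples;
   the nonzero penalized covariates are the signature. The *prognostic
   index* of a sample is the Cox linear predictor `PI = Σᵢ β̂ᵢ xᵢ`;
   samples are split at the median PI (ties to low risk) and the groups
   compared with a two-sample log-rank test plus a one-covariate Cox fit
   for the group hazard ratio. Per-gene Cox models (gene + age + type)
   flag individually prognostic genes at `p <= 0.05`. Validation-style
   views (average-linkage correlation-distance clustering, PCA scores)
   are provided for signature expression.

## The unpenalized Cox fitter

`fit_cox` maximizes the Cox partial likelihood with **Breslow** tie
handling by Newton iteration with step halving, stopping at gradient
max-norm `< 1e-8`; standard errors come from the inverse observed
information. Breslow is the default because it has a simple, exactly
testable closed form; Efron tie handling is available behind
`ties="efron"` (delegated to lifelines, and equal to Breslow on tie-free
data, which is how the two implementations cross-check each other in the
tests). Monotone likelihood (perfect separation) is detected when a
coefficient exceeds 10 in absolute value with a flat likelihood (SE > 5
or singular information) and reported via `flags["separation"]` instead
of raising.

## The synthetic-data generator

The generator plants known structure so every stage has a recovery
target; it emulates the *statistical skeleton* of a two-cohort tumor
study, not its biology:

- **Expression** is linear-Gaussian: per sample each TF has a standard
  normal activity; a target gene is the effect-weighted sum (effects
  default to 1) of its condition's regulating activities plus
  `N(0, noise_sd²)` noise (default 0.5); a TF's own expression row is its
  activity plus noise. Pearson co-expression therefore provably carries
  the planted edge signal.
- **Condition-specific regulation** is organized as regulator programs:
  each condition owns a dedicated program TF (configurable) whose target
  module is regulated only in that condition, the way a master regulator
  switches a mesenchymal program on. This is both the realistic shape of
  phenotype-specific rewiring and the detectable one — an isolated
  rewired edge on a TF whose other targets are unchanged leaves too
  little target-set coherence for message passing to register at any
  sample size.
- **The signature metagene** is a random gene subset shifted by +2 log2
  units in the high condition (default), giving the cohorting and DEG
  stages real signal.
- **The motif prior** contains every true edge (union over conditions)
  plus 20% false-positive motif hits; the PPI connects TFs sharing at
  least one target (weight 0.5, unit diagonal).
- **Survival** is exponential with rate `h₀·exp(βᵀx)` on signature-gene
  expression, age (β = 0.04/year, hazard ratio ≈ 1.04) and a high-grade
  indicator (β = 1.5), matching the magnitudes a glioma cohort shows.
  Censoring is uniform on `[0, Q]` with `Q` solved by bisection against
  the target censoring fraction (default 0.3) — one knob, calibrated to
  ±0.1.
- Ages are drawn at `N(41, 8)` for low-grade and `N(60, 8)` for
  high-grade samples; identical seeds give identical outputs everywhere.

What it does **not** emulate: count noise (no negative-binomial layer —
the pipeline consumes normalized values), batch effects, correlated TF
activities, indirect regulation, non-proportional hazards, or informative
censoring. Tests passing on this generator show the pipeline recovers the
structure it is designed to detect under its own model assumptions; they
do not certify performance on RNA-seq data with those artifacts.

## Study sizes used by the test and acceptance suites

Chosen once as the desk-scale analog of the study design: 10 TFs × 50
genes; 30 shared edges; 10 condition-specific edges per condition on one
program TF each; 50 samples per condition for single-network recovery;
69 per condition (the published quartile cohort size) for jackknife
differential-network studies over 5 replicate seeds; n = 300 with 5
signal genes (|β| = 1) among 50 for signature recovery over 10 seeds;
n = 200 with a planted group hazard ratio of 3 over 50 replicates for
prognostic-index power; 400 samples × 200 noise genes for the per-gene
null calibration.

## Numerical choices and degenerate inputs

- BH adjustment is the standard step-up with monotonicity enforcement
  (statsmodels); p-values outside [0,1] are rejected.
- Welch tests with zero variance in both groups: p = 1 when the means are
  equal (t = 0), p = 0 when they differ — defined, never NaN.
- `tanimoto` returns 0 for a zero-norm pair; `normalize_network` of a
  constant matrix returns zeros with a warning; constant gene rows get
  co-expression 0 against everything.
- FDRs are floored at 1e-300 before `−log10`.
- Median-split ties go to the low-risk group (deterministic and
  conservative). Note that a two-valued PI (e.g. from a single binary
  covariate) can place everything at or below the median; risk
  stratification presumes an effectively continuous PI.
- Cross-validation folds, permutations, and all generator draws are
  seeded from the caller; there is no hidden global random state.

## Known limitations

- Jackknife-based p-values are anti-conservative by construction (see the
  caveat above); interpret flags as rankings, not error rates.
- The existence threshold (`existence_tau = 0`) presumes the z-score-like
  weight convention where motif-supported edges sit well above zero;
  tune it if a different prior scale is used.
- `lasso_cox` reports no standard errors for penalized covariates
  (post-selection inference is out of scope); refit the support with
  `fit_cox` when CIs are needed, with the usual selection caveats.
- The per-gene Cox sweep refits from scratch per gene; at genome scale it
  is O(genes × Newton steps) and would want batching.
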