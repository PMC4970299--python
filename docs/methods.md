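# Methods

## Model and reduction to correlations

Every hypothesis tested by the suite is a slope test in an ordinary
linear model with Gaussian errors:

* Emodel: `M_i = α + β E_k + γ·cvrt + ε` — one test per (CpG i,
  environment k).
* Gmodel: `M_i = α + β G_j + γ·cvrt + ε` — one test per (CpG i, SNP j),
  with genotype coded as additive dosage 0/1/2 (the AA/AB/BB group
  labels used in the segregation plot are display-only).
* GxEmodel: `M_i = α + γ·cvrt + δ E_k + φ G_j + β (G_j ∘ E_k) + ε` —
  the product coefficient β is tested; genotype and environment main
  effects are always included, because a product-only model confounds
  the interaction with the mains.

Let Q be an orthonormal basis of span{1, cvrt} (an intercept is always
implicit; a user-supplied constant covariate row is rejected rather
than silently duplicating it). Writing x̃ for `(I − QQᵀ)x` scaled to
unit norm, the slope test for the simple models is carried entirely by
r = ⟨x̃, ỹ⟩:

    t = r √(df / (1 − r²)),  p = 2·P(T_df ≥ |t|),  β = r‖ỹ_res‖/‖x̃_res‖

with df = n − n_cvrt − 2 (intercept + covariates projected out, one
residual degree of freedom consumed by the slope). This is
algebraically identical to the t statistic of β in the explicit fit;
the `oracle` module verifies it numerically rather than by assumption.

For the interaction, all of y, g and h = g∘e are residualized against
{1, cvrt, e}; the test of the product coefficient is the partial
correlation of ỹ and h̃ given g̃:

    r_p = (r_yh − r_yg r_gh) / √((1 − r_yg²)(1 − r_gh²)),
    df  = n − n_cvrt − 4.

The df conventions are pinned down operationally: the suite's defining
equivalence is agreement with the explicit full-model least-squares fit,
and these are the values under which the t statistics coincide.

## Blocking, determinism and numerical policy

Scans stream over predictor rows in blocks of `block_size` (default
1,000), bounding the live correlation block at `block_size ×
n_outcomes` entries; results are required to be *bytewise* independent
of `block_size`. Because large matrix-matrix kernels may reorder the
inner summation depending on the operand shape, each output row of the
correlation block is computed as an independent vector-matrix product
(`engine.rowwise_gemm`); rows are then grouped into blocks freely
without changing a single bit.

Other numerical choices:

* Correlations are clipped to [−1, 1]. |r| within 1e-12 of 1 sets a
  saturation flag and reports p at the smallest positive double rather
  than an exact zero or an infinite t.
* A row whose residual norm falls below `1e-12·max(1, ‖row‖)` after
  projection has no residual variance (e.g. it lies in the covariate
  span) and is excluded as degenerate; exclusions are itemized in the
  scan summary, never silent.
* Rank-deficient covariate sets are rejected with the name of the first
  dependent covariate (QR diagonal test at 1e-10 relative).
* In the interaction scan, SNPs whose product term is collinear with
  the genotype after projection (|r_gh| → 1, e.g. nearly constant
  environments) are excluded per environment; entirely constant
  environments are skipped with a warning, not an error.

## Missing data

Missing cells ("NA"/"NaN"/empty in the input dialect) are imputed with
the feature's mean over observed samples, row-wise, before projection —
genotype rows on the dosage scale, without rounding. Features with no
observed values are dropped and reported. Imputation keeps the matrix
algebra dense and the sample count fixed, at a cost: the oracle fits
complete cases only (as a naive per-pair `lm` loop would), so p-values
for features **without** missing values match the oracle exactly, while
features **with** missing values legitimately diverge (imputed n vs
complete-case n). This divergence is a property of mean imputation, not
a defect, and is surfaced as its own check; `--no-impute` turns the
policy into a hard failure for users who prefer explicit handling.

## Multiple testing and output thresholding

Genotype-scale scans cannot keep billions of rows, so records are
emitted only below a p-value output threshold (defaults: 1.0 for the
environment scan, 1e-5 for the genotype and interaction scans). The BH
step-up family size m is the number of tests *computed* (the full
product of kept dimensions), never the emitted count, so thresholding
cannot inflate significance. Because the emitted records are exactly
the smallest p-values, their global BH ranks are known; q-values whose
step-up minimum would fall beyond the emitted tail are (slightly)
conservative upper bounds — the standard behavior of thresholded
streaming scans. The environment scan keeps everything by default, and
its FDR is computed within each environment independently (each
environment is its own scan family); the genotype and interaction scans
correct across the full cross.

λ (genomic control) is the median observed 1-df χ² over its null
median, computed from a streaming 1e5-bin histogram of r² (bin-width
error ≤ 1e-5 in r², negligible for a diagnostic).

## Pair classification

SNP–CpG pairs on different chromosomes are `trans`; same chromosome is
`cis`; a same-chromosome pair whose interval gap (half-open BED
intervals) is ≤ `disrupting_window_bp` is upgraded to `disrupting`. The
default window of 0 means overlapping or abutting intervals — a variant
inside the CpG dinucleotide destroys the site. The window is
configurable because no canonical distance exists for this class; at
window 0, abutting (gap exactly 0) intervals are included, which is the
natural closed boundary of the gap metric. The methQTL scan tests the
full CpG × SNP cross by default; an optional `cis_window_bp` restricts
it for users replicating cis-only designs.

## Synthetic studies

The generator emulates the structure of a neonatal array-EWAS cohort:
237 samples, 1,423 variably methylated CpGs, 19 continuous exposures
and a binary sex covariate by default, with the SNP panel scaled down
to 5,000 (the full ~708k panel is enumerated, never fit, at desk
scale). Genotypes are Hardy–Weinberg draws at per-SNP MAFs uniform in
[0.05, 0.5]; environments are independent standard normals; effects are
planted on the latent logit-methylation scale and squashed through the
logistic map around per-CpG baselines uniform in [0.2, 0.8], keeping
values strictly inside (0, 1) without boundary atoms (truncation would
create atoms that break uniformity checks). Default latent noise SD is
0.3, a mid-range choice giving realistic per-CpG variability; planted
effects in tests use |β|·SD(predictor)/noise ≥ 5 so recovery is a
property of the method, not luck. Missingness is masked i.i.d. per
cell, optionally concentrated in a fraction of rows (`row_fraction`) to
mimic array data where only a subset of probes carries missing values —
necessary for any check that contrasts complete and incomplete rows,
since i.i.d. masking at 10% leaves no complete 200-sample row. Features
are placed on two synthetic chromosomes so all pair classes occur, and
CpGs carrying a planted genotype effect are positioned within 50 kb of
their SNP so those pairs are cis by construction.

What the generator does **not** model: linkage disequilibrium between
SNPs, spatial correlation between neighboring CpGs, cell-type mixture,
batch structure, or array-specific (beta-mixture) noise. Passing tests
on these fixtures demonstrate the statistical machinery — equivalence
with explicit fits, calibration, recovery, bookkeeping — not robustness
to those real-data features.

## Problem sizes used in the checks

The equivalence/invariance checks run on 200 samples × 500 CpGs ×
2,000 SNPs × 2 environments with one covariate; null calibration uses
10,000 tests (5,000 CpGs × 2 environments at n = 200); recovery uses
n = 300 with 100 CpGs × 500 SNPs. These sizes exercise every code path
(blocking, thresholding, FDR, classification) while keeping the whole
suite fast; the engine itself is dimension-agnostic and the exact
model-count bookkeeping is additionally checked at the full
1,423 × 708,365 scale by enumeration.

## Known limitations

* Outcomes are modeled as Gaussian after covariate projection;
  logistic/beta regression for bounded methylation is out of scope.
* No permutation p-values, kinship/mixed-model correction, or
  conditional (stepwise) methQTL analysis.
* The thresholded-stream q-values are conservative near the output
  threshold (see above).
* Mean imputation biases toward the null for features with many
  missing values; users with heavy missingness should compare against
  complete-case fits (the oracle module makes this a one-liner).
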