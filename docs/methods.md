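# Methods

## Problem

A gene-level hypothesis in a multi-compound screen is *complex*: the gene is
declared differentially expressed if it responds to the treatment condition,
where the condition comprises several compounds each compared against one
shared control arm.  The per-compound comparisons ("partial tests") are
dependent — they reuse the same control replicates — so the classical null
distributions of the usual p-value combiners (Tippett's minimum p, Fisher's
omnibus) do not apply and are typically replaced by permutation calibration,
which is expensive at genome scale and resolution-limited for small p-values.

The package's core method avoids resampling altogether by combining signed
z-scores.  Dependence then enters the null distribution only through a
covariance matrix, and that matrix can be estimated from the thousands of
genes measured in the same experiment.

## Model and procedure

For gene *g* and compound *i* the partial statistic is the pooled-variance
two-sample t of compound versus control, `T_gi`, with
`dof = k_control + k_i − 2`.  The pooled t (not Welch) is required because
the z transform needs an exact null CDF: under normal errors the pooled t is
exactly t-distributed.  The signed z-score is the probability integral
transform `z_gi = Φ⁻¹(F_dof(T_gi))`, computed tail-wise for numerical
precision and clipped at |z| = 8.2 (the largest quantile distinguishable in
double precision); under the null each `z_gi` is exactly standard normal.

The combined statistic is Stouffer's

    T^S_g = (z_g1 + … + z_gn) / √n ,

normal with mean 0 under the null, with variance

    σ² = (1/n) Σ_ij Cov(z_i, z_j) = 1 + (2/n) Σ_{i<j} ρ_ij .

The covariance is assumed common across equally expressed genes and is
estimated by the sample covariance of the z-score columns over a null gene
set (denominator count − 1, means taken over the selected genes).  The final
two-sided p-value is `2(1 − Φ(|T^S_g|/σ̂))`, and FDR is controlled with
Storey q-values.

For equal-sized arms sharing one control, the induced correlation between
partial statistics is `Var(X̄_ctrl) / (Var(X̄_ctrl)+Var(X̄_i)) = 1/2`, so the
shared-control design has σ² ≈ 2 for n = 3 — the value the estimator
recovers on simulated null data.

## Null-gene selection and the default x0 = ∞

The textbook version of the procedure selects "surely null" genes by
`|T^S_g| ≤ x0` (the zero assumption) before estimating the covariance.  Both
a fixed threshold (`x0`) and a quantile rule (`x0_quantile`, threshold at a
quantile of |T^S|) are implemented.  However, the plain sample covariance
over a hard-thresholded set conditions on the *sum* of the z-scores and is
therefore truncation-biased: `Var(T^S | |T^S| ≤ x0)` can be far below σ²
(about 0.16 σ² at x0 = σ), which would make the final test strongly
anti-conservative.  The pipeline therefore warns whenever selection is
requested, and by default applies **no selection** (x0 = ∞): with a null
proportion near one the selection step is unnecessary, and when true
effects are present they inflate σ̂² and push the test toward conservatism
— the behaviour this class of estimator is known for in practice, and the
price of never resampling.  Users who want a sharper σ̂² on data with many
large effects should prefer the quantile rule with a high quantile and
interpret σ̂² with the truncation caveat in mind.

## Comparators

* **Permutation Tippett / Fisher.**  Whole-column permutation: one random
  permutation of the sample-to-arm assignment is applied to every gene and
  the full pooled-t / t-CDF machinery is recomputed, preserving both the
  shared-control dependence and any gene–gene structure.  P-values use the
  add-one estimator `(1 + #extreme)/(B + 1)` per gene.  Two refinements are
  available: exhaustive enumeration of all distinct labelings (small designs,
  ≤ 9 samples; used as an exact oracle in the tests) and a gene-pooled null
  (`pool_genes`) that merges the permutation statistics of all genes into a
  single reference distribution.  Pooling trades exactness of the per-gene
  null for resolution: with B = 1,000 the per-gene p-value floor of ~10⁻³ is
  too coarse for q-value thresholding at m = 4,000 (a rejection at q ≤ 0.1
  would need ~40 genes exactly at the floor), so the benchmark runs at
  reduced B use the pooled null.
* **Dunnett's test.**  Per gene, `max_i |t_i|` with the error variance
  pooled over all arms (`dof = n_arms (k − 1)`); its two-sided p-value is
  evaluated under the equicorrelated (ρ = 1/2) multivariate t via one seeded
  Monte Carlo sample (default 10⁵ draws) of the common-denominator
  representation `T_i = (Z_i − Z_0)/√2 / √(χ²_dof/dof)`, shared across all
  genes.  Monte Carlo standard error at p ≈ 0.05 is about 7·10⁻⁴.

## Synthetic data

The generator draws a genes × samples matrix with one control and `n`
compound arms, `k` replicates each, IID errors (standard normal, t₅, or
uncentered Gamma(3, 1) — a common location offset cancels in every
two-sample comparison), and adds `δ` to all compound-arm entries of the DEG
genes.  Defaults are the benchmark design: 4,000 genes, 200 DEGs, 3
compounds, δ = 1.5; dataset *i* of a replicate study uses `seed + i`.
Deliberately **not** emulated: probe-level structure and normalization
artifacts, gene–gene correlation, mixed-sign or compound-specific effects,
and unequal arm sizes.  Passing tests therefore demonstrate correctness of
the statistical machinery under an idealized IID model, not robustness to
correlated real microarray noise (where the theoretical-vs-empirical null
deviation that motivates empirical-Bayes nulls would matter).

## Numerical and design choices

* z-scores clipped at |z| = 8.2; infinite t statistics (zero pooled variance
  with nonzero mean difference) map to the clip value and are flagged; zero
  variance with zero difference gives t = 0 with a logged warning.
* σ̂² < 1 is kept, with a warning — negative correlations are legitimate; a
  non-positive σ̂² raises.
* Storey q-values use a single fixed λ = 0.5, π̂₀ capped at 1, and the
  step-up envelope on sorted p-values; ties in ranks are resolved by average
  rank.
* ROC curves are computed per dataset on the full set of observed p-value
  thresholds, interpolated to a common 512-point FPR grid, and averaged
  pointwise over datasets.
* Realized ("true") FDR at a target is the false discovery proportion among
  genes with q ≤ target, defined as 0 when nothing is rejected.
* The benchmark runs 20 datasets per condition and 1,000 permutations
  (gene-pooled null), sizes chosen to keep a full run in minutes on one
  core while leaving the Monte Carlo error of the summary quantities well
  below the differences of interest.

## Known limitations

* The variance estimator is exact only under the IID-error, common-covariance
  model; heavy contamination by true effects makes the test conservative
  rather than invalid, but a formal empirical-null fit is not implemented.
* The permutation null assumes exchangeability of whole sample columns under
  the complex null; it is not a per-gene residual bootstrap.
* Dunnett p-values require equal replicate counts per arm; unbalanced
  designs raise.
* With the t₅ and gamma error families the pooled t is only approximately
  t-distributed, so the z-scores are only approximately normal; the data-
  driven σ̂² absorbs part, not all, of that misspecification.
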