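# Methods

## Problem and model

`structcov` studies how regional gray-matter (GM) morphometry and
voxelwise white-matter (WM) microstructure co-vary across the adult
lifespan.  Two participants-by-features blocks are analyzed jointly:

* **X** — WM diffusion metrics (FA, unitless in [0, 1], or MD, mm²/s),
  one column per template voxel;
* **Y** — GM morphometry (cortical thickness mm, surface area mm², or
  volume mm³), one column per Desikan region (34 hemisphere-averaged
  regions by default).

After sex is residualized from every column and each column is
centered and scaled to unit sum of squares, the cross-product
`R = XᵀY` holds the Pearson correlations between all WM/GM feature
pairs.  Partial least squares correlation (PLSC) decomposes it:

```
R = U diag(δ) Vᵀ
```

The columns of `U` and `V` are *saliences* — paired loading patterns
that maximize cross-block covariance — and each singular value `δ_k`
is the covariance captured by component k, with
`δ_k² / Σ_j δ_j²` the fraction of cross-block covariance explained.
Participants' projections `L_X = XU`, `L_Y = YV` are their latent
*brain scores*; on the fitting data `L_X[:,k]ᵀ L_Y[:,k] = δ_k`.

For a voxelwise X the matrix `R` (voxels × regions) is never required
explicitly: the decomposition runs through the smaller block's Gram
matrix, `M = Yᵀ(XXᵀ)Y = VΛVᵀ`, with `δ = √λ` and
`U = Xᵀ(YV)/δ`.  This dual route is algebraically identical to the
direct SVD and is equality-tested against it on small instances
(1e-8).  Components with `δ ≤ 1e-10·δ_max` are treated as numerical
rank deficiency and dropped; the retained count never exceeds
`min(p, q, n−1)`.

**Sign convention.** SVD signs are arbitrary; each component is
flipped so the GM salience has positive sum (largest-magnitude entry
decides ties).  This makes refits, row-permutation invariance checks
and serialized artifacts deterministic.

## Inference

**Permutation test of the singular values.**  Rows of the GM block are
shuffled (n_perm iterations), breaking the cross-block pairing while
preserving each block's internal covariance; the block is
re-normalized (a no-op for a row shuffle, executed for safety) and the
singular values recorded.  Permuted values are compared to observed
ones positionally (k-th to k-th), the convention of the PLSC
literature, and `p_k = (#{δ_k^perm ≥ δ_k} + 1)/(n_perm + 1)`.  The
add-one correction is the default; a raw-proportion mode
(`paper_literal`) is available.  Under positional matching the
component-1 p-value is exact and calibrated (uniformity is verified
over 200 replicate null datasets).

**Bootstrap ratios (BSR).**  Participants are resampled with
replacement, the same resample applied to both blocks; blocks are
re-centered/normalized within each resample (a fixed-scaling mode
exists for comparison), the model refitted, and each bootstrap
component sign-aligned to the original by maximizing the combined
salience dot product (`align="procrustes"` applies a full rotation,
for near-degenerate singular values).  Per-element first and second
moments are accumulated by the Welford/Knuth single-pass recurrence —
no iterate is stored, so memory is independent of n_boot.  `BSR =
bootstrap mean / bootstrap SD`; the bootstrap SD of a statistic
estimates its standard error, so the BSR behaves like a z-score:
1.96 ↔ p ≈ .05, 3 ↔ p ≈ .0027 (two-tailed normal).  Elements with
zero bootstrap SD are flagged, not divided.  Resamples producing a
constant column (or losing a component) are redrawn and counted.
Per-iteration RNG substreams are spawned from the master seed, so
changing n_boot never reshuffles earlier iterations.

**Score–age regressions.**  Latent scores are regressed on age
(centered before squaring) as `score ~ age` and `score ~ age + age²`,
reporting F(1, n−2) and F(2, n−3); the quadratic form is preferred iff
its age² term is significant at α.  When the linear fit is exact to
machine precision the quadratic t-statistic is undefined and the
linear form is kept.

## Univariate battery

Each ROI is fitted as `y ~ 1 + age_c + age_c² + sex`; the quadratic
term's significance is assessed by Freedman–Lane residual permutation
(the reduced model's residuals are permuted, so sex is respected under
the null) and dropped when p ≥ α, after which the linear age term gets
its own permutation p-value.  Standardized betas are computed on the
z-scored response and predictors of the selected model.  The default
permutation p-value is two-sided with the add-one correction; the
one-sided lower-tail raw proportion (`#{t_perm < t_obs}/B`) is
available as `paper_literal`.

The voxelwise GLM runs the same model batched over all template
voxels.  Family-wise error is controlled by the max-statistic
procedure: each Freedman–Lane permutation yields a statistic map, and
every voxel's corrected p compares it to the null distribution of the
image-wide maximum.  Threshold-free cluster enhancement (TFCE) with
`E = 0.5`, `H = 2`, 6-neighbour connectivity and `dh = max|t|/100`
(frozen at the observed scale across permutations) is applied by
default; the negative tail is enhanced on the negated map, keeping the
statistic signed.

**Gradient profiles.**  The per-voxel age correlation is summarized
slice by slice along the anatomical axes (x = left→right,
y = posterior→anterior, z = inferior→superior; fixed RAS-like
convention).  The default statistic is the mean |r| over masked voxels
per slice (a signed-mean mode exists; neither is asserted to be the
only reasonable choice).  The medial-lateral axis is folded about the
mid-sagittal plane and reported outward; slices with no masked voxels
carry NaN, never 0.

## Synthetic data generator

The generator emulates the statistical structure of a lifespan cohort
study, not its anatomy:

* **Cohort** — 186 participants by default, four age strata
  (43/46/48/49 participants with mean ± SD ages 27.58 ± 4.37,
  45.72 ± 5.36, 61.23 ± 3.66, 76.75 ± 5.87), truncated-normal within
  20–94 years; sex by fair coin.  Truncation lifts the youngest
  stratum's mean slightly, so the expected grand mean is ≈ 53.8 rather
  than the strata-weighted 53.70 of the stated centers; the cohort
  test uses the closed-form truncated-normal mean as its oracle.
* **Latent aging factor** — `ℓ = c · std(z_age + 0.3 ε)` with
  `c = coupling_strength ∈ [0, 1]`.  Scaling by `c` (rather than
  mixing) makes `c = 0` remove the cross-block channel entirely, which
  is what null-calibration requires.
* **GM** — thickness(i, j) = 2.5 + 0.15 · (−A·u*_j·ℓ_i + b_j·z_i +
  q_j·(z_i²−1) + sex_effect·sex_i + noise_sd·ε), with `u*` the planted
  unit-norm salience (|N(1, 0.3)| weights, ~10% null regions zeroed),
  `b` the per-ROI standardized age slope (default −0.35 at the
  strongest ROI, proportional to `u*` so the univariate and
  multivariate patterns agree), and `A = 3` the latent loading
  amplitude (a moderate effect comparable to the planted slopes).
  Surface area is generated independently with half the age slope;
  volume is the exact elementwise product.  Quadratic terms use
  centered age squared to decorrelate the regressors;
  `quad_fraction = 0.25` of non-null features receive one.
* **WM** — the planted voxel salience follows a posterior→anterior
  plus inferior→superior gradient field (10% null voxels zeroed); the
  latent factor loads negatively on FA and positively on MD with
  amplitude spread over the voxel pattern.  The FA baseline is high
  centrally and ≈ 0.18 at the grid boundary, so the all-participants
  FA > 0.15 template rule excludes a realistic rim (typically ~40% of
  a 10×12×10 grid); per-ROI/voxel effect magnitudes are free
  parameters of the generator, not calibrated to any real dataset.
* **WMH** — per-participant Poisson(rate) lesioned-voxel counts placed
  uniformly over the template; the default rate of 2 voxels
  reproduces a ≈ 0.4% median burden at the default template size.

What passing tests show: the pipeline recovers planted saliences
(|r| > 0.9), brain-score–age alignment (|r| > 0.8), null features
(|BSR| < 3) and planted gradients under i.i.d. Gaussian noise.  What
they do not show: behavior under spatial noise correlation, anatomical
boundary effects, registration error, or non-Gaussian artifacts —
none of which the generator emulates.

## Numerical and design choices

* Preprocessing order is enforced and logged: WMH exclusion →
  residualization → center/normalize.  Residualization precedes
  normalization because covariate removal is a data-cleaning step and
  unit-sum-of-squares scaling is part of the PLSC recipe itself.
  Constant columns are an error (silently dropping them would
  desynchronize feature registries).
* Sex is coded {0, 1} with an intercept; residuals are invariant to
  the coding.
* WMH exclusion uses the union rule (a voxel flagged in any
  participant is removed for all).  On a desk-scale template the union
  of many participants' lesions removes a large voxel fraction — a
  genuine scale effect of the rule; the sensitivity driver shows the
  component structure is nonetheless unchanged (salience agreement
  r > 0.99).
* Hemisphere averaging happens before decomposition by default (the
  per-region tables are 34-column); a 68-column lh_/rh_ path with
  averaging afterwards is supported by `average_hemispheres`.
* Cohort summaries use display-only age groups (20–34, 35–54, 55–69,
  70–94); all models treat age as continuous.  The pooled mean is the
  size-weighted mean of group means.
* Default problem sizes in the analysis drivers and tests — grid
  10×12×10, n_perm 200–1,000, n_boot 300–1,000 — are chosen so every
  planted effect is comfortably detectable at n = 186 while the whole
  suite runs in minutes; all counts are configuration parameters and
  scale up unchanged (the streaming bootstrap is O(1) in memory).
* With quadratic age terms planted, a genuine second cross-block
  channel (the age² pattern) exists, so the permutation test may
  legitimately flag a second component; "exactly one significant
  component" holds when `quad_fraction = 0`.

## Known limitations

* The generator's voxel grid is abstract: no tract geometry, partial
  volumes, or scanner noise; gradients are globally linear.
* TFCE parameters are the field-standard defaults; no attempt is made
  to reproduce any specific external permutation tool numerically.
* Only one covariate (sex) is supported in residualization, matching
  the analysis design; arbitrary covariates would need a design-matrix
  generalization.
* Confidence intervals on variance explained, split-half reliability
  and cross-validated component selection are out of scope.
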