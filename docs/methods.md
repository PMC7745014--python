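# Methods

This note documents the models, conventions and defaults behind
`sbm-gm`, the design choices that were genuinely open, and what the
synthetic validation does and does not establish.

## Generative model of the synthetic cohort

A cohort is `X = A·S + b + E`, clipped at zero, on an ellipsoidal
"brain" occupying ~28% of a 32×32×32 grid of 4-mm voxels (≈9,100 mask
voxels).  SBM operates on the subjects × voxels matrix, not on spatial
resolution, so a coarse grid preserves the statistical problem while
keeping the full pipeline at ~1 s per cohort.

* **Sources** `S`: each of `k_true = 8` networks is a sum of 3 Gaussian
  blobs (FWHM 24 mm) centred at random interior voxels, smoothed with
  the study's 8-mm FWHM kernel, nonnegative, and scaled to unit
  variance over the mask.  Sources are rejection-sampled (with
  whole-set restarts) until all pairwise |correlations| are below 0.2,
  so "recovering a source" is well defined.  Spatial extent is not
  constrained by any published value; blob count and size are package
  defaults chosen to give sparse, network-like maps.
* **Loadings** `A`: unit-variance Gaussian per component.  Components
  0 and 1 carry planted group effects of d = 0.85 and d = 0.7 pooled-SD
  units (healthy group shifted up by d/2, patient group down by d/2),
  matching the magnitude range of the emulated study's two affected
  networks.
* **Cortisol**: log-normal per group, moment-matched to 9.6 ± 3.6
  (healthy) and 12.3 ± 5.1 nmol/L (patients) — hormone assays are
  positive and right-skewed.  Within the patient group, component 1's
  loadings and cortisol share a Gaussian copula with latent Pearson
  correlation `r = 2·sin(π·ρ/6)`, which makes the population Spearman
  correlation exactly the target ρ = −0.35 (Spearman is preserved under
  the monotone log-normal transform).  The finite-sample expectation at
  n = 42 is ≈ −0.342; the recovery tolerance (±0.05) covers this.
* **Baseline and clipping**: the baseline GM level is
  `baseline_factor (=5)` × the worst-case voxelwise SD of signal plus
  noise.  With unit-variance sources the mixed signal's voxel SD is ~3
  in standardized units, so anchoring the baseline to the noise SD
  alone would leave the zero-clip active on >15% of entries and the
  clip artifacts corrupt the covariance spectrum; anchoring to the
  worst-case mixture SD puts the clip ~5σ below the data, keeping the
  mixture essentially exactly linear while honouring nonnegative GM.
* **Noise** `E`: per-subject Gaussian fields smoothed to the same 8-mm
  FWHM and rescaled so the SD over the mask equals `noise_sd` (default
  0.5 standardized units).
* **Demographics**: age and sex are drawn to roughly match the emulated
  cohort margins (ages ~44/48 ± 12/14; sex 26:13 vs 21:21 odds) but
  carry no planted effect — they are covariates of no interest in the
  loading statistics.

Everything is deterministic given the config seed; the three stages
(sources, cohort, noise) draw from tagged substreams of that seed.

What the generator does **not** emulate: real neuroanatomy, tissue
segmentation and registration error, scanner artifacts, site effects,
non-Gaussian loading distributions, or correlated confounds between
demographics and loadings.  Passing the recovery tests therefore shows
the pipeline is correct under its own model assumptions — linear
mixing, smooth compact sources, independent smooth noise — not that it
is robust to real-data violations of them.

## Decomposition conventions

* **Centering**: each subject's row mean is removed, then the
  across-subject mean voxel profile (the "mean GM map"); this costs one
  rank, so at most N − 1 components exist.  For generic channel data
  (e.g. a 2 × V mixture demo) the mean-map removal can be disabled.
* **MDL**: classic Wax–Kailath form with M = number of voxels.  The
  criterion assumes i.i.d. observations across voxels; spatially
  smoothed noise violates this and inflates the selected order (e.g.
  K ≈ 22–25 on 8-mm-smoothed synthetic cohorts whose true order is
  5–8; the same mechanism plausibly affects published MDL counts).
  `estimate_order_mdl(..., subsample_fraction=0.1)` evaluates the
  criterion on a random voxel subset — mostly distant, hence nearly
  independent voxels — and recovers the true order on smoothed
  cohorts.  The classic form stays the default for fidelity.
* **Infomax defaults**: learning rate `0.015/ln K`, batch
  `8·⌊√V⌋`, annealing ×0.9 whenever successive weight updates differ
  by more than 60°, stop when the summed squared weight change per
  sweep falls below `tol = 1e-6`, at most 512 sweeps.  These are the
  community-standard settings; all are overridable.  The plain
  logistic update separates super-Gaussian sources only (GM networks
  are sparse, positive-going, hence super-Gaussian); `extended=True`
  switches to tanh/kurtosis-sign updates and also separates
  sub-Gaussian (e.g. uniform) sources.
* **Convergence caveat**: with `tol = 1e-6` an occasional run stalls
  near a saddle where two sources remain mixed (weight changes are
  small near saddles, so the stop fires early).  Stability analyses in
  the tests and acceptance script therefore run with `tol = 1e-8` and
  a larger sweep budget, which reliably escapes these saddles; ICASSO
  exists precisely to expose the residual run-to-run variability.
* **Scale/sign/order**: each source row has unit variance and zero
  mean; the mixing column absorbs the scale, so loadings are in data
  units.  Sources are flipped to positive skewness (ties: largest
  |voxel| positive) and ordered by descending explained subject-space
  variance.  This makes decompositions comparable across runs and
  loading signs interpretable.

## ICASSO

Runs differ only in their random initialization seed (`randinit`;
voxel-bootstrap resampling is out of scope).  Pooled sources are
clustered by average linkage on `1 − |corr|`, cut at exactly K
clusters.  `Iq = mean intra − mean extra similarity`, clipped into
[0, 1]; a singleton's intra term is 1 by convention.  Note that even
bit-identical duplicate runs give `Iq = 1 − (mean inter-component
similarity) ≈ 0.97–0.99`, not exactly 1, because distinct components
always retain some sample correlation; the tests assert the exact
attainable facts (intra-cluster similarity 1, Iq above 0.95).  The
reported decomposition is the set of cluster centrotypes (member with
maximal total within-cluster similarity) with loadings re-estimated by
regressing the centered data on the centrotype sources.

## Statistics

* "Z-scoring" of loadings is plain per-column standardization by
  default.  An `atanh` variant (columns rescaled to max |value| < 1,
  inverse hyperbolic tangent, then z-scored) is available behind a
  flag for users who want the Fisher-style variance-stabilizing curve;
  loadings are not correlations, routinely exceed 1 in magnitude, and
  published group summaries (e.g. 0.43 ± 0.54) are consistent with
  plain z-scores, so that is the default.  Both transforms are
  monotone per column, so rank statistics are identical either way.
* Group tests pool variances (Student t, df = n₁+n₂−2): the published
  effect sizes are exactly the pooled-SD Cohen's d values, which fixes
  this choice.  d is reported as an absolute value.
* Bonferroni families: m defaults to the number of components tested
  (10 in the emulated design) for the group comparisons and m = 2 for
  the cortisol correlations (the two significant networks carried
  forward); both are config-overridable.
* Spearman p-values use the t-approximation
  `t = ρ·√((n−2)/(1−ρ²))` with average-rank ties — standard at n ≈ 40;
  exact enumeration is reserved for tiny-n test oracles.
* Mann–Whitney U uses the tie-corrected two-sided normal
  approximation; the sex comparison is a 2 × 2 χ² with Yates
  continuity correction.

## Statistical power of the planted design

At n = 39/42, a true standardized shift of d = 0.85 yields exact power
0.82 for the pooled t-test at the Bonferroni level α = 0.05/10
(noncentral t, ncp = 3.82), and d = 0.7 yields 0.60.  Detection-rate
checks on seeded cohorts must be read against these ceilings: even an
oracle using the planted loadings detects the d = 0.85 component in
only ~80% of cohorts, and the full pipeline (which adds a little
estimation noise) sits slightly below that.  The acceptance report
therefore publishes the observed detection rate rather than asserting
near-certain detection.

## Problem sizes used in validation

Unit and acceptance tests run on the default 32³ cohort (~9,100 mask
voxels, 81 subjects, K = 8) for single-cohort checks; Monte-Carlo
loops use 20 cohorts (detection rate), 200 draws (coupling recovery),
500–1,000 draws (null calibration, on a 16³ mini-grid where image
content is irrelevant), and 100 draws (noise-only MDL).  These sizes
put Monte-Carlo error well inside each asserted tolerance (binomial
3σ bands are used wherever a rate is compared to a theoretical value).

## Known limitations

* Classic MDL over-estimates the order under spatially correlated
  noise (see above); use the subsampling correction when noise
  smoothness is substantial.
* Plain Infomax cannot separate sub-Gaussian sources; use
  `extended=True` if negative-kurtosis components are plausible.
* Artifact flagging is a quantitative proxy (edge-rim fraction, GM
  overlap) for what is usually a visual judgement; thresholds
  (edge depth 2 voxels, fraction limits 0.5) are defaults, not
  validated against expert ratings.
* Component selection by anatomical circuit membership is inherently
  configuration: the package never infers anatomy.
* The statistics layer deliberately omits covariate-adjusted models
  (age/sex/TIV regression) — loadings are compared directly between
  groups, mirroring the emulated design.
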