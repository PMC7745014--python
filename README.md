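# sbm-gm — source-based morphometry of gray-matter volumes

`sbm-gm` implements source-based morphometry (SBM) for structural MRI:
a multivariate alternative to voxel-based morphometry that decomposes a
cohort of modulated, smoothed gray-matter (GM) probability maps into
spatial networks and per-subject loading coefficients, then tests the
loadings for group differences and biomarker correlations.  The target
use case is a two-group clinical design — here emulated as 39 healthy
subjects (HS) versus 42 first-episode, drug-naive patients with major
depressive disorder (MDD) with a morning serum-cortisol covariate —
where univariate voxel-wise contrasts are underpowered but coordinated
network-level GM covariation is detectable.

## The model

Stacking each subject's masked GM map into a row gives a data matrix
`X` (subjects × voxels).  SBM models it as a linear mixture

```
X ≈ A · S
```

where `S` (K × voxels) holds K spatially independent source maps (GM
networks) and `A` (subjects × K) holds the loading coefficients: how
strongly each subject expresses each network.  The pipeline:

1. **Model order** K by the minimum description length (MDL) criterion
   on the eigenvalues λ₁ ≥ … ≥ λ_p of the subject-space covariance
   (p = N − 1 after centering, M = number of voxels):
   `MDL(k) = −(p−k)·M·log(G_k/A_k) + ½·k·(2p−k+1)·log M`,
   with `G_k`/`A_k` the geometric/arithmetic means of the trailing
   eigenvalues; K = argmin.
2. **Whitening** by the top-K principal components.
3. **Infomax ICA** — natural-gradient updates
   `ΔW = η (I + (1 − 2g(u)) uᵀ/B) W` with the logistic nonlinearity
   `g` over mini-batches of B voxels, annealed learning rate; an
   extended (kurtosis-switching) variant handles sub-Gaussian sources.
4. **ICASSO stability** — ICA repeated from `runs` random
   initializations, pooled components clustered by absolute
   correlation, each cluster scored by the quality index
   `Iq = mean intra-cluster − mean extra-cluster similarity ∈ [0, 1]`
   and represented by its centrotype.
5. **Network maps** — sources scaled to unit SD (Z maps), displayed at
   Z > 2.5, with quantitative proxies of the usual artifact screens
   (edge-dominated support, support outside a GM reference mask) and
   configuration-driven component selection.
6. **Statistics** — loadings z-scored per component; pooled-variance
   two-tailed t-tests per network with Bonferroni control and absolute
   pooled-SD Cohen's d; Spearman rank correlation of loadings with the
   biomarker per group; demographics tests (t, Mann–Whitney U, Yates
   χ²).  Every test is also computable from printed summary statistics,
   so published tables can be re-derived without subject-level data.

Because public subject-level GM maps are rarely available, the package
ships a first-class synthetic-cohort generator (`sbmgm.synthcohort`)
that plants known networks, group effects (Cohen's d on loadings) and a
Gaussian-copula cortisol coupling (target Spearman ρ), so every stage
can be validated against ground truth.

## Worked example

Simulate the default 81-subject cohort (eight networks; two planted
group effects at d = 0.85 and 0.7; the d = 0.7 network coupled to
cortisol at ρ = −0.35 within the patient group) and run the full
pipeline with 20 ICASSO repetitions:

```yaml
# demo.yaml
simulate: {enabled: true, seed: 1}
ica:      {k: 8, seed: 0}
icasso:   {runs: 20}
paths:    {out: demo_out}
```

```bash
sbm-gm run --config demo.yaml
```

prints

```json
{"k": 8, "selected_components": [1, 2, 3, 4, 5, 6, 7, 8], "significant": [1, 7]}
```

and `demo_out/report.md` contains the per-component table (excerpt):

```
- Iq per component: 0.986, 0.980, 0.976, 0.972, 0.978, 0.983, 0.973, 0.984

| IC | HS mean±SD | MDD mean±SD | t    | p        | d    | sig |
| 1  | 0.38±0.97  | -0.35±0.92  | 3.48 | 0.00083  | 0.77 | *   |
| 7  | 0.40±1.02  | -0.37±0.84  | 3.72 | 0.000371 | 0.83 | *   |

- IC 1 (MDD): rho = -0.419, adjusted p = 0.0114
```

Reading: all eight decompositions are highly stable (Iq > 0.97); the
two planted networks surface as IC 1 and IC 7 with Bonferroni-significant
loading reductions in the patient group (recovered d ≈ 0.77 and 0.83
against planted 0.7 and 0.85), and the planted cortisol coupling is
recovered as a significant negative Spearman correlation (ρ = −0.42)
for IC 1 in the MDD group only.

The same stages are available as library calls (`InfomaxICA` and
`IcassoICA` are scikit-learn estimators: `fit`, `transform`,
`components_`, `mixing_`, `iq_`) and as individual CLI subcommands
(`simulate`, `decompose`, `stability`, `maps`, `stats`, `validate`).

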