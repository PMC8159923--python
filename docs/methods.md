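# Methods

## Model and estimation

`kmimpute` treats a metabolomics intensity matrix X (p metabolites × n
samples) as approximately bilinear: each cell is the product of a metabolite
effect and a sample effect, `x_ij = r_i c_j + e_ij`. A rank-r approximation
is built by deflation — fit one rank-1 layer, subtract it from the observed
cells, fit the next layer to the remainder — and the completed, cleaned
matrix replaces missing and outlier-flagged cells by the fitted values.

Each rank-1 layer is estimated by alternating weighted least squares:

* initialise the column effects c with the per-column medians of the
  observed cells;
* row step: `r_i = Σ_j w_ij c_j x_ij / Σ_j w_ij c_j²` over observed j;
* column step: `c_j = Σ_i w_ij r_i x_ij / Σ_i w_ij r_i²` over observed i;
* stop when `(Σ|Δr| + Σ|Δc|)/(n+p) ≤ ε`.

The weights are the robust kernel

    w_ij = exp{ −λ (x_ij − median_i)² / (2 mad_i²) } ∈ (0, 1],

with median and raw (unscaled) MAD taken along the metabolite row. Weights
decay with the squared robust z-score of the cell, so grossly outlying
intensities contribute almost nothing to the normal equations; λ = 0 gives
all-ones weights and plain alternating least squares, which on a complete
matrix reproduces the truncated SVD layer by layer (this equivalence is
tested to 1e−6). Missing cells carry weight 0 and never enter any sum.

Identifiability: only the product r·cᵀ is determined (any rescaling
r/κ, κ·c gives the same fit), so after every column step c is renormalised
to unit L2 length. This leaves every fitted value unchanged but makes the
stopping rule scale-stable; all tests compare products, never raw effects.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| λ (`lam`) | chosen by CV | kernel sharpness; 0 = unweighted ALS |
| `lam_grid` | 0, 0.01, 0.1, 0.5, 1, 2, 5, 10 | CV candidates (dimensionless) |
| `cv_folds` | 5 | entry-holdout cross-validation folds |
| ε (`eps`) | 0.01 | alternation stopping tolerance (per-coordinate mean absolute change) |
| α (`alpha`) | 0.05 | rank grows until (1−α)·100% of observed variation is explained |
| `max_components` | min(p, n, 20) | hard rank cap (flagged if hit) |
| `max_iter` | 500 | alternation cap per layer |
| `weight_axis` | row | reference vector for median/MAD (column available) |

λ **cross-validation** partitions the observed cells at random into k folds;
for each candidate λ and fold, the fold's cells are masked as additionally
missing, the decomposition refitted, and the squared error on the held-out
cells recorded. The λ with the smallest mean held-out MSE wins; ties go to
the smaller (less aggressive) λ. Fold draws are rejected (and redrawn, up
to 20 times) if removing a fold would leave any row or column with no
observed cell.

**Rank selection.** The explained fraction is `1 − Σ w·resid² / Σ w·x²`
over observed cells, where w are the kernel weights of the first layer.
At λ = 0 this is exactly the plain uncentered RSS/TSS ratio. The weighting
matters under contamination: gross outliers are fitted by *no* low-rank
structure, so an unweighted ratio can never reach 1−α and the deflation
would always run to the rank cap and overfit ~rank·(p+n) parameters to
noise. Down-weighting the outlier cells in the *statistic* exactly as they
are down-weighted in the *fit* keeps the selected rank meaningful (an
unweighted variant is available via `explained_statistic="unweighted"`).

**Outlier replacement.** After fitting, observed cells outside
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] of their metabolite row (linear-interpolation
quartiles; rows with < 4 observed cells are skipped) are replaced by the
fitted values, together with all missing cells. Every other cell is
returned bit-identically — the imputer never perturbs clean data.

**Group-wise application.** With sample-group labels the whole procedure
(λ-CV, deflation, IQR detection, substitution) runs independently on each
group's column block and the blocks are re-assembled in the original order.
Each block's CV uses the same integer seed, so identical blocks yield
identical reconstructions.

## Numerical choices and degenerate inputs

* mad = 0 (constant reference vector): the scale falls back to
  `max(mad, 1e−8·(1+|median|))` and the exponent is clipped at ±700, so a
  constant vector still gets all-ones weights and nothing under/overflows.
* Vanishing WLS denominators (≤1e−12) yield a 0 effect plus a diagnostic
  flag instead of an exception, so one dead row cannot abort a fit.
* Zero-variance metabolites in the DE test receive p = 1 (the statistic is
  undefined; calling them non-DE is the conservative choice).
* Exact-recovery guarantees (noiseless rank-1 data reconstructed to ≤1e−6)
  are certified with ε = 1e−10; the default ε = 0.01 targets noisy data,
  where iterating below the noise floor buys nothing.

## The synthetic benchmark

The generator emulates the additive intensity model
`x = μ_i + g + e` with `μ_i ~ Uniform(5,10)` per metabolite and `g, e`
standard normal per cell; differential (DE) metabolites shift the mean of
g by +2 in the disease group (up) or the healthy group (down); the
three-class design uses means (0,1,2)/(2,1,0). The group effect is drawn
**per cell**: drawing it once per metabolite×group would give every EE
metabolite a realised between-group difference of sd √2, making the DE/EE
truth labels meaningless and between-group testing impossible at the
reported error rates — the per-cell reading is the only self-consistent
one. The default design is 200 metabolites × 90 samples, 40 up + 40 down
+ 120 EE, equal group sizes.

Missingness mixes 60% completely-at-random cells with 40% low-abundance
(MNAR) cells sampled from the lowest decile of each metabolite, metabolites
cycled until the quota is met; counts are exact (5% of 200×90 = 900 cells:
540 + 360). Outliers replace randomly chosen observed cells by draws from
`N(5·μ_i, σ_i²)` of the clean metabolite row. What this does **not**
emulate: metabolite–metabolite correlation, batch effects, peak-level
artefacts, or intensity-dependent noise — so passing benchmarks show
robustness to the modelled contaminations only, not performance on every
real acquisition.

## Evaluation protocols

* **Reconstruction MSE** over all p·n cells against the clean truth. This
  deliberately penalises untreated outlier cells for the fill-only
  baselines — the point of contrast with simultaneous outlier replacement.
* **DE identification**: Welch t-test (two groups) or one-way ANOVA (≥3)
  per metabolite on the reconstructed matrix; MER = 100·(FP+FN)/p at
  unadjusted p < 0.05; AUC from the ascending-p ranking (trapezoidal).
  Imputation for this protocol runs *without* the group labels: imputing
  each group separately and then testing between groups leaks the labels
  (imputed cells duplicate their group's mean, deflating the within-group
  variance and inflating the false-positive rate by several percentage
  points, measured), and in a real pipeline the phenotype is not an input
  to imputation.
* **SVM sample classification**: stratified 2/3–1/3 splits; DE features
  selected on the training columns only (fallback: 10 smallest p-values);
  radial-kernel SVC at library defaults (C = 1, γ = 'scale'); test MER and
  ROC AUC from decision values (multi-class: one-vs-rest macro-average).
  The benchmark pools 20 simulated datasets × 5 splits = 100 repetitions,
  balancing dataset-level and split-level variability. Here imputation is
  group-wise (the group-partitioned variant of the method).

Problem sizes used by the shipped benchmark (`scripts/acceptance.py`):
100 replicate datasets for each DE-identification condition and
20 datasets × 5 splits for each classification condition — the same sizes
the tests assert against.

## Known limitations

* The bilinear model has no intercept; data should be on a scale where a
  multiplicative row×column structure is plausible (raw intensities are;
  heavily centred data may need `explained_statistic` care).
* Alternating WLS converges to a stationary point, not a certified global
  optimum; with strong contamination and λ near 0 individual layers may
  hit `max_iter` (flagged in diagnostics).
* IQR outlier detection is per metabolite and assumes ≥4 observed cells;
  rows below that are imputed but never outlier-cleaned.
* The λ grid is finite and shared across groups; pathological columns
  (all-constant) rely on the degenerate-scale fallbacks above.
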