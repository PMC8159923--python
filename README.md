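# kmimpute

Kernel-weighted two-way least-squares imputation of missing values — with
simultaneous outlier replacement — for metabolomics intensity matrices.

## The problem

LC-MS/NMR metabolomics matrices (metabolites × samples) routinely contain
5–20% missing cells, a mix of random dropouts and left-censored low-abundance
values, plus occasional grossly outlying intensities. Downstream analyses
(differential-abundance testing, sample classification) need a complete,
clean matrix. Most imputers fill the holes but propagate the outliers;
`kmimpute` handles both at once.

## The model

Each cell is approximated bilinearly by a metabolite (row) effect and a
sample (column) effect,

    x_ij ≈ r_i · c_j ,

and a rank-r approximation X̂⁽ʳ⁾ = Σₖ r̂ₖ ĉₖᵀ is built by fitting rank-1
layers to successive remainder matrices. Each layer is estimated by
alternating **weighted** least squares with the kernel weight

    w_ij = exp{ −λ (x_ij − median_i)² / (2 · mad_i²) } ,

where the median and (raw) MAD are taken along the metabolite row. Cells far
from their row median receive weight ≈ 0, so outliers barely influence the
fit; λ = 0 recovers classical alternating least squares. λ is chosen by
k-fold cross-validation on held-out observed cells; the rank r is the
smallest that explains (1 − α)·100% of the observed variation (α = 0.05).
Finally, missing cells and cells flagged by the per-metabolite 1.5·IQR rule
are replaced by the corresponding cells of X̂⁽ʳ⁾; every other cell is
returned bit-identically. With sample-group labels, the procedure can be
applied independently per group.

The package also ships the trivial baselines (zero, per-metabolite
mean / median / half-minimum), an adapter registry for external imputers
(a kNN adapter is included), an additive-model simulator with configurable
MCAR/MNAR missingness and planted outliers, and the evaluation battery
(reconstruction MSE; t-test/ANOVA DE identification scored by MER and AUC;
SVM sample classification with train-only feature selection).

## Worked example

```python
import numpy as np
from kmimpute import (AnnotatedMatrix, KernelWeightConfig,
                      SimulationConfig, generate_dataset, impute_kmi,
                      reconstruction_mse)

ds = generate_dataset(SimulationConfig(design="two_class", seed=7,
                                       missing_rate=0.05, outlier_rate=0.10))
X = ds.annotated(with_groups=False)
res = impute_kmi(X, KernelWeightConfig(seed=7))
print("lambda chosen :", res.lam_used)
print("rank used     :", res.rank_used)
print("cells imputed :", int(res.imputed_mask.sum()))
print("outliers fixed:", int(res.outlier_mask.sum()))
print("MSE vs truth  :", round(reconstruction_mse(ds.clean, res.reconstructed), 3))
```

prints

```
lambda chosen : 10.0
rank used     : 1
cells imputed : 900
outliers fixed: 1853
MSE vs truth  : 0.552
```

Cross-validation picks a strongly robust weight (λ = 10) because 10% of the
cells are gross outliers; a rank-1 bilinear fit suffices for this additive
two-class design; 900 missing cells (5% of 200×90) are filled and ~1850
flagged cells (the planted outliers plus a few extreme noise draws) are
replaced. The resulting whole-matrix MSE of ≈0.55 compares with ≈102.6 for
per-metabolite mean imputation on the same data, which fills the holes but
leaves every outlier in place.

The same pipeline is available from the shell:

```bash
kmimpute simulate --design two_class --missing-rate 0.05 --outlier-rate 0.1 \
                  --seed 7 --out-prefix sim
kmimpute impute --in sim_observed.csv --out sim_imputed.csv \
                --groups sim_groups.csv --seed 7 --diagnostics diag.json
kmimpute benchmark --methods kmi,mean,zero --n-reps 5 --seed 7 --out bench.csv
```

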