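"""Kernel-weighted two-way alternating least-squares imputation (KMI).

The observed metabolite × sample intensity matrix is modelled cell-wise as the
product of a metabolite (row) effect and a sample (column) effect,
``x_ij ≈ r_i · c_j``.  Each rank-1 layer is fitted by alternating *weighted*
least squares, where the weight of a cell decays with its squared deviation
from the robust centre (median) of its reference vector, standardised by the
median absolute deviation (MAD):

    w_ij = exp{ -λ/(2·mad²) · (x_ij − median)² }

Outlying cells therefore contribute almost nothing to the fit; λ = 0 recovers
the classical unweighted alternating least squares.  Successive rank-1 layers
are fitted to the remainder ("deflation") until the fitted sum explains
(1 − α)·100% of the observed variation.  Missing cells and cells flagged by
the per-metabolite IQR rule are finally replaced by the fitted values, giving
a complete, outlier-cleaned matrix.  λ is chosen by k-fold cross-validation
over held-out observed cells.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnnotatedMatrix",
    "KernelWeightConfig",
    "BilinearComponent",
    "Decomposition",
    "ImputationResult",
    "robust_location_scale",
    "kernel_weights",
    "init_column_effects",
    "update_row_effects",
    "update_column_effects",
    "fit_rank1",
    "fit_decomposition",
    "detect_outliers_iqr",
    "select_lambda",
    "impute_kmi",
    "impute_groupwise",
]

# Default λ grid for cross-validation.
DEFAULT_LAMBDA_GRID: tuple[float, ...] = (0.0, 0.01, 0.1, 0.5, 1.0, 2.0, 5.0, 10.0)

# Denominators in the WLS updates below this are treated as degenerate.
_DEGENERATE_DEN = 1e-12
# Exponent clipping for the kernel weight (avoids under/overflow).
_EXP_CLIP = 700.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class AnnotatedMatrix:
    """Intensity matrix (metabolites × samples) with a missing-cell mask.

    Parameters
    ----------
    values
        Real p×n matrix.  Cells flagged in ``missing_mask`` carry no usable
        value and are stored as NaN.
    missing_mask
        Boolean p×n matrix, True where the cell is missing.
    metabolite_ids, sample_ids
        Row / column labels.  Generated automatically when omitted.
    groups
        Optional length-n vector of categorical sample-group labels; each
        group must contain at least two samples.
    """

    values: np.ndarray
    missing_mask: np.ndarray | None = None
    metabolite_ids: Sequence[str] | None = None
    sample_ids: Sequence[str] | None = None
    groups: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.array(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        p, n = self.values.shape
        if p < 2 or n < 2:
            raise ValueError(f"matrix must be at least 2×2, got {p}×{n}")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.array(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("values and missing_mask must have identical shape")
        # missing cells carry no usable value
        self.values[self.missing_mask] = np.nan
        if np.isnan(self.values[~self.missing_mask]).any():
            raise ValueError("non-missing cells must be finite")
        if self.metabolite_ids is None:
            self.metabolite_ids = [f"M{i + 1}" for i in range(p)]
        if self.sample_ids is None:
            self.sample_ids = [f"S{j + 1}" for j in range(n)]
        self.metabolite_ids = list(map(str, self.metabolite_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        if len(self.metabolite_ids) != p or len(self.sample_ids) != n:
            raise ValueError("label lengths do not match matrix shape")
        if self.groups is not None:
            self.groups = np.asarray(self.groups, dtype=object)
            if self.groups.shape != (n,):
                raise ValueError("groups must have one label per sample")
            _, counts = np.unique(self.groups.astype(str), return_counts=True)
            if (counts < 2).any():
                raise ValueError("each sample group needs at least 2 samples")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def observed_mask(self) -> np.ndarray:
        return ~self.missing_mask

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.metabolite_ids, columns=self.sample_ids
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, groups: Sequence[str] | None = None
    ) -> "AnnotatedMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            metabolite_ids=list(df.index.astype(str)),
            sample_ids=list(df.columns.astype(str)),
            groups=groups,
        )


@dataclass
class KernelWeightConfig:
    """Tuning parameters of the kernel-weighted imputation.

    ``lam`` is the kernel sharpness λ; ``None`` requests k-fold
    cross-validation over ``lam_grid``.  ``eps`` is the alternation stopping
    tolerance, ``alpha`` the rank-selection level (the decomposition stops at
    the smallest rank explaining (1−alpha)·100% of the observed variation).
    """

    lam: float | None = None
    lam_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    cv_folds: int = 5
    weight_axis: Literal["row", "column"] = "row"
    eps: float = 0.01
    alpha: float = 0.05
    max_components: int | None = None
    max_iter: int = 500
    seed: int = 0
    refresh_weights_each_iter: bool = False
    explained_statistic: Literal["weighted", "unweighted"] = "weighted"
    cv_max_retries: int = 20

    def __post_init__(self) -> None:
        if self.lam is not None and self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if len(self.lam_grid) == 0:
            raise ValueError("lam_grid must be non-empty")
        if any(l < 0 for l in self.lam_grid):
            raise ValueError("lam_grid values must be nonnegative")
        self.lam_grid = tuple(sorted(self.lam_grid))
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.weight_axis not in ("row", "column"):
            raise ValueError("weight_axis must be 'row' or 'column'")

    def resolved_max_components(self, shape: tuple[int, int]) -> int:
        cap = min(shape[0], shape[1], 20)
        if self.max_components is not None:
            cap = min(cap, self.max_components)
        return max(cap, 1)


@dataclass
class BilinearComponent:
    """One rank-1 layer ``r·cᵀ``; only the product is identified."""

    r: np.ndarray
    c: np.ndarray
    n_iter: int = 0
    converged: bool = True
    degenerate_rows: np.ndarray | None = None
    degenerate_cols: np.ndarray | None = None

    @property
    def fitted(self) -> np.ndarray:
        return np.outer(self.r, self.c)


@dataclass
class Decomposition:
    """Deflation sequence of rank-1 layers approximating X."""

    components: list[BilinearComponent]
    rank: int
    explained_fraction: float
    fitted: np.ndarray
    rss_path: list[float] = field(default_factory=list)
    hit_max_components: bool = False


@dataclass
class ImputationResult:
    """Reconstructed complete matrix with provenance masks and diagnostics."""

    reconstructed: np.ndarray
    imputed_mask: np.ndarray
    outlier_mask: np.ndarray
    lam_used: float | dict
    rank_used: int | dict
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Robust location/scale and kernel weights
# ---------------------------------------------------------------------------


def robust_location_scale(v: np.ndarray) -> tuple[float, float]:
    """Median and raw (unscaled) MAD of the non-missing entries of ``v``.

    Missing entries are NaN.  Raises on an all-missing vector.
    """
    v = np.asarray(v, dtype=float)
    obs = v[~np.isnan(v)]
    if obs.size == 0:
        raise ValueError("all entries missing: cannot compute median/MAD")
    med = float(np.median(obs))
    mad = float(np.median(np.abs(obs - med)))
    return med, mad


def _kernel_weights(
    values: np.ndarray, missing_mask: np.ndarray, lam: float, weight_axis: str
) -> np.ndarray:
    """Weight matrix with zeros at missing cells (internal, array-level)."""
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    v = np.where(missing_mask, np.nan, values)
    axis = 1 if weight_axis == "row" else 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(v, axis=axis, keepdims=True)
        mad = np.nanmedian(np.abs(v - med), axis=axis, keepdims=True)
    # degenerate-scale fallback keeps "constant vector => all weights 1"
    scale = np.maximum(mad, 1e-8 * (1.0 + np.abs(med)))
    z = np.where(missing_mask, 0.0, (v - med) / scale)
    arg = np.clip(-0.5 * lam * z * z, -_EXP_CLIP, _EXP_CLIP)
    w = np.exp(arg)
    w[missing_mask] = 0.0
    return w


def kernel_weights(
    X: AnnotatedMatrix, lam: float, weight_axis: str = "row"
) -> np.ndarray:
    """Kernel weight matrix ``w_ij = exp{-λ (x_ij − med)² / (2·mad²)}``.

    The reference median/MAD is taken along the metabolite row
    (``weight_axis='row'``, default) or the sample column.  Observed weights
    lie in (0, 1]; missing cells get weight 0 and never enter any sum.
    """
    if weight_axis not in ("row", "column"):
        raise ValueError("weight_axis must be 'row' or 'column'")
    return _kernel_weights(X.values, X.missing_mask, lam, weight_axis)


# ---------------------------------------------------------------------------
# Alternating weighted least squares (one rank-1 layer)
# ---------------------------------------------------------------------------


def init_column_effects(X: AnnotatedMatrix) -> np.ndarray:
    """Initial column (sample) effects: per-column medians of observed cells."""
    return _init_column_effects(X.values, X.missing_mask, X.sample_ids)


def _init_column_effects(values, missing_mask, sample_ids=None) -> np.ndarray:
    all_missing = missing_mask.all(axis=0)
    if all_missing.any():
        j = int(np.argmax(all_missing))
        name = sample_ids[j] if sample_ids is not None else f"column {j}"
        raise ValueError(f"sample {name!r} has no observed values")
    v = np.where(missing_mask, np.nan, values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(v, axis=0)


def _wls_solve(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    degenerate = den <= _DEGENERATE_DEN
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=~degenerate)
    return out, degenerate


def update_row_effects(
    X: AnnotatedMatrix, c: np.ndarray, W: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form WLS row effects r_i = Σ_j w·c·x / Σ_j w·c² (observed j).

    Returns ``(r, degenerate_mask)``; rows with a vanishing denominator get
    r_i = 0 and are flagged rather than raising.
    """
    values0 = np.where(X.missing_mask, 0.0, X.values)
    return _wls_solve((W * values0) @ c, W @ (c * c))


def update_column_effects(
    X: AnnotatedMatrix, r: np.ndarray, W: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric WLS column update c_j = Σ_i w·r·x / Σ_i w·r² (observed i)."""
    values0 = np.where(X.missing_mask, 0.0, X.values)
    return _wls_solve((W * values0).T @ r, W.T @ (r * r))


def fit_rank1(
    X: AnnotatedMatrix,
    lam: float = 0.0,
    eps: float = 0.01,
    max_iter: int = 500,
    weight_axis: str = "row",
    W: np.ndarray | None = None,
    refresh_weights_each_iter: bool = False,
) -> BilinearComponent:
    """Fit one rank-1 layer by alternating WLS from the column-median start.

    Stops when (Σ|Δr| + Σ|Δc|)/(n+p) ≤ eps.  The column effects are
    renormalised to unit L2 length after every column step (the product
    r·cᵀ is unchanged) so the stopping rule is scale-stable.
    """
    return _fit_rank1(
        X.values,
        X.missing_mask,
        lam=lam,
        eps=eps,
        max_iter=max_iter,
        weight_axis=weight_axis,
        W=W,
        refresh_weights_each_iter=refresh_weights_each_iter,
    )


def _fit_rank1(
    values,
    missing_mask,
    lam=0.0,
    eps=0.01,
    max_iter=500,
    weight_axis="row",
    W=None,
    refresh_weights_each_iter=False,
) -> BilinearComponent:
    p, n = values.shape
    if missing_mask.all(axis=1).any():
        raise ValueError("a metabolite row has no observed values")
    if W is None:
        W = _kernel_weights(values, missing_mask, lam, weight_axis)
    values0 = np.where(missing_mask, 0.0, values)

    c = _init_column_effects(values, missing_mask)
    norm = float(np.linalg.norm(c))
    if norm > 0:
        c = c / norm
    r = np.zeros(p)

    converged = False
    it = 0
    deg_r = np.zeros(p, dtype=bool)
    deg_c = np.zeros(n, dtype=bool)
    for it in range(1, max_iter + 1):
        if refresh_weights_each_iter and it > 1:
            W = _kernel_weights(values, missing_mask, lam, weight_axis)
        r_new, deg_r = _wls_solve((W * values0) @ c, W @ (c * c))
        c_new, deg_c = _wls_solve((W * values0).T @ r_new, W.T @ (r_new * r_new))
        norm = float(np.linalg.norm(c_new))
        if norm > 0:
            # rescale so the product is unchanged but c has unit length
            c_new = c_new / norm
            r_new = r_new * norm
        if not (np.isfinite(r_new).all() and np.isfinite(c_new).all()):
            raise FloatingPointError(
                f"non-finite effects at alternation iteration {it}"
            )
        delta = (np.abs(r_new - r).sum() + np.abs(c_new - c).sum()) / (n + p)
        r, c = r_new, c_new
        if delta <= eps:
            converged = True
            break
    return BilinearComponent(
        r=r, c=c, n_iter=it, converged=converged,
        degenerate_rows=deg_r, degenerate_cols=deg_c,
    )


# ---------------------------------------------------------------------------
# Deflation with rank selection
# ---------------------------------------------------------------------------


def fit_decomposition(X: AnnotatedMatrix, cfg: KernelWeightConfig) -> Decomposition:
    """Sequential rank-1 deflation until (1−alpha)·100% variation is explained.

    Each layer is fitted to the current remainder (missing cells excluded);
    the explained fraction is 1 − Σw·resid² / Σw·x² over observed cells,
    where w are the kernel weights of the first layer (all ones at λ = 0,
    where the statistic coincides with the plain uncentered RSS/TSS ratio).
    """
    lam = cfg.lam
    if lam is None:
        raise ValueError("fit_decomposition needs a concrete lam; run select_lambda first")
    return _fit_decomposition(X.values, X.missing_mask, lam, cfg)


def _fit_decomposition(values, missing_mask, lam, cfg: KernelWeightConfig) -> Decomposition:
    p, n = values.shape
    obs = ~missing_mask
    values0 = np.where(missing_mask, 0.0, values)
    max_comp = cfg.resolved_max_components((p, n))

    w_ref = _kernel_weights(values, missing_mask, lam, cfg.weight_axis)
    if cfg.explained_statistic == "unweighted":
        w_stat = obs.astype(float)
    else:
        w_stat = w_ref
    tss = float(np.sum(w_stat * values0 * values0))

    fitted = np.zeros((p, n))
    remainder = values.copy()  # NaN at missing
    components: list[BilinearComponent] = []
    rss_path: list[float] = []
    explained = 1.0
    hit_max = False

    if tss <= 0:
        return Decomposition([], 0, 1.0, fitted, [], False)

    for k in range(1, max_comp + 1):
        comp = _fit_rank1(
            remainder,
            missing_mask,
            lam=lam,
            eps=cfg.eps,
            max_iter=cfg.max_iter,
            weight_axis=cfg.weight_axis,
            refresh_weights_each_iter=cfg.refresh_weights_each_iter,
        )
        layer = comp.fitted
        fitted += layer
        remainder = remainder - layer
        components.append(comp)
        resid0 = np.where(missing_mask, 0.0, values0 - fitted)
        rss_path.append(float(np.sum(w_stat * resid0 * resid0)))
        explained = 1.0 - rss_path[-1] / tss
        if explained >= 1.0 - cfg.alpha:
            break
    else:
        hit_max = True

    return Decomposition(
        components=components,
        rank=len(components),
        explained_fraction=float(explained),
        fitted=fitted,
        rss_path=rss_path,
        hit_max_components=hit_max,
    )


# ---------------------------------------------------------------------------
# IQR outlier detection
# ---------------------------------------------------------------------------


def detect_outliers_iqr(X: AnnotatedMatrix, min_observed: int = 4) -> np.ndarray:
    """Per-metabolite IQR rule: flag observed cells outside the 1.5·IQR fences.

    Quartiles use linear interpolation.  Rows with fewer than ``min_observed``
    observed cells are never flagged; missing cells are never flagged.
    """
    return _detect_outliers_iqr(X.values, X.missing_mask, min_observed)


def _detect_outliers_iqr(values, missing_mask, min_observed: int = 4) -> np.ndarray:
    v = np.where(missing_mask, np.nan, values)
    n_obs = (~missing_mask).sum(axis=1)
    flagged = np.zeros(values.shape, dtype=bool)
    enough = n_obs >= min_observed
    if not enough.any():
        return flagged
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        q1 = np.nanpercentile(v[enough], 25, axis=1)
        q3 = np.nanpercentile(v[enough], 75, axis=1)
    iqr = q3 - q1
    lo = (q1 - 1.5 * iqr)[:, None]
    hi = (q3 + 1.5 * iqr)[:, None]
    sub = v[enough]
    flagged[enough] = (~np.isnan(sub)) & ((sub < lo) | (sub > hi))
    return flagged


# ---------------------------------------------------------------------------
# λ selection by entry-holdout cross-validation
# ---------------------------------------------------------------------------


def _make_cv_folds(
    missing_mask: np.ndarray, k: int, rng: np.random.Generator, max_retries: int
) -> list[np.ndarray]:
    """Partition observed cell indices into k folds so that every row and
    column keeps ≥1 observed cell after removing any single fold."""
    obs_idx = np.flatnonzero(~missing_mask)
    p, n = missing_mask.shape
    row_obs = (~missing_mask).sum(axis=1)
    col_obs = (~missing_mask).sum(axis=0)
    for _ in range(max_retries):
        perm = rng.permutation(obs_idx)
        folds = np.array_split(perm, k)
        ok = True
        for f in folds:
            ri, ci = np.unravel_index(f, (p, n))
            if (np.bincount(ri, minlength=p) >= row_obs).any():
                ok = False
                break
            if (np.bincount(ci, minlength=n) >= col_obs).any():
                ok = False
                break
        if ok:
            return folds
    raise ValueError(
        "could not draw cross-validation folds leaving every row/column observed"
    )


def select_lambda(
    X: AnnotatedMatrix, cfg: KernelWeightConfig
) -> tuple[float, pd.DataFrame]:
    """Choose λ by k-fold entry-holdout cross-validation.

    Observed cells are partitioned at random (seeded) into ``cv_folds``
    folds; for every candidate λ and fold, the fold's cells are masked as
    additionally missing, the decomposition refitted, and the squared error
    on the held-out cells recorded.  Returns the λ with the smallest mean
    held-out MSE (ties go to the smaller λ) and the per-λ CV table.
    """
    grid = cfg.lam_grid
    if len(grid) == 1:
        table = pd.DataFrame({"lam": list(grid), "cv_mse": [np.nan]})
        return float(grid[0]), table
    rng = np.random.default_rng(cfg.seed)
    folds = _make_cv_folds(X.missing_mask, cfg.cv_folds, rng, cfg.cv_max_retries)
    p, n = X.shape
    mean_err = []
    for lam in grid:
        errs = []
        for f in folds:
            mask = X.missing_mask.copy()
            ri, ci = np.unravel_index(f, (p, n))
            mask[ri, ci] = True
            d = _fit_decomposition(X.values, mask, lam, cfg)
            diff = d.fitted[ri, ci] - X.values[ri, ci]
            errs.append(float(np.mean(diff * diff)))
        mean_err.append(float(np.mean(errs)))
    table = pd.DataFrame({"lam": list(grid), "cv_mse": mean_err})
    best = int(np.argmin(mean_err))  # grid sorted ascending; argmin takes first
    return float(grid[best]), table


# ---------------------------------------------------------------------------
# Full imputation (Steps 1–6) and group-wise application
# ---------------------------------------------------------------------------


def impute_kmi(X: AnnotatedMatrix, cfg: KernelWeightConfig | None = None) -> ImputationResult:
    """Impute missing cells and replace IQR-flagged outliers with fitted values.

    Runs λ cross-validation (unless ``cfg.lam`` is fixed), fits the deflation
    decomposition, flags outliers per metabolite with the IQR rule, and
    substitutes missing and flagged cells by the corresponding cells of the
    fitted low-rank matrix.  All other cells are returned bit-identically.
    """
    if cfg is None:
        cfg = KernelWeightConfig()
    if X.missing_mask.all(axis=1).any():
        i = int(np.argmax(X.missing_mask.all(axis=1)))
        raise ValueError(f"metabolite {X.metabolite_ids[i]!r} has no observed values")
    if X.missing_mask.all(axis=0).any():
        j = int(np.argmax(X.missing_mask.all(axis=0)))
        raise ValueError(f"sample {X.sample_ids[j]!r} has no observed values")

    cv_table = None
    if cfg.lam is None:
        lam, cv_table = select_lambda(X, cfg)
    else:
        lam = float(cfg.lam)

    decomp = _fit_decomposition(X.values, X.missing_mask, lam, cfg)
    outlier_mask = _detect_outliers_iqr(X.values, X.missing_mask)

    replace = X.missing_mask | outlier_mask
    reconstructed = np.where(replace, decomp.fitted, X.values)

    diagnostics = {
        "iterations": [c.n_iter for c in decomp.components],
        "converged": [bool(c.converged) for c in decomp.components],
        "explained_fraction": decomp.explained_fraction,
        "hit_max_components": decomp.hit_max_components,
        "n_imputed": int(X.missing_mask.sum()),
        "n_outliers": int(outlier_mask.sum()),
    }
    if cv_table is not None:
        diagnostics["cv_table"] = cv_table
    return ImputationResult(
        reconstructed=reconstructed,
        imputed_mask=X.missing_mask.copy(),
        outlier_mask=outlier_mask,
        lam_used=lam,
        rank_used=decomp.rank,
        diagnostics=diagnostics,
    )


def impute_groupwise(
    X: AnnotatedMatrix, cfg: KernelWeightConfig | None = None
) -> ImputationResult:
    """Apply the imputation independently within each sample group.

    The matrix is partitioned column-wise by group label, each block imputed
    with :func:`impute_kmi` (its own λ cross-validation, rank selection and
    per-metabolite outlier detection), and the blocks re-assembled in the
    original column order.  Without group labels this is :func:`impute_kmi`.
    """
    if cfg is None:
        cfg = KernelWeightConfig()
    if X.groups is None:
        return impute_kmi(X, cfg)

    groups = np.asarray(X.groups).astype(str)
    labels = list(dict.fromkeys(groups))  # first-appearance order
    p, n = X.shape
    reconstructed = np.empty((p, n))
    outlier_mask = np.zeros((p, n), dtype=bool)
    lam_used: dict[str, float] = {}
    rank_used: dict[str, int] = {}
    diagnostics: dict[str, dict] = {}
    for g in labels:
        cols = np.flatnonzero(groups == g)
        sub_missing = X.missing_mask[:, cols]
        row_dead = sub_missing.all(axis=1)
        if row_dead.any():
            i = int(np.argmax(row_dead))
            raise ValueError(
                f"group {g!r}: metabolite {X.metabolite_ids[i]!r} has no observed values"
            )
        sub = AnnotatedMatrix(
            values=X.values[:, cols],
            missing_mask=sub_missing,
            metabolite_ids=X.metabolite_ids,
            sample_ids=[X.sample_ids[j] for j in cols],
        )
        res = impute_kmi(sub, cfg)
        reconstructed[:, cols] = res.reconstructed
        outlier_mask[:, cols] = res.outlier_mask
        lam_used[g] = res.lam_used
        rank_used[g] = res.rank_used
        diagnostics[g] = res.diagnostics
    return ImputationResult(
        reconstructed=reconstructed,
        imputed_mask=X.missing_mask.copy(),
        outlier_mask=outlier_mask,
        lam_used=lam_used,
        rank_used=rank_used,
        diagnostics=diagnostics,
    )
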