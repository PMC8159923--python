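"""Unit and property tests for the kernel-weighted imputation core."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kmimpute import (
    AnnotatedMatrix,
    KernelWeightConfig,
    detect_outliers_iqr,
    fit_decomposition,
    fit_rank1,
    impute_groupwise,
    impute_kmi,
    init_column_effects,
    kernel_weights,
    robust_location_scale,
    select_lambda,
    update_column_effects,
    update_row_effects,
)
from kmimpute.simulate import SimulationConfig, generate_dataset

from conftest import NA, matrix

TIGHT = dict(eps=1e-10, max_iter=20000)


# ---------------------------------------------------------------------------
# robust location / scale
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "v, expected",
    [
        ([1, 2, 3, 4, 100], (3.0, 1.0)),
        ([5, 5, 5], (5.0, 0.0)),
        ([2, NA, 4], (3.0, 1.0)),
    ],
)
def test_robust_location_scale(v, expected):
    assert robust_location_scale(np.array(v, dtype=float)) == expected


def test_robust_location_scale_all_missing_errors():
    with pytest.raises(ValueError, match="missing"):
        robust_location_scale(np.array([NA, NA]))


# ---------------------------------------------------------------------------
# kernel weights
# ---------------------------------------------------------------------------


def test_weights_all_one_at_lambda_zero(rng):
    X = matrix(rng.normal(size=(6, 5)))
    W = kernel_weights(X, lam=0.0)
    assert np.array_equal(W, np.ones((6, 5)))


def test_weight_is_one_at_the_median():
    X = matrix([[1, 2, 3, 4, 100], [5, 6, 7, 8, 9]])
    W = kernel_weights(X, lam=3.0, weight_axis="row")
    assert W[0, 2] == 1.0  # value 3 is its row median
    assert W[1, 2] == 1.0


def test_weight_hand_values_reference_row():
    # row median 3, raw MAD 1: value 2 -> exp(-1/2), value 100 -> ~0
    X = matrix([[1, 2, 3, 4, 100], [1, 2, 3, 4, 5]])
    W = kernel_weights(X, lam=1.0, weight_axis="row")
    assert W[0, 1] == pytest.approx(np.exp(-0.5), rel=1e-12)
    assert W[0, 4] == pytest.approx(0.0, abs=1e-300)


def test_weights_bounds_missing_and_monotonicity():
    X = matrix([[1, 2, 3, NA, 50], [4, 4, 4, 4, 4]])
    W = kernel_weights(X, lam=2.0)
    assert W[0, 3] == 0.0  # missing cell
    obs = W[~X.missing_mask]
    assert ((obs > 0) & (obs <= 1)).all()
    assert W[0, 4] < W[0, 0] < W[0, 1]  # further from median => smaller
    assert np.array_equal(W[1], np.ones(5))  # constant row: mad=0 fallback


def test_weights_negative_lambda_rejected():
    with pytest.raises(ValueError, match="nonnegative"):
        kernel_weights(matrix([[1, 2], [3, 4]]), lam=-1.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.floats(0.01, 20.0))
def test_weight_bounds_property(seed, lam):
    """Weights lie in (0,1]; equal 1 iff the deviation is 0 (for mad>0)."""
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(6, 7)) * rng.uniform(0.5, 10)
    X = AnnotatedMatrix(values)
    W = kernel_weights(X, lam=lam)
    assert ((W > 0) & (W <= 1)).all()
    med = np.median(values, axis=1, keepdims=True)
    mad = np.median(np.abs(values - med), axis=1, keepdims=True)
    at_median = np.isclose(values, med) & (mad > 1e-8)
    assert (W[at_median] == 1.0).all()
    off_median = (~np.isclose(values, med)) & np.broadcast_to(mad > 1e-8, W.shape)
    assert (W[off_median] < 1.0).all()


# ---------------------------------------------------------------------------
# initialisation and WLS updates
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "col, expected",
    [([2, 4, 6], 4.0), ([1, NA, 3], 2.0), ([7, 7, 7], 7.0)],
)
def test_init_column_effects(col, expected):
    X = matrix(np.column_stack([col, col]))
    assert init_column_effects(X)[0] == expected


def test_init_column_effects_all_missing_column_errors():
    X = matrix([[1, NA], [2, NA]], sample_ids=["a", "b"])
    with pytest.raises(ValueError, match="b"):
        init_column_effects(X)


def test_update_row_effects_closed_form():
    X = matrix([[2, 4, 6], [2, NA, 6]])
    W = np.where(X.missing_mask, 0.0, 1.0)
    c = np.array([1.0, 2.0, 3.0])
    r, degen = update_row_effects(X, c, W)
    assert r[0] == pytest.approx(28 / 14)  # full row
    assert r[1] == pytest.approx((2 + 18) / (1 + 9))  # missing cell excluded
    assert not degen.any()


def test_update_row_effects_reduces_to_mean_for_unit_c():
    X = matrix([[2, 4, 9], [1, NA, 5]])
    W = np.where(X.missing_mask, 0.0, 1.0)
    r, _ = update_row_effects(X, np.ones(3), W)
    assert r == pytest.approx([5.0, 3.0])


def test_update_column_effects_symmetric_and_degenerate():
    X = matrix(np.array([[2.0, 1], [4, 1], [6, 1]]))
    W = np.ones((3, 2))
    c, degen = update_column_effects(X, np.array([1.0, 2.0, 3.0]), W)
    assert c[0] == pytest.approx(2.0)
    assert not degen.any()
    c0, degen0 = update_column_effects(X, np.zeros(3), W)
    assert np.array_equal(c0, np.zeros(2)) and degen0.all()


# ---------------------------------------------------------------------------
# rank-1 fits and deflation
# ---------------------------------------------------------------------------


def test_fit_rank1_recovers_exact_rank1(rank1_complete):
    comp = fit_rank1(AnnotatedMatrix(rank1_complete), lam=0.0, **TIGHT)
    assert comp.converged
    np.testing.assert_allclose(comp.fitted, rank1_complete, rtol=1e-8)


def test_fit_rank1_matches_truncated_svd(rng):
    X = rng.normal(size=(5, 4))
    comp = fit_rank1(AnnotatedMatrix(X), lam=0.0, **TIGHT)
    u, s, vt = np.linalg.svd(X)
    best = s[0] * np.outer(u[:, 0], vt[0])
    rel = np.linalg.norm(comp.fitted - best) / np.linalg.norm(best)
    assert rel < 1e-6


def test_fit_rank1_product_scale_invariant(rank1_complete):
    comp = fit_rank1(AnnotatedMatrix(rank1_complete), lam=0.0, **TIGHT)
    kappa = 7.3
    np.testing.assert_allclose(
        np.outer(comp.r / kappa, comp.c * kappa), comp.fitted, rtol=1e-12
    )


def test_decomposition_exact_rank2(rng):
    X = np.outer(rng.uniform(1, 2, 8), rng.uniform(1, 2, 6))
    X += np.outer(rng.uniform(-2, 2, 8), rng.uniform(-2, 2, 6))  # comparable norm
    cfg = KernelWeightConfig(lam=0.0, **TIGHT)
    d = fit_decomposition(AnnotatedMatrix(X), cfg)
    assert d.rank == 2
    assert d.explained_fraction >= 0.95
    np.testing.assert_allclose(d.fitted, X, atol=1e-7)


def test_decomposition_constant_matrix():
    d = fit_decomposition(
        AnnotatedMatrix(np.full((4, 3), 7.0)), KernelWeightConfig(lam=0.0)
    )
    assert d.rank == 1
    assert d.explained_fraction == pytest.approx(1.0, abs=1e-12)


def test_decomposition_rss_monotone(rng):
    X = AnnotatedMatrix(rng.normal(loc=5, size=(12, 9)))
    cfg = KernelWeightConfig(lam=0.0, alpha=1e-9, max_components=6, **TIGHT)
    d = fit_decomposition(X, cfg)
    assert all(b <= a + 1e-9 for a, b in zip(d.rss_path, d.rss_path[1:]))


def test_decomposition_equals_truncated_svd_at_lambda_zero(rng):
    """λ=0 complete-matrix deflation = truncated SVD, ≤1e−6 relative error."""
    X = rng.normal(loc=3, size=(20, 15))
    cfg = KernelWeightConfig(lam=0.0, **TIGHT)
    d = fit_decomposition(AnnotatedMatrix(X), cfg)
    u, s, vt = np.linalg.svd(X)
    r = d.rank
    trunc = (u[:, :r] * s[:r]) @ vt[:r]
    rel = np.linalg.norm(d.fitted - trunc) / np.linalg.norm(trunc)
    assert rel < 1e-6


def test_decomposition_requires_concrete_lambda(rng):
    with pytest.raises(ValueError, match="lam"):
        fit_decomposition(
            AnnotatedMatrix(rng.normal(size=(4, 4))), KernelWeightConfig(lam=None)
        )


# ---------------------------------------------------------------------------
# IQR outlier detection
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "row, flagged_cols",
    [
        ([1, 2, 3, 4, 100], [4]),  # Q1=2, Q3=4, upper fence 7
        ([5, 5, 5, 5, 5], []),
        ([1, 2, 3, 4, 5], []),  # fences 0.5 and 5.5
    ],
)
def test_detect_outliers_iqr_rows(row, flagged_cols):
    X = matrix([row, [1, 2, 3, 4, 5]])
    mask = detect_outliers_iqr(X)
    assert sorted(np.flatnonzero(mask[0])) == flagged_cols
    assert not mask[1].any()


def test_detect_outliers_needs_four_observed():
    X = matrix([[1, 2, NA, NA, 1000], [1, 2, 3, 4, 1000]])
    mask = detect_outliers_iqr(X)
    assert not mask[0].any()  # only 3 observed cells: row skipped
    assert mask[1, 4]
    assert not mask[X.missing_mask].any()


# ---------------------------------------------------------------------------
# λ cross-validation
# ---------------------------------------------------------------------------


def test_select_lambda_single_candidate(rng):
    X = AnnotatedMatrix(rng.normal(size=(6, 6)))
    cfg = KernelWeightConfig(lam_grid=(0.0,), seed=1)
    lam, table = select_lambda(X, cfg)
    assert lam == 0.0
    assert list(table["lam"]) == [0.0]


def test_select_lambda_prefers_smaller_on_clean_rank1(rng):
    X = AnnotatedMatrix(np.outer(rng.uniform(1, 2, 10), rng.uniform(1, 2, 8)))
    cfg = KernelWeightConfig(lam_grid=(0.0, 1.0), seed=3, **TIGHT)
    lam, table = select_lambda(X, cfg)
    assert lam == 0.0
    assert table["cv_mse"].iloc[0] < 1e-10  # exact recovery of held-out cells


def test_select_lambda_deterministic(rng):
    X = AnnotatedMatrix(rng.normal(loc=6, size=(15, 10)))
    cfg = KernelWeightConfig(lam_grid=(0.0, 0.5), seed=11)
    lam1, t1 = select_lambda(X, cfg)
    lam2, t2 = select_lambda(X, cfg)
    assert lam1 == lam2
    assert np.array_equal(t1["cv_mse"], t2["cv_mse"])


def test_select_lambda_positive_under_contamination():
    """Outliers of the planted form inflate held-out error at λ=0."""
    chosen_positive = 0
    n_rep = 50
    for rep in range(n_rep):
        ds = generate_dataset(
            SimulationConfig(
                design="no_class", p=50, n=30, missing_rate=0.02,
                outlier_rate=0.10, seed=5000 + rep,
            )
        )
        cfg = KernelWeightConfig(lam_grid=(0.0, 0.5, 2.0), seed=rep)
        lam, _ = select_lambda(ds.annotated(), cfg)
        chosen_positive += lam > 0
    assert chosen_positive >= 0.9 * n_rep


# ---------------------------------------------------------------------------
# full imputation
# ---------------------------------------------------------------------------


def test_impute_identity_when_nothing_to_replace():
    X = matrix(np.full((5, 4), 3.25))  # complete, no IQR flag possible
    res = impute_kmi(X, KernelWeightConfig(lam=0.0))
    assert np.array_equal(res.reconstructed, X.values)
    assert res.outlier_mask.sum() == 0 and res.imputed_mask.sum() == 0


def test_impute_exact_recovery_rank1_missing(rng):
    true = np.outer(rng.uniform(1, 3, 15), rng.uniform(1, 3, 12))
    mask = rng.random(true.shape) < 0.2
    obs = true.copy()
    obs[mask] = np.nan
    res = impute_kmi(AnnotatedMatrix(obs), KernelWeightConfig(lam=0.0, **TIGHT))
    assert np.abs(res.reconstructed - true)[mask].max() < 1e-6
    np.testing.assert_array_equal(res.imputed_mask, mask)


def test_impute_replaces_planted_extreme_cell_only():
    rows = [[1, 2, 3, 4, 100]] + [[1, 2, 3, 4, 5]] * 4
    X = matrix(rows)
    res = impute_kmi(X, KernelWeightConfig(lam=1.0))
    assert res.outlier_mask[0, 4] and res.outlier_mask.sum() == 1
    untouched = ~(res.outlier_mask | res.imputed_mask)
    assert np.array_equal(res.reconstructed[untouched], X.values[untouched])
    assert res.reconstructed[0, 4] != 100.0


def test_impute_errors_on_dead_row():
    X = matrix([[NA, NA, NA], [1, 2, 3]], metabolite_ids=["bad", "ok"])
    with pytest.raises(ValueError, match="bad"):
        impute_kmi(X, KernelWeightConfig(lam=0.0))


def test_groupwise_identical_blocks_get_identical_reconstructions(rng):
    block = rng.normal(loc=7, size=(10, 6))
    block[rng.random(block.shape) < 0.1] = np.nan
    X = AnnotatedMatrix(
        np.hstack([block, block]),
        groups=["a"] * 6 + ["b"] * 6,
    )
    res = impute_groupwise(X, KernelWeightConfig(lam_grid=(0.0, 1.0), seed=4))
    np.testing.assert_array_equal(
        res.reconstructed[:, :6], res.reconstructed[:, 6:]
    )
    assert res.lam_used["a"] == res.lam_used["b"]


def test_groupwise_single_group_equals_plain(rng):
    vals = rng.normal(loc=7, size=(8, 6))
    vals[rng.random(vals.shape) < 0.1] = np.nan
    cfg = KernelWeightConfig(lam=0.5, seed=9)
    res_g = impute_groupwise(AnnotatedMatrix(vals, groups=["g"] * 6), cfg)
    res_p = impute_kmi(AnnotatedMatrix(vals), cfg)
    np.testing.assert_array_equal(res_g.reconstructed, res_p.reconstructed)


def test_groupwise_untouched_cells_bit_identical():
    ds = generate_dataset(SimulationConfig(p=40, n=20, seed=77, outlier_rate=0.05))
    X = ds.annotated()
    res = impute_groupwise(X, KernelWeightConfig(lam=2.0, seed=77))
    keep = ~(res.imputed_mask | res.outlier_mask)
    assert np.array_equal(res.reconstructed[keep], X.values[keep])
    assert not np.isnan(res.reconstructed).any()


def test_groupwise_errors_on_group_dead_row():
    vals = np.full((4, 6), 5.0)
    vals[0, :3] = np.nan  # metabolite 0 unobserved in group 'a'
    X = AnnotatedMatrix(vals, metabolite_ids=["m0", "m1", "m2", "m3"],
                        groups=["a"] * 3 + ["b"] * 3)
    with pytest.raises(ValueError, match="a.*m0"):
        impute_groupwise(X, KernelWeightConfig(lam=0.0))


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_non_destructiveness_property(seed):
    """Cells neither missing nor IQR-flagged come back bit-identical."""
    rng = np.random.default_rng(seed)
    vals = rng.normal(loc=8, scale=2, size=(8, 7))
    vals[rng.random(vals.shape) < 0.15] = np.nan
    if np.isnan(vals).all(axis=1).any() or np.isnan(vals).all(axis=0).any():
        return
    X = AnnotatedMatrix(vals.copy())
    res = impute_kmi(X, KernelWeightConfig(lam=1.0))
    keep = ~(res.imputed_mask | res.outlier_mask)
    assert np.array_equal(res.reconstructed[keep], vals[keep])
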