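"""Reference imputation baselines and a plug-in adapter registry.

The trivial baselines (zero, per-metabolite mean / median / half-minimum)
fill missing cells only: unlike the kernel-weighted method they never touch
outlying observed cells, which is exactly the contrast the benchmark probes.
External imputers (e.g. kNN) plug in through the adapter registry and are
contract-checked rather than re-implemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .core import AnnotatedMatrix

__all__ = [
    "BaselineSpec",
    "impute_zero",
    "impute_row_statistic",
    "impute_baseline",
    "register_adapter",
    "run_adapter",
    "list_adapters",
]

BASELINE_METHODS = ("zero", "mean", "median", "halfmin")


@dataclass
class BaselineSpec:
    method: Literal["zero", "mean", "median", "halfmin", "external"]
    external_name: str | None = None

    def __post_init__(self) -> None:
        if self.method not in BASELINE_METHODS + ("external",):
            raise ValueError(f"unknown baseline method {self.method!r}")
        if self.method == "external" and not self.external_name:
            raise ValueError("external baseline needs external_name")


def impute_zero(X: AnnotatedMatrix) -> np.ndarray:
    """Replace every missing cell by zero."""
    return np.where(X.missing_mask, 0.0, X.values)


def impute_row_statistic(
    X: AnnotatedMatrix, statistic: Literal["mean", "median", "halfmin"]
) -> np.ndarray:
    """Fill missing cells with a per-metabolite statistic of the observed cells.

    ``mean`` / ``median`` / ``halfmin`` (half of the row minimum).  Raises,
    naming the metabolite, if a row has no observed value.
    """
    if statistic not in ("mean", "median", "halfmin"):
        raise ValueError(f"unknown row statistic {statistic!r}")
    dead = X.missing_mask.all(axis=1)
    if dead.any():
        i = int(np.argmax(dead))
        raise ValueError(
            f"metabolite {X.metabolite_ids[i]!r} has no observed values"
        )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if statistic == "mean":
            fill = np.nanmean(X.values, axis=1)
        elif statistic == "median":
            fill = np.nanmedian(X.values, axis=1)
        else:
            fill = np.nanmin(X.values, axis=1) / 2.0
    return np.where(X.missing_mask, fill[:, None], X.values)


# ---------------------------------------------------------------------------
# Adapter registry for external imputers
# ---------------------------------------------------------------------------

_ADAPTERS: dict[str, tuple[Callable[[AnnotatedMatrix], np.ndarray], bool]] = {}


def register_adapter(
    name: str,
    fn: Callable[[AnnotatedMatrix], np.ndarray],
    modifies_observed: bool = False,
) -> None:
    """Register an external imputer ``fn(X) -> full matrix`` under ``name``.

    ``modifies_observed`` declares that the adapter may alter observed cells
    (the contract check is relaxed accordingly).
    """
    _ADAPTERS[name] = (fn, modifies_observed)


def list_adapters() -> list[str]:
    return sorted(_ADAPTERS)


def run_adapter(X: AnnotatedMatrix, spec: BaselineSpec | str) -> np.ndarray:
    """Run a registered adapter and validate its output contract.

    The output must have the input shape, contain no missing value, and —
    unless the adapter declares otherwise — leave observed cells unchanged.
    """
    name = spec if isinstance(spec, str) else spec.external_name
    if name not in _ADAPTERS:
        raise KeyError(f"no adapter registered under {name!r}")
    fn, modifies_observed = _ADAPTERS[name]
    out = np.asarray(fn(X), dtype=float)
    if out.shape != X.shape:
        raise ValueError(
            f"adapter {name!r} returned shape {out.shape}, expected {X.shape}"
        )
    if np.isnan(out).any():
        raise ValueError(f"adapter {name!r} left missing cells in its output")
    if not modifies_observed:
        obs = ~X.missing_mask
        if not np.array_equal(out[obs], X.values[obs]):
            raise ValueError(f"adapter {name!r} modified observed cells")
    return out


def _knn_adapter_factory(k: int = 10) -> Callable[[AnnotatedMatrix], np.ndarray]:
    """kNN imputation over metabolite rows via scikit-learn's KNNImputer."""

    def _impute(X: AnnotatedMatrix) -> np.ndarray:
        from sklearn.impute import KNNImputer

        imp = KNNImputer(n_neighbors=k)
        # metabolites as observations: neighbours are similar metabolites
        return imp.fit_transform(np.where(X.missing_mask, np.nan, X.values))

    return _impute


register_adapter("knn", _knn_adapter_factory())


def impute_baseline(X: AnnotatedMatrix, method: str) -> np.ndarray:
    """Dispatch a baseline by name; adapter names are resolved last."""
    if method == "zero":
        return impute_zero(X)
    if method in ("mean", "median", "halfmin"):
        return impute_row_statistic(X, method)
    return run_adapter(X, method)
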