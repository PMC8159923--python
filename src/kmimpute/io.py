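"""Delimited-text round-tripping for intensity matrices and group files.

Matrices are CSV/TSV with metabolite IDs in the first column and sample IDs
in the header row; an empty cell, ``NA`` or ``NaN`` marks a missing value.
Numeric output uses ``repr`` round-trip precision so write→read is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AnnotatedMatrix, ImputationResult

__all__ = ["read_matrix", "read_groups", "write_matrix", "write_diagnostics"]

_MISSING_TOKENS = ["", "NA", "NaN", "nan"]


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_matrix(
    path: str | Path,
    sep: str | None = None,
    transpose: bool = False,
    groups: "pd.Series | None" = None,
) -> AnnotatedMatrix:
    """Read a metabolite × sample matrix; missing tokens become the mask.

    Rejects ragged rows, duplicate metabolite/sample IDs and non-numeric
    cells (other than the missing tokens).  ``transpose=True`` reads a
    samples × metabolites file.
    """
    path = Path(path)
    sep_char = _sep_for(path, sep)
    # pandas pads short rows with NaN, which would masquerade as missing cells
    with open(path) as fh:
        n_fields = None
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            count = line.rstrip("\n").count(sep_char) + 1
            if n_fields is None:
                n_fields = count
            elif count != n_fields:
                raise ValueError(
                    f"ragged file {path}: line {lineno} has {count} fields, "
                    f"expected {n_fields}"
                )
    df = pd.read_csv(
        path,
        sep=sep_char,
        index_col=0,
        na_values=_MISSING_TOKENS,
        keep_default_na=False,
        dtype=str,
    )
    if transpose:
        df = df.T
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate metabolite ID {dup!r} in {path}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate sample ID {dup!r} in {path}")
    try:
        values = df.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc

    group_vec = None
    if groups is not None:
        missing_samples = [s for s in df.columns if s not in groups.index]
        if missing_samples:
            raise ValueError(f"no group label for samples {missing_samples}")
        group_vec = [groups.loc[s] for s in df.columns]
    return AnnotatedMatrix(
        values=values,
        metabolite_ids=list(df.index.astype(str)),
        sample_ids=list(df.columns.astype(str)),
        groups=group_vec,
    )


def read_groups(path: str | Path, sep: str | None = None) -> pd.Series:
    """Read a two-column (sample_id, group) file into a Series."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"group file {path} needs two columns (sample_id, group)")
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)
    if s.index.duplicated().any():
        raise ValueError(f"duplicate sample ID in group file {path}")
    return s


def write_matrix(
    X: "AnnotatedMatrix | np.ndarray",
    path: str | Path,
    sep: str | None = None,
    metabolite_ids=None,
    sample_ids=None,
) -> None:
    """Write a matrix (masked cells rendered as ``NA``) preserving order."""
    path = Path(path)
    if isinstance(X, AnnotatedMatrix):
        df = X.to_dataframe()
    else:
        df = pd.DataFrame(np.asarray(X, dtype=float),
                          index=metabolite_ids, columns=sample_ids)
    df.to_csv(path, sep=_sep_for(path, sep), na_rep="NA", index_label="metabolite")


def write_diagnostics(result: ImputationResult, path: str | Path) -> None:
    """JSON sidecar: λ and rank used, iteration counts, cell tallies."""

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items() if k != "cv_table"}
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, list):
            return [_clean(v) for v in obj]
        return obj

    payload = {
        "lam_used": _clean(result.lam_used),
        "rank_used": _clean(result.rank_used),
        "n_imputed": int(result.imputed_mask.sum()),
        "n_outliers": int(result.outlier_mask.sum()),
        "diagnostics": _clean(result.diagnostics),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
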