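"""Normalization and kernel Gram matrix construction.

Each measurement domain (e.g. scRNA-seq expression, scMethyl-seq methylation
rates) enters the alignment only through an n_samples x n_samples similarity
(Gram) matrix computed with a positive definite kernel.  The default pipeline
z-scores every feature across cells and takes inner products of the
standardized rows ("linear kernel"); arbitrary user-supplied positive definite
kernels (graph, string, ...) can be loaded from delimited text instead.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "z_normalize",
    "linear_kernel",
    "load_matrix",
    "load_kernel",
    "validate_kernel",
]

#: symmetry tolerance above which :func:`load_kernel` warns
ASYMMETRY_WARN = 1e-6


def _as_values(X) -> tuple[np.ndarray, pd.Index | None]:
    """Return a float ndarray view of ``X`` plus its row index if it has one."""
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), X.index
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {arr.shape}")
    return arr, None


def z_normalize(X, *, axis: str = "features", ddof: int = 0):
    """Standardize ``X`` so each feature has mean 0 and unit standard deviation.

    Standardization uses the population (1/n) standard deviation by default.
    Zero-variance features (constant genes are common after filtering real
    single-cell matrices) are mapped to all-zero columns with a warning rather
    than raising.

    Parameters
    ----------
    X : array-like or DataFrame of shape (n_samples, n_features)
        Observed data, cells as rows.
    axis : {"features", "samples"}
        ``"features"`` (default) standardizes each column across cells;
        ``"samples"`` standardizes each row across its features.
    ddof : int
        Delta degrees of freedom for the standard deviation; 0 (population)
        by default.

    Returns
    -------
    Standardized matrix of the same type (DataFrame in, DataFrame out).
    """
    values, index = _as_values(X)
    if values.size == 0:
        raise ValueError("cannot z-normalize an empty matrix")
    if np.isnan(values).any():
        raise ValueError("input contains NaN values; impute or filter first")
    if axis not in ("features", "samples"):
        raise ValueError(f"axis must be 'features' or 'samples', got {axis!r}")
    if values.shape[0] < 2 and axis == "features":
        raise ValueError("need at least 2 samples to standardize features")

    along = 0 if axis == "features" else 1
    mean = values.mean(axis=along, keepdims=True)
    sd = values.std(axis=along, ddof=ddof, keepdims=True)
    zero = sd == 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance {axis[:-1]}(s) set to all-zero",
            UserWarning,
            stacklevel=2,
        )
    Z = (values - mean) / np.where(zero, 1.0, sd)
    Z = np.where(np.broadcast_to(zero, Z.shape), 0.0, Z)
    if isinstance(X, pd.DataFrame):
        return pd.DataFrame(Z, index=X.index, columns=X.columns)
    return Z


def linear_kernel(Xz, *, scale: str | None = None) -> np.ndarray:
    """Inner products of the rows of ``Xz``: ``K[i, j] = <x_i, x_j>``.

    Applied to z-scored data this is (up to a factor n_features) the matrix of
    Pearson correlations between cells.  With ``scale="features"`` the inner
    product is averaged over features, which keeps the Gram matrix on an O(1)
    scale independent of how many genes were measured — the convention the
    high-level pipeline uses so the objective's three terms stay comparable.

    The result is symmetrized (averaged with its transpose) to wash out
    floating-point asymmetry.
    """
    values, _ = _as_values(Xz)
    if np.isnan(values).any():
        raise ValueError("input contains NaN values")
    K = values @ values.T
    if scale == "features":
        K = K / values.shape[1]
    elif scale is not None:
        raise ValueError(f"scale must be None or 'features', got {scale!r}")
    return (K + K.T) / 2.0


def _looks_numeric(token) -> bool:
    try:
        value = float(token)
    except (TypeError, ValueError):
        return False
    return value == value  # a blank cell (NaN) is not a numeric label


def load_matrix(path) -> pd.DataFrame:
    """Read a delimited text matrix (TSV/CSV, delimiter sniffed).

    An optional header row and an optional leading row-label column are
    auto-detected: a row/column counts as labels when any of its cells (other
    than the shared corner cell) is non-numeric.  Row order defines sample
    order.  NaNs and duplicated sample ids raise.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str,
                      comment="#", skip_blank_lines=True)
    if raw.empty:
        raise ValueError(f"{path}: empty matrix")
    def _is_label(v) -> bool:
        # label cells are non-numeric, non-blank text; a blank is missing data
        return not _looks_numeric(v) and not pd.isna(v)

    corner = raw.iloc[0, 0]
    corner_numeric = _looks_numeric(corner)
    row_rest = raw.shape[1] > 1 and any(_is_label(v) for v in raw.iloc[0, 1:])
    col_rest = raw.shape[0] > 1 and any(_is_label(v) for v in raw.iloc[1:, 0])
    # The corner cell disambiguates files whose labels are themselves numeric:
    # a non-numeric corner above an all-numeric id column means "header plus
    # index" when it is a conventional index name (or blank, pandas style).
    corner_is_index_name = not corner_numeric and (
        pd.isna(corner)
        or str(corner).strip().lower() in {"", "sample_id", "id", "index", "cell_id"}
    )
    has_header = row_rest or (not corner_numeric and not col_rest)
    has_index = col_rest or corner_is_index_name
    r0 = 1 if has_header else 0
    c0 = 1 if has_index else 0
    try:
        values = raw.iloc[r0:, c0:].to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric entries in matrix body: {exc}") from None
    if np.isnan(values).any():
        raise ValueError(f"{path}: matrix contains missing values")
    if has_index:
        index = pd.Index(raw.iloc[r0:, 0].astype(str), name="sample_id")
    else:
        index = pd.RangeIndex(values.shape[0])
    if index.has_duplicates:
        raise ValueError(f"{path}: duplicated sample ids")
    if has_header:
        columns = pd.Index(raw.iloc[0, c0:].astype(str))
    else:
        columns = pd.RangeIndex(values.shape[1])
    return pd.DataFrame(values, index=index, columns=columns)


def load_kernel(path) -> pd.DataFrame:
    """Read a precomputed square kernel matrix from delimited text.

    Symmetry is enforced by averaging with the transpose; if the maximum
    asymmetry exceeds ``ASYMMETRY_WARN`` a warning reports it first.
    Non-square input is a format error.
    """
    df = load_matrix(path)
    n, m = df.shape
    if n != m:
        raise ValueError(f"{path}: kernel matrix must be square, got {n}x{m}")
    K = df.to_numpy(dtype=float)
    asym = float(np.abs(K - K.T).max()) if n else 0.0
    if asym > ASYMMETRY_WARN:
        warnings.warn(
            f"{path}: kernel asymmetry {asym:.3g} exceeds {ASYMMETRY_WARN:.0e}; "
            "symmetrizing by averaging with the transpose",
            UserWarning,
            stacklevel=2,
        )
    K = (K + K.T) / 2.0
    return pd.DataFrame(K, index=df.index, columns=df.columns)


def validate_kernel(K, *, name: str = "K", check_psd: bool = False) -> np.ndarray:
    """Validate a Gram matrix: square, finite, symmetric within 1e-8.

    ``check_psd=True`` additionally eigendecomposes the matrix and warns if the
    smallest eigenvalue is below ``-1e-8 * max eigenvalue`` (full check is
    O(n^3), so it is opt-in).
    """
    arr = np.asarray(K, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite entries")
    if np.abs(arr - arr.T).max() > 1e-8:
        raise ValueError(f"{name} is not symmetric within 1e-8")
    arr = (arr + arr.T) / 2.0
    if check_psd:
        eigvals = np.linalg.eigvalsh(arr)
        if eigvals[0] < -1e-8 * max(eigvals[-1], 1.0):
            warnings.warn(
                f"{name} is not positive semidefinite "
                f"(min eigenvalue {eigvals[0]:.3g})",
                UserWarning,
                stacklevel=2,
            )
    return arr
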