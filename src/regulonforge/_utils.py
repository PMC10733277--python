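"""Small shared helpers: normalization, sparse handling, errors, logging."""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger("regulonforge")


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is infeasible."""


class DegenerateInputError(ValueError):
    """Raised when an input is too small or ill-formed for the operation."""


def as_dense(X) -> np.ndarray:
    """Return a dense 2-D float array view of a matrix (sparse or dense)."""
    if sp.issparse(X):
        return np.asarray(X.todense(), dtype=float)
    return np.asarray(X, dtype=float)


def lognorm(counts, target_sum: float = 1e4) -> np.ndarray:
    """Library-size normalize counts (cells x features) to ``target_sum`` and log1p.

    Cells with zero total counts are left at zero (they carry no information
    and would otherwise divide by zero).
    """
    X = as_dense(counts)
    totals = X.sum(axis=1)
    scale = np.where(totals > 0, target_sum / np.maximum(totals, 1e-12), 0.0)
    return np.log1p(X * scale[:, None])


def delog(X_norm: np.ndarray) -> np.ndarray:
    """Invert log1p to the normalized-count scale."""
    return np.expm1(X_norm)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs propagate as NaN)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    adj = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return adj


def pearson_columns(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r between vector ``x`` and each column of ``Y``.

    Constant columns (or constant ``x``) yield NaN.
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    sx = np.sqrt((xc**2).sum())
    sY = np.sqrt((Yc**2).sum(axis=0))
    denom = sx * sY
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ Yc) / denom
    r[denom == 0] = np.nan
    if sx == 0:
        r[:] = np.nan
    return r
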