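"""Per-cell motif activity (deviation z-scores) and activator/repressor calls.

The deviation of a motif in a cell is the relative excess of fragment counts
in the motif's peaks over the expectation from the cell's sequencing depth and
the peaks' global share of counts.  Each motif is standardized against
deviations of GC- and accessibility-matched background peak sets, yielding a
z-score per cell.  TF-motif pairs are then classified by the Spearman
correlation between TF expression and motif activity at the single-cell
level: activator if rho > 0.05, repressor if rho < -0.05, strict on both
sides; everything in between is discarded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata
from sklearn.neighbors import NearestNeighbors

from ._utils import DegenerateInputError, as_dense, logger

#: strict Spearman-correlation cutoffs for activator / repressor calls
RHO_ACTIVATOR = 0.05
RHO_REPRESSOR = -0.05

#: peaks per matching neighborhood and background sets sampled per peak
N_NEIGHBORS = 50
N_BACKGROUND = 50


def match_background_peaks(
    peak_gc: np.ndarray,
    peak_mean_access: np.ndarray,
    n_background: int = N_BACKGROUND,
    seed: int = 0,
    n_neighbors: int = N_NEIGHBORS,
) -> np.ndarray:
    """Sample GC/accessibility-matched background peaks for every peak.

    Peaks are embedded in standardized (GC, mean accessibility) space; for
    each peak, ``n_background`` indices are drawn with replacement from its
    ``n_neighbors`` nearest peaks (self included).  Returns an integer array
    (n_peaks x n_background).
    """
    gc = np.asarray(peak_gc, dtype=float)
    acc = np.asarray(peak_mean_access, dtype=float)
    if gc.ndim != 1 or gc.shape != acc.shape:
        raise DegenerateInputError("peak_gc and peak_mean_access must be equal-length 1-D")
    if np.any((gc < 0) | (gc > 1)):
        raise DegenerateInputError("GC fractions must lie in [0, 1]")
    if n_background < 1:
        raise DegenerateInputError("n_background must be >= 1")
    n_peaks = len(gc)
    k = min(n_neighbors, n_peaks)
    if n_peaks < 2:
        raise DegenerateInputError("background matching needs at least 2 peaks")

    feats = np.column_stack([gc, acc])
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    feats = (feats - feats.mean(axis=0)) / sd
    nn = NearestNeighbors(n_neighbors=k).fit(feats)
    _, idx = nn.kneighbors(feats)
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, k, size=(n_peaks, n_background))
    return idx[np.arange(n_peaks)[:, None], pick]


def _raw_deviations(counts, peak_sets: list[np.ndarray]) -> np.ndarray:
    """(observed - expected) / expected per cell for each peak set.

    expected_i = total_i * (set's share of all-cell counts); returns
    cells x len(peak_sets).
    """
    X = sp.csr_matrix(counts) if not sp.issparse(counts) else counts.tocsr()
    totals = np.asarray(X.sum(axis=1)).ravel()
    col_totals = np.asarray(X.sum(axis=0)).ravel()
    grand = col_totals.sum()
    out = np.empty((X.shape[0], len(peak_sets)))
    Xc = X.tocsc()
    for j, pset in enumerate(peak_sets):
        share = col_totals[pset].sum() / grand
        obs = np.asarray(Xc[:, pset].sum(axis=1)).ravel()
        exp = totals * share
        out[:, j] = (obs - exp) / exp
    return out


def compute_deviations(
    peak_matrix,
    motif_hits: pd.DataFrame,
    backgrounds: np.ndarray,
) -> pd.DataFrame:
    """Motif deviation z-scores per cell (cells x motifs DataFrame).

    ``peak_matrix`` is an AnnData of capped fragment counts; ``motif_hits``
    needs columns ``motif`` and ``peak``.  For each motif the raw deviation is
    standardized by the mean/sd of deviations over ``backgrounds.shape[1]``
    background peak sets (per-peak matched indices from
    :func:`match_background_peaks`).  Cells with zero total counts are an
    error; motifs whose peaks are all absent from the matrix are dropped with
    a warning.
    """
    X = peak_matrix.X
    X = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr()
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        bad = peak_matrix.obs_names[np.nonzero(totals == 0)[0][0]]
        raise DegenerateInputError(
            f"cell {bad!r} has zero total counts; deviations are undefined"
        )
    peak_index = {p: i for i, p in enumerate(peak_matrix.var_names)}
    n_bg = backgrounds.shape[1]

    motif_names, cols = [], []
    for motif, sub in motif_hits.groupby("motif", sort=True):
        pset = np.unique([peak_index[p] for p in sub["peak"] if p in peak_index])
        if len(pset) == 0:
            logger.warning("compute_deviations: motif %s matched no peaks; dropped", motif)
            continue
        sets = [pset] + [np.unique(backgrounds[pset, b]) for b in range(n_bg)]
        devs = _raw_deviations(X, sets)
        raw = devs[:, 0]
        bg = devs[:, 1:]
        mu = bg.mean(axis=1)
        sd = bg.std(axis=1, ddof=1)
        sd[sd == 0] = 1.0
        motif_names.append(motif)
        cols.append((raw - mu) / sd)
    return pd.DataFrame(
        np.column_stack(cols) if cols else np.empty((X.shape[0], 0)),
        index=peak_matrix.obs_names,
        columns=motif_names,
    )


def raw_deviation(peak_matrix, peak_ids) -> np.ndarray:
    """Un-standardized deviation of one peak set per cell (exposed for tests
    and diagnostics)."""
    idx = {p: i for i, p in enumerate(peak_matrix.var_names)}
    pset = np.unique([idx[p] for p in peak_ids])
    return _raw_deviations(peak_matrix.X, [pset])[:, 0]


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with average ranks; NaN when either input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rx = rankdata(x)
    ry = rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def classify_role(rho: float) -> str | None:
    """Map a Spearman correlation to activator/repressor (strict cutoffs)."""
    if np.isnan(rho):
        return None
    if rho > RHO_ACTIVATOR:
        return "activator"
    if rho < RHO_REPRESSOR:
        return "repressor"
    return None


def classify_tf_motif_pairs(
    tf_expression: pd.DataFrame,
    activity: pd.DataFrame,
    tf_motif_map: pd.DataFrame,
) -> pd.DataFrame:
    """Classify TF-motif pairs as activators or repressors.

    ``tf_expression`` is cells x TFs normalized expression, ``activity`` the
    cells x motifs z-score matrix (shared cell order), ``tf_motif_map`` a
    DataFrame with columns ``tf`` and ``motif`` (name matching is exact but
    case-insensitive).  Pairs whose |rho| does not strictly exceed 0.05, or
    whose correlation is undefined, are absent from the output.
    """
    expr_cols = {c.lower(): c for c in tf_expression.columns}
    act_cols = {c.lower(): c for c in activity.columns}
    rows = []
    for pair in tf_motif_map.itertuples(index=False):
        tf_key, motif_key = pair.tf.lower(), pair.motif.lower()
        if tf_key not in expr_cols or motif_key not in act_cols:
            continue
        x = tf_expression[expr_cols[tf_key]].to_numpy()
        y = activity[act_cols[motif_key]].to_numpy()
        rho = spearman(x, y)
        if np.isnan(rho):
            logger.warning(
                "classify_tf_motif_pairs: constant input for (%s, %s); pair dropped",
                pair.tf, pair.motif,
            )
            continue
        role = classify_role(rho)
        if role is not None:
            rows.append({"tf": pair.tf, "motif": pair.motif, "rho": rho, "role": role})
    return pd.DataFrame(rows, columns=["tf", "motif", "rho", "role"])
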