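"""Differential and consensus feature calls, trajectory binning, k-means.

Differential expression uses a two-sided Wilcoxon rank-sum test per feature
with Benjamini-Hochberg adjustment; the fold change is
``log2((mu_A + 1) / (mu_B + 1))`` on de-logged normalized means.  Class rules
(strict inequalities throughout):

* DEG: |log2FC| > 0.25 (between the two injury conditions) or > 0.5 (injury
  vs development) with adj-p < 0.05, after removing mature-neuron markers.
* mature markers: per mature cell group vs rest in control cells,
  log2FC > 2 and adj-p < 0.05.
* CEG: log2FC > 0.5 and adj-p < 0.05 for the same group in BOTH datasets.
* DAR: |log2FC| > 0.25 and RAW p < 0.05 (the accessibility rule is the one
  call made on unadjusted p), restricted to peaks with >= 1 DEG target.
* CAR: log2FC > 0.25 and raw p < 0.05 in both datasets, restricted to peaks
  linked to CEGs.
* DM: |log2FC| > 0.25 and adj-p < 0.05 from a logistic-regression likelihood
  ratio test on motif z-scores, consistent with the TF's DEG call, keeping
  the highest-correlation motif per TF.
* CM: same thresholds in both datasets, restricted to CEG TFs, highest
  correlation kept.

Trajectory profiles are equal-frequency pseudotime bins (20-50), rolling-mean
smoothed and per-feature z-scaled before k-means clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from ._utils import DegenerateInputError, bh_adjust, delog, logger, lognorm

DEG_LFC = {"LD_vs_NMDA": 0.25, "injury_vs_dev": 0.5}
DEG_ADJ_P = 0.05
MATURE_LFC = 2.0
CEG_LFC = 0.5
DAR_LFC = 0.25
DAR_RAW_P = 0.05
CAR_LFC = 0.25
DM_LFC = 0.25


def wilcoxon_de(matrix: pd.DataFrame, group_a, group_b) -> pd.DataFrame:
    """Per-feature rank-sum test between two cell groups.

    ``matrix`` is cells x features of log1p-normalized values; ``group_a`` /
    ``group_b`` are disjoint boolean masks or positional indices.  Returns a
    DataFrame indexed by feature with ``log2fc`` (on de-logged means), ``p``
    (two-sided, tie-corrected asymptotic) and ``adj_p`` (BH).  Features
    constant across both groups get p = 1.
    """
    X = matrix.to_numpy(dtype=float)
    a = np.asarray(group_a)
    b = np.asarray(group_b)
    if a.dtype == bool:
        a = np.nonzero(a)[0]
    if b.dtype == bool:
        b = np.nonzero(b)[0]
    if len(a) == 0 or len(b) == 0:
        raise DegenerateInputError("both groups must be non-empty")
    if set(a) & set(b):
        raise DegenerateInputError("groups must be disjoint")
    Xa, Xb = X[a], X[b]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(Xa, Xb, axis=0, alternative="two-sided",
                                 method="asymptotic")
    p = np.asarray(res.pvalue, dtype=float)
    const = (Xa.max(axis=0) == Xa.min(axis=0)) & (Xb.max(axis=0) == Xb.min(axis=0)) \
        & (Xa[0] == Xb[0])
    p[const | ~np.isfinite(p)] = 1.0
    mu_a = delog(Xa).mean(axis=0)
    mu_b = delog(Xb).mean(axis=0)
    log2fc = np.log2((mu_a + 1.0) / (mu_b + 1.0))
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "adj_p": bh_adjust(p)}, index=matrix.columns
    )


def is_deg(log2fc, adj_p, comparison_kind: str) -> np.ndarray:
    """Strict DEG rule for one comparison kind."""
    if comparison_kind not in DEG_LFC:
        raise DegenerateInputError(f"unknown comparison_kind {comparison_kind!r}")
    thr = DEG_LFC[comparison_kind]
    return (np.abs(np.asarray(log2fc)) > thr) & (np.asarray(adj_p) < DEG_ADJ_P)


def call_degs(de: pd.DataFrame, comparison_kind: str, mature_markers: set[str]) -> set[str]:
    """DEGs from one group comparison, mature markers removed."""
    mask = is_deg(de["log2fc"].to_numpy(), de["adj_p"].to_numpy(), comparison_kind)
    return set(de.index[mask]) - set(mature_markers)


def call_mature_markers(control_expression, mature_groups) -> set[str]:
    """Markers of mature cell groups in control cells (log2FC > 2, adj-p < 0.05).

    ``control_expression`` is an AnnData of raw counts over control cells with
    ``cell_group`` in ``.obs``; the union over ``mature_groups`` is returned,
    missing groups skipped with a warning.
    """
    norm = pd.DataFrame(
        lognorm(control_expression.X),
        columns=control_expression.var_names,
        index=control_expression.obs_names,
    )
    groups = control_expression.obs["cell_group"].to_numpy()
    markers: set[str] = set()
    for g in mature_groups:
        mask = groups == g
        if mask.sum() == 0 or (~mask).sum() == 0:
            logger.warning("call_mature_markers: group %s absent from controls", g)
            continue
        de = wilcoxon_de(norm, mask, ~mask)
        hit = (de["log2fc"] > MATURE_LFC) & (de["adj_p"] < DEG_ADJ_P)
        markers |= set(de.index[hit])
    return markers


def call_consensus_features(
    tables_a: dict[str, pd.DataFrame],
    tables_b: dict[str, pd.DataFrame],
    modality: str,
    *,
    peak_targets: dict[str, list[str]] | None = None,
    cegs: set[str] | None = None,
    motif_tf_map: dict[str, str] | None = None,
    motif_correlations: dict[str, float] | None = None,
) -> set[str]:
    """Consensus features across two datasets (CEG / CAR / CM).

    ``tables_a`` / ``tables_b`` map cell group -> per-feature enrichment table
    (columns log2fc, p, adj_p from the group-vs-rest comparison within each
    dataset).  A feature is consensus iff it passes the modality threshold in
    BOTH datasets for the same group; CARs additionally need a CEG target
    (via ``peak_targets``), CMs a CEG TF with only the highest-correlation
    motif kept per TF.
    """
    if modality not in {"gene", "peak", "motif"}:
        raise DegenerateInputError(f"unknown modality {modality!r}")

    def passes(t: pd.DataFrame) -> pd.Series:
        if modality == "gene":
            return (t["log2fc"] > CEG_LFC) & (t["adj_p"] < DEG_ADJ_P)
        if modality == "peak":
            return (t["log2fc"] > CAR_LFC) & (t["p"] < DAR_RAW_P)
        return (t["log2fc"].abs() > DM_LFC) & (t["adj_p"] < DEG_ADJ_P)

    consensus: set[str] = set()
    for group, ta in tables_a.items():
        if group not in tables_b:
            logger.warning("call_consensus_features: group %s absent from one dataset", group)
            continue
        tb = tables_b[group]
        hits_a = set(ta.index[passes(ta)])
        hits_b = set(tb.index[passes(tb)])
        consensus |= hits_a & hits_b

    if modality == "peak" and peak_targets is not None:
        cegs = cegs or set()
        consensus = {p for p in consensus
                     if any(g in cegs for g in peak_targets.get(p, []))}
    if modality == "motif" and motif_tf_map is not None:
        cegs = cegs or set()
        consensus = {m for m in consensus if motif_tf_map.get(m) in cegs}
        if motif_correlations is not None:
            best: dict[str, str] = {}
            for m in sorted(consensus):
                tf = motif_tf_map[m]
                if tf not in best or abs(motif_correlations.get(m, 0.0)) > abs(
                    motif_correlations.get(best[tf], 0.0)
                ):
                    best[tf] = m
            consensus = set(best.values())
    return consensus


def is_dar(log2fc, p) -> np.ndarray:
    """Strict DAR rule on raw p (|log2FC| > 0.25, p < 0.05)."""
    return (np.abs(np.asarray(log2fc)) > DAR_LFC) & (np.asarray(p) < DAR_RAW_P)


def call_dars(
    de_peaks: dict[str, pd.DataFrame],
    degs: set[str],
    peak_targets: dict[str, list[str]],
) -> set[str]:
    """DARs: significant in >= 1 group comparison and with >= 1 DEG target."""
    dars: set[str] = set()
    for table in de_peaks.values():
        mask = is_dar(table["log2fc"].to_numpy(), table["p"].to_numpy())
        dars |= set(table.index[mask])
    return {p for p in dars if any(g in degs for g in peak_targets.get(p, []))}


def lr_test_motifs(
    activity: pd.DataFrame,
    group_a,
    group_b,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio test of group membership on each motif's z-score.

    Per motif, logistic regression of group-A membership on (score +
    covariates) is compared with the covariates-only model; the LRT statistic
    is chi-square with 1 df.  The fold change is computed on scores shifted by
    the global minimum + 1 (z-scores may be negative).  ``separation`` flags
    motifs where the full fit did not converge cleanly (quasi-separation); the
    deviance-based p is still reported.
    """
    import statsmodels.api as sm

    a = np.asarray(group_a)
    b = np.asarray(group_b)
    if a.dtype == bool:
        a = np.nonzero(a)[0]
    if b.dtype == bool:
        b = np.nonzero(b)[0]
    if len(a) == 0 or len(b) == 0:
        raise DegenerateInputError("both groups must be non-empty")
    idx = np.concatenate([a, b])
    y = np.concatenate([np.ones(len(a)), np.zeros(len(b))])
    X = activity.to_numpy(dtype=float)[idx]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        C = C[idx] if C.ndim == 1 else C[idx, :]
        C = C.reshape(len(idx), -1)
        base = np.column_stack([np.ones(len(idx)), C])
    else:
        base = np.ones((len(idx), 1))

    null_fit = sm.Logit(y, base).fit(disp=0, method="lbfgs", maxiter=200)
    shift = 1.0 - activity.to_numpy(dtype=float).min()
    rows = []
    for j, motif in enumerate(activity.columns):
        x = X[:, j]
        if np.all(x == x[0]):
            llf_full, converged = null_fit.llf, True
        else:
            full = sm.Logit(y, np.column_stack([base, x])).fit(
                disp=0, method="lbfgs", maxiter=200
            )
            llf_full, converged = full.llf, bool(full.mle_retvals.get("converged", True))
        lrt = max(2.0 * (llf_full - null_fit.llf), 0.0)
        p = float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
        mu_a = (x[y == 1] + shift).mean()
        mu_b = (x[y == 0] + shift).mean()
        rows.append({"motif": motif, "log2fc": float(np.log2(mu_a / mu_b)),
                     "p": p, "separation": not converged})
    out = pd.DataFrame(rows).set_index("motif")
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out


def call_dms(
    lr_results: pd.DataFrame,
    degs: set[str],
    motif_tf_map: dict[str, str],
    motif_correlations: dict[str, float] | None = None,
    deg_lfc: dict[str, float] | None = None,
) -> set[str]:
    """Differential motifs consistent with the DEG calls of their TFs.

    Requires |log2FC| > 0.25 and adj-p < 0.05; the motif's TF must itself be
    a DEG (and, when ``deg_lfc`` is given, change in the same direction).
    Per TF only the motif with the highest |correlation| is retained.
    """
    mask = (lr_results["log2fc"].abs() > DM_LFC) & (lr_results["adj_p"] < DEG_ADJ_P)
    hits = [m for m in lr_results.index[mask] if motif_tf_map.get(m) in degs]
    if deg_lfc is not None:
        hits = [
            m for m in hits
            if np.sign(lr_results.loc[m, "log2fc"]) == np.sign(deg_lfc.get(motif_tf_map[m], 0.0))
        ]
    if motif_correlations is None:
        return set(hits)
    best: dict[str, str] = {}
    for m in sorted(hits):
        tf = motif_tf_map[m]
        if tf not in best or abs(motif_correlations.get(m, 0.0)) > abs(
            motif_correlations.get(best[tf], 0.0)
        ):
            best[tf] = m
    return set(best.values())


@dataclass
class TrajectoryBins:
    """Equal-frequency pseudotime bins with smoothed, z-scaled profiles.

    ``binned`` holds raw per-bin feature means (features x bins); ``scaled``
    the rolling-mean-smoothed, per-feature z-scored profiles used for
    clustering and heatmaps.  Constant profiles are exempt from scaling and
    flagged in ``constant_mask``.
    """

    feature_names: list[str]
    binned: np.ndarray
    scaled: np.ndarray
    constant_mask: np.ndarray
    n_bins: int
    smooth_window: int


def bin_pseudotime(
    pseudotime: np.ndarray,
    profiles: pd.DataFrame,
    n_bins: int = 30,
    smooth_window: int = 3,
) -> TrajectoryBins:
    """Bin features along pseudotime into 20-50 equal-frequency bins."""
    pt = np.asarray(pseudotime, dtype=float)
    if not np.all(np.isfinite(pt)):
        raise DegenerateInputError("pseudotime must be finite")
    if not 20 <= n_bins <= 50:
        raise DegenerateInputError("n_bins must be in [20, 50]")
    if len(pt) < n_bins:
        raise DegenerateInputError("fewer cells than bins")
    X = profiles.to_numpy(dtype=float)
    order = np.argsort(pt, kind="stable")
    splits = np.array_split(order, n_bins)
    binned = np.column_stack([X[s].mean(axis=0) for s in splits])  # features x bins
    smoothed = (
        pd.DataFrame(binned)
        .T.rolling(window=smooth_window, center=True, min_periods=1)
        .mean()
        .T.to_numpy()
    )
    mu = smoothed.mean(axis=1, keepdims=True)
    sd = smoothed.std(axis=1, keepdims=True)
    constant = sd.ravel() == 0
    sd[sd == 0] = 1.0
    scaled = (smoothed - mu) / sd
    scaled[constant] = 0.0
    return TrajectoryBins(
        feature_names=list(profiles.columns),
        binned=binned,
        scaled=scaled,
        constant_mask=constant,
        n_bins=n_bins,
        smooth_window=smooth_window,
    )


def kmeans_cluster_profiles(bins: TrajectoryBins, k: int, seed: int = 0) -> dict[str, int]:
    """k-means on scaled binned profiles; feature -> cluster id."""
    n_features = len(bins.feature_names)
    if k < 1 or k > n_features:
        raise DegenerateInputError("k must be in [1, n_features]")
    km = KMeans(n_clusters=k, n_init=20, random_state=seed)
    labels = km.fit_predict(bins.scaled)
    return dict(zip(bins.feature_names, labels.tolist()))
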