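"""Peak categorization and correlation-based peak-to-gene linking.

Peaks are classified against gene annotation with priority promoter >
gene_body > intergenic: promoter when the peak intersects TSS +/- 500 bp,
gene_body when it intersects a gene-body interval, intergenic otherwise.
Candidate targets are the overlapped gene(s) for promoter/gene-body peaks and
every gene whose TSS lies within 200 kb of the peak center for intergenic
peaks.  Candidate pairs are then tested by Pearson correlation of normalized
accessibility and expression across metacells (k-means groups in a combined
reduced space); links are retained when |r| > 0.25 and BH FDR < 0.01, both
strict.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import TruncatedSVD

from ._utils import DegenerateInputError, as_dense, bh_adjust, logger, lognorm
from .types import GenomeAnnotation, PeakSet

#: strict retention thresholds for peak-to-gene links
LINK_MIN_ABS_R = 0.25
LINK_MAX_FDR = 0.01

#: promoter window half-width around the TSS (bases)
PROMOTER_HALFWIDTH = 500

#: maximum peak-center-to-TSS distance for intergenic candidates (bases)
INTERGENIC_MAX_DIST = 200_000

DEFAULT_N_METACELLS = 100


def link_retained(r: np.ndarray, fdr: np.ndarray) -> np.ndarray:
    """Strict |r| > 0.25 and FDR < 0.01 retention rule."""
    return (np.abs(r) > LINK_MIN_ABS_R) & (np.asarray(fdr) < LINK_MAX_FDR)


def categorize_peaks(peaks: PeakSet, genes: GenomeAnnotation) -> pd.DataFrame:
    """Assign each peak a category and candidate target genes.

    Returns a DataFrame indexed like the peak set with columns ``category``
    (promoter / gene_body / intergenic) and ``targets`` (list of gene
    symbols).  Peaks on chromosomes absent from the annotation become
    intergenic with no candidates (logged).
    """
    promoter_trees: dict[str, IntervalTree] = {}
    body_trees: dict[str, IntervalTree] = {}
    tss_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in genes.df.groupby("chrom"):
        ptree, btree = IntervalTree(), IntervalTree()
        for g, row in sub.iterrows():
            # promoter window is TSS +/- 500 inclusive -> half-open end + 1
            ptree.addi(row["tss"] - PROMOTER_HALFWIDTH, row["tss"] + PROMOTER_HALFWIDTH + 1, g)
            if row["body_end"] > row["body_start"]:
                btree.addi(row["body_start"], row["body_end"], g)
        promoter_trees[chrom] = ptree
        body_trees[chrom] = btree
        order = np.argsort(sub["tss"].to_numpy())
        tss_by_chrom[chrom] = (sub["tss"].to_numpy()[order], sub.index.to_numpy()[order])

    missing_chroms = set()
    cats, targets = [], []
    for peak, row in peaks.df.iterrows():
        chrom, start, end = row["chrom"], row["start"], row["end"]
        if chrom not in promoter_trees:
            missing_chroms.add(chrom)
            cats.append("intergenic")
            targets.append([])
            continue
        hit = promoter_trees[chrom].overlap(start, end)
        if hit:
            cats.append("promoter")
            targets.append(sorted(iv.data for iv in hit))
            continue
        hit = body_trees[chrom].overlap(start, end)
        if hit:
            cats.append("gene_body")
            targets.append(sorted(iv.data for iv in hit))
            continue
        center = (start + end) // 2
        tss, names = tss_by_chrom[chrom]
        lo = np.searchsorted(tss, center - INTERGENIC_MAX_DIST, side="left")
        hi = np.searchsorted(tss, center + INTERGENIC_MAX_DIST, side="right")
        cand = [names[i] for i in range(lo, hi) if abs(tss[i] - center) <= INTERGENIC_MAX_DIST]
        cats.append("intergenic")
        targets.append(sorted(cand))
    if missing_chroms:
        logger.warning("categorize_peaks: chromosomes absent from annotation: %s",
                       sorted(missing_chroms))
    return pd.DataFrame({"category": cats, "targets": targets}, index=peaks.df.index)


def multiome_embedding(rna, atac, n_dims: int = 30, seed: int = 0) -> np.ndarray:
    """Combined reduced space: truncated SVD of log-normalized RNA
    concatenated with TF-IDF + SVD of ATAC, columns standardized.

    ``rna`` / ``atac`` are count AnnData objects over the same cells; returns
    cells x ``n_dims``.
    """
    half = n_dims // 2
    Xr = lognorm(rna.X)
    svd_r = TruncatedSVD(n_components=min(half, Xr.shape[1] - 1), random_state=seed)
    Er = svd_r.fit_transform(Xr)

    Xa = as_dense(atac.X)
    tf = Xa / np.maximum(Xa.sum(axis=1, keepdims=True), 1e-12)
    idf = np.log1p(Xa.shape[0] / np.maximum((Xa > 0).sum(axis=0), 1))
    Xa = tf * idf[None, :]
    svd_a = TruncatedSVD(n_components=min(n_dims - half, Xa.shape[1] - 1), random_state=seed)
    Ea = svd_a.fit_transform(Xa)

    E = np.column_stack([Er, Ea])
    sd = E.std(axis=0)
    sd[sd == 0] = 1.0
    return (E - E.mean(axis=0)) / sd


def make_metacells(embedding: np.ndarray, n_groups: int = DEFAULT_N_METACELLS,
                   seed: int = 0) -> np.ndarray:
    """k-means partition of cells into metacell groups; returns labels."""
    embedding = np.asarray(embedding, dtype=float)
    if embedding.ndim != 2 or embedding.shape[1] < 1:
        raise DegenerateInputError("embedding must be cells x dims with dims >= 1")
    if n_groups > embedding.shape[0]:
        raise DegenerateInputError("n_groups exceeds the number of cells")
    km = KMeans(n_clusters=n_groups, n_init=10, random_state=seed)
    return km.fit_predict(embedding)


def aggregate_by_group(X, labels: np.ndarray) -> np.ndarray:
    """Within-group means of a cells x features matrix -> groups x features."""
    X = as_dense(X)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    out = np.empty((len(groups), X.shape[1]))
    for i, g in enumerate(groups):
        out[i] = X[labels == g].mean(axis=0)
    return out


def link_peaks_to_genes(
    agg_expression: pd.DataFrame,
    agg_accessibility: pd.DataFrame,
    candidates: pd.DataFrame,
) -> pd.DataFrame:
    """Correlate candidate (peak, gene) pairs across metacells.

    ``agg_expression`` / ``agg_accessibility`` are metacell x gene / peak
    mean matrices (DataFrames, shared row order); ``candidates`` is the
    output of :func:`categorize_peaks`.  Returns one row per tested pair with
    columns peak, gene, category, r, p, fdr, retained (strict |r| > 0.25 and
    FDR < 0.01).  Constant profiles are skipped with a warning.
    """
    n = len(agg_expression)
    if n < 3:
        raise DegenerateInputError("need >= 3 metacells for correlation")
    E = agg_expression.to_numpy(dtype=float)
    A = agg_accessibility.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(agg_expression.columns)}
    peak_pos = {p: i for i, p in enumerate(agg_accessibility.columns)}

    rows = []
    n_const = 0
    for peak, cand in candidates.iterrows():
        if peak not in peak_pos or not cand["targets"]:
            continue
        a = A[:, peak_pos[peak]]
        if np.all(a == a[0]):
            n_const += len(cand["targets"])
            continue
        for gene in cand["targets"]:
            if gene not in gene_pos:
                continue
            e = E[:, gene_pos[gene]]
            if np.all(e == e[0]):
                n_const += 1
                continue
            r, p = stats.pearsonr(a, e)
            rows.append({"peak": peak, "gene": gene, "category": cand["category"],
                         "r": float(r), "p": float(p)})
    if n_const:
        logger.warning("link_peaks_to_genes: skipped %d constant-profile pairs", n_const)
    out = pd.DataFrame(rows, columns=["peak", "gene", "category", "r", "p"])
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
        out["retained"] = link_retained(out["r"].to_numpy(), out["fdr"].to_numpy())
    else:
        out["fdr"] = pd.Series(dtype=float)
        out["retained"] = pd.Series(dtype=bool)
    return out
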