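"""End-to-end orchestration: from a multiome dataset to condition GRNs,
enriched sub-networks, DEG clusters and key activators.

The per-condition route is: motif deviations -> activator/repressor roles;
peak categorization -> metacell correlation links; footprint-retained sites;
boosted-ensemble edges with importance filter and correlation signs; triple
assembly under the MG-enrichment filter.  Across conditions: per-group
rank-sum comparisons feed the enriched sub-networks, the DEG clusters (binned
pseudotime profiles per condition, concatenated, k-means) and the
hypergeometric key-activator calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import activity, binding, diff, edges as edges_mod, grn as grn_mod, links
from ._utils import lognorm
from .types import GRN, SyntheticTruth


@dataclass
class PipelineOptions:
    """Runtime knobs of the full pipeline.

    The ensemble here is deliberately lighter than the module default (fewer,
    faster trees) since the pipeline fits one model per gene per condition;
    recovery is insensitive to this within wide margins.
    """

    n_metacells: int = 100
    embedding_dims: int = 30
    importance_quantile: float = 0.90
    deg_comparison: str = "LD_vs_NMDA"
    n_bins: int = 20
    smooth_window: int = 3
    ensemble: edges_mod.EnsembleParams = field(
        default_factory=lambda: edges_mod.EnsembleParams(n_estimators=150, learning_rate=0.1)
    )
    seed: int = 0


def mg_enriched_tfs(
    norm_expr: pd.DataFrame, cell_groups: np.ndarray, mg_groups, tf_list
) -> set[str]:
    """TFs marker-enriched (log2FC > 0.25, adj-p < 0.05) in >= 1 MG group
    versus all other cells."""
    enriched: set[str] = set()
    sub = norm_expr[list(tf_list)]
    for g in mg_groups:
        mask = cell_groups == g
        if mask.sum() == 0 or (~mask).sum() == 0:
            continue
        de = diff.wilcoxon_de(sub, mask, ~mask)
        hit = (de["log2fc"] > diff.DEG_LFC["LD_vs_NMDA"]) & (de["adj_p"] < diff.DEG_ADJ_P)
        enriched |= set(de.index[hit])
    return enriched


def build_condition_grn(
    rna, atac, peaks, genes, motif_hits, footprints,
    condition: str, mg_groups, opts: PipelineOptions,
) -> dict:
    """Build the total GRN for one condition; returns all intermediates."""
    mask = (rna.obs["condition"] == condition).to_numpy()
    rsub = rna[mask].copy()
    asub = atac[mask].copy()
    norm_rna = pd.DataFrame(lognorm(rsub.X), columns=rsub.var_names,
                            index=rsub.obs_names)
    tf_list = sorted(motif_hits["tf"].unique())

    # motif activity and TF roles
    mean_access = np.asarray(asub.X.mean(axis=0)).ravel()
    backgrounds = activity.match_background_peaks(
        peaks.df["gc"].to_numpy(), mean_access, seed=opts.seed
    )
    deviations = activity.compute_deviations(asub, motif_hits, backgrounds)
    tf_motif_map = motif_hits[["tf", "motif"]].drop_duplicates()
    roles = activity.classify_tf_motif_pairs(norm_rna[tf_list], deviations, tf_motif_map)

    # peak-gene links across metacells
    cats = links.categorize_peaks(peaks, genes)
    embedding = links.multiome_embedding(rsub, asub, opts.embedding_dims, seed=opts.seed)
    metacells = links.make_metacells(embedding, opts.n_metacells, seed=opts.seed)
    agg_e = pd.DataFrame(links.aggregate_by_group(lognorm(rsub.X), metacells),
                         columns=rsub.var_names)
    agg_a = pd.DataFrame(links.aggregate_by_group(lognorm(asub.X), metacells),
                         columns=asub.var_names)
    link_table = links.link_peaks_to_genes(agg_e, agg_a, cats)

    # footprint-retained, expressed TF sites
    sites = binding.score_footprints(motif_hits, footprints)
    sites = binding.filter_expressed_tfs(sites, rsub, mg_groups)
    sites = sites[sites["retained"]].reset_index(drop=True)

    # signed, importance-filtered edges
    importances = edges_mod.compute_importances(
        norm_rna, tf_list, seed=opts.seed, params=opts.ensemble
    )
    filtered = edges_mod.filter_importance_quantile(importances, opts.importance_quantile)
    edge_table = edges_mod.sign_edges(filtered, norm_rna)

    enriched = mg_enriched_tfs(norm_rna, rsub.obs["cell_group"].to_numpy(),
                               mg_groups, tf_list)
    total = grn_mod.assemble_triples(sites, link_table, edge_table, roles,
                                     enriched, label=condition)
    return {
        "grn": total, "roles": roles, "links": link_table, "sites": sites,
        "edges": edge_table, "deviations": deviations, "mg_enriched": enriched,
        "metacells": metacells, "norm_rna": norm_rna, "mask": mask,
    }


def condition_de_tables(
    rna, atac, focal: str, other: str, mg_groups
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Per-MG-group focal-vs-other rank-sum results for genes and peaks.

    Returns the long-form table consumed by the sub-network extraction
    (feature, modality, group, log2fc, p, adj_p; log2fc positive = higher in
    the focal condition) and the per-group gene tables for DEG calling.
    """
    cond = rna.obs["condition"].to_numpy()
    groups = rna.obs["cell_group"].to_numpy()
    norm_g = pd.DataFrame(lognorm(rna.X), columns=rna.var_names)
    norm_p = pd.DataFrame(lognorm(atac.X), columns=atac.var_names)
    rows = []
    gene_tables: dict[str, pd.DataFrame] = {}
    for g in mg_groups:
        a = (cond == focal) & (groups == g)
        b = (cond == other) & (groups == g)
        if a.sum() == 0 or b.sum() == 0:
            continue
        de_g = diff.wilcoxon_de(norm_g, a, b)
        gene_tables[g] = de_g
        for feat, r in de_g.iterrows():
            rows.append({"feature": feat, "modality": "gene", "group": g,
                         "log2fc": r["log2fc"], "p": r["p"], "adj_p": r["adj_p"]})
        de_p = diff.wilcoxon_de(norm_p, a, b)
        for feat, r in de_p.iterrows():
            rows.append({"feature": feat, "modality": "peak", "group": g,
                         "log2fc": r["log2fc"], "p": r["p"], "adj_p": r["adj_p"]})
    return pd.DataFrame(rows), gene_tables


def concat_condition_profiles(
    rna, deg_genes: list[str], conditions, n_bins: int, smooth_window: int
):
    """Per-condition binned pseudotime profiles of the DEG genes, smoothed,
    concatenated along bins, then z-scaled jointly so condition-level
    differences survive; returns a TrajectoryBins over the concatenation."""
    norm = pd.DataFrame(lognorm(rna.X), columns=rna.var_names)
    cond = rna.obs["condition"].to_numpy()
    pt = rna.obs["pseudotime"].to_numpy()
    parts = []
    for c in conditions:
        mask = cond == c
        bins = diff.bin_pseudotime(pt[mask], norm.loc[mask, deg_genes],
                                   n_bins=n_bins, smooth_window=smooth_window)
        smoothed = (
            pd.DataFrame(bins.binned).T
            .rolling(window=smooth_window, center=True, min_periods=1)
            .mean().T.to_numpy()
        )
        parts.append(smoothed)
    raw = np.concatenate(parts, axis=1)
    mu = raw.mean(axis=1, keepdims=True)
    sd = raw.std(axis=1, keepdims=True)
    constant = sd.ravel() == 0
    sd[sd == 0] = 1.0
    scaled = (raw - mu) / sd
    scaled[constant] = 0.0
    return diff.TrajectoryBins(
        feature_names=list(deg_genes), binned=raw, scaled=scaled,
        constant_mask=constant, n_bins=raw.shape[1], smooth_window=smooth_window,
    )


@dataclass
class PipelineResult:
    conditions: list[str]
    per_condition: dict[str, dict]
    de_tables: dict[str, pd.DataFrame]
    degs: set[str]
    deg_clusters: dict[int, set[str]]
    sub_grns: dict[str, GRN]
    key_activators: dict[str, pd.DataFrame]

    def total_grns(self) -> dict[str, GRN]:
        return {c: self.per_condition[c]["grn"] for c in self.conditions}

    def predicted_triples(self) -> set[tuple[str, str, str]]:
        out: set[tuple[str, str, str]] = set()
        for c in self.conditions:
            out |= self.per_condition[c]["grn"].triple_tuples()
        return out


def run_full_pipeline(
    rna, atac, peaks, genes, motif_hits, footprints,
    mg_groups=("RestMG", "ActMG", "MGPC"),
    mature_markers: set[str] | None = None,
    opts: PipelineOptions | None = None,
) -> PipelineResult:
    """Two-condition end-to-end run: total GRNs, enriched sub-GRNs, DEG
    clusters and key activators per condition."""
    opts = opts or PipelineOptions()
    mature_markers = mature_markers or set()
    conditions = list(rna.obs["condition"].cat.categories
                      if hasattr(rna.obs["condition"], "cat")
                      else pd.unique(rna.obs["condition"]))
    per_condition = {
        c: build_condition_grn(rna, atac, peaks, genes, motif_hits, footprints,
                               c, mg_groups, opts)
        for c in conditions
    }

    de_tables: dict[str, pd.DataFrame] = {}
    degs: set[str] = set()
    for ci, focal in enumerate(conditions):
        other = conditions[1 - ci] if len(conditions) == 2 else None
        if other is None:
            continue
        table, gene_tables = condition_de_tables(rna, atac, focal, other, mg_groups)
        de_tables[focal] = table
        if ci == 0:  # DEG set is direction-symmetric; call it once
            for g, de in gene_tables.items():
                degs |= diff.call_degs(de, opts.deg_comparison, mature_markers)

    deg_list = sorted(degs)
    if deg_list:
        profiles = concat_condition_profiles(rna, deg_list, conditions,
                                             opts.n_bins, opts.smooth_window)
        assign = diff.kmeans_cluster_profiles(profiles, k=max(2, len(conditions)),
                                              seed=opts.seed)
        deg_clusters: dict[int, set[str]] = {}
        for gene, cl in assign.items():
            deg_clusters.setdefault(cl, set()).add(gene)
    else:
        deg_clusters = {}

    sub_grns, key_activators = {}, {}
    for focal in conditions:
        if focal not in de_tables:
            continue
        sub = grn_mod.extract_enriched_subgrn(
            per_condition[focal]["grn"], de_tables[focal], focal
        )
        sub_grns[focal] = sub
        key_activators[focal] = grn_mod.identify_key_activators(
            sub, per_condition[focal]["grn"], deg_clusters
        )
    return PipelineResult(
        conditions=conditions, per_condition=per_condition, de_tables=de_tables,
        degs=degs, deg_clusters=deg_clusters, sub_grns=sub_grns,
        key_activators=key_activators,
    )


def evaluate_recovery(result: PipelineResult, truth: SyntheticTruth) -> dict:
    """Precision/recall of planted triples plus key-activator recovery."""
    predicted = result.predicted_triples()
    planted = truth.triple_tuples()
    tp = len(predicted & planted)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(planted) if planted else 0.0

    # map each condition to the k-means cluster best matching its planted
    # responsive-target set, then ask whether each planted enriched TF is a
    # key activator of that cluster
    planted_by_cond: dict[str, set[str]] = {}
    for gene, ci in truth.deg_cluster_assignments.items():
        cond = result.conditions[ci] if ci < len(result.conditions) else str(ci)
        planted_by_cond.setdefault(cond, set()).add(gene)
    n_tfs = sum(len(s) for s in truth.condition_enriched_tfs.values())
    n_found = 0
    for cond, tfs in truth.condition_enriched_tfs.items():
        ka = result.key_activators.get(cond)
        if ka is None or not len(ka) or cond not in planted_by_cond:
            continue
        best_cluster, best_ov = None, -1
        for cl, genes_cl in result.deg_clusters.items():
            ov = len(genes_cl & planted_by_cond[cond])
            if ov > best_ov:
                best_cluster, best_ov = cl, ov
        hits = ka[(ka["deg_cluster"] == best_cluster) & ka["key_activator"]]
        n_found += len(set(hits["tf"]) & tfs)
    return {
        "precision": precision,
        "recall": recall,
        "n_predicted": len(predicted),
        "n_planted": len(planted),
        "key_activator_recovery": n_found / n_tfs if n_tfs else float("nan"),
    }
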