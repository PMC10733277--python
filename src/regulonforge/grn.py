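"""Regulon assembly: TF-peak-target triples, enriched sub-networks, key TFs.

A triple forms when a footprint-retained (tf, peak) site joins a retained
(peak, gene) link, and survives only if a signed (tf, gene) edge exists whose
direction matches the TF's role (activator <-> positive, repressor <->
negative), the TF is marker-enriched in at least one glia-lineage (MG) cell
group, and duplicates are collapsed keeping the highest footprint score.

Condition-enriched sub-networks keep triples whose TF is significantly higher
(lower, for repressors) in the focal condition in >= 1 MG-group comparison,
whose peak is not significantly lower in any group, and whose target is
significantly higher in >= 1 group.

Key activators are TFs whose positive sub-network targets are
hypergeometrically enriched in a DEG cluster: population = the TF's targets
in the total network, successes = those in the cluster, sample = its targets
in the sub-network, with the upper-tail p including the observed overlap.
TFs with p < 0.001 and coverage (overlap / cluster size) > 0.01 qualify.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._utils import DegenerateInputError, logger
from .diff import DAR_LFC, DAR_RAW_P, DEG_ADJ_P, DEG_LFC
from .types import GRN

KEY_ACTIVATOR_MAX_P = 0.001
KEY_ACTIVATOR_MIN_COVERAGE = 0.01

_ROLE_TO_SIGN = {"activator": "positive", "repressor": "negative"}


def is_key_activator(p_value: float, coverage: float) -> bool:
    """Strict key-activator rule: p < 0.001 and coverage > 0.01."""
    return bool(p_value < KEY_ACTIVATOR_MAX_P and coverage > KEY_ACTIVATOR_MIN_COVERAGE)


def assemble_triples(
    sites: pd.DataFrame,
    links: pd.DataFrame,
    edges: pd.DataFrame,
    roles: pd.DataFrame,
    mg_enriched_tfs: set[str],
    label: str = "GRN",
) -> GRN:
    """Merge binding sites, peak-gene links and signed edges into a GRN.

    ``sites``: footprint-scored TF sites (tf, peak, footprint_score, retained);
    ``links``: peak-gene links (peak, gene, retained); ``edges``: signed
    (tf, gene, sign) edges surviving the importance filter; ``roles``:
    TF-motif pairs (tf, role).  ``mg_enriched_tfs`` is the set of TFs passing
    the MG-group marker test.  Row order of the inputs never affects the
    result.
    """
    role_of: dict[str, str] = {}
    for r in roles.itertuples(index=False):
        role_of.setdefault(r.tf, r.role)
    edge_sign = {(e.tf, e.gene): e.sign for e in edges.itertuples(index=False)}

    sites_r = sites[sites["retained"]] if "retained" in sites else sites
    links_r = links[links["retained"]] if "retained" in links else links
    skipped_roleless: set[str] = set()
    merged = sites_r.merge(links_r[["peak", "gene"]], on="peak", how="inner")

    rows = []
    for t in merged.itertuples(index=False):
        role = role_of.get(t.tf)
        if role is None:
            skipped_roleless.add(t.tf)
            continue
        if t.tf not in mg_enriched_tfs:
            continue
        sign = edge_sign.get((t.tf, t.gene))
        if sign is None or sign != _ROLE_TO_SIGN[role]:
            continue
        rows.append({"tf": t.tf, "peak": t.peak, "gene": t.gene, "sign": sign,
                     "tf_role": role, "footprint_score": t.footprint_score,
                     "provenance": label})
    if skipped_roleless:
        logger.warning("assemble_triples: no activator/repressor role for TFs %s",
                       sorted(skipped_roleless))
    cols = ["tf", "peak", "gene", "sign", "tf_role", "footprint_score", "provenance"]
    if not rows:
        return GRN(label=label, triples=pd.DataFrame(columns=cols))
    df = pd.DataFrame(rows, columns=cols)
    df = (
        df.sort_values("footprint_score", ascending=False)
        .drop_duplicates(["tf", "peak", "gene"], keep="first")
        .sort_values(["tf", "peak", "gene"], kind="stable")
        .reset_index(drop=True)
    )
    return GRN(label=label, triples=df)


def extract_enriched_subgrn(
    grn: GRN,
    de_results: pd.DataFrame,
    focal_condition: str,
) -> GRN:
    """Condition-enriched sub-network of a total GRN.

    ``de_results`` holds focal-vs-other differential results with columns
    ``feature``, ``modality`` ('gene' or 'peak'), ``group`` (MG cell group),
    ``log2fc``, ``p``, ``adj_p``; positive log2fc means higher in the focal
    condition.  Retention per triple: TF significantly higher (lower for
    repressors) in >= 1 group; peak not significantly lower in ANY group
    (accessibility rule on raw p); target significantly higher in >= 1 group.
    Features without a DE record count as unchanged (logged once per class).
    """
    lfc_thr = DEG_LFC["LD_vs_NMDA"]
    genes = de_results[de_results["modality"] == "gene"]
    peaks_de = de_results[de_results["modality"] == "peak"]

    gene_up: set[str] = set()
    gene_down: set[str] = set()
    for r in genes.itertuples(index=False):
        if r.adj_p < DEG_ADJ_P and r.log2fc > lfc_thr:
            gene_up.add(r.feature)
        if r.adj_p < DEG_ADJ_P and r.log2fc < -lfc_thr:
            gene_down.add(r.feature)
    peak_down: set[str] = set()
    for r in peaks_de.itertuples(index=False):
        if r.p < DAR_RAW_P and r.log2fc < -DAR_LFC:
            peak_down.add(r.feature)

    known_genes = set(genes["feature"])
    known_peaks = set(peaks_de["feature"])
    missing = {"gene": 0, "peak": 0}
    keep = []
    for t in grn.triples.itertuples(index=False):
        if t.tf not in known_genes or t.gene not in known_genes:
            missing["gene"] += 1
        if t.peak not in known_peaks:
            missing["peak"] += 1
        tf_ok = t.tf in (gene_down if t.tf_role == "repressor" else gene_up)
        peak_ok = t.peak not in peak_down
        target_ok = t.gene in gene_up
        keep.append(tf_ok and peak_ok and target_ok)
    for cls, n in missing.items():
        if n:
            logger.warning(
                "extract_enriched_subgrn[%s]: %d %s lookups had no DE record "
                "(treated as unchanged)", focal_condition, n, cls,
            )
    sub = grn.triples[np.asarray(keep, dtype=bool)].reset_index(drop=True)
    return GRN(label=f"{grn.label}:{focal_condition}-enriched", triples=sub)


def hypergeom_upper_tail(q: int, N: int, m: int, k: int) -> float:
    """P(X >= q) for overlap X of a size-k sample from a population of N
    with m successes (the observed overlap is included in the tail)."""
    if q <= 0:
        return 1.0
    return float(hypergeom.sf(q - 1, N, m, k))


def identify_key_activators(
    sub_grn: GRN,
    total_grn: GRN,
    deg_clusters: dict[int, set[str]],
) -> pd.DataFrame:
    """Hypergeometric enrichment of each TF's sub-network targets per cluster.

    Negative regulations are removed from both networks before target-set
    projection.  Returns one row per (tf, cluster) with n_overlap, n_cluster,
    coverage, p_value and the strict ``key_activator`` flag (p < 0.001,
    coverage > 0.01).  TFs absent from the total network and empty clusters
    are skipped (logged).
    """
    rows = []
    total_tfs = set(total_grn.tfs)
    for tf in sub_grn.tfs:
        sample = sub_grn.targets_of(tf, positive_only=True)
        if not sample:
            continue
        if tf not in total_tfs:
            logger.warning("identify_key_activators: %s missing from total GRN", tf)
            continue
        population = total_grn.targets_of(tf, positive_only=True)
        N = len(population)
        if N == 0:
            continue
        for cluster_id, cluster_genes in deg_clusters.items():
            if not cluster_genes:
                logger.warning("identify_key_activators: cluster %s is empty", cluster_id)
                continue
            m = len(population & cluster_genes)
            k = len(sample)
            q = len(sample & cluster_genes)
            p = hypergeom_upper_tail(q, N, m, k)
            coverage = q / len(cluster_genes)
            rows.append({"tf": tf, "deg_cluster": cluster_id, "n_overlap": q,
                         "n_cluster": len(cluster_genes), "n_sample": k,
                         "n_population": N, "n_successes": m,
                         "coverage": coverage, "p_value": p,
                         "key_activator": is_key_activator(p, coverage)})
    return pd.DataFrame(
        rows,
        columns=["tf", "deg_cluster", "n_overlap", "n_cluster", "n_sample",
                 "n_population", "n_successes", "coverage", "p_value", "key_activator"],
    )
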