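"""Synthetic paired RNA + ATAC multiome with planted regulatory ground truth.

The generator plants TF -> peak -> target-gene regulons on a single synthetic
chromosome.  Each TF carries a per-cell latent activity (cell-group pattern
plus Gaussian noise); the TF's own expression, the accessibility of its bound
peaks, and the expression of its targets all respond to that latent on the
log-mean scale, so the pairwise correlations the downstream pipeline relies on
are tunable through a single ``coupling_strength`` knob.  Counts are drawn
negative-binomially with log-normal per-cell size factors; ATAC counts are
capped at the fixed ceiling.  Bound motif sites leave a footprint: the
corrected insertion signal dips by ``footprint_depth`` over the motif center
relative to its flanks.
"""

from __future__ import annotations

import math

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._utils import ConfigurationError
from .binding import PWM
from .config import SimulationConfig
from .types import (
    PEAK_COUNT_CEILING,
    PEAK_WIDTH,
    FootprintSignalSet,
    GenomeAnnotation,
    PeakSet,
    PlantedTriple,
    SyntheticTruth,
)

# internal scales of the generative model (not exposed: the public knob is
# coupling_strength, which multiplies the coupled response)
_SIGMA_EXPR = 0.8      # log-mean response of TF expression to its latent
_TF_BASE_MEAN = 2.0    # baseline mean counts of TF genes
_GENE_BASE_MEAN = 1.5  # baseline mean counts of target / bystander genes
_PEAK_BASE_MEAN = 0.8  # baseline mean fragment counts per peak
_SIZE_FACTOR_SD = 0.3  # log-normal(0, 0.3) per-cell size factors
_TF_GROUP_LFC = 0.5   # extra log-mean boost of a TF gene in its high MG group;
                      # keeps TFs marker-detectable after library-size
                      # normalization shrinks group differences (composition)
_GENE_SPACING = 50_000
_GENE_BODY_LEN = 2_000
_PLANTED_PEAK_OFFSET = 3_000   # planted peak center sits this far upstream of its target TSS
_BG_PEAK_SPACING = 13_000
_FOOTPRINT_BASE_LEVEL = 1.0


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu**2."""
    size = 1.0 / dispersion
    mu = np.clip(mu, 1e-9, 1e5)
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _group_counts(n_cells: int, n_groups: int) -> list[int]:
    """Deterministic per-group cell counts (glia-heavy for 4 groups)."""
    if n_groups == 4:
        weights = np.array([0.30, 0.30, 0.25, 0.15])
    else:
        weights = np.full(n_groups, 1.0 / n_groups)
    counts = np.floor(weights * n_cells).astype(int)
    counts[: n_cells - counts.sum()] += 1
    return counts.tolist()


def _allocate_triples(cfg: SimulationConfig, rng: np.random.Generator):
    """Decide, per planted triple: TF, sign, condition-responsiveness.

    Condition-enriched TFs are interleaved so that consecutive triples (and
    hence consecutive target genes along the chromosome) belong to different
    TFs; repressor TFs are drawn from the non-enriched pool.
    """
    tfs = [f"tf{i:03d}" for i in range(cfg.n_tfs)]
    n_enriched = cfg.n_enriched_tfs_per_condition * len(cfg.conditions)
    enriched_by_cond: dict[str, list[str]] = {}
    for ci, cond in enumerate(cfg.conditions):
        lo = ci * cfg.n_enriched_tfs_per_condition
        enriched_by_cond[cond] = tfs[lo : lo + cfg.n_enriched_tfs_per_condition]
    enriched = tfs[:n_enriched]
    others = tfs[n_enriched:]
    repressors = set(others[-cfg.n_repressor_tfs :]) if cfg.n_repressor_tfs else set()
    tf_condition = {tf: cond for cond, ts in enriched_by_cond.items() for tf in ts}

    # Target genes are handed out in emission order along the tiled
    # chromosome, so a TF's consecutive triples must sit far enough apart
    # that one triple's peak is outside the 200 kb candidate window of the
    # TF's other targets; otherwise the TF's shared latent creates genuine
    # cross peak-gene correlations that are bookkept as false positives.
    min_gap = math.ceil((200_000 + _PLANTED_PEAK_OFFSET) / _GENE_SPACING) + 1
    quota = {tf: 0 for tf in tfs}
    for tf in enriched:
        quota[tf] = min(cfg.triples_per_enriched_tf, cfg.n_planted_triples)
    remaining = cfg.n_planted_triples - sum(quota.values())
    pool = others if others else tfs
    i = 0
    while remaining > 0:
        quota[pool[i % len(pool)]] += 1
        remaining -= 1
        i += 1
    order: list[str] = []
    last = {tf: -min_gap for tf in tfs}
    for slot in range(cfg.n_planted_triples):
        candidates = [tf for tf in tfs if quota[tf] > 0]
        eligible = [tf for tf in candidates if slot - last[tf] >= min_gap]
        chosen_from = eligible if eligible else candidates
        tf = max(chosen_from, key=lambda t: (quota[t], slot - last[t]))
        order.append(tf)
        quota[tf] -= 1
        last[tf] = slot

    n_resp = math.ceil(cfg.triples_per_enriched_tf * cfg.responsive_fraction)
    seen: dict[str, int] = {}
    rows = []
    for j, tf in enumerate(order):
        k = seen.get(tf, 0)
        seen[tf] = k + 1
        responsive = tf in tf_condition and k < n_resp
        sign = "negative" if tf in repressors else "positive"
        rows.append(
            {
                "tf": tf,
                "sign": sign,
                "responsive": responsive,
                "condition": tf_condition.get(tf),
            }
        )
    return tfs, enriched_by_cond, repressors, pd.DataFrame(rows)


def _build_genome(cfg: SimulationConfig) -> GenomeAnnotation:
    rows = []
    for i in range(cfg.n_genes):
        name = f"tf{i:03d}" if i < cfg.n_tfs else f"gene{i:04d}"
        anchor = 20_000 + i * _GENE_SPACING
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            tss, body_start, body_end = anchor, anchor, anchor + _GENE_BODY_LEN
        else:
            tss, body_start, body_end = anchor, anchor - _GENE_BODY_LEN, anchor
        rows.append(
            {"gene": name, "chrom": "chr1", "strand": strand, "tss": tss,
             "body_start": body_start, "body_end": body_end}
        )
    return GenomeAnnotation(pd.DataFrame(rows).set_index("gene"))


def _build_peaks(cfg: SimulationConfig, genes: GenomeAnnotation,
                 planted_targets: list[str], rng: np.random.Generator):
    """Planted peaks upstream of their target TSS, background peaks tiled in
    intergenic space with >= 1 kb gaps; returns (PeakSet, planted peak id per
    triple)."""
    half = PEAK_WIDTH // 2
    tss = genes.df["tss"]
    centers, planted_flag = [], []
    for g in planted_targets:
        centers.append(int(tss[g]) - _PLANTED_PEAK_OFFSET)
        planted_flag.append(True)

    n_bg = cfg.n_peaks - len(planted_targets)
    tss_sorted = np.sort(tss.to_numpy())
    # keep background peaks out of [tss-4600, tss+3000]: clears promoters,
    # gene bodies and the planted-peak slots with >= 1 kb to spare
    c = 6_500
    bg = []
    limit = tss_sorted[-1] + _GENE_SPACING * (n_bg + 10)
    while len(bg) < n_bg and c < limit:
        j = np.searchsorted(tss_sorted, c)
        near = []
        if j < len(tss_sorted):
            near.append(tss_sorted[j])
        if j > 0:
            near.append(tss_sorted[j - 1])
        if all(not (t - 4_600 <= c <= t + 3_000) for t in near):
            bg.append(c)
        c += _BG_PEAK_SPACING
    if len(bg) < n_bg:
        raise ConfigurationError("chromosome too crowded to place background peaks")
    centers.extend(bg)
    planted_flag.extend([False] * n_bg)

    df = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": [c - half for c in centers],
            "end": [c - half + PEAK_WIDTH for c in centers],
            "gc": rng.uniform(0.35, 0.65, size=len(centers)),
        }
    )
    df["_planted_rank"] = np.where(planted_flag, np.cumsum(planted_flag) - 1, -1)
    df = df.sort_values("start").reset_index(drop=True)
    df.index = [f"peak{i:05d}" for i in range(len(df))]
    planted_peak_ids = (
        df[df["_planted_rank"] >= 0].sort_values("_planted_rank").index.tolist()
    )
    peaks = PeakSet(df.drop(columns="_planted_rank"))
    return peaks, planted_peak_ids


def _random_pwm(rng: np.random.Generator, length: int) -> np.ndarray:
    consensus = rng.integers(0, 4, size=length)
    mat = np.full((length, 4), 0.05)
    mat[np.arange(length), consensus] = 0.85
    mat += rng.uniform(0, 0.02, size=(length, 4))
    return mat / mat.sum(axis=1, keepdims=True)


def generate_multiome(config: SimulationConfig):
    """Generate a planted-regulon multiome dataset.

    Returns
    -------
    tuple
        ``(rna, atac, peaks, genes, motif_hits, footprints, truth)`` where
        ``rna`` / ``atac`` are AnnData (cells x genes, cells x peaks; counts),
        ``motif_hits`` is a DataFrame (motif, tf, peak, start, end, strand),
        ``footprints`` a :class:`FootprintSignalSet` and ``truth`` the
        :class:`SyntheticTruth` of everything planted.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tf_names, enriched_by_cond, repressors, alloc = _allocate_triples(cfg, rng)
    genes = _build_genome(cfg)
    gene_names = genes.genes
    non_tf_genes = gene_names[cfg.n_tfs :]
    alloc = alloc.assign(gene=non_tf_genes[: len(alloc)])
    peaks, planted_peak_ids = _build_peaks(cfg, genes, alloc["gene"].tolist(), rng)
    alloc = alloc.assign(peak=planted_peak_ids)

    # --- cells -------------------------------------------------------------
    n_groups = len(cfg.cell_groups)
    per_group = _group_counts(cfg.n_cells, n_groups)
    conds, groups_col, pt = [], [], []
    for cond in cfg.conditions:
        for gi, grp in enumerate(cfg.cell_groups):
            n = per_group[gi]
            conds.extend([cond] * n)
            groups_col.extend([grp] * n)
            pt.append(rng.uniform(gi / n_groups, (gi + 1) / n_groups, size=n))
    n_total = len(conds)
    obs = pd.DataFrame(
        {
            "condition": pd.Categorical(conds, categories=list(cfg.conditions)),
            "timepoint": rng.choice(["T1", "T2", "T3"], size=n_total),
            "cell_group": pd.Categorical(groups_col, categories=list(cfg.cell_groups)),
            "pseudotime": np.concatenate(pt),
        },
        index=[f"cell{i:05d}" for i in range(n_total)],
    )
    group_idx = obs["cell_group"].cat.codes.to_numpy()
    cond_arr = obs["condition"].to_numpy()

    # --- latent TF activities ----------------------------------------------
    mg_pos = [cfg.cell_groups.index(g) for g in cfg.mg_groups]
    latents = np.empty((cfg.n_tfs, n_total))
    tf_high_group = {}
    for ti, tf in enumerate(tf_names):
        hg = mg_pos[ti % len(mg_pos)]
        tf_high_group[tf] = hg
        pattern = np.zeros(n_groups)
        pattern[hg] = cfg.group_amp
        latents[ti] = pattern[group_idx] + rng.normal(0.0, cfg.latent_sd, size=n_total)

    tf_cond = {tf: cond for cond, ts in enriched_by_cond.items() for tf in ts}
    coupled = cfg.coupling_strength * cfg.coupling_scale * _SIGMA_EXPR

    # --- RNA log-means -----------------------------------------------------
    log_mu_rna = np.empty((n_total, cfg.n_genes))
    gene_pos = {g: i for i, g in enumerate(gene_names)}
    # bystander genes: independent per-gene group effects only
    bystander_fx = rng.normal(0.0, cfg.group_amp, size=(cfg.n_genes, n_groups))
    for gi, g in enumerate(gene_names):
        log_mu_rna[:, gi] = math.log(_GENE_BASE_MEAN) + bystander_fx[gi][group_idx]
    for ti, tf in enumerate(tf_names):
        col = math.log(_TF_BASE_MEAN) + _SIGMA_EXPR * latents[ti]
        col = col + _TF_GROUP_LFC * (group_idx == tf_high_group[tf])
        if tf in tf_cond:
            col = col + cfg.condition_lfc * (cond_arr == tf_cond[tf])
        log_mu_rna[:, gene_pos[tf]] = col
    tf_index = {tf: i for i, tf in enumerate(tf_names)}
    for row in alloc.itertuples(index=False):
        s = 1.0 if row.sign == "positive" else -1.0
        col = math.log(_GENE_BASE_MEAN) + s * coupled * latents[tf_index[row.tf]]
        if row.responsive:
            # target condition response is TF-mediated, hence coupling-scaled
            col = col + cfg.condition_lfc * cfg.coupling_strength * (
                cond_arr == row.condition
            )
        log_mu_rna[:, gene_pos[row.gene]] = col

    # --- ATAC log-means ----------------------------------------------------
    log_mu_atac = np.empty((n_total, cfg.n_peaks))
    peak_pos = {p: i for i, p in enumerate(peaks.names)}
    peak_fx = rng.normal(0.0, cfg.group_amp, size=(cfg.n_peaks, n_groups))
    for pi in range(cfg.n_peaks):
        log_mu_atac[:, pi] = math.log(_PEAK_BASE_MEAN) + peak_fx[pi][group_idx]
    for row in alloc.itertuples(index=False):
        s = 1.0 if row.sign == "positive" else -1.0
        col = math.log(_PEAK_BASE_MEAN) + s * coupled * latents[tf_index[row.tf]]
        if row.responsive:
            col = col + cfg.peak_condition_lfc * cfg.coupling_strength * (
                cond_arr == row.condition
            )
        log_mu_atac[:, peak_pos[row.peak]] = col

    # --- counts ------------------------------------------------------------
    sf_rna = rng.lognormal(0.0, _SIZE_FACTOR_SD, size=n_total)
    sf_atac = rng.lognormal(0.0, _SIZE_FACTOR_SD, size=n_total)
    X_rna = _nb_counts(rng, sf_rna[:, None] * np.exp(log_mu_rna), cfg.nb_dispersion)
    X_atac = _nb_counts(rng, sf_atac[:, None] * np.exp(log_mu_atac), cfg.nb_dispersion)
    X_atac = np.minimum(X_atac, PEAK_COUNT_CEILING)

    rna = ad.AnnData(
        X=sp.csr_matrix(X_rna.astype(np.int64)), obs=obs.copy(),
        var=pd.DataFrame(index=gene_names),
    )
    atac = ad.AnnData(
        X=sp.csr_matrix(X_atac.astype(np.int64)), obs=obs.copy(),
        var=pd.DataFrame(index=peaks.names),
    )

    # --- PWMs, motif hits, footprints --------------------------------------
    L = cfg.motif_length
    pwms = {
        f"M_{tf}": PWM(motif_id=f"M_{tf}", tf=tf, matrix=_random_pwm(rng, L))
        for tf in tf_names
    }
    hit_rows = []
    for row in alloc.itertuples(index=False):
        start = int(250 - L // 2 + rng.integers(-30, 31))
        hit_rows.append(
            {"motif": f"M_{row.tf}", "tf": row.tf, "peak": row.peak,
             "start": start, "end": start + L, "strand": "+"}
        )
    bg_peaks = [p for p in peaks.names if p not in set(alloc["peak"])]
    for tf in tf_names:
        if cfg.n_decoy_hits_per_tf and bg_peaks:
            chosen = rng.choice(
                bg_peaks, size=min(cfg.n_decoy_hits_per_tf, len(bg_peaks)),
                replace=False,
            )
            for p in chosen:
                start = int(rng.integers(3 * L, PEAK_WIDTH - 4 * L + 1))
                hit_rows.append(
                    {"motif": f"M_{tf}", "tf": tf, "peak": p,
                     "start": start, "end": start + L, "strand": "+"}
                )
    motif_hits = pd.DataFrame(hit_rows)

    signal = np.clip(
        _FOOTPRINT_BASE_LEVEL
        + rng.normal(0.0, cfg.footprint_noise_sd, size=(cfg.n_peaks, PEAK_WIDTH)),
        0.0, None,
    )
    for row in alloc.itertuples(index=False):  # bound sites dip at the center
        pi = peak_pos[row.peak]
        hit = motif_hits[(motif_hits["tf"] == row.tf) & (motif_hits["peak"] == row.peak)]
        st = int(hit["start"].iloc[0])
        signal[pi, st : st + L] *= 1.0 - cfg.footprint_depth
    footprints = FootprintSignalSet(peaks=peaks.names, values=signal)

    truth = SyntheticTruth(
        planted_triples=[
            PlantedTriple(tf=r.tf, peak=r.peak, gene=r.gene, sign=r.sign)
            for r in alloc.itertuples(index=False)
        ],
        planted_peak_gene_links=[(r.peak, r.gene) for r in alloc.itertuples(index=False)],
        condition_enriched_tfs={c: set(ts) for c, ts in enriched_by_cond.items()},
        pseudotime=obs["pseudotime"].to_numpy(),
        deg_cluster_assignments={
            r.gene: list(cfg.conditions).index(r.condition)
            for r in alloc.itertuples(index=False)
            if r.responsive
        },
    )
    rna.uns["pwms"] = {m: p.matrix for m, p in pwms.items()}
    return rna, atac, peaks, genes, motif_hits, footprints, truth


def generate_footprint_track(
    region_width: int,
    bound: bool,
    depth: float,
    noise_sd: float,
    seed: int,
    base_level: float = 0.5,
) -> np.ndarray:
    """Per-base corrected insertion signal for one motif region.

    The region is center (one motif width ``L``) plus two flanks of ``3 L``
    each, so ``region_width`` must be a multiple of 7.  If ``bound``, the
    expected center mean is ``(1 - depth)`` times the expected flank mean.
    """
    if not 0.0 <= depth <= 1.0:
        raise ConfigurationError("depth must be in [0, 1]")
    if region_width % 7 != 0 or region_width < 7:
        raise ConfigurationError("region_width must be a positive multiple of 7")
    L = region_width // 7
    rng = np.random.default_rng(seed)
    track = base_level + rng.normal(0.0, noise_sd, size=region_width)
    track = np.clip(track, 0.0, None)
    if bound:
        track[3 * L : 4 * L] *= 1.0 - depth
    return track
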