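"""File formats: MTX triplets, BED, gene-annotation TSV, MEME motifs,
bedGraph signal, JSON truth, GRN serialization.

BED intervals are 0-based half-open; the MTX bundle follows the common
cell-by-feature layout (matrix.mtx with features as rows, plus barcodes.tsv
and features.tsv).  MEME output is the minimal motif format and is read back
with Biopython's ``minimal`` parser.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import motifs as bio_motifs

from .binding import PWM
from .types import (
    FootprintSignalSet,
    GenomeAnnotation,
    PeakSet,
    PlantedTriple,
    SyntheticTruth,
    GRN,
)

# --- cell-by-feature matrices (MTX bundle) ---------------------------------

def write_mtx_bundle(adata, outdir, prefix: str = "") -> None:
    """Write an AnnData as matrix.mtx (features x cells) + barcodes/features TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    scipy.io.mmwrite(str(outdir / f"{prefix}matrix.mtx"), X.T.tocoo())
    pd.Series(adata.obs_names).to_csv(outdir / f"{prefix}barcodes.tsv",
                                      sep="\t", index=False, header=False)
    pd.Series(adata.var_names).to_csv(outdir / f"{prefix}features.tsv",
                                      sep="\t", index=False, header=False)
    adata.obs.to_csv(outdir / f"{prefix}metadata.tsv", sep="\t")


def read_mtx_bundle(outdir, prefix: str = ""):
    """Read a bundle written by :func:`write_mtx_bundle` back into AnnData."""
    outdir = Path(outdir)
    X = sp.csr_matrix(scipy.io.mmread(str(outdir / f"{prefix}matrix.mtx")).T)
    barcodes = pd.read_csv(outdir / f"{prefix}barcodes.tsv", sep="\t", header=None)[0]
    features = pd.read_csv(outdir / f"{prefix}features.tsv", sep="\t", header=None)[0]
    meta_path = outdir / f"{prefix}metadata.tsv"
    obs = (pd.read_csv(meta_path, sep="\t", index_col=0) if meta_path.exists()
           else pd.DataFrame(index=barcodes))
    obs.index = obs.index.astype(str)
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=features.astype(str)))


# --- genomic intervals ------------------------------------------------------

def write_bed(peaks: PeakSet, path) -> None:
    """Peaks as 0-based half-open BED with name and GC columns."""
    df = peaks.df.reset_index(names="name")
    df[["chrom", "start", "end", "name", "gc"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_bed(path) -> PeakSet:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "gc"])
    return PeakSet(df.set_index("name"))


def write_gene_annotation(genes: GenomeAnnotation, path) -> None:
    genes.df.reset_index(names="gene").to_csv(path, sep="\t", index=False)


def read_gene_annotation(path) -> GenomeAnnotation:
    return GenomeAnnotation(pd.read_csv(path, sep="\t").set_index("gene"))


# --- motifs (MEME minimal format) ------------------------------------------

def write_meme(pwms: dict[str, PWM], path, background: np.ndarray | None = None) -> None:
    """Write PWMs in MEME minimal motif format (one MOTIF block per PWM)."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for motif_id, pwm in pwms.items():
            fh.write(f"MOTIF {motif_id} {pwm.tf}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.length} "
                f"nsites= 100000 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" " + "  ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path) -> dict[str, PWM]:
    """Read a MEME minimal file back into :class:`PWM` objects.

    Biopython's minimal parser supplies the matrices; the alternate name on
    each MOTIF line (the TF symbol) is recovered from the raw lines since the
    parser keeps only the primary id.
    """
    alt: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("MOTIF"):
                parts = line.split()
                if len(parts) >= 3:
                    alt[parts[1]] = parts[2]
    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
        out = {}
        for rec in records:
            mat = np.column_stack([rec.counts[b] for b in "ACGT"]).astype(float)
            mat /= mat.sum(axis=1, keepdims=True)
            bg = np.array([rec.background[b] for b in "ACGT"], dtype=float)
            out[rec.name] = PWM(motif_id=rec.name, tf=alt.get(rec.name, rec.name),
                                matrix=mat, background=bg)
    return out


# --- footprint signal (bedGraph) --------------------------------------------

def write_bedgraph(signals: FootprintSignalSet, peaks: PeakSet, path) -> None:
    """Per-base signal for every peak as bedGraph (runs of equal value merged)."""
    with open(path, "w") as fh:
        for name in signals.peaks:
            row = peaks.df.loc[name]
            track = signals.track(name)
            start = 0
            for i in range(1, len(track) + 1):
                if i == len(track) or track[i] != track[start]:
                    fh.write(
                        f"{row['chrom']}\t{row['start'] + start}\t"
                        f"{row['start'] + i}\t{track[start]:.6g}\n"
                    )
                    start = i


def read_bedgraph(path, peaks: PeakSet) -> FootprintSignalSet:
    """Reconstruct per-peak signal tracks from a bedGraph over the peak set."""
    width = int((peaks.df["end"] - peaks.df["start"]).iloc[0])
    values = np.zeros((len(peaks), width))
    starts = peaks.df["start"].to_numpy()
    order = np.argsort(starts)
    sorted_starts = starts[order]
    bg = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"])
    ends = sorted_starts + width
    for rec in bg.itertuples(index=False):
        j = np.searchsorted(sorted_starts, rec.start, side="right") - 1
        if j < 0 or rec.start >= ends[j]:
            continue
        pi = order[j]
        off = rec.start - starts[pi]
        values[pi, off : off + (rec.end - rec.start)] = rec.value
    return FootprintSignalSet(peaks=peaks.names, values=values)


# --- truth and networks -----------------------------------------------------

def write_truth(truth: SyntheticTruth, path) -> None:
    data = {
        "planted_triples": [
            {"tf": t.tf, "peak": t.peak, "gene": t.gene, "sign": t.sign}
            for t in truth.planted_triples
        ],
        "planted_peak_gene_links": [list(x) for x in truth.planted_peak_gene_links],
        "condition_enriched_tfs": {c: sorted(s) for c, s in
                                   truth.condition_enriched_tfs.items()},
        "pseudotime": np.asarray(truth.pseudotime).tolist(),
        "deg_cluster_assignments": truth.deg_cluster_assignments,
    }
    with open(path, "w") as fh:
        json.dump(data, fh)


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        data = json.load(fh)
    return SyntheticTruth(
        planted_triples=[PlantedTriple(**t) for t in data["planted_triples"]],
        planted_peak_gene_links=[tuple(x) for x in data["planted_peak_gene_links"]],
        condition_enriched_tfs={c: set(s) for c, s in
                                data["condition_enriched_tfs"].items()},
        pseudotime=np.asarray(data["pseudotime"]),
        deg_cluster_assignments={g: int(c) for g, c in
                                 data["deg_cluster_assignments"].items()},
    )


def write_grn(grn: GRN, path) -> None:
    grn.triples.to_csv(path, sep="\t", index=False)


def read_grn(path, label: str | None = None) -> GRN:
    df = pd.read_csv(path, sep="\t")
    lbl = label or (df["provenance"].iloc[0] if len(df) else "GRN")
    return GRN(label=lbl, triples=df)
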