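"""Domain containers shared across the pipeline.

Cell-by-feature matrices travel as :class:`anndata.AnnData` (counts in ``.X``,
per-cell metadata ``condition`` / ``timepoint`` / ``cell_group`` / optional
``pseudotime`` in ``.obs``).  Tabular results (motif hits, links, sites, edges,
triples) travel as pandas DataFrames with documented column sets; the light
dataclasses below anchor everything coordinate- or truth-related.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import ConfigurationError

#: maximum fragment count per cell/peak entry (applied on load and in the
#: generator; matches the fixed-ceiling convention for ATAC peak matrices)
PEAK_COUNT_CEILING = 4

#: fixed peak width in bases
PEAK_WIDTH = 501


@dataclass
class PeakSet:
    """Fixed-width, non-overlapping peaks on genomic coordinates.

    ``df`` is indexed by peak id with columns ``chrom`` (str), ``start``/``end``
    (0-based half-open ints) and ``gc`` (GC fraction in [0, 1]).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        widths = self.df["end"] - self.df["start"]
        if not (widths == PEAK_WIDTH).all():
            bad = self.df.index[widths != PEAK_WIDTH][:3].tolist()
            raise ConfigurationError(
                f"peaks must be exactly {PEAK_WIDTH} bp wide; offending: {bad}"
            )
        for chrom, sub in self.df.groupby("chrom"):
            s = sub.sort_values("start")
            if (s["start"].values[1:] < s["end"].values[:-1]).any():
                raise ConfigurationError(f"overlapping peaks on {chrom}")

    @property
    def names(self) -> list[str]:
        return list(self.df.index)

    @property
    def centers(self) -> np.ndarray:
        return ((self.df["start"] + self.df["end"]) // 2).to_numpy()

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class GenomeAnnotation:
    """Gene coordinates: ``df`` indexed by gene symbol with columns ``chrom``,
    ``strand`` (+/-), ``tss``, ``body_start``, ``body_end`` (0-based half-open).

    The TSS must sit on the strand-consistent boundary of the gene body
    (left edge for ``+`` genes, right edge for ``-`` genes).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        plus = self.df["strand"] == "+"
        tss_ok = np.where(
            plus,
            self.df["tss"] == self.df["body_start"],
            self.df["tss"] == self.df["body_end"],
        )
        if not np.all(tss_ok):
            bad = self.df.index[~tss_ok][:3].tolist()
            raise ConfigurationError(f"TSS off the strand-consistent body boundary: {bad}")

    @property
    def genes(self) -> list[str]:
        return list(self.df.index)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class FootprintSignalSet:
    """Per-peak, per-base corrected insertion signal.

    ``values`` has one row per peak (same order as ``peaks``) and one column
    per base of the fixed peak width.
    """

    peaks: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.peaks):
            raise ConfigurationError("signal matrix shape does not match peak list")
        self._index = {p: i for i, p in enumerate(self.peaks)}

    def track(self, peak: str) -> np.ndarray:
        return self.values[self._index[peak]]

    def __contains__(self, peak: str) -> bool:
        return peak in self._index


@dataclass(frozen=True)
class PlantedTriple:
    tf: str
    peak: str
    gene: str
    sign: str  # "positive" | "negative"


@dataclass
class SyntheticTruth:
    """Ground truth planted by the synthetic multiome generator."""

    planted_triples: list[PlantedTriple]
    planted_peak_gene_links: list[tuple[str, str]]
    condition_enriched_tfs: dict[str, set[str]]
    pseudotime: np.ndarray
    deg_cluster_assignments: dict[str, int]

    def __post_init__(self) -> None:
        links = set(self.planted_peak_gene_links)
        for t in self.planted_triples:
            if (t.peak, t.gene) not in links:
                raise ConfigurationError(
                    f"triple ({t.tf},{t.peak},{t.gene}) missing from planted links"
                )
        seen: set[str] = set()
        for cond, tfs in self.condition_enriched_tfs.items():
            dup = seen & set(tfs)
            if dup:
                raise ConfigurationError(f"TFs enriched in several conditions: {dup}")
            seen |= set(tfs)

    def triple_tuples(self) -> set[tuple[str, str, str]]:
        return {(t.tf, t.peak, t.gene) for t in self.planted_triples}


@dataclass
class GRN:
    """A gene regulatory network: a set of signed TF-peak-target triples.

    ``triples`` columns: ``tf``, ``peak``, ``gene``, ``sign``, ``tf_role``,
    ``footprint_score``, ``provenance``.  (tf, peak, gene) is unique.
    """

    label: str
    triples: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["tf", "peak", "gene", "sign", "tf_role", "footprint_score", "provenance"]
        )
    )

    def __post_init__(self) -> None:
        if len(self.triples) and self.triples.duplicated(["tf", "peak", "gene"]).any():
            raise ConfigurationError("duplicate (tf, peak, gene) triples in GRN")

    @property
    def tfs(self) -> list[str]:
        return sorted(self.triples["tf"].unique()) if len(self.triples) else []

    def targets_of(self, tf: str, positive_only: bool = False) -> set[str]:
        sub = self.triples[self.triples["tf"] == tf]
        if positive_only:
            sub = sub[sub["sign"] == "positive"]
        return set(sub["gene"])

    def triple_tuples(self) -> set[tuple[str, str, str]]:
        return set(map(tuple, self.triples[["tf", "peak", "gene"]].itertuples(index=False)))

    def __len__(self) -> int:
        return len(self.triples)
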