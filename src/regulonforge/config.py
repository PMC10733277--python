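"""Simulation configuration for the synthetic multiome generator."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from ._utils import ConfigurationError


@dataclass
class SimulationConfig:
    """Parameters of the planted-regulon multiome simulator.

    The defaults define the study conditions exercised throughout the test
    suite: two injury-like conditions with 1,000 cells each, 20 TFs among 200
    genes, 500 fixed-width peaks and 160 planted TF->peak->gene triples.

    Parameters
    ----------
    n_cells
        Cells generated per condition.
    n_genes, n_tfs, n_peaks
        Feature counts; the first ``n_tfs`` genes are transcription factors.
    n_planted_triples
        Total TF->peak->gene regulons planted with ground-truth sign.
    cell_groups
        Ordered cell-group labels along the trajectory (resting glia ->
        activated glia -> progenitors -> neuronal precursors).
    mg_groups
        The glia-lineage subset of ``cell_groups`` used for MG-enrichment
        filters and condition comparisons.
    conditions
        Condition labels; one dataset (and one GRN) is built per condition.
    n_enriched_tfs_per_condition
        TFs planted with a condition-specific activity boost (the ground
        truth for enriched sub-networks and key-activator calls).
    triples_per_enriched_tf
        Regulon size of each condition-enriched TF; half of these targets
        (``responsive_fraction``) respond to the condition, the rest are
        constitutive.
    coupling_strength
        Scale in [0, 1] of the correlation between a TF's expression and its
        motif activity / bound-peak accessibility / target expression.
    footprint_depth
        Fractional dip of insertion signal at bound motif centers (0 = no
        footprint, 1 = complete protection).
    footprint_noise_sd
        Per-base Gaussian noise of the corrected insertion signal.
    nb_dispersion
        Negative-binomial dispersion (variance = mu + dispersion * mu^2).
    condition_lfc, peak_condition_lfc
        Natural-log boost of enriched-TF expression / responsive-target
        expression and of their peaks' accessibility in the focal condition.
    group_amp
        Amplitude of cell-group effects on the latent TF activity (drives
        MG-group marker enrichment of planted TFs).
    latent_sd
        SD of the per-cell latent activity noise shared by a TF and its
        planted features.
    coupling_scale
        Log-mean response (per latent SD) of coupled features.
    motif_length
        PWM length in bases.
    n_decoy_hits_per_tf
        Unbound (flat-footprint) motif hits planted per TF in random
        background peaks.
    n_repressor_tfs
        Number of non-enriched TFs acting as repressors (negative coupling).
    seed
        Base seed; identical configs with identical seeds generate
        bit-identical datasets.
    """

    n_cells: int = 1000
    n_genes: int = 200
    n_tfs: int = 20
    n_peaks: int = 500
    n_planted_triples: int = 160
    cell_groups: tuple[str, ...] = ("RestMG", "ActMG", "MGPC", "NeuPre")
    mg_groups: tuple[str, ...] = ("RestMG", "ActMG", "MGPC")
    conditions: tuple[str, ...] = ("LD", "NMDA")
    n_enriched_tfs_per_condition: int = 3
    triples_per_enriched_tf: int = 20
    responsive_fraction: float = 0.5
    coupling_strength: float = 0.8
    footprint_depth: float = 0.6
    footprint_noise_sd: float = 0.05
    nb_dispersion: float = 0.4
    condition_lfc: float = 1.0
    peak_condition_lfc: float = 0.5
    group_amp: float = 0.5
    latent_sd: float = 1.0
    coupling_scale: float = 1.5
    motif_length: int = 8
    n_decoy_hits_per_tf: int = 2
    n_repressor_tfs: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_genes", "n_tfs", "n_peaks"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_planted_triples < 0:
            raise ConfigurationError("n_planted_triples must be non-negative")
        if self.n_tfs > self.n_genes:
            raise ConfigurationError("n_tfs must not exceed n_genes")
        if self.n_planted_triples > self.n_tfs * self.n_peaks:
            raise ConfigurationError(
                "more planted triples than available TF-peak combinations"
            )
        if self.n_planted_triples > self.n_genes - self.n_tfs:
            raise ConfigurationError(
                "each planted triple needs a distinct non-TF target gene: "
                f"{self.n_planted_triples} > {self.n_genes - self.n_tfs}"
            )
        if self.n_planted_triples > self.n_peaks:
            raise ConfigurationError("each planted triple needs a distinct peak")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ConfigurationError("coupling_strength must be in [0, 1]")
        if not 0.0 <= self.footprint_depth <= 1.0:
            raise ConfigurationError("footprint_depth must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if not set(self.mg_groups) <= set(self.cell_groups):
            raise ConfigurationError("mg_groups must be a subset of cell_groups")
        n_enriched = self.n_enriched_tfs_per_condition * len(self.conditions)
        if n_enriched + self.n_repressor_tfs > self.n_tfs:
            raise ConfigurationError(
                "enriched + repressor TFs exceed n_tfs "
                f"({n_enriched} + {self.n_repressor_tfs} > {self.n_tfs})"
            )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("cell_groups", "mg_groups", "conditions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        for key in ("cell_groups", "mg_groups", "conditions"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
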