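import numpy as np
import pytest

from regulonforge import SimulationConfig, generate_multiome


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A compact planted multiome: 2 conditions x 250 cells, 8 TFs, 60 genes,
    120 peaks, 24 planted triples (4 condition-enriched TFs, 2 repressors).

    Group structure and coupling are stronger than the full-scale defaults so
    the planted signal stays detectable at a quarter of the cell count.
    """
    return SimulationConfig(
        n_cells=250,
        n_genes=60,
        n_tfs=8,
        n_peaks=120,
        n_planted_triples=24,
        n_enriched_tfs_per_condition=2,
        triples_per_enriched_tf=5,
        n_repressor_tfs=2,
        coupling_strength=0.9,
        group_amp=1.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_multiome(small_cfg):
    return generate_multiome(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
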