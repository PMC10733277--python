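"""Differential/consensus calls, trajectory binning and profile clustering."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from regulonforge import DegenerateInputError
from regulonforge._utils import bh_adjust, lognorm
from regulonforge.diff import (
    bin_pseudotime,
    call_consensus_features,
    call_dars,
    call_degs,
    call_dms,
    call_mature_markers,
    is_dar,
    is_deg,
    kmeans_cluster_profiles,
    lr_test_motifs,
    wilcoxon_de,
)


def _table(rows):
    df = pd.DataFrame(rows, columns=["feature", "log2fc", "p", "adj_p"])
    return df.set_index("feature")


class TestWilcoxon:
    def test_log2fc_formula(self):
        # means 10 vs 1 on the de-logged scale -> log2(11/2)
        a = np.log1p(np.full((20, 1), 10.0))
        b = np.log1p(np.full((20, 1), 1.0))
        de = wilcoxon_de(pd.DataFrame(np.vstack([a, b]), columns=["g"]),
                         np.arange(20), np.arange(20, 40))
        assert de["log2fc"].iloc[0] == pytest.approx(np.log2(11 / 2))

    def test_all_zero_feature(self):
        X = pd.DataFrame(np.zeros((30, 1)), columns=["g"])
        de = wilcoxon_de(X, np.arange(15), np.arange(15, 30))
        assert de["log2fc"].iloc[0] == 0.0
        assert de["p"].iloc[0] == 1.0

    def test_separated_groups_detected(self, rng):
        X = pd.DataFrame({"g": np.concatenate([rng.normal(3, 0.3, 50),
                                               rng.normal(0, 0.3, 50)])})
        de = wilcoxon_de(X, np.arange(50), np.arange(50, 100))
        assert de["adj_p"].iloc[0] < 1e-6

    def test_empty_or_overlapping_groups_rejected(self, rng):
        X = pd.DataFrame({"g": rng.normal(size=10)})
        with pytest.raises(DegenerateInputError):
            wilcoxon_de(X, np.array([], dtype=int), np.arange(5))
        with pytest.raises(DegenerateInputError):
            wilcoxon_de(X, np.arange(5), np.arange(4, 8))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=200))
def test_bh_matches_step_up_oracle(pvals):
    """BH adjustment equals the reference step-up procedure."""
    p = np.asarray(pvals)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    stepped = np.minimum.accumulate(ranked[::-1])[::-1]
    oracle = np.empty(n)
    oracle[order] = np.minimum(stepped, 1.0)
    assert np.allclose(bh_adjust(p), oracle, atol=1e-12)


class TestDegCalls:
    def test_thresholds_differ_by_comparison(self):
        de = _table([("g1", 0.3, 1e-3, 0.01)])
        assert call_degs(de, "LD_vs_NMDA", set()) == {"g1"}
        assert call_degs(de, "injury_vs_dev", set()) == set()

    def test_mature_markers_excluded(self):
        de = _table([("g1", 1.0, 1e-4, 1e-3), ("g2", 1.0, 1e-4, 1e-3)])
        assert call_degs(de, "LD_vs_NMDA", {"g2"}) == {"g1"}

    def test_strict_boundaries(self):
        assert not is_deg(0.25, 0.01, "LD_vs_NMDA")
        assert not is_deg(0.5, 0.01, "injury_vs_dev")
        assert not is_deg(1.0, 0.05, "LD_vs_NMDA")
        assert is_deg(-0.2500001, 0.0499, "LD_vs_NMDA")

    def test_unknown_comparison_rejected(self):
        with pytest.raises(DegenerateInputError):
            is_deg(1.0, 0.01, "nonsense")


class TestMatureMarkers:
    def test_planted_rod_markers_recovered(self):
        """10 genes at ~8-fold in Rod cells are all called; a housekeeping
        gene is not."""
        rng = np.random.default_rng(2)
        n = 500
        groups = np.array(["Rod"] * 100 + ["Cone"] * 100 + ["MG"] * 300)
        mu = np.full((n, 200), 1.0)
        mu[groups == "Rod", :10] = 8.0
        X = rng.poisson(mu)
        adata = ad.AnnData(X=sp.csr_matrix(X))
        adata.var_names = [f"g{i}" for i in range(200)]
        adata.obs["cell_group"] = groups
        markers = call_mature_markers(adata, ["Rod", "Cone"])
        assert {f"g{i}" for i in range(10)} <= markers
        assert "g20" not in markers

    def test_missing_group_skipped(self, rng, caplog):
        adata = ad.AnnData(X=sp.csr_matrix(rng.poisson(1.0, (50, 5))))
        adata.var_names = [f"g{i}" for i in range(5)]
        adata.obs["cell_group"] = ["Rod"] * 25 + ["MG"] * 25
        with caplog.at_level("WARNING", logger="regulonforge"):
            call_mature_markers(adata, ["Rod", "HC"])
        assert "HC" in caplog.text


class TestConsensus:
    def test_gene_needs_both_datasets(self):
        ta = {"MG": _table([("g1", 0.8, 1e-4, 1e-3), ("g2", 0.9, 1e-4, 1e-3)])}
        tb = {"MG": _table([("g1", 0.6, 1e-3, 1e-2), ("g2", 0.1, 0.5, 0.9)])}
        assert call_consensus_features(ta, tb, "gene") == {"g1"}

    def test_gene_boundary_excluded(self):
        ta = {"MG": _table([("g1", 0.5, 1e-4, 1e-3)])}
        tb = {"MG": _table([("g1", 0.8, 1e-4, 1e-3)])}
        assert call_consensus_features(ta, tb, "gene") == set()

    def test_car_requires_ceg_target(self):
        ta = {"MG": _table([("pk1", 0.4, 1e-3, 0.2), ("pk2", 0.4, 1e-3, 0.2)])}
        tb = {"MG": _table([("pk1", 0.3, 1e-3, 0.2), ("pk2", 0.3, 1e-3, 0.2)])}
        out = call_consensus_features(
            ta, tb, "peak",
            peak_targets={"pk1": ["g1"], "pk2": ["g9"]}, cegs={"g1"},
        )
        assert out == {"pk1"}

    def test_cm_keeps_highest_correlation_per_tf(self):
        ta = {"MG": _table([("m1", 0.4, 1e-4, 1e-3), ("m2", 0.5, 1e-4, 1e-3)])}
        tb = {"MG": _table([("m1", 0.4, 1e-4, 1e-3), ("m2", 0.5, 1e-4, 1e-3)])}
        out = call_consensus_features(
            ta, tb, "motif",
            motif_tf_map={"m1": "tfA", "m2": "tfA"}, cegs={"tfA"},
            motif_correlations={"m1": 0.2, "m2": 0.7},
        )
        assert out == {"m2"}

    def test_group_missing_from_one_dataset_logged(self, caplog):
        ta = {"MG": _table([("g1", 0.8, 1e-4, 1e-3)])}
        with caplog.at_level("WARNING", logger="regulonforge"):
            out = call_consensus_features(ta, {}, "gene")
        assert out == set()


class TestDars:
    def test_raw_p_rule_and_deg_target_filter(self):
        tables = {"MG": _table([("pk1", 0.4, 0.04, 0.2), ("pk2", 0.4, 0.04, 0.2),
                                ("pk3", 0.1, 0.01, 0.02)])}
        out = call_dars(tables, degs={"g1"},
                        peak_targets={"pk1": ["g1"], "pk2": ["gX"], "pk3": ["g1"]})
        # pk1: passes (raw p 0.04 despite adj 0.2) and has a DEG target
        # pk2: passes thresholds but no DEG target; pk3: |lfc| too small
        assert out == {"pk1"}

    def test_boundaries(self):
        assert not is_dar(0.25, 0.01)
        assert not is_dar(0.5, 0.05)
        assert is_dar(-0.26, 0.049)


class TestLrMotifs:
    def test_identical_scores_give_p_one(self, rng):
        act = pd.DataFrame({"m1": np.ones(60), "m2": rng.normal(size=60)})
        out = lr_test_motifs(act, np.arange(30), np.arange(30, 60))
        assert out.loc["m1", "p"] == 1.0

    def test_shifted_motif_detected(self, rng):
        """1-sd shift at n = 150/group is essentially always significant."""
        hits = 0
        for s in range(10):
            r = np.random.default_rng(s)
            act = pd.DataFrame(r.normal(size=(300, 20)),
                               columns=[f"m{i}" for i in range(20)])
            act.iloc[:150, 0] += 1.0
            out = lr_test_motifs(act, np.arange(150), np.arange(150, 300),
                                 covariates=r.normal(size=300))
            hits += out.loc["m0", "adj_p"] < 0.05
        assert hits == 10

    def test_log2fc_on_min_shifted_scores(self):
        act = pd.DataFrame({"m1": np.array([-1.0] * 10 + [1.0] * 10)})
        out = lr_test_motifs(act, np.arange(10), np.arange(10, 20))
        # shift = 1 - (-1) = 2: groups at (-1+2)=1 and (1+2)=3
        assert out.loc["m1", "log2fc"] == pytest.approx(np.log2(1 / 3))

    def test_dm_call_requires_deg_tf_and_keeps_best_motif(self):
        lr = pd.DataFrame(
            {"log2fc": [0.5, 0.6, 0.7], "p": [1e-4] * 3, "adj_p": [1e-3] * 3,
             "separation": [False] * 3},
            index=["m1", "m2", "m3"],
        )
        out = call_dms(lr, degs={"tfA"},
                       motif_tf_map={"m1": "tfA", "m2": "tfA", "m3": "tfB"},
                       motif_correlations={"m1": 0.9, "m2": 0.3})
        assert out == {"m1"}


class TestTrajectoryBins:
    def test_equal_frequency_bins(self, rng):
        pt = rng.uniform(size=100)
        prof = pd.DataFrame({"f": rng.normal(size=100)})
        bins = bin_pseudotime(pt, prof, n_bins=20)
        assert bins.binned.shape == (1, 20)

    def test_monotone_feature_has_increasing_binned_means(self, rng):
        pt = rng.uniform(size=200)
        prof = pd.DataFrame({"f": pt})
        bins = bin_pseudotime(pt, prof, n_bins=20)
        assert (np.diff(bins.binned[0]) > 0).all()

    def test_scaled_profiles_are_zscored(self, rng):
        pt = rng.uniform(size=300)
        prof = pd.DataFrame(rng.normal(size=(300, 5)), columns=list("abcde"))
        bins = bin_pseudotime(pt, prof, n_bins=25)
        assert np.allclose(bins.scaled.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(bins.scaled.std(axis=1), 1.0, atol=1e-9)

    def test_constant_profile_flagged_not_scaled(self, rng):
        pt = rng.uniform(size=100)
        prof = pd.DataFrame({"const": np.ones(100)})
        bins = bin_pseudotime(pt, prof, n_bins=20)
        assert bins.constant_mask[0]
        assert np.all(bins.scaled[0] == 0.0)

    def test_bounds_enforced(self, rng):
        pt = rng.uniform(size=100)
        prof = pd.DataFrame({"f": pt})
        with pytest.raises(DegenerateInputError):
            bin_pseudotime(pt, prof, n_bins=19)
        with pytest.raises(DegenerateInputError):
            bin_pseudotime(pt, prof, n_bins=51)
        with pytest.raises(DegenerateInputError):
            bin_pseudotime(pt[:10], prof.iloc[:10], n_bins=20)


class TestProfileClustering:
    def test_rising_vs_falling_recovered(self, rng):
        pt = np.sort(rng.uniform(size=200))
        rise = {f"r{i}": pt + 0.05 * rng.normal(size=200) for i in range(10)}
        fall = {f"f{i}": 1 - pt + 0.05 * rng.normal(size=200) for i in range(10)}
        prof = pd.DataFrame({**rise, **fall})
        bins = bin_pseudotime(pt, prof, n_bins=20)
        assign = kmeans_cluster_profiles(bins, k=2, seed=0)
        labels = [assign[c] for c in prof.columns]
        truth = [0] * 10 + [1] * 10
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_n_features(self, rng):
        pt = rng.uniform(size=50)
        prof = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        bins = bin_pseudotime(pt, prof, n_bins=20)
        assign = kmeans_cluster_profiles(bins, k=4, seed=0)
        assert len(set(assign.values())) == 4

    def test_invalid_k_rejected(self, rng):
        pt = rng.uniform(size=50)
        prof = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        bins = bin_pseudotime(pt, prof, n_bins=20)
        with pytest.raises(DegenerateInputError):
            kmeans_cluster_profiles(bins, k=0)
        with pytest.raises(DegenerateInputError):
            kmeans_cluster_profiles(bins, k=5)
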