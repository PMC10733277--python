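"""PWM thresholds/scanning and footprint-score retention."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regulonforge import ConfigurationError
from regulonforge.binding import (
    PWM,
    filter_expressed_tfs,
    footprint_components,
    footprint_retained,
    pwm_score_threshold,
    scan_peaks,
    score_footprints,
)
from regulonforge.types import FootprintSignalSet


def _consensus_pwm(consensus: str, p: float = 0.997) -> PWM:
    base = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.full((len(consensus), 4), (1 - p) / 3)
    for i, b in enumerate(consensus):
        mat[i, base[b]] = p
    return PWM(motif_id="m", tf="tf", matrix=mat)


def _enumerate_tail(pwm: PWM, thresholds: np.ndarray) -> np.ndarray:
    """Exact P(score >= t) by exhaustive k-mer enumeration (oracle)."""
    lo = pwm.log_odds()
    bg = pwm.background / pwm.background.sum()
    scores = np.zeros(1)
    probs = np.ones(1)
    for row, b in zip(lo, itertools.repeat(bg)):
        scores = (scores[:, None] + row[None, :]).ravel()
        probs = (probs[:, None] * b[None, :]).ravel()
    return np.array([(probs[scores >= t - 1e-9]).sum() for t in thresholds])


class TestThreshold:
    def test_degenerate_pwm_admits_only_consensus(self):
        pwm = _consensus_pwm("ACGT", p=0.997)
        t = pwm_score_threshold(pwm, p_cutoff=1 / 256)
        lo = pwm.log_odds()
        best = lo.max(axis=1).sum()
        second = best - (lo[0].max() - np.sort(lo[0])[-2])
        assert second < t <= best + 1e-6

    def test_p_cutoff_one_gives_minimum_attainable_score(self):
        pwm = _consensus_pwm("ACGTAC")
        t = pwm_score_threshold(pwm, p_cutoff=1.0)
        assert t == pytest.approx(pwm.log_odds().min(axis=1).sum(), abs=1e-2)

    def test_threshold_non_increasing_in_p_cutoff(self):
        rng = np.random.default_rng(4)
        mat = rng.dirichlet(np.ones(4), size=8)
        pwm = PWM(motif_id="m", tf="tf", matrix=mat)
        cutoffs = [1e-5, 1e-4, 1e-3, 1e-2, 0.1, 0.5, 1.0]
        ts = [pwm_score_threshold(pwm, c) for c in cutoffs]
        assert all(a >= b - 1e-12 for a, b in zip(ts, ts[1:]))

    def test_dp_tail_matches_enumeration_L6(self):
        rng = np.random.default_rng(7)
        pwm = PWM(motif_id="m", tf="tf", matrix=rng.dirichlet(np.ones(4), size=6),
                  background=np.array([0.3, 0.2, 0.2, 0.3]))
        for cutoff in (1e-4, 1e-3, 0.01, 0.2):
            t = pwm_score_threshold(pwm, cutoff)
            tail = _enumerate_tail(pwm, np.array([t]))[0]
            assert tail <= cutoff + 1e-3


class TestScan:
    def test_forward_consensus_match(self):
        pwm = _consensus_pwm("AACG")  # non-palindromic
        t = pwm_score_threshold(pwm, 1 / 256)
        out = scan_peaks(pwm, {"pk": "TTAACGAT"}, t)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["start"], row["end"], row["strand"]) == (2, 6, "+")

    def test_reverse_complement_match_reported_forward(self):
        pwm = _consensus_pwm("ACGT")  # revcomp of consensus = ACGT... use asymmetric
        pwm = _consensus_pwm("AACG")  # revcomp = CGTT
        t = pwm_score_threshold(pwm, 1 / 256)
        out = scan_peaks(pwm, {"pk": "TTCGTTTT"}, t)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["start"], row["end"], row["strand"]) == (2, 6, "-")

    def test_windows_with_N_skipped_and_short_sequences_empty(self):
        pwm = _consensus_pwm("ACGT")
        t = pwm_score_threshold(pwm, 1 / 256)
        assert len(scan_peaks(pwm, {"pk": "TTANGTTT"}, t)) == 0
        assert len(scan_peaks(pwm, {"pk": "AC"}, t)) == 0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=10, max_size=60), st.integers(0, 100))
    def test_strand_symmetry(self, seq, seed):
        """Scanning the reverse complement mirrors matches with equal scores."""
        rng = np.random.default_rng(seed)
        pwm = PWM(motif_id="m", tf="tf", matrix=rng.dirichlet(np.full(4, 0.4), size=5))
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        fwd = scan_peaks(pwm, {"pk": seq}, threshold=-1e9)
        rev = scan_peaks(pwm, {"pk": rc}, threshold=-1e9)
        flip = {"+": "-", "-": "+"}
        observed = sorted(
            (int(s), str(d), round(float(sc), 9))
            for s, d, sc in zip(fwd["start"], fwd["strand"], fwd["pwm_score"])
        )
        mirrored = sorted(
            (len(seq) - int(e), flip[str(d)], round(float(sc), 9))
            for e, d, sc in zip(rev["end"], rev["strand"], rev["pwm_score"])
        )
        assert observed == mirrored

    def test_match_rate_matches_background_model(self):
        """Monte Carlo: matches per random peak agree with the DP tail mass."""
        rng = np.random.default_rng(11)
        pwm = PWM(motif_id="m", tf="tf", matrix=rng.dirichlet(np.ones(4), size=10))
        t = pwm_score_threshold(pwm, 5e-5)
        tail = _enumerate_tail(pwm, np.array([t]))[0]
        n_peaks, width = 4000, 201
        seqs = {f"pk{i}": "".join("ACGT"[b] for b in rng.integers(0, 4, width))
                for i in range(n_peaks)}
        counts = []
        for pk, seq in seqs.items():
            hits = scan_peaks(pwm, {pk: seq}, t)
            counts.append(len(hits))
        expected = 2 * (width - 10 + 1) * tail
        se = np.std(counts, ddof=1) / np.sqrt(n_peaks)
        assert abs(np.mean(counts) - expected) < 3 * se + 1e-9


class TestFootprints:
    def _signals(self, track):
        return FootprintSignalSet(peaks=["pk"], values=np.asarray(track)[None, :])

    def _matches(self, start, end):
        return pd.DataFrame({"motif": ["m"], "tf": ["tf"], "peak": ["pk"],
                             "start": [start], "end": [end], "strand": ["+"]})

    def test_flat_signal_scores_zero_and_not_retained(self):
        out = score_footprints(self._matches(24, 32), self._signals(np.full(56, 0.7)))
        assert out["footprint_score"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert not out["retained"].iloc[0]

    def test_dip_arithmetic(self):
        track = np.full(56, 0.5)
        track[24:32] = 0.2
        out = score_footprints(self._matches(24, 32), self._signals(track))
        row = out.iloc[0]
        assert (row["NC"], row["NL"], row["NR"]) == (0.2, 0.5, 0.5)
        assert row["footprint_score"] == pytest.approx(0.6)
        assert row["retained"]

    def test_boundary_score_not_retained(self):
        # NL=0.3, NR=0.2, NC=0.2 -> score 0.1: strict rule excludes it
        track = np.concatenate([np.full(24, 0.3), np.full(8, 0.2), np.full(24, 0.2)])
        out = score_footprints(self._matches(24, 32), self._signals(track))
        assert not out["retained"].iloc[0]
        assert not footprint_retained(0.1)
        assert footprint_retained(0.10000001)

    def test_truncated_flank_uses_available_bases(self):
        track = np.full(40, 0.5)
        track[:4] = 0.9  # only 4 of the 24 left-flank bases exist
        out = score_footprints(self._matches(4, 12), self._signals(track))
        row = out.iloc[0]
        assert row["NL"] == pytest.approx(0.9)
        assert row["NR"] == pytest.approx(0.5)

    def test_fully_truncated_flank_drops_site(self, caplog):
        track = np.full(40, 0.5)
        with caplog.at_level("WARNING", logger="regulonforge"):
            out = score_footprints(self._matches(0, 8), self._signals(track))
        assert len(out) == 0

    def test_missing_signal_dropped_with_warning(self, caplog):
        m = self._matches(24, 32)
        m.loc[0, "peak"] = "absent"
        with caplog.at_level("WARNING", logger="regulonforge"):
            out = score_footprints(m, self._signals(np.full(56, 0.5)))
        assert len(out) == 0
        assert "missing signal" in caplog.text

    def test_vectorized_components_match_bruteforce(self, rng):
        for _ in range(50):
            L = int(rng.integers(4, 12))
            width = 7 * L + int(rng.integers(0, 30))
            track = rng.uniform(0, 2, width)
            start = int(rng.integers(0, width - L))
            nc, nl, nr = footprint_components(track, start, start + L)
            center = [track[i] for i in range(start, start + L)]
            left = [track[i] for i in range(max(start - 3 * L, 0), start)]
            right = [track[i] for i in range(start + L, min(start + 4 * L, width))]
            assert nc == pytest.approx(sum(center) / len(center), abs=1e-12)
            if left:
                assert nl == pytest.approx(sum(left) / len(left), abs=1e-12)
            if right:
                assert nr == pytest.approx(sum(right) / len(right), abs=1e-12)


class TestExpressedFilter:
    def _expr(self, fractions, n_cells=100):
        import anndata as ad
        import scipy.sparse as sp

        X = np.zeros((n_cells, len(fractions)))
        for j, f in enumerate(fractions):
            X[: int(round(f * n_cells)), j] = 2
        a = ad.AnnData(X=sp.csr_matrix(X))
        a.var_names = [f"tf{j}" for j in range(len(fractions))]
        a.obs["cell_group"] = "MG"
        return a

    def _sites(self, tfs):
        return pd.DataFrame({"tf": tfs, "motif": ["m"] * len(tfs),
                             "peak": ["pk"] * len(tfs), "footprint_score": 1.0,
                             "retained": True})

    def test_silent_tf_sites_removed_detected_tf_kept(self):
        expr = self._expr([0.0, 0.5])
        out = filter_expressed_tfs(self._sites(["tf0", "tf1"]), expr, ["MG"])
        assert out["tf"].tolist() == ["tf1"]

    def test_exact_five_percent_is_kept(self):
        expr = self._expr([0.05])
        out = filter_expressed_tfs(self._sites(["tf0"]), expr, ["MG"])
        assert len(out) == 1

    def test_unknown_tf_removed_with_warning(self, caplog):
        expr = self._expr([0.5])
        with caplog.at_level("WARNING", logger="regulonforge"):
            out = filter_expressed_tfs(self._sites(["ghost"]), expr, ["MG"])
        assert len(out) == 0
        assert "ghost" in caplog.text


def test_pwm_row_validation():
    with pytest.raises(ConfigurationError):
        PWM(motif_id="m", tf="t", matrix=np.full((4, 4), 0.3))
    with pytest.raises(ConfigurationError):
        PWM(motif_id="m", tf="t", matrix=np.full((2, 4), 0.25))
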