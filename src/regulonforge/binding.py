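"""TF binding-site prediction: PWM scanning and footprint-score retention.

Matches are called by log-odds PWM score against a dynamic-programming
p-value threshold (independent-position background model), then retained by
the footprint statistic ``NL + NR - 2*NC`` computed from corrected insertion
signal, where NC is the mean over the motif center and NL/NR are means over
flanks of triple the motif width.  Sites are kept only when the score strictly
exceeds ``FOOTPRINT_SCORE_MIN`` and the TF is detectably expressed in the
glia-lineage (MG) cell groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import ConfigurationError, DegenerateInputError, as_dense, logger

#: strict lower bound for retaining a footprinted site
FOOTPRINT_SCORE_MIN = 0.1

#: fraction of MG-group cells in which a TF must be detected to count as expressed
MIN_EXPRESSED_FRACTION = 0.05

_BASES = "ACGT"
_PSEUDOCOUNT = 1e-4


@dataclass
class PWM:
    """Position probability matrix for one motif.

    ``matrix`` is length x 4 (A, C, G, T) with rows summing to 1;
    ``background`` defaults to the uniform base distribution.
    """

    motif_id: str
    tf: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ConfigurationError("PWM matrix must be length x 4")
        if self.matrix.shape[0] < 4:
            raise ConfigurationError("PWM length must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ConfigurationError("PWM rows must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """Base-2 log-odds with a pseudocount to avoid infinite scores."""
        p = self.matrix + _PSEUDOCOUNT
        p /= p.sum(axis=1, keepdims=True)
        b = self.background + _PSEUDOCOUNT
        b /= b.sum()
        return np.log2(p / b[None, :])

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement_log_odds(self) -> np.ndarray:
        return self.log_odds()[::-1, ::-1]


def _background_score_distribution(pwm: PWM, bin_width: float):
    """Exact DP distribution of the log-odds score under the background model
    (independent positions), on a grid of ``bin_width`` log-odds units.

    Returns ``(offset, dist)``: ``dist[k]`` is the probability of the score
    bin ``(k + offset) * bin_width``.
    """
    lo = pwm.log_odds()
    bg = pwm.background / pwm.background.sum()
    steps = np.rint(lo / bin_width).astype(np.int64)
    offset = int(steps.min(axis=1).sum())
    dist = np.zeros(1)
    dist[0] = 1.0
    pos = 0
    for j in range(pwm.length):
        s = steps[j] - steps[j].min()
        new = np.zeros(pos + int(s.max()) + 1)
        for b in range(4):
            new[s[b] : s[b] + pos + 1] += bg[b] * dist[: pos + 1]
        dist = new
        pos += int(s.max())
    return offset, dist


def pwm_tail_probabilities(pwm: PWM, thresholds, bin_width: float = 1e-3) -> np.ndarray:
    """P(score >= t) under the background model for each threshold t."""
    offset, dist = _background_score_distribution(pwm, bin_width)
    tail = np.concatenate([np.cumsum(dist[::-1])[::-1], [0.0]])
    out = []
    for t in np.atleast_1d(thresholds):
        k = int(np.ceil(t / bin_width - 1e-9)) - offset
        out.append(tail[min(max(k, 0), len(tail) - 1)])
    return np.asarray(out)


def pwm_score_threshold(pwm: PWM, p_cutoff: float, bin_width: float = 1e-3) -> float:
    """Smallest log-odds threshold t with P(score >= t) <= ``p_cutoff``.

    The null distribution of the match score under the background model
    (independent positions) is computed exactly by dynamic programming over
    scores discretized to ``bin_width`` log-odds units.
    """
    if not 0.0 < p_cutoff <= 1.0:
        raise ConfigurationError("p_cutoff must be in (0, 1]")
    offset, dist = _background_score_distribution(pwm, bin_width)
    tail = np.cumsum(dist[::-1])[::-1]  # tail[k] = P(score_bin >= k + offset)
    ok = np.nonzero(tail <= p_cutoff + 1e-12)[0]
    idx = ok[0] if len(ok) else len(tail)  # no bin qualifies: above the max score
    return (idx + offset) * bin_width


_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Score every length-L window; windows containing N score -inf."""
    L = lo.shape[0]
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    for j in range(L):
        c = codes[j : j + n_win]
        good = c >= 0
        valid &= good
        scores += np.where(good, lo[j, np.clip(c, 0, 3)], 0.0)
    scores[~valid] = -np.inf
    return scores


def scan_peaks(pwm: PWM, peak_sequences: dict[str, str], threshold: float) -> pd.DataFrame:
    """Report every window on either strand scoring >= ``threshold``.

    Reverse-strand matches are scored on the reverse complement and reported
    in forward coordinates.  Columns: motif, tf, peak, start, end, strand,
    pwm_score.
    """
    L = pwm.length
    lo_f = pwm.log_odds()
    lo_r = pwm.reverse_complement_log_odds()
    rows = []
    for peak, seq in peak_sequences.items():
        if len(seq) < L:
            continue
        codes = _encode(seq)
        for strand, lo in (("+", lo_f), ("-", lo_r)):
            scores = _window_scores(codes, lo)
            for off in np.nonzero(scores >= threshold)[0]:
                rows.append(
                    {"motif": pwm.motif_id, "tf": pwm.tf, "peak": peak,
                     "start": int(off), "end": int(off) + L, "strand": strand,
                     "pwm_score": float(scores[off])}
                )
    return pd.DataFrame(
        rows, columns=["motif", "tf", "peak", "start", "end", "strand", "pwm_score"]
    )


def footprint_components(track: np.ndarray, start: int, end: int):
    """(NC, NL, NR) means for a motif at [start, end) on a per-base track.

    Flanks are 3x the motif width, truncated at the track boundaries (means
    use the available bases only); a fully truncated flank yields NaN.
    """
    L = end - start
    width = len(track)
    center = track[max(start, 0) : min(end, width)]
    left = track[max(start - 3 * L, 0) : max(start, 0)]
    right = track[min(end, width) : min(end + 3 * L, width)]
    nc = float(np.mean(center)) if len(center) else np.nan
    nl = float(np.mean(left)) if len(left) else np.nan
    nr = float(np.mean(right)) if len(right) else np.nan
    return nc, nl, nr


def footprint_retained(score: float) -> bool:
    """Strict retention rule for footprinted sites (score > 0.1)."""
    return bool(score > FOOTPRINT_SCORE_MIN)


def score_footprints(matches: pd.DataFrame, signals) -> pd.DataFrame:
    """Footprint-score PWM matches against per-peak insertion signal.

    Adds NC/NL/NR, ``footprint_score`` = NL + NR - 2*NC and the strict
    ``retained`` flag; matches with missing signal (or a fully truncated
    window on every side) are dropped with a warning.
    """
    rows = []
    n_dropped = 0
    for m in matches.itertuples(index=False):
        if m.peak not in signals:
            n_dropped += 1
            continue
        nc, nl, nr = footprint_components(signals.track(m.peak), m.start, m.end)
        if not np.isfinite([nc, nl, nr]).all():
            n_dropped += 1
            continue
        score = nl + nr - 2.0 * nc
        rows.append({**m._asdict(), "NC": nc, "NL": nl, "NR": nr,
                     "footprint_score": score, "retained": footprint_retained(score)})
    if n_dropped:
        logger.warning("score_footprints: dropped %d matches with missing signal", n_dropped)
    cols = list(matches.columns) + ["NC", "NL", "NR", "footprint_score", "retained"]
    return pd.DataFrame(rows, columns=cols)


def filter_expressed_tfs(
    sites: pd.DataFrame,
    expression,
    mg_groups,
    min_fraction: float = MIN_EXPRESSED_FRACTION,
) -> pd.DataFrame:
    """Keep sites whose TF is detected in >= ``min_fraction`` of MG-group cells.

    ``expression`` is an AnnData of raw counts with ``cell_group`` in ``.obs``.
    TFs absent from the expression matrix lose all their sites (logged).
    """
    mask = expression.obs["cell_group"].isin(list(mg_groups)).to_numpy()
    if mask.sum() == 0:
        raise DegenerateInputError("no cells in the requested MG groups")
    X = as_dense(expression.X[mask])
    det = (X > 0).mean(axis=0)
    frac = dict(zip(expression.var_names, det))
    keep, missing = [], set()
    for tf in sites["tf"]:
        if tf not in frac:
            missing.add(tf)
            keep.append(False)
        else:
            keep.append(frac[tf] >= min_fraction)
    if missing:
        logger.warning("filter_expressed_tfs: TFs absent from expression: %s",
                       sorted(missing))
    return sites[np.asarray(keep, dtype=bool)].reset_index(drop=True)
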