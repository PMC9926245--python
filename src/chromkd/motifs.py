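"""PWM scanning at peak summits, positional preference, cluster z-scores.

Motifs are scored by log-odds (bits) against a background model over
summit-centered sequence windows.  Positional preference asks whether a
motif's hits pile up at the summit (direct binding of the profiled TF's
site, or a co-binder sharing the site) or sit in the flanks (adjacent
cooperative sites); cluster-wise z-scores compare per-cluster motif
presence against the pooled binomial expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .degsets import bh_adjust

__all__ = [
    "PWM",
    "MotifHit",
    "PositionalCall",
    "read_jaspar_pwms",
    "scan_pwm",
    "positional_preference",
    "positional_preference_table",
    "cluster_motif_zscores",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """Position probability matrix over {A,C,G,T} with a background."""

    name: str
    matrix: np.ndarray  # L x 4 probabilities
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if self.matrix.shape[0] < 4:
            raise ValueError("PWM length must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")
        if np.any(self.matrix <= 0) or np.any(self.background <= 0):
            raise ValueError("probabilities must be strictly positive")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """L x 4 log2(p/bg) scoring matrix."""
        return np.log2(self.matrix / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    def informative_positions(self) -> np.ndarray:
        """Boolean mask of positions whose column differs from background."""
        lo = self.log_odds
        return ~np.all(np.abs(lo) < 1e-12, axis=1)

    @classmethod
    def from_counts(
        cls, name: str, counts: np.ndarray, background=None, pseudocount_total: float = 0.8
    ) -> "PWM":
        """Convert a 4-row count matrix (JASPAR layout: rows A,C,G,T) to
        probabilities, adding ``pseudocount_total`` split by background."""
        counts = np.asarray(counts, dtype=np.float64)
        if counts.shape[0] != 4:
            raise ValueError("count matrix must have 4 rows (A,C,G,T)")
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        col = counts.T  # L x 4
        totals = col.sum(axis=1, keepdims=True)
        probs = (col + pseudocount_total * bg) / (totals + pseudocount_total)
        return cls(name, probs, bg)


@dataclass(frozen=True)
class MotifHit:
    peak_name: str
    offset: int  # bp of hit center from summit, signed
    strand: str  # "+" | "-"
    score: float  # log-odds, bits


@dataclass
class PositionalCall:
    motif: str
    n_hits: int
    center_fraction: float
    p_center: float
    p_flank: float
    expected_fraction: float
    classification: str  # center_concentrated | flanking | uniform
    low_count: bool = False


def read_jaspar_pwms(path, background=None) -> list[PWM]:
    """Read JASPAR-style count matrices: ``>name`` then 4 rows A,C,G,T of
    counts, brackets optional."""
    pwms: list[PWM] = []
    name = None
    rows: list[list[float]] = []

    def flush():
        if name is not None:
            if len(rows) != 4:
                raise ValueError(f"motif {name}: expected 4 count rows")
            pwms.append(PWM.from_counts(name, np.array(rows), background))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                rows = []
            else:
                parts = line.replace("[", " ").replace("]", " ").split()
                if parts and parts[0].upper() in _BASE_INDEX:
                    parts = parts[1:]
                rows.append([float(x) for x in parts])
    flush()
    return pwms


def _score_positions(seq_idx: np.ndarray, pwm: PWM) -> np.ndarray:
    """Log-odds at every start position of a forward scan.

    ``seq_idx`` encodes A,C,G,T as 0..3 and N as 4; any N at an
    informative motif position makes that window score −inf.
    """
    L = pwm.length
    n_pos = len(seq_idx) - L + 1
    if n_pos <= 0:
        raise ValueError("sequence shorter than PWM")
    lo = pwm.log_odds  # L x 4
    informative = pwm.informative_positions()
    # pad the scoring matrix with an N column: 0 where uninformative, -inf else
    n_col = np.where(informative, -np.inf, 0.0)
    lo5 = np.column_stack([lo, n_col])  # L x 5
    scores = np.zeros(n_pos)
    for j in range(L):
        scores += lo5[j, seq_idx[j : j + n_pos]]
    return scores


def _encode(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int64)
    for base, i in _BASE_INDEX.items():
        out[arr == ord(base)] = i
    return out


def scan_pwm(
    sequence: str,
    pwm: PWM,
    score_fraction_threshold: float = 0.8,
    peak_name: str = ".",
) -> list[MotifHit]:
    """Scan a summit-centered window on both strands.

    A position is a hit when its log-odds reaches
    ``score_fraction_threshold`` × the PWM's maximum achievable score.
    Overlapping hits on the same strand are collapsed to the
    best-scoring position (ties to the leftmost).  Hit offsets are the
    motif-center position relative to the window center (the summit).
    """
    if len(sequence) < pwm.length:
        raise ValueError("sequence shorter than PWM")
    threshold = score_fraction_threshold * pwm.max_score
    center = len(sequence) // 2
    L = pwm.length
    hits: list[MotifHit] = []
    fwd = _encode(sequence)
    rev = _encode(sequence.translate(_COMPLEMENT)[::-1])
    for strand, idx in (("+", fwd), ("-", rev)):
        scores = _score_positions(idx, pwm)
        cand = [
            (float(scores[p]), p) for p in range(len(scores)) if scores[p] >= threshold
        ]
        # collapse same-strand overlaps: keep best score, ties leftmost
        cand.sort(key=lambda t: (-t[0], t[1]))
        kept: list[tuple[float, int]] = []
        for score, p in cand:
            if all(abs(p - q) >= L for _, q in kept):
                kept.append((score, p))
        for score, p in kept:
            if strand == "+":
                pos = p
            else:
                pos = len(sequence) - p - L  # map back to forward coordinates
            offset = pos + L // 2 - center
            hits.append(MotifHit(peak_name, offset, strand, score))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def positional_preference(
    hits: Sequence[MotifHit],
    motif_name: str = ".",
    window_bp: int = 100,
    center_bp: int = 20,
    min_hits: int = 20,
    alpha: float = 0.05,
) -> PositionalCall:
    """Classify a motif's hit geometry around summits.

    Under a uniform placement over the ±window the expected center
    fraction is (2·center_bp+1)/(2·window_bp+1).  The upper binomial
    tail tests center concentration, the lower tail flanking depletion
    of the center.  Fewer than ``min_hits`` hits → uniform, flagged.
    """
    n = len(hits)
    expected = (2 * center_bp + 1) / (2 * window_bp + 1)
    if n < min_hits:
        return PositionalCall(motif_name, n, float("nan"), 1.0, 1.0, expected,
                              "uniform", low_count=True)
    k = sum(1 for h in hits if abs(h.offset) <= center_bp)
    frac = k / n
    p_center = float(stats.binom.sf(k - 1, n, expected))
    p_flank = float(stats.binom.cdf(k, n, expected))
    if p_center <= alpha and frac > expected:
        cls = "center_concentrated"
    elif p_flank <= alpha and frac < expected:
        cls = "flanking"
    else:
        cls = "uniform"
    return PositionalCall(motif_name, n, frac, p_center, p_flank, expected, cls)


def positional_preference_table(
    hits_by_motif: Mapping[str, Sequence[MotifHit]],
    window_bp: int = 100,
    center_bp: int = 20,
    min_hits: int = 20,
    alpha: float = 0.05,
) -> list[PositionalCall]:
    """Positional calls for several motifs with BH correction across them."""
    calls = [
        positional_preference(h, m, window_bp, center_bp, min_hits, alpha=1.1)
        for m, h in hits_by_motif.items()
    ]
    # re-classify with BH-adjusted p of the winning tail per motif
    raw = [min(c.p_center, c.p_flank) for c in calls]
    adj = bh_adjust(raw)
    for c, p_adj in zip(calls, adj):
        if c.low_count:
            c.classification = "uniform"
        elif p_adj <= alpha and c.center_fraction > c.expected_fraction \
                and c.p_center <= c.p_flank:
            c.classification = "center_concentrated"
        elif p_adj <= alpha and c.center_fraction < c.expected_fraction \
                and c.p_flank <= c.p_center:
            c.classification = "flanking"
        else:
            c.classification = "uniform"
    return calls


def cluster_motif_zscores(
    cluster_sequences: Mapping[int, Sequence[tuple[str, str]]],
    pwms: Sequence[PWM],
    score_fraction_threshold: float = 0.8,
) -> "pd.DataFrame":
    """Motif × cluster enrichment z-scores against the pooled expectation.

    ``cluster_sequences`` maps cluster label to (peak_name, sequence)
    pairs.  Per motif, a peak counts once if it has any hit; the pooled
    per-peak presence probability across all clusters sets the binomial
    null, and z = (obs − n·p̂)/√(n·p̂·(1−p̂)).  Degenerate pooled p̂ of 0
    or 1 leaves z undefined (NaN, flagged).
    """
    import pandas as pd

    if len(cluster_sequences) < 2:
        raise ValueError("need at least 2 clusters")
    rows = []
    for pwm in pwms:
        present: dict[int, int] = {}
        totals: dict[int, int] = {}
        for cluster, seqs in cluster_sequences.items():
            n_present = 0
            for name, seq in seqs:
                if scan_pwm(seq, pwm, score_fraction_threshold, name):
                    n_present += 1
            present[cluster] = n_present
            totals[cluster] = len(seqs)
        pooled = sum(present.values()) / sum(totals.values())
        for cluster in cluster_sequences:
            n = totals[cluster]
            obs = present[cluster]
            if pooled in (0.0, 1.0):
                z, flagged = float("nan"), True
            else:
                z = (obs - n * pooled) / math.sqrt(n * pooled * (1 - pooled))
                flagged = False
            rows.append(
                {
                    "motif": pwm.name,
                    "cluster": cluster,
                    "n_peaks": n,
                    "n_with_hit": obs,
                    "pooled_rate": pooled,
                    "zscore": z,
                    "degenerate": flagged,
                }
            )
    return pd.DataFrame(rows)
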