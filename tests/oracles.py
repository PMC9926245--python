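"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plainly as possible (all-pairs scans,
per-position loops, exact integer enumeration) and shares no code with
the package paths it verifies.
"""

from __future__ import annotations

import math
from math import comb

import numpy as np


def brute_force_overlaps(query, subjects) -> list[int]:
    """All-pairs half-open interval overlap scan."""
    out = []
    for i, s in enumerate(subjects):
        if s.chrom == query.chrom and query.start < s.end and s.start < query.end:
            out.append(i)
    return out


def hypergeom_upper_tail(N: int, nA: int, nB: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, nA, nB) by exact integer enumeration."""
    denom = comb(N, nB)
    num = 0
    for i in range(k, min(nA, nB) + 1):
        if nB - i <= N - nA:
            num += comb(nA, i) * comb(N - nA, nB - i)
    return num / denom


def bin_means_by_bp(track, chrom: str, start: int, n_bins: int, bin_bp: int):
    """Per-bin mean coverage by summing every single base pair."""
    runs = track.runs(chrom)
    out = np.zeros(n_bins)
    for b in range(n_bins):
        lo = start + b * bin_bp
        total = 0.0
        for bp in range(lo, lo + bin_bp):
            if bp < 0:
                continue
            for s, e, v in runs:
                if s <= bp < e:
                    total += v
                    break
        out[b] = total / bin_bp
    return out


def assign_feature_oracle(peak, genes, promoter_up, promoter_down, downstream_bp):
    """Try every (gene, feature) combination and apply the precedence and
    tie-break rules directly; returns (feature, gene_id, signed_distance)."""
    order = ["promoter", "exon", "intron", "downstream", "distal_intergenic"]
    summit = peak.start + peak.summit_offset
    candidates = []  # (feature_rank, |dist|, gene_id, feature, dist)
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        dist = summit - g.tss if g.strand == "+" else g.tss - summit
        feats = []
        if -promoter_up <= dist <= promoter_down:
            feats.append("promoter")
        if g.gene_start <= summit < g.gene_end:
            in_exon = any(s <= summit < e for s, e in g.exons)
            feats.append("exon" if in_exon else "intron")
        if g.strand == "+" and g.gene_end <= summit < g.gene_end + downstream_bp:
            feats.append("downstream")
        if g.strand == "-" and g.gene_start - downstream_bp < summit <= g.gene_start:
            feats.append("downstream")
        for f in feats:
            candidates.append((order.index(f), abs(dist), g.gene_id, f, dist))
    if candidates:
        candidates.sort()
        rank, _, gid, feat, dist = candidates[0]
        return feat, gid, dist
    nearest = None
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        dist = summit - g.tss if g.strand == "+" else g.tss - summit
        key = (abs(dist), g.gene_id)
        if nearest is None or key < nearest[0]:
            nearest = (key, g.gene_id, dist)
    if nearest is None:
        return "distal_intergenic", None, 0
    return "distal_intergenic", nearest[1], nearest[2]


def scan_pwm_oracle(sequence, pwm, score_fraction_threshold):
    """Score every position and strand independently with explicit loops,
    then apply the same best-score collapse rule; returns a set of
    (offset, strand, score-rounded) triples."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = pwm.length
    lo = np.log2(pwm.matrix / pwm.background)
    informative = [bool(np.max(np.abs(lo[j])) > 1e-12) for j in range(L)]
    threshold = score_fraction_threshold * float(lo.max(axis=1).sum())
    center = len(sequence) // 2

    def score_at(seq, p):
        total = 0.0
        for j in range(L):
            b = seq[p + j]
            if b == "N":
                if informative[j]:
                    return -math.inf
            else:
                total += lo[j, base_idx[b]]
        return total

    hits = []
    for strand in ("+", "-"):
        seq = sequence if strand == "+" else "".join(
            comp[b] for b in reversed(sequence)
        )
        cand = []
        for p in range(len(seq) - L + 1):
            s = score_at(seq, p)
            if s >= threshold:
                cand.append((s, p))
        cand.sort(key=lambda t: (-t[0], t[1]))
        kept = []
        for s, p in cand:
            if all(abs(p - q) >= L for _, q in kept):
                kept.append((s, p))
        for s, p in kept:
            pos = p if strand == "+" else len(seq) - p - L
            hits.append((pos + L // 2 - center, strand, round(s, 9)))
    return set(hits)


def partition_oracle(peaks_a, peaks_b, min_overlap_bp=1):
    """All-pairs overlap graph + naive connected components."""
    n_a = len(peaks_a)
    peaks = list(peaks_a) + list(peaks_b)
    adj = {i: set() for i in range(len(peaks))}
    for i, pa in enumerate(peaks_a):
        for j, pb in enumerate(peaks_b):
            if pa.chrom != pb.chrom:
                continue
            ov = min(pa.end, pb.end) - max(pa.start, pb.start)
            if ov >= min_overlap_bp:
                adj[i].add(n_a + j)
                adj[n_a + j].add(i)
    seen = set()
    shared = []
    linked = {i for i in adj if adj[i]}
    for i in sorted(linked):
        if i in seen:
            continue
        comp, stack = [], [i]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            comp.append(v)
            stack.extend(adj[v] - seen)
        shared.append(
            (
                peaks[comp[0]].chrom,
                min(peaks[v].start for v in comp),
                max(peaks[v].end for v in comp),
            )
        )
    a_unique = [
        (p.chrom, p.start, p.end) for i, p in enumerate(peaks_a) if i not in linked
    ]
    b_unique = [
        (p.chrom, p.start, p.end)
        for j, p in enumerate(peaks_b)
        if n_a + j not in linked
    ]
    return sorted(shared), sorted(a_unique), sorted(b_unique)


def binomial_two_sided_oracle(k: int, n: int, p: float) -> float:
    """Two-sided exact binomial p by enumerating all outcomes whose
    probability does not exceed the observed one (minlike convention)."""
    if n == 0:
        return 1.0
    pmf = [comb(n, i) * (p ** i) * ((1 - p) ** (n - i)) for i in range(n + 1)]
    obs = pmf[k]
    return min(1.0, sum(q for q in pmf if q <= obs * (1 + 1e-12)))
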