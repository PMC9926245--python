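"""TF-pair shared/unique partitioning, differential binding, binding modes.

Two TFs profiled in each other's knockdown reveal how they share
chromatin: at a *cooperative* site each TF's binding collapses when its
partner is depleted; at a *competitive* site the remaining TF gains
binding; *independent* sites do not react.  Differential binding uses an
exact conditional binomial test on summed region counts — a deliberate
replicate-free simplification of negative-binomial differential-binding
machinery, adequate for n = 1–2 ChIP designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .degsets import bh_adjust
from .genomic_io import GenomicInterval, OverlapIndex, Peak, SignalTrack

__all__ = [
    "RegionCounts",
    "BindingModeCall",
    "partition_shared_unique",
    "differential_binding",
    "classify_mode",
    "region_counts_from_tracks",
]

MODES = ("cooperative", "competitive", "independent", "asymmetric")
CALLS = ("gain", "loss", "unchanged")
MOTIF_PRESENCE = ("A_motif_center", "B_motif_center", "adjacent", "neither")


@dataclass(frozen=True)
class RegionCounts:
    region_id: str
    count_control: float
    count_kd: float
    library_control: float
    library_kd: float

    def __post_init__(self) -> None:
        if self.library_control <= 0 or self.library_kd <= 0:
            raise ValueError(f"{self.region_id}: library sizes must be positive")
        if self.count_control < 0 or self.count_kd < 0:
            raise ValueError(f"{self.region_id}: negative counts")


@dataclass
class BindingModeCall:
    region_id: str
    partition: str  # shared | A_unique | B_unique
    deltaA_on_Bkd: float
    deltaB_on_Akd: float
    callA: str
    callB: str
    mode: str
    site_annotation: str | None = None  # shared_site | adjacent_site for cooperative


@dataclass
class PartitionedRegions:
    shared: list[GenomicInterval]
    a_unique: list[GenomicInterval]
    b_unique: list[GenomicInterval]


def partition_shared_unique(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    min_overlap_bp: int = 1,
) -> PartitionedRegions:
    """Split two peak sets into shared and TF-unique regions.

    Peaks of A and B that overlap by at least ``min_overlap_bp`` are
    chained into connected components; each component becomes one merged
    shared region spanning all its peaks.  Peaks without any partner
    overlap stay unique.  Every input peak lands in exactly one output
    region.
    """
    n_a, n_b = len(peaks_a), len(peaks_b)
    all_peaks = list(peaks_a) + list(peaks_b)
    parent = list(range(len(all_peaks)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    index_b = OverlapIndex([p.interval for p in peaks_b])
    linked = [False] * len(all_peaks)
    for i, pa in enumerate(peaks_a):
        for j in index_b.query(pa.interval):
            pb = peaks_b[j]
            ov = min(pa.end, pb.end) - max(pa.start, pb.start)
            if ov >= min_overlap_bp:
                union(i, n_a + j)
                linked[i] = linked[n_a + j] = True
    components: dict[int, list[int]] = {}
    for i in range(len(all_peaks)):
        if linked[i]:
            components.setdefault(find(i), []).append(i)
    shared = []
    for members in components.values():
        chrom = all_peaks[members[0]].chrom
        start = min(all_peaks[i].start for i in members)
        end = max(all_peaks[i].end for i in members)
        shared.append(GenomicInterval(chrom, start, end))
    shared.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    a_unique = [p.interval for i, p in enumerate(peaks_a) if not linked[i]]
    b_unique = [p.interval for j, p in enumerate(peaks_b) if not linked[n_a + j]]
    return PartitionedRegions(shared, a_unique, b_unique)


def binomial_conditional_p(c_kd: int, c_ctrl: int, s_kd: float, s_ctrl: float) -> float:
    """Two-sided exact binomial test of the KD count conditional on the
    total, with success probability s_kd/(s_kd+s_ctrl)."""
    n = c_kd + c_ctrl
    if n == 0:
        return 1.0
    p0 = s_kd / (s_kd + s_ctrl)
    return float(stats.binomtest(c_kd, n, p0).pvalue)


def differential_binding(
    counts: Sequence[RegionCounts],
    lfc_threshold: float = 1.0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-region differential binding between KD and control.

    log2FC compares library-scaled counts with a 0.5 pseudocount; the
    p-value is the exact conditional binomial test.  ``gain``/``loss``
    requires BH-p <= fdr and |log2FC| >= lfc_threshold; ``unchanged``
    means failing either criterion, not evidence of equivalence.
    """
    if not counts:
        return pd.DataFrame(
            columns=["region_id", "log2fc", "p_value", "padj", "call"]
        )
    rows = []
    for rc in counts:
        lfc = math.log2((rc.count_kd + 0.5) / rc.library_kd) - math.log2(
            (rc.count_control + 0.5) / rc.library_control
        )
        p = binomial_conditional_p(
            int(round(rc.count_kd)),
            int(round(rc.count_control)),
            rc.library_kd,
            rc.library_control,
        )
        rows.append({"region_id": rc.region_id, "log2fc": lfc, "p_value": p})
    df = pd.DataFrame(rows)
    df["padj"] = bh_adjust(df["p_value"].to_numpy())
    sig = (df["padj"] <= fdr) & (df["log2fc"].abs() >= lfc_threshold)
    df["call"] = "unchanged"
    df.loc[sig & (df["log2fc"] > 0), "call"] = "gain"
    df.loc[sig & (df["log2fc"] < 0), "call"] = "loss"
    return df


def classify_mode(
    region_id: str,
    callA_on_Bkd: str,
    callB_on_Akd: str,
    motif_presence: str = "neither",
    deltaA_on_Bkd: float = float("nan"),
    deltaB_on_Akd: float = float("nan"),
    partition: str = "shared",
) -> BindingModeCall:
    """Map reciprocal differential-binding calls to a binding mode.

    cooperative: both TFs lose binding under the partner's KD;
    competitive: at least one gains while the other gains or is unchanged;
    independent: both unchanged; asymmetric: any remaining combination
    (one loss with one gain/unchanged).  Motif presence refines
    cooperative calls into shared-site vs adjacent-site binding.
    """
    for call in (callA_on_Bkd, callB_on_Akd):
        if call not in CALLS:
            raise ValueError(f"unknown call {call!r}")
    if motif_presence not in MOTIF_PRESENCE:
        raise ValueError(f"unknown motif presence {motif_presence!r}")
    a, b = callA_on_Bkd, callB_on_Akd
    if a == "loss" and b == "loss":
        mode = "cooperative"
    elif ("gain" in (a, b)) and a != "loss" and b != "loss":
        mode = "competitive"
    elif a == "unchanged" and b == "unchanged":
        mode = "independent"
    else:
        mode = "asymmetric"
    annotation = None
    if mode == "cooperative":
        if motif_presence in ("A_motif_center", "B_motif_center"):
            annotation = "shared_site"
        elif motif_presence == "adjacent":
            annotation = "adjacent_site"
        else:
            annotation = "unspecified"
    return BindingModeCall(
        region_id, partition, deltaA_on_Bkd, deltaB_on_Akd, a, b, mode, annotation
    )


def region_counts_from_tracks(
    regions: Sequence[GenomicInterval],
    track_control: SignalTrack,
    track_kd: SignalTrack,
    region_ids: Sequence[str] | None = None,
) -> list[RegionCounts]:
    """Integrate coverage over regions and round to integer counts.

    Library size per condition is the whole-track integral, so the
    conditional test sees each condition's sequencing depth.
    """
    if region_ids is None:
        region_ids = [f"{r.chrom}:{r.start}-{r.end}" for r in regions]

    def library(track: SignalTrack) -> float:
        total = 0.0
        for chrom in track.chroms:
            for s, e, v in track.runs(chrom):
                total += (e - s) * v
        return total

    lib_c, lib_k = library(track_control), library(track_kd)
    out = []
    for rid, r in zip(region_ids, regions):
        out.append(
            RegionCounts(
                rid,
                count_control=round(track_control.integral(r.chrom, r.start, r.end)),
                count_kd=round(track_kd.integral(r.chrom, r.start, r.end)),
                library_control=lib_c,
                library_kd=lib_k,
            )
        )
    return out
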