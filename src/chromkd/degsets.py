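"""DEG thresholding and gene-set overlap statistics.

A gene counts as differentially expressed when |log2FC| >= log2(1.5) and
BH-adjusted p <= 0.05, the convention used throughout knockdown RNA-seq
comparisons here.  Overlap significance is the one-sided hypergeometric
(Fisher) enrichment test with the tested genes as universe, matching the
GeneOverlap convention; cluster-wise DEG enrichment applies it per
cluster and direction with BH correction across that family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEGTable",
    "DEGSet",
    "OverlapTestResult",
    "read_deg_table",
    "filter_degs",
    "overlap_test",
    "cluster_deg_enrichment",
    "bh_adjust",
]

DEFAULT_LFC = math.log2(1.5)
DEFAULT_PADJ = 0.05


@dataclass
class DEGTable:
    """Differential-expression results: gene_id, log2fc, padj (may be NaN)."""

    df: pd.DataFrame  # columns gene_id, log2fc, padj

    def __post_init__(self) -> None:
        required = {"gene_id", "log2fc", "padj"}
        if not required <= set(self.df.columns):
            raise ValueError(f"DEG table needs columns {sorted(required)}")
        if self.df["gene_id"].duplicated().any():
            dup = self.df.loc[self.df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id {dup!r}")
        if not np.all(np.isfinite(self.df["log2fc"].to_numpy(dtype=float))):
            raise ValueError("non-finite log2fc")

    @property
    def genes(self) -> set[str]:
        return set(self.df["gene_id"])


@dataclass
class DEGSet:
    increased: frozenset[str]
    decreased: frozenset[str]
    universe: frozenset[str]
    lfc_threshold: float = DEFAULT_LFC
    padj_threshold: float = DEFAULT_PADJ

    def __post_init__(self) -> None:
        if self.increased & self.decreased:
            raise ValueError("increased and decreased sets intersect")
        if not (self.increased <= self.universe and self.decreased <= self.universe):
            raise ValueError("DEG sets not contained in universe")

    @property
    def degs(self) -> frozenset[str]:
        return self.increased | self.decreased


@dataclass
class OverlapTestResult:
    n_a: int
    n_b: int
    n_overlap: int
    n_universe: int
    odds_ratio: float
    p_value: float

    @property
    def expected_overlap(self) -> float:
        return self.n_a * self.n_b / self.n_universe


def read_deg_table(path) -> DEGTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return DEGTable(df[["gene_id", "log2fc", "padj"]].copy())


def filter_degs(
    table: DEGTable,
    lfc_threshold: float = DEFAULT_LFC,
    padj_threshold: float = DEFAULT_PADJ,
) -> DEGSet:
    """Threshold a DEG table into increased/decreased sets.

    increased: log2fc >= +threshold and padj <= padj_threshold;
    decreased: log2fc <= −threshold and padj <= padj_threshold.
    Genes with missing padj stay in the universe but in neither set.
    """
    if lfc_threshold <= 0 or padj_threshold <= 0:
        raise ValueError("thresholds must be positive")
    df = table.df
    lfc = df["log2fc"].to_numpy(dtype=float)
    padj = df["padj"].to_numpy(dtype=float)
    sig = np.isfinite(padj) & (padj <= padj_threshold)
    inc = df.loc[sig & (lfc >= lfc_threshold), "gene_id"]
    dec = df.loc[sig & (lfc <= -lfc_threshold), "gene_id"]
    return DEGSet(
        frozenset(inc), frozenset(dec), frozenset(df["gene_id"]),
        lfc_threshold, padj_threshold,
    )


def overlap_test(A: set, B: set, universe: set) -> OverlapTestResult:
    """One-sided hypergeometric enrichment test for |A ∩ B|.

    p = P(X >= |A∩B|) with X ~ Hypergeom(N=|universe|, K=|A|, n=|B|).
    The odds ratio comes from the 2×2 contingency table, with a 0.5
    continuity correction applied only when some margin cell is zero.
    """
    if not universe:
        raise ValueError("empty universe")
    if not (A <= universe and B <= universe):
        raise ValueError("A and B must be subsets of the universe")
    N, nA, nB = len(universe), len(A), len(B)
    k = len(A & B)
    # upper tail P(X >= k) == survival function at k-1
    p = float(stats.hypergeom.sf(k - 1, N, nA, nB))
    p = min(max(p, 0.0), 1.0)
    a = k
    b = nA - k
    c = nB - k
    d = N - nA - nB + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return OverlapTestResult(nA, nB, k, N, odds, p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return stats.false_discovery_control(p, method="bh")


def cluster_deg_enrichment(
    cluster_genes: dict[int, set], degs: DEGSet
) -> pd.DataFrame:
    """Per-cluster DEG enrichment and median log2FC summary.

    For every cluster, tests enrichment of the cluster's genes in the
    increased and in the decreased DEG set (one-sided hypergeometric),
    BH-corrected across the clusters × 2 family.  ``median_log2fc`` is not
    computed here (requires the DEG table); callers merge it separately or
    use :func:`cluster_deg_summary`.
    """
    universe = set(degs.universe)
    rows = []
    for cluster in sorted(cluster_genes):
        genes = set(cluster_genes[cluster]) & universe
        for direction, deg_set in (
            ("increased", set(degs.increased)),
            ("decreased", set(degs.decreased)),
        ):
            res = overlap_test(genes, deg_set, universe)
            rows.append(
                {
                    "cluster": cluster,
                    "direction": direction,
                    "n_cluster": res.n_a,
                    "n_degs": res.n_b,
                    "n_overlap": res.n_overlap,
                    "odds_ratio": res.odds_ratio,
                    "p_value": res.p_value,
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["padj"] = bh_adjust(df["p_value"].to_numpy())
    return df


def cluster_deg_summary(
    cluster_genes: dict[int, set], degs: DEGSet, table: DEGTable
) -> pd.DataFrame:
    """Enrichment table plus per-cluster median log2FC of member DEGs.

    Clusters with no member DEGs get NaN median and ``no_degs=True``.
    """
    enr = cluster_deg_enrichment(cluster_genes, degs)
    lfc = dict(zip(table.df["gene_id"], table.df["log2fc"]))
    med_rows = []
    for cluster in sorted(cluster_genes):
        member_degs = set(cluster_genes[cluster]) & set(degs.degs)
        vals = [lfc[g] for g in member_degs if g in lfc]
        med_rows.append(
            {
                "cluster": cluster,
                "n_member_degs": len(vals),
                "median_log2fc": float(np.median(vals)) if vals else float("nan"),
                "no_degs": not vals,
            }
        )
    return enr.merge(pd.DataFrame(med_rows), on="cluster", how="left")
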