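"""Summit/TSS-centered signal matrices, deterministic k-means, metaprofiles.

The matrix is the substrate of every heatmap-style analysis: rows are
regions (anchored at a peak summit or a gene TSS), columns are fixed-width
bins spanning ``window_bp`` on either side of the anchor.  Normalizations
follow ChIP-seq convention: depth-normalized coverage combined as
log2(ChIP/Input) within a condition and log2(KD/Control) between
conditions, with a pseudocount bounding log-ratios at empty bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .genomic_io import SignalTrack

__all__ = [
    "SignalMatrix",
    "ClusterAssignment",
    "extract_matrix",
    "log2_ratio_matrix",
    "kmeans_rows",
    "metaprofile",
]

NORMALIZATIONS = {"log2_chip_over_input", "log2_kd_over_control", "raw"}


@dataclass
class SignalMatrix:
    row_ids: list[str]
    values: np.ndarray  # n_regions x n_bins, float64, finite
    window_bp: int
    bin_bp: int
    anchor: str  # "summit" | "tss"
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.window_bp % self.bin_bp != 0:
            raise ValueError("window_bp must be divisible by bin_bp")
        n_bins = 2 * self.window_bp // self.bin_bp
        if self.values.shape != (len(self.row_ids), n_bins):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {n_bins} bins"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite values")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def bin_offsets(self) -> np.ndarray:
        """Signed bp offset of each bin center from the anchor."""
        return (
            -self.window_bp
            + self.bin_bp * np.arange(self.n_bins)
            + self.bin_bp / 2
        )


@dataclass
class ClusterAssignment:
    labels: dict[str, int]  # row_id -> 1..k, cluster 1 = highest mean signal
    k: int
    seed: int
    cluster_order: list[int] = field(default_factory=list)

    def members(self, cluster: int) -> list[str]:
        return [r for r, c in self.labels.items() if c == cluster]

    def label_array(self, row_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.labels[r] for r in row_ids], dtype=np.int64)


def extract_matrix(
    track: SignalTrack,
    anchors: Sequence[tuple[str, int, str]],
    window_bp: int = 2000,
    bin_bp: int = 50,
    anchor_kind: str = "summit",
    row_ids: Sequence[str] | None = None,
) -> SignalMatrix:
    """Build an anchor-centered binned signal matrix.

    ``anchors`` are (chrom, position, strand) triples.  Bin value is the
    mean track value over the bin; bins extending past the chromosome
    start are zero-filled.  For ``-`` strand anchors the bin order is
    reversed so upstream is always on the left.
    """
    if not anchors:
        raise ValueError("empty anchor list")
    if window_bp % bin_bp != 0:
        raise ValueError("window_bp must be divisible by bin_bp")
    n_bins = 2 * window_bp // bin_bp
    rows = np.zeros((len(anchors), n_bins), dtype=np.float64)
    for i, (chrom, pos, strand) in enumerate(anchors):
        row = track.binned_means(chrom, pos - window_bp, n_bins, bin_bp)
        if strand == "-":
            row = row[::-1]
        rows[i] = row
    if row_ids is None:
        row_ids = [f"{c}:{p}" for c, p, _ in anchors]
    return SignalMatrix(list(row_ids), rows, window_bp, bin_bp, anchor_kind)


def log2_ratio_matrix(
    numerator: SignalMatrix,
    denominator: SignalMatrix,
    pseudocount: float = 1.0,
    normalization: str = "log2_chip_over_input",
) -> SignalMatrix:
    """Elementwise log2((a + c)/(b + c)) of two aligned matrices."""
    if numerator.row_ids != denominator.row_ids:
        raise ValueError("row_ids mismatch")
    for attr in ("window_bp", "bin_bp", "anchor"):
        if getattr(numerator, attr) != getattr(denominator, attr):
            raise ValueError(f"{attr} mismatch")
    if numerator.values.shape != denominator.values.shape:
        raise ValueError("shape mismatch")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    vals = np.log2(
        (numerator.values + pseudocount) / (denominator.values + pseudocount)
    )
    return SignalMatrix(
        list(numerator.row_ids),
        vals,
        numerator.window_bp,
        numerator.bin_bp,
        numerator.anchor,
        normalization,
    )


def kmeans_rows(
    matrix: SignalMatrix, k: int, seed: int, n_restarts: int = 10
) -> ClusterAssignment:
    """Euclidean k-means on matrix rows, deterministic given ``seed``.

    Best of ``n_restarts`` k-means++ initializations by within-cluster sum
    of squares.  Labels are relabeled by descending cluster mean signal so
    that "cluster 1" always names the strongest cluster regardless of the
    initialization permutation.
    """
    n = matrix.values.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside [1, n_regions={n}]")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(matrix.values)
    # rank raw labels by mean matrix value of members, descending;
    # ties broken by raw label for determinism
    means = np.array([matrix.values[raw == j].mean() for j in range(k)])
    order = sorted(range(k), key=lambda j: (-means[j], j))
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = {rid: remap[int(lab)] for rid, lab in zip(matrix.row_ids, raw)}
    return ClusterAssignment(labels, k=k, seed=seed,
                             cluster_order=list(range(1, k + 1)))


def metaprofile(
    matrix: SignalMatrix, clusters: ClusterAssignment
) -> dict[int, np.ndarray]:
    """Per-cluster column-wise mean profile."""
    idx = {rid: i for i, rid in enumerate(matrix.row_ids)}
    out: dict[int, np.ndarray] = {}
    for c in range(1, clusters.k + 1):
        members = [idx[r] for r in clusters.members(c) if r in idx]
        if not members:
            out[c] = np.full(matrix.n_bins, np.nan)
        else:
            out[c] = matrix.values[members].mean(axis=0)
    return out


def write_matrix(matrix: SignalMatrix, path, sidecar_path=None) -> None:
    """Serialize a matrix as TSV with a JSON sidecar of its parameters."""
    import json

    with open(path, "w") as fh:
        n = matrix.n_bins
        fh.write("row_id\t" + "\t".join(f"bin{i}" for i in range(n)) + "\n")
        for rid, row in zip(matrix.row_ids, matrix.values):
            fh.write(rid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(
                {
                    "window_bp": matrix.window_bp,
                    "bin_bp": matrix.bin_bp,
                    "anchor": matrix.anchor,
                    "normalization": matrix.normalization,
                },
                fh,
                indent=2,
            )
            fh.write("\n")


def write_clusters(clusters: ClusterAssignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("row_id\tcluster\n")
        for rid, c in clusters.labels.items():
            fh.write(f"{rid}\t{c}\n")
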