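"""Genomic interval / track data model and flat-file readers and writers.

All coordinates are 0-based half-open (BED convention) throughout the
package; conversions, if any, happen only at the I/O boundary.  Chromosome
names are matched by exact string comparison — no ``chr`` aliasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Peak",
    "SignalTrack",
    "GeneModel",
    "read_peaks",
    "write_peaks",
    "read_bedgraph",
    "write_bedgraph",
    "read_gene_table",
    "write_gene_table",
    "overlap_query",
    "fetch_sequence",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A called peak with a single-bp summit anchoring windowed analyses."""

    interval: GenomicInterval
    summit_offset: int
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if self.summit_offset < 0:
            raise ValueError(f"peak {self.name}: negative summit_offset")
        if self.interval.start + self.summit_offset >= self.interval.end:
            raise ValueError(
                f"peak {self.name}: summit_offset {self.summit_offset} outside "
                f"interval of length {len(self.interval)}"
            )
        if self.score < 0:
            raise ValueError(f"peak {self.name}: negative score")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def summit(self) -> int:
        """Absolute summit position (bp)."""
        return self.interval.start + self.summit_offset


class SignalTrack:
    """Piecewise-constant coverage, per-chromosome sorted non-overlapping runs.

    Queries outside covered runs return 0.  Values are in arbitrary
    depth-normalized units (RPKM-like); a bedGraph file is the exchange
    format.
    """

    def __init__(self, runs: dict[str, list[tuple[int, int, float]]] | None = None):
        self._runs: dict[str, tuple] = {}
        if runs:
            for chrom, r in runs.items():
                self._set_chrom(chrom, r)

    def _set_chrom(self, chrom: str, runs: Sequence[tuple[int, int, float]]) -> None:
        import numpy as np

        runs = sorted(runs)
        prev_end = -1
        for start, end, value in runs:
            if start >= end:
                raise ValueError(f"{chrom}: empty run [{start},{end})")
            if start < prev_end:
                raise ValueError(f"{chrom}: overlapping runs at {start}")
            if not math.isfinite(value):
                raise ValueError(f"{chrom}: non-finite value at {start}")
            prev_end = end
        starts = np.array([r[0] for r in runs], dtype=np.int64)
        ends = np.array([r[1] for r in runs], dtype=np.int64)
        values = np.array([r[2] for r in runs], dtype=np.float64)
        # cumulative integral up to each run start, for O(log n) point queries
        cum = np.concatenate(([0.0], np.cumsum((ends - starts) * values)))
        self._runs[chrom] = (starts, ends, values, cum)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._runs)

    def runs(self, chrom: str) -> list[tuple[int, int, float]]:
        if chrom not in self._runs:
            return []
        starts, ends, values, _ = self._runs[chrom]
        return [(int(s), int(e), float(v)) for s, e, v in zip(starts, ends, values)]

    def _cumulative_at(self, chrom: str, positions):
        """Integral of the track over [0, x) for each x, vectorized."""
        import numpy as np

        starts, ends, values, cum = self._runs[chrom]
        x = np.clip(np.asarray(positions, dtype=np.float64), 0.0, None)
        if len(starts) == 0:
            return np.zeros_like(x)
        j = np.searchsorted(ends, x, side="right")  # runs fully before x
        F = cum[j]
        inside = j < len(starts)
        jj = np.minimum(j, len(starts) - 1)
        partial = np.where(
            inside & (x > starts[jj]), (x - starts[jj]) * values[jj], 0.0
        )
        return F + partial

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean value over [start, end), counting uncovered bp as 0."""
        if end <= start:
            raise ValueError("empty query interval")
        return self.integral(chrom, start, end) / (end - start)

    def integral(self, chrom: str, start: int, end: int) -> float:
        """Sum of value × bp over [start, end)."""
        if chrom not in self._runs:
            return 0.0
        lo, hi = self._cumulative_at(chrom, [start, end])
        return float(hi - lo)

    def binned_means(self, chrom: str, start: int, n_bins: int, bin_bp: int):
        """Means over ``n_bins`` consecutive bins of width ``bin_bp`` from
        ``start``; bins reaching before position 0 count the off-chromosome
        part as 0 coverage but still divide by the full bin width."""
        import numpy as np

        if chrom not in self._runs:
            return np.zeros(n_bins, dtype=np.float64)
        edges = start + bin_bp * np.arange(n_bins + 1, dtype=np.int64)
        F = self._cumulative_at(chrom, edges)
        return (F[1:] - F[:-1]) / bin_bp


@dataclass(frozen=True)
class GeneModel:
    """A single-isoform gene model with TSS derived from strand."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    gene_start: int
    gene_end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (self.gene_start <= self.tss <= self.gene_end):
            raise ValueError(f"gene {self.gene_id}: TSS outside gene body")
        prev = self.gene_start
        for s, e in self.exons:
            if s < prev or e > self.gene_end or s >= e:
                raise ValueError(f"gene {self.gene_id}: bad exon ({s},{e})")
            prev = e


# ---------------------------------------------------------------------------
# readers / writers


def _split(line: str) -> list[str]:
    return line.rstrip("\n").split("\t")


def read_peaks(path: str | Path, format: str = "narrowPeak") -> list[Peak]:
    """Read BED6 or ENCODE narrowPeak peak calls.

    narrowPeak column 10 is the summit offset from the interval start; a
    value of −1 (or BED6 input, which has no summit column) falls back to
    the interval midpoint ``floor((end-start)/2)``.
    """
    if format not in {"bed6", "narrowPeak"}:
        raise ValueError(f"unknown peak format {format!r}")
    ncol = 6 if format == "bed6" else 10
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split(line)
            if len(fields) < ncol:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {ncol} columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                score = float(fields[4])
                strand = fields[5]
                if format == "narrowPeak":
                    summit = int(fields[9])
                else:
                    summit = -1
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if summit == -1:
                summit = (end - start) // 2
            try:
                peaks.append(
                    Peak(
                        GenomicInterval(chrom, start, end, strand if strand in "+-." else "."),
                        summit_offset=summit,
                        score=score,
                        name=name,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path, format: str = "narrowPeak") -> None:
    with open(path, "w") as fh:
        for p in peaks:
            base = [p.chrom, str(p.start), str(p.end), p.name,
                    format_score(p.score), p.interval.strand]
            if format == "narrowPeak":
                base += [format_score(p.score), "-1", "-1", str(p.summit_offset)]
            fh.write("\t".join(base) + "\n")


def format_score(x: float) -> str:
    # shortest representation that round-trips exactly
    return repr(float(x))


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`.

    Header lines beginning with ``track`` or ``#`` are tolerated.
    Overlapping runs are an error; adjacent equal-value runs may or may not
    be merged by a writer — queries are invariant to that.
    """
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            fields = _split(line)
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            if not math.isfinite(value):
                raise ValueError(f"{path}:{lineno}: non-finite value")
            by_chrom.setdefault(chrom, []).append((start, end, value))
    try:
        return SignalTrack(by_chrom)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_bedgraph(track: SignalTrack, path: str | Path, merge: bool = True) -> None:
    """Write a SignalTrack as bedGraph, merging adjacent equal-value runs."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            merged: list[list] = []
            for s, e, v in track.runs(chrom):
                if merge and merged and merged[-1][1] == s and merged[-1][2] == v:
                    merged[-1][1] = e
                else:
                    merged.append([s, e, v])
            for s, e, v in merged:
                fh.write(f"{chrom}\t{s}\t{e}\t{format_score(v)}\n")


_GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "gene_start", "gene_end", "exons"]


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a tab-separated gene table.

    Required columns: gene_id, chrom, strand, gene_start, gene_end.
    Optional: tss (computed from strand if absent: + ⇒ gene_start,
    − ⇒ gene_end), exons (comma-separated ``start-end`` blocks).
    Duplicate gene_ids are an error.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = _split(next(fh))
        idx = {name: i for i, name in enumerate(header)}
        for req in ("gene_id", "chrom", "strand", "gene_start", "gene_end"):
            if req not in idx:
                raise ValueError(f"{path}: missing column {req!r}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            f = _split(line)
            gene_id = f[idx["gene_id"]]
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            strand = f[idx["strand"]]
            gene_start = int(f[idx["gene_start"]])
            gene_end = int(f[idx["gene_end"]])
            if "tss" in idx and f[idx["tss"]] not in ("", "."):
                tss = int(f[idx["tss"]])
            else:
                tss = gene_start if strand == "+" else gene_end
            exons: tuple[tuple[int, int], ...] = ()
            if "exons" in idx and f[idx["exons"]] not in ("", "."):
                exons = tuple(
                    (int(a), int(b))
                    for a, b in (blk.split("-") for blk in f[idx["exons"]].split(","))
                )
            try:
                genes.append(
                    GeneModel(gene_id, f[idx["chrom"]], strand, tss,
                              gene_start, gene_end, exons)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in genes:
            exons = ",".join(f"{s}-{e}" for s, e in g.exons) or "."
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t"
                f"{g.gene_start}\t{g.gene_end}\t{exons}\n"
            )


def overlap_query(
    query: GenomicInterval, subjects: Sequence[GenomicInterval]
) -> list[int]:
    """Indices of ``subjects`` overlapping ``query`` (half-open semantics)."""
    trees: dict[str, IntervalTree] = {}
    for i, s in enumerate(subjects):
        trees.setdefault(s.chrom, IntervalTree()).addi(s.start, s.end, i)
    tree = trees.get(query.chrom)
    if tree is None:
        return []
    return sorted(iv.data for iv in tree.overlap(query.start, query.end))


class OverlapIndex:
    """Reusable interval index over a fixed subject list."""

    def __init__(self, subjects: Sequence[GenomicInterval]):
        self._trees: dict[str, IntervalTree] = {}
        for i, s in enumerate(subjects):
            self._trees.setdefault(s.chrom, IntervalTree()).addi(s.start, s.end, i)

    def query(self, interval: GenomicInterval) -> list[int]:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.overlap(interval.start, interval.end))


def fetch_sequence(fasta_path: str | Path, interval: GenomicInterval) -> str:
    """Fetch the (uppercased) sequence of an interval from a FASTA file.

    Positions beyond the chromosome are padded with ``N`` so callers can
    request fixed-width summit windows near contig edges.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    if interval.chrom not in fa:
        raise KeyError(f"chromosome {interval.chrom!r} not in {fasta_path}")
    chrom_len = len(fa[interval.chrom])
    lo = max(interval.start, 0)
    hi = min(interval.end, chrom_len)
    core = str(fa[interval.chrom][lo:hi]) if hi > lo else ""
    left = "N" * (lo - interval.start)
    right = "N" * (interval.end - hi)
    return left + core + right
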