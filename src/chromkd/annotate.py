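"""Peak-to-feature and peak-to-gene annotation by summit position.

Classification precedence is promoter > exon > intron > downstream >
distal_intergenic, evaluated at the peak summit.  The promoter window is
measured in transcription direction (default −2000/+500 bp around the
TSS); ``downstream`` extends a fixed distance past the gene end.  Distal
peaks are still assigned their nearest-TSS gene so that gene-level set
analyses can include distal regulatory regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .genomic_io import GeneModel, Peak

__all__ = ["FeatureCall", "assign_feature", "annotate_peaks", "genomic_distribution"]

FEATURES = ("promoter", "exon", "intron", "downstream", "distal_intergenic")


@dataclass(frozen=True)
class FeatureCall:
    peak_name: str
    feature: str
    assigned_gene: str | None
    distance_to_tss: int  # signed, in transcription direction; negative = upstream


def _signed_distance(summit: int, gene: GeneModel) -> int:
    """Signed summit−TSS distance in transcription direction."""
    d = summit - gene.tss
    return d if gene.strand == "+" else -d


def _feature_for_gene(
    summit: int, gene: GeneModel, promoter_up: int, promoter_down: int, downstream_bp: int
) -> str | None:
    """Most specific feature this gene can claim for the summit, or None."""
    d = _signed_distance(summit, gene)
    if -promoter_up <= d <= promoter_down:
        return "promoter"
    if gene.gene_start <= summit < gene.gene_end:
        for s, e in gene.exons:
            if s <= summit < e:
                return "exon"
        return "intron"
    # downstream of the gene end in transcription direction
    if gene.strand == "+":
        if gene.gene_end <= summit < gene.gene_end + downstream_bp:
            return "downstream"
    else:
        if gene.gene_start - downstream_bp < summit <= gene.gene_start:
            return "downstream"
    return None


def assign_feature(
    peak: Peak,
    genes: Sequence[GeneModel],
    promoter_up: int = 2000,
    promoter_down: int = 500,
    downstream_bp: int = 3000,
) -> FeatureCall:
    """Classify one peak by its summit against a gene list.

    The best (highest-precedence) feature over all same-chromosome genes
    wins; among genes offering that feature, ties break by smallest
    |distance_to_tss|, then lexicographic gene_id, so the call is invariant
    to gene-list order.  With no matching feature the peak is
    distal_intergenic, assigned to the nearest TSS.
    """
    if not genes:
        raise ValueError("gene list is empty")
    summit = peak.summit
    rank = {f: i for i, f in enumerate(FEATURES)}
    best: tuple[int, int, str] | None = None  # (feature_rank, |dist|, gene_id)
    best_gene: GeneModel | None = None
    nearest: tuple[int, str] | None = None
    nearest_gene: GeneModel | None = None
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        d = _signed_distance(summit, g)
        key_near = (abs(d), g.gene_id)
        if nearest is None or key_near < nearest:
            nearest, nearest_gene = key_near, g
        feat = _feature_for_gene(summit, g, promoter_up, promoter_down, downstream_bp)
        if feat is None:
            continue
        key = (rank[feat], abs(d), g.gene_id)
        if best is None or key < best:
            best, best_gene = key, g
    if best_gene is not None:
        return FeatureCall(
            peak.name,
            FEATURES[best[0]],
            best_gene.gene_id,
            _signed_distance(summit, best_gene),
        )
    if nearest_gene is None:
        # no gene on this chromosome at all
        return FeatureCall(peak.name, "distal_intergenic", None, 0)
    return FeatureCall(
        peak.name,
        "distal_intergenic",
        nearest_gene.gene_id,
        _signed_distance(summit, nearest_gene),
    )


def annotate_peaks(
    peaks: Iterable[Peak], genes: Sequence[GeneModel], **kwargs
) -> list[FeatureCall]:
    return [assign_feature(p, genes, **kwargs) for p in peaks]


def genomic_distribution(
    calls: Sequence[FeatureCall],
    groups: Sequence | None = None,
    all_groups: Sequence | None = None,
) -> dict:
    """Per-group fraction of each feature class.

    Returns ``{group: {feature: fraction}}``; fractions per group sum to 1.
    An empty group (possible when ``all_groups`` names groups with no
    calls) yields all-zero fractions with an ``_empty`` flag.  With
    ``groups=None`` everything falls in group ``"all"``.
    """
    if groups is None:
        groups = ["all"] * len(calls)
    if len(groups) != len(calls):
        raise ValueError("groups length must match calls")
    wanted = set(groups) if all_groups is None else set(all_groups) | set(groups)
    out: dict = {}
    for g in wanted:
        members = [c for c, gg in zip(calls, groups) if gg == g]
        fracs = {f: 0.0 for f in FEATURES}
        if members:
            for c in members:
                fracs[c.feature] += 1.0
            for f in FEATURES:
                fracs[f] /= len(members)
        else:
            fracs["_empty"] = True
        out[g] = fracs
    return out


def write_feature_calls(
    calls: Sequence[FeatureCall], path, groups: Sequence | None = None
) -> None:
    if groups is None:
        groups = ["."] * len(calls)
    with open(path, "w") as fh:
        fh.write("peak\tfeature\tgene\tdistance_to_tss\tgroup\n")
        for c, g in zip(calls, groups):
            gene = c.assigned_gene if c.assigned_gene is not None else "."
            fh.write(f"{c.peak_name}\t{c.feature}\t{gene}\t{c.distance_to_tss}\t{g}\n")
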