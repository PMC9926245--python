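"""Synthetic genomes, tracks, DEG tables and TF-pair scenarios with truth.

Every generator is deterministic given the root seed: each component
draws from a named substream derived from the seed, so regenerating one
component never perturbs another.  The emitted files are exactly the
formats the I/O module reads (narrowPeak, bedGraph, gene table, DEG
table, FASTA), and each scenario returns a truth table sufficient to
validate the downstream analysis that consumes it.

The planted structure mirrors the experimental design being emulated:
peaks whose ChIP signal is stable, gained or lost under knockdown;
DEG tables with planted repression-/recruitment-model genes that are
consistent across all required input sets; motif placements that are
summit-centered or flanking; and TF-pair regions whose reciprocal
knockdown response is cooperative, competitive or independent.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .degsets import DEGTable
from .genomic_io import (
    GeneModel,
    GenomicInterval,
    Peak,
    SignalTrack,
)
from .motifs import PWM

__all__ = [
    "ScenarioConfig",
    "substream",
    "generate_genome",
    "generate_tracks_and_peaks",
    "generate_deg_tables",
    "generate_motif_sequences",
    "generate_pair_scenario",
    "builtin_pwms",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named RNG substream: independent, deterministic, platform-stable."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


@dataclass
class ScenarioConfig:
    """All knobs of the synthetic study, with the emulated design as defaults."""

    seed: int = 0
    # genome
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 80
    gene_slot_bp: int = 10_000
    # peaks / tracks
    n_peaks: int = 90
    signal_class_props: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    peak_halfwidth: int = 250
    bump_sd: float = 150.0
    amp_shape: float = 4.0
    amp_scale: float = 5.0
    background_rate: float = 1.0  # Poisson mean per resolution bin
    kd_factor_gain: float = 2.0
    kd_factor_loss: float = 0.5
    track_resolution: int = 10  # bedGraph bin width, bp
    # DEG / mechanism scenario
    n_repression: int = 30
    n_recruitment: int = 10
    n_null_genes: int = 1960
    n_repression_decoys: int = 0  # candidate-stage genes excluded by TSA-control response
    deg_lfc_mean: float = 1.5
    deg_lfc_sd: float = 0.3
    null_lfc_sd: float = 0.2
    frac_null_tsa_responders: float = 0.05
    frac_null_ac_members: float = 0.05
    frac_null_bound: float = 0.10
    # motif geometry
    motif_window: int = 100
    motif_center_sd: float = 5.0
    motif_flank_min: int = 40
    motif_flank_max: int = 100
    # TF-pair scenario
    n_pair_regions: int = 300
    pair_mode_props: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    pair_effect_log2: float = 1.5
    pair_region_halfwidth: int = 500

    def __post_init__(self) -> None:
        for props in (self.signal_class_props, self.pair_mode_props):
            if abs(sum(props) - 1.0) > 1e-9:
                raise ValueError("class proportions must sum to 1")
        if self.background_rate < 0 or self.amp_shape <= 0 or self.amp_scale <= 0:
            raise ValueError("rates must be positive")


SIGNAL_CLASSES = ("stable", "gain", "loss")
PAIR_MODES = ("cooperative", "competitive", "independent")


def builtin_pwms() -> dict[str, PWM]:
    """Sharp forkhead-like and E-box-like PWMs used for motif planting."""

    def sharp(name: str, consensus: str) -> PWM:
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        mat = np.full((len(consensus), 4), 0.01)
        for i, b in enumerate(consensus):
            mat[i, idx[b]] = 0.97
        return PWM(name, mat)

    return {"FKH": sharp("FKH", "TGTTTAC"), "EBOX": sharp("EBOX", "CAGCTGG")}


# ---------------------------------------------------------------------------
# genome


@dataclass
class Genome:
    genes: list[GeneModel]
    sequences: dict[str, str]
    chrom_lengths: dict[str, int]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from .genomic_io import write_gene_table

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gene_path = outdir / "genes.tsv"
        fasta_path = outdir / "genome.fa"
        write_gene_table(self.genes, gene_path)
        with open(fasta_path, "w") as fh:
            for chrom in sorted(self.sequences):
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        return {"genes": gene_path, "fasta": fasta_path}


def generate_genome(config: ScenarioConfig) -> Genome:
    """Place non-overlapping genes on alternating strands over a random genome.

    Each gene occupies one ``gene_slot_bp`` slot; gene bodies are 2–8 kb
    with 2–5 exons.  Sequence is i.i.d. uniform {A,C,G,T}.
    """
    total = config.n_chromosomes * config.chrom_length
    if total < config.n_genes * config.gene_slot_bp:
        raise ValueError(
            f"infeasible packing: {config.n_genes} genes x {config.gene_slot_bp} bp "
            f"> genome of {total} bp"
        )
    rng = substream(config.seed, "genome")
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    slots_per_chrom = config.chrom_length // config.gene_slot_bp
    genes: list[GeneModel] = []
    g = 0
    for ci, chrom in enumerate(chroms):
        n_here = min(
            slots_per_chrom,
            max(0, config.n_genes - ci * slots_per_chrom),
        )
        for s in range(n_here):
            slot = s * config.gene_slot_bp
            body = int(rng.integers(2000, 8001))
            start = slot + int(rng.integers(200, config.gene_slot_bp - body - 200))
            end = start + body
            strand = "+" if g % 2 == 0 else "-"
            n_ex = int(rng.integers(2, 6))
            cuts = np.sort(rng.choice(np.arange(1, body), size=2 * n_ex, replace=False))
            exons = tuple(
                (start + int(cuts[2 * i]), start + int(cuts[2 * i + 1]))
                for i in range(n_ex)
            )
            tss = start if strand == "+" else end
            genes.append(
                GeneModel(f"gene{g:05d}", chrom, strand, tss, start, end, exons)
            )
            g += 1
    sequences = {
        chrom: "".join(
            np.array(list("ACGT"))[
                rng.integers(0, 4, size=config.chrom_length)
            ]
        )
        for chrom in chroms
    }
    lengths = {c: config.chrom_length for c in chroms}
    return Genome(genes, sequences, lengths)


# ---------------------------------------------------------------------------
# tracks and peaks


@dataclass
class TrackScenario:
    peaks: list[Peak]
    truth: pd.DataFrame  # peak, class, amplitude
    chip_control: SignalTrack
    chip_kd: SignalTrack
    input_control: SignalTrack
    input_kd: SignalTrack

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from .genomic_io import write_bedgraph, write_peaks

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"peaks": outdir / "peaks.narrowPeak", "truth": outdir / "peak_truth.tsv"}
        write_peaks(self.peaks, paths["peaks"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        for name in ("chip_control", "chip_kd", "input_control", "input_kd"):
            paths[name] = outdir / f"{name}.bedGraph"
            write_bedgraph(getattr(self, name), paths[name])
        return paths


def _poisson_track(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    resolution: int,
    background: float,
    bumps: dict[str, list[tuple[int, float]]],
    bump_sd: float,
) -> SignalTrack:
    """Sample a coverage track: per-bin Poisson(background + Gaussian bumps),
    written as per-bp rates so that integrals recover sampled counts."""
    runs: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, length in sorted(chrom_lengths.items()):
        n_bins = length // resolution
        lam = np.full(n_bins, background, dtype=np.float64)
        centers = resolution * np.arange(n_bins) + resolution / 2
        for summit, amp in bumps.get(chrom, []):
            lo = max(0, int((summit - 5 * bump_sd) // resolution))
            hi = min(n_bins, int((summit + 5 * bump_sd) // resolution) + 1)
            d = centers[lo:hi] - summit
            lam[lo:hi] += amp * np.exp(-0.5 * (d / bump_sd) ** 2)
        counts = rng.poisson(lam)
        edges = resolution * np.arange(n_bins + 1)
        runs[chrom] = [
            (int(edges[i]), int(edges[i + 1]), counts[i] / resolution)
            for i in range(n_bins)
            if counts[i] > 0
        ]
    return SignalTrack(runs)


def generate_tracks_and_peaks(
    config: ScenarioConfig, chrom_lengths: dict[str, int] | None = None
) -> TrackScenario:
    """Plant peaks with stable/gain/loss knockdown classes into coverage.

    Peaks are laid out evenly with at least 2×(window+width) spacing so
    summit windows never overlap.  Each peak adds a Gaussian bump
    (sd ``bump_sd``) of amplitude ~ Gamma(``amp_shape``, ``amp_scale``)
    to the ChIP tracks; the knockdown track multiplies the amplitude by
    the class factor (stable 1.0, gain ``kd_factor_gain``, loss
    ``kd_factor_loss``).  Input tracks carry background only.
    """
    if chrom_lengths is None:
        chrom_lengths = {
            f"chr{i + 1}": config.chrom_length for i in range(config.n_chromosomes)
        }
    rng = substream(config.seed, "tracks")
    chroms = sorted(chrom_lengths)
    # even peak layout with margins
    margin = 6000
    spacing_ok = sum(
        max(0, (chrom_lengths[c] - margin) // margin) for c in chroms
    )
    if spacing_ok < config.n_peaks:
        raise ValueError("genome too small for requested peak count")
    slots: list[tuple[str, int]] = []
    for c in chroms:
        n_slots = (chrom_lengths[c] - margin) // margin
        for s in range(n_slots):
            slots.append((c, margin // 2 + s * margin))
    take = np.linspace(0, len(slots) - 1, config.n_peaks).astype(int)
    # planted class per peak, shuffled
    n_per = np.floor(np.array(config.signal_class_props) * config.n_peaks).astype(int)
    while n_per.sum() < config.n_peaks:
        n_per[int(np.argmin(n_per))] += 1
    classes = np.repeat(SIGNAL_CLASSES, n_per)
    rng.shuffle(classes)
    amps = rng.gamma(config.amp_shape, config.amp_scale, size=config.n_peaks)
    factor = {
        "stable": 1.0,
        "gain": config.kd_factor_gain,
        "loss": config.kd_factor_loss,
    }
    peaks: list[Peak] = []
    rows = []
    bumps_ctrl: dict[str, list[tuple[int, float]]] = {}
    bumps_kd: dict[str, list[tuple[int, float]]] = {}
    for i, slot_idx in enumerate(take):
        chrom, center = slots[slot_idx]
        summit = center + int(rng.integers(-100, 101))
        start = summit - config.peak_halfwidth
        end = summit + config.peak_halfwidth
        name = f"peak{i:05d}"
        peaks.append(
            Peak(
                GenomicInterval(chrom, start, end),
                summit_offset=summit - start,
                score=float(amps[i]),
                name=name,
            )
        )
        rows.append(
            {"peak": name, "class": classes[i], "amplitude": float(amps[i])}
        )
        bumps_ctrl.setdefault(chrom, []).append((summit, float(amps[i])))
        bumps_kd.setdefault(chrom, []).append(
            (summit, float(amps[i]) * factor[classes[i]])
        )
    res, bg, sd = config.track_resolution, config.background_rate, config.bump_sd
    return TrackScenario(
        peaks=peaks,
        truth=pd.DataFrame(rows),
        chip_control=_poisson_track(rng, chrom_lengths, res, bg, bumps_ctrl, sd),
        chip_kd=_poisson_track(rng, chrom_lengths, res, bg, bumps_kd, sd),
        input_control=_poisson_track(rng, chrom_lengths, res, bg, {}, sd),
        input_kd=_poisson_track(rng, chrom_lengths, res, bg, {}, sd),
    )


# ---------------------------------------------------------------------------
# DEG tables and mechanism scenario


@dataclass
class MechanismScenario:
    deg_kd: DEGTable  # KD vs control
    deg_tsa: DEGTable  # KD+TSA vs KD
    deg_tsa_control: DEGTable  # TSA vs vehicle under control conditions
    ac_down_genes: frozenset[str]
    ac_up_genes: frozenset[str]
    bound_genes: frozenset[str]
    tsa_control_responders: frozenset[str]
    truth: pd.DataFrame  # gene_id, class

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("deg_kd", "deg_tsa", "deg_tsa_control"):
            paths[name] = outdir / f"{name}.tsv"
            getattr(self, name).df.to_csv(paths[name], sep="\t", index=False)
        for name in ("ac_down_genes", "ac_up_genes", "bound_genes"):
            paths[name] = outdir / f"{name}.txt"
            with open(paths[name], "w") as fh:
                for g in sorted(getattr(self, name)):
                    fh.write(g + "\n")
        paths["truth"] = outdir / "mechanism_truth.tsv"
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _deg_frame(
    gene_ids: list[str],
    planted_sign: dict[str, int],
    rng: np.random.Generator,
    config: ScenarioConfig,
) -> DEGTable:
    """DEG table with planted significant genes and null background.

    Null genes: log2fc ~ N(0, null_lfc_sd), padj ~ U(0.05, 1) — never
    passing the padj <= 0.05 rule.  Planted genes: |log2fc| ~
    N(deg_lfc_mean, deg_lfc_sd) truncated above the LFC cutoff, sign per
    class, padj ~ U(0, 0.01).
    """
    import math

    lfc_cut = math.log2(1.5)
    rows = []
    for g in gene_ids:
        sign = planted_sign.get(g, 0)
        if sign == 0:
            lfc = rng.normal(0.0, config.null_lfc_sd)
            padj = rng.uniform(0.05, 1.0)
        else:
            mag = abs(rng.normal(config.deg_lfc_mean, config.deg_lfc_sd))
            mag = max(mag, lfc_cut + 0.05)  # planted DEGs always pass the cutoff
            lfc = sign * mag
            padj = rng.uniform(0.0, 0.01)
        rows.append({"gene_id": g, "log2fc": lfc, "padj": padj})
    return DEGTable(pd.DataFrame(rows))


def generate_deg_tables(
    config: ScenarioConfig,
    peak_truth: pd.DataFrame | None = None,
    gene_assignment: dict[str, str] | None = None,
) -> MechanismScenario:
    """Plant repression-, recruitment- and null-class genes consistently.

    Repression genes are down in KD, in the H3K27ac-loss set, up under
    TSA-on-KD, and absent from TSA-control responders.  Recruitment
    genes are up in KD, in the H3K27ac-gain set, TF-bound, and TSA
    non-responsive.  Optional repression decoys satisfy the candidate
    criteria but are TSA-control responders, so the confirmation stage
    must exclude them.  A fraction of null genes is sprinkled into the
    acetylation/bound/TSA-responder sets as annotation noise.

    If ``peak_truth``/``gene_assignment`` map peaks to genes, those genes
    join the TF-bound set.
    """
    rng = substream(config.seed, "degs")
    n_total = (
        config.n_repression
        + config.n_recruitment
        + config.n_repression_decoys
        + config.n_null_genes
    )
    gene_ids = [f"gene{i:05d}" for i in range(n_total)]
    perm = rng.permutation(n_total)
    rep = [gene_ids[i] for i in perm[: config.n_repression]]
    rec = [
        gene_ids[i]
        for i in perm[config.n_repression : config.n_repression + config.n_recruitment]
    ]
    off = config.n_repression + config.n_recruitment
    decoys = [gene_ids[i] for i in perm[off : off + config.n_repression_decoys]]
    null = [gene_ids[i] for i in perm[off + config.n_repression_decoys :]]

    # KD vs control: repression and decoys down, recruitment up
    sign_kd = {g: -1 for g in rep + decoys}
    sign_kd.update({g: +1 for g in rec})
    deg_kd = _deg_frame(gene_ids, sign_kd, rng, config)

    # KD+TSA vs KD: repression and decoys rescued (up); recruitment silent
    sign_tsa = {g: +1 for g in rep + decoys}
    deg_tsa = _deg_frame(gene_ids, sign_tsa, rng, config)

    # TSA vs vehicle under control conditions: decoys respond, plus random null genes
    n_null_resp = int(round(config.frac_null_tsa_responders * len(null)))
    null_responders = list(rng.choice(null, size=n_null_resp, replace=False))
    sign_ctrl = {g: int(rng.choice([-1, 1])) for g in decoys + null_responders}
    deg_tsa_control = _deg_frame(gene_ids, sign_ctrl, rng, config)
    tsa_control_responders = frozenset(decoys + null_responders)

    n_ac_noise = int(round(config.frac_null_ac_members * len(null)))
    ac_down = frozenset(rep) | frozenset(decoys) | frozenset(
        rng.choice(null, size=n_ac_noise, replace=False)
    )
    ac_up = frozenset(rec) | frozenset(
        rng.choice(null, size=n_ac_noise, replace=False)
    )
    bound = set(rec) | set(
        rng.choice(null, size=int(round(config.frac_null_bound * len(null))),
                   replace=False)
    )
    if peak_truth is not None and gene_assignment is not None:
        for peak in peak_truth["peak"]:
            g = gene_assignment.get(peak)
            if g in set(gene_ids):
                bound.add(g)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "class": [
                "repression" if g in set(rep)
                else "recruitment" if g in set(rec)
                else "repression_decoy" if g in set(decoys)
                else "null"
                for g in gene_ids
            ],
        }
    )
    return MechanismScenario(
        deg_kd, deg_tsa, deg_tsa_control,
        frozenset(ac_down), frozenset(ac_up), frozenset(bound),
        tsa_control_responders, truth,
    )


# ---------------------------------------------------------------------------
# motif geometry scenario


@dataclass
class MotifScenario:
    sequences: list[tuple[str, str]]  # (peak name, summit-centered sequence)
    truth: pd.DataFrame  # peak, geometry, planted_offset
    pwm: PWM
    window_bp: int


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def generate_motif_sequences(
    config: ScenarioConfig,
    geometry: str,
    n_peaks: int,
    pwm: PWM | None = None,
    stream: str = "motifs",
) -> MotifScenario:
    """Summit-centered windows with a motif planted per geometry class.

    ``center``: offsets ~ round(Normal(0, motif_center_sd));
    ``flank``: |offset| ~ Uniform(motif_flank_min, motif_flank_max),
    random sign; ``absent``: no planting.  The consensus sequence is
    planted on a random strand; windows extend one motif length past
    ±window so flank placements near the edge still fit.
    """
    if geometry not in ("center", "flank", "absent"):
        raise ValueError(f"unknown geometry {geometry!r}")
    if pwm is None:
        pwm = builtin_pwms()["FKH"]
    rng = substream(config.seed, f"{stream}:{geometry}")
    L = pwm.length
    half = config.motif_window + L
    seq_len = 2 * half + 1
    consensus = pwm.consensus
    rc = consensus.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    seqs = []
    rows = []
    for i in range(n_peaks):
        seq = list(_random_seq(rng, seq_len))
        offset = None
        if geometry == "center":
            offset = int(round(rng.normal(0.0, config.motif_center_sd)))
            offset = max(-config.motif_window, min(config.motif_window, offset))
        elif geometry == "flank":
            mag = int(rng.integers(config.motif_flank_min, config.motif_flank_max + 1))
            offset = int(rng.choice([-1, 1])) * mag
        if offset is not None:
            word = consensus if rng.random() < 0.5 else rc
            start = half + offset - L // 2
            seq[start : start + L] = list(word)
        name = f"mpeak{i:05d}"
        seqs.append((name, "".join(seq)))
        rows.append(
            {"peak": name, "geometry": geometry,
             "planted_offset": offset if offset is not None else np.nan}
        )
    return MotifScenario(seqs, pd.DataFrame(rows), pwm, config.motif_window)


# ---------------------------------------------------------------------------
# TF-pair scenario


@dataclass
class PairScenario:
    peaks_a: list[Peak]
    peaks_b: list[Peak]
    truth: pd.DataFrame  # region_id, mode, chrom, start, end
    track_a_control: SignalTrack
    track_a_bkd: SignalTrack  # TF A ChIP under B knockdown
    track_b_control: SignalTrack
    track_b_akd: SignalTrack  # TF B ChIP under A knockdown
    sequences: dict[str, str]  # region_id -> summit-window sequence

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from .genomic_io import write_bedgraph, write_peaks

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "peaks_a": outdir / "tfA_peaks.narrowPeak",
            "peaks_b": outdir / "tfB_peaks.narrowPeak",
            "truth": outdir / "pair_truth.tsv",
        }
        write_peaks(self.peaks_a, paths["peaks_a"])
        write_peaks(self.peaks_b, paths["peaks_b"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        for name in ("track_a_control", "track_a_bkd", "track_b_control", "track_b_akd"):
            paths[name] = outdir / f"{name}.bedGraph"
            write_bedgraph(getattr(self, name), paths[name])
        return paths


def generate_pair_scenario(config: ScenarioConfig) -> PairScenario:
    """Shared TF-pair regions with planted cooperative/competitive/independent
    response to the reciprocal knockdowns.

    Cooperative regions lose both TFs' signal under the partner's KD,
    competitive regions gain the remaining TF's signal, independent
    regions are unchanged; the planted effect is ``pair_effect_log2``
    (factors 2^∓effect).  Region sequences carry an E-box planted at the
    center and a forkhead motif in the flank, emulating adjacent-site
    co-binding geometry.
    """
    rng = substream(config.seed, "pair")
    n = config.n_pair_regions
    spacing = 6000
    needed = (n + 1) * spacing
    n_chrom = max(1, -(-needed // config.chrom_length))
    chrom_lengths = {f"chr{i + 1}": config.chrom_length for i in range(n_chrom)}
    per_chrom = config.chrom_length // spacing - 1
    n_per = np.floor(np.array(config.pair_mode_props) * n).astype(int)
    while n_per.sum() < n:
        n_per[int(np.argmin(n_per))] += 1
    modes = np.repeat(PAIR_MODES, n_per)
    rng.shuffle(modes)
    up, down = 2.0 ** config.pair_effect_log2, 2.0 ** -config.pair_effect_log2
    factor_a = {"cooperative": down, "competitive": up, "independent": 1.0}
    factor_b = dict(factor_a)
    amps_a = rng.gamma(config.amp_shape, config.amp_scale, size=n)
    amps_b = rng.gamma(config.amp_shape, config.amp_scale, size=n)
    pwms = builtin_pwms()
    ebox, fkh = pwms["EBOX"], pwms["FKH"]
    peaks_a, peaks_b, rows = [], [], []
    bumps = {key: {} for key in ("a_ctrl", "a_bkd", "b_ctrl", "b_akd")}
    sequences = {}
    hw = config.pair_region_halfwidth
    for i in range(n):
        chrom = f"chr{i // per_chrom + 1}"
        center = spacing * (i % per_chrom) + spacing // 2
        rid = f"region{i:05d}"
        mode = str(modes[i])
        # overlapping peak pair around the shared center
        ia = GenomicInterval(chrom, center - 300, center + 150)
        ib = GenomicInterval(chrom, center - 150, center + 300)
        peaks_a.append(Peak(ia, summit_offset=300, score=float(amps_a[i]), name=f"A_{rid}"))
        peaks_b.append(Peak(ib, summit_offset=150, score=float(amps_b[i]), name=f"B_{rid}"))
        bumps["a_ctrl"].setdefault(chrom, []).append((center, float(amps_a[i])))
        bumps["b_ctrl"].setdefault(chrom, []).append((center, float(amps_b[i])))
        bumps["a_bkd"].setdefault(chrom, []).append(
            (center, float(amps_a[i]) * factor_a[mode])
        )
        bumps["b_akd"].setdefault(chrom, []).append(
            (center, float(amps_b[i]) * factor_b[mode])
        )
        rows.append(
            {"region_id": rid, "mode": mode, "chrom": chrom,
             "start": center - hw, "end": center + hw}
        )
        # sequence: E-box at center, forkhead motif in the flank
        half = config.motif_window + max(ebox.length, fkh.length)
        seq = list(_random_seq(rng, 2 * half + 1))
        c0 = half - ebox.length // 2
        seq[c0 : c0 + ebox.length] = list(ebox.consensus)
        fo = int(rng.choice([-1, 1])) * int(
            rng.integers(config.motif_flank_min, config.motif_flank_max + 1)
        )
        f0 = half + fo - fkh.length // 2
        seq[f0 : f0 + fkh.length] = list(fkh.consensus)
        sequences[rid] = "".join(seq)
    res, bg, sd = config.track_resolution, config.background_rate, config.bump_sd
    return PairScenario(
        peaks_a,
        peaks_b,
        pd.DataFrame(rows),
        track_a_control=_poisson_track(rng, chrom_lengths, res, bg, bumps["a_ctrl"], sd),
        track_a_bkd=_poisson_track(rng, chrom_lengths, res, bg, bumps["a_bkd"], sd),
        track_b_control=_poisson_track(rng, chrom_lengths, res, bg, bumps["b_ctrl"], sd),
        track_b_akd=_poisson_track(rng, chrom_lengths, res, bg, bumps["b_akd"], sd),
        sequences=sequences,
    )
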