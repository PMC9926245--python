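"""Config-driven orchestration of the full analysis with a run manifest.

Stages run in dependency order (simulate → signal → annotate → degsets →
mechanisms / motifs / binding_modes), each reading only declared inputs
and writing its tables under the output directory.  The manifest records
the config hash and a checksum for every input and output, so two runs
with the same config can be compared byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import annotate as annotate_mod
from . import binding_modes as bm
from . import degsets as degsets_mod
from . import mechanisms as mech_mod
from . import motifs as motifs_mod
from . import signal as signal_mod
from . import synthetic_data as synth
from .genomic_io import (
    GenomicInterval,
    fetch_sequence,
    read_bedgraph,
    read_gene_table,
    read_peaks,
)

logger = logging.getLogger("chromkd")

STAGES = (
    "simulate",
    "signal",
    "annotate",
    "degsets",
    "mechanisms",
    "motifs",
    "binding_modes",
)


@dataclass
class AnalysisParams:
    window_bp: int = 2000  # summit-anchored half-window
    tss_window_bp: int = 5000  # TSS-anchored half-window
    bin_bp: int = 50
    pseudocount: float = 1.0
    k: int = 3
    n_restarts: int = 10
    lfc_threshold: float = degsets_mod.DEFAULT_LFC
    padj_threshold: float = 0.05
    diff_lfc_threshold: float = 1.0
    fdr: float = 0.05
    motif_score_fraction: float = 0.8
    motif_window_bp: int = 100
    center_bp: int = 20
    promoter_up: int = 2000
    promoter_down: int = 500
    downstream_bp: int = 3000


@dataclass
class RunConfig:
    seed: int
    outdir: Path
    scenario: synth.ScenarioConfig = field(default_factory=synth.ScenarioConfig)
    params: AnalysisParams = field(default_factory=AnalysisParams)
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.scenario.seed = self.seed

    @classmethod
    def from_yaml(cls, path, outdir=None, seed=None, stages=None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg_seed = seed if seed is not None else raw.get("seed", 0)
        cfg_out = outdir if outdir is not None else raw.get("outdir", "chromkd_out")
        scenario = synth.ScenarioConfig(**{**raw.get("scenario", {}), "seed": cfg_seed})
        params = AnalysisParams(**raw.get("params", {}))
        cfg_stages = tuple(stages if stages is not None else raw.get("stages", STAGES))
        return cls(seed=cfg_seed, outdir=Path(cfg_out), scenario=scenario,
                   params=params, stages=cfg_stages)

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "outdir": str(self.outdir),
            "scenario": dataclasses.asdict(self.scenario),
            "params": dataclasses.asdict(self.params),
            "stages": list(self.stages),
        }
        return d

    def config_hash(self) -> str:
        # hash the analysis definition, not where it is written
        d = self.to_dict()
        d.pop("outdir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def validate(config: RunConfig) -> list[str]:
    """Return a list of validation problems (empty = valid)."""
    problems = []
    for stage in config.stages:
        if stage not in STAGES:
            problems.append(f"unknown stage {stage!r}")
    if "simulate" not in config.stages:
        sim = config.outdir / "sim"
        if not sim.is_dir():
            problems.append(
                f"simulate disabled but no simulated inputs at {sim}"
            )
    return problems


class _Run:
    """One pipeline execution: stage methods plus manifest bookkeeping."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = config.outdir
        self.sim = self.out / "sim"
        self.manifest: dict = {
            "config_hash": config.config_hash(),
            "version": __version__,
            "stages": {},
        }

    def _record(self, stage: str, inputs: list[Path], outputs: list[Path]) -> None:
        self.manifest["stages"][stage] = {
            "inputs": {str(p.relative_to(self.out)): _sha256(p) for p in sorted(inputs)},
            "outputs": {str(p.relative_to(self.out)): _sha256(p) for p in sorted(outputs)},
        }

    # -- stages -------------------------------------------------------------

    def simulate(self) -> None:
        cfg = self.config.scenario
        genome = synth.generate_genome(cfg)
        tracks = synth.generate_tracks_and_peaks(cfg, genome.chrom_lengths)
        # plant the forkhead motif at summits of loss-class peaks so the
        # cluster-wise motif statistics have signal to find
        fkh = synth.builtin_pwms()["FKH"]
        loss = set(tracks.truth.loc[tracks.truth["class"] == "loss", "peak"])
        seqs = {c: list(s) for c, s in genome.sequences.items()}
        for p in tracks.peaks:
            if p.name in loss:
                s = p.summit - fkh.length // 2
                seqs[p.chrom][s : s + fkh.length] = list(fkh.consensus)
        genome.sequences = {c: "".join(s) for c, s in seqs.items()}
        paths = list(genome.write(self.sim).values())
        paths += list(tracks.write(self.sim).values())
        mech = synth.generate_deg_tables(cfg)
        paths += list(mech.write(self.sim).values())
        pair = synth.generate_pair_scenario(cfg)
        paths += list(pair.write(self.sim).values())
        for geometry in ("center", "flank"):
            sc = synth.generate_motif_sequences(cfg, geometry, n_peaks=200)
            p = self.sim / f"motif_{geometry}.tsv"
            pd.DataFrame(sc.sequences, columns=["peak", "sequence"]).to_csv(
                p, sep="\t", index=False
            )
            paths.append(p)
            t = self.sim / f"motif_{geometry}_truth.tsv"
            sc.truth.to_csv(t, sep="\t", index=False)
            paths.append(t)
        self._record("simulate", [], paths)

    def signal(self) -> None:
        p = self.config.params
        inputs = [
            self.sim / "peaks.narrowPeak",
            self.sim / "chip_control.bedGraph",
            self.sim / "chip_kd.bedGraph",
            self.sim / "input_control.bedGraph",
        ]
        peaks = read_peaks(inputs[0])
        anchors = [(pk.chrom, pk.summit, ".") for pk in peaks]
        names = [pk.name for pk in peaks]
        ctrl = signal_mod.extract_matrix(
            read_bedgraph(inputs[1]), anchors, p.window_bp, p.bin_bp, row_ids=names
        )
        kd = signal_mod.extract_matrix(
            read_bedgraph(inputs[2]), anchors, p.window_bp, p.bin_bp, row_ids=names
        )
        inp = signal_mod.extract_matrix(
            read_bedgraph(inputs[3]), anchors, p.window_bp, p.bin_bp, row_ids=names
        )
        chip_over_input = signal_mod.log2_ratio_matrix(
            ctrl, inp, p.pseudocount, "log2_chip_over_input"
        )
        diff = signal_mod.log2_ratio_matrix(
            kd, ctrl, p.pseudocount, "log2_kd_over_control"
        )
        clusters = signal_mod.kmeans_rows(diff, p.k, self.config.seed, p.n_restarts)
        sigdir = self.out / "signal"
        sigdir.mkdir(parents=True, exist_ok=True)
        outputs = [
            sigdir / "log2_kd_over_control.tsv",
            sigdir / "log2_kd_over_control.json",
            sigdir / "log2_chip_over_input.tsv",
            sigdir / "log2_chip_over_input.json",
            sigdir / "clusters.tsv",
            sigdir / "metaprofiles.tsv",
        ]
        signal_mod.write_matrix(diff, outputs[0], outputs[1])
        signal_mod.write_matrix(chip_over_input, outputs[2], outputs[3])
        signal_mod.write_clusters(clusters, outputs[4])
        profiles = signal_mod.metaprofile(diff, clusters)
        with open(outputs[5], "w") as fh:
            fh.write("cluster\t" + "\t".join(
                f"bin{i}" for i in range(diff.n_bins)) + "\n")
            for c in sorted(profiles):
                fh.write(str(c) + "\t" + "\t".join(
                    f"{v:.6g}" for v in profiles[c]) + "\n")
        self._record("signal", inputs, outputs)

    def annotate(self) -> None:
        p = self.config.params
        inputs = [
            self.sim / "peaks.narrowPeak",
            self.sim / "genes.tsv",
            self.out / "signal" / "clusters.tsv",
        ]
        peaks = read_peaks(inputs[0])
        genes = read_gene_table(inputs[1])
        clusters = pd.read_csv(inputs[2], sep="\t")
        cluster_of = dict(zip(clusters["row_id"], clusters["cluster"]))
        calls = annotate_mod.annotate_peaks(
            peaks, genes, promoter_up=p.promoter_up,
            promoter_down=p.promoter_down, downstream_bp=p.downstream_bp,
        )
        groups = [cluster_of.get(pk.name, 0) for pk in peaks]
        anndir = self.out / "annotate"
        anndir.mkdir(parents=True, exist_ok=True)
        outputs = [anndir / "feature_calls.tsv", anndir / "genomic_distribution.tsv"]
        annotate_mod.write_feature_calls(calls, outputs[0], groups)
        dist = annotate_mod.genomic_distribution(calls, groups)
        rows = []
        for group in sorted(dist):
            row = {"group": group}
            row.update({k: v for k, v in dist[group].items() if k != "_empty"})
            rows.append(row)
        pd.DataFrame(rows).to_csv(outputs[1], sep="\t", index=False,
                                  float_format="%.6g")
        self._record("annotate", inputs, outputs)

    def degsets(self) -> None:
        p = self.config.params
        inputs = [self.sim / "deg_kd.tsv", self.out / "annotate" / "feature_calls.tsv"]
        table = degsets_mod.read_deg_table(inputs[0])
        degs = degsets_mod.filter_degs(table, p.lfc_threshold, p.padj_threshold)
        calls = pd.read_csv(inputs[1], sep="\t")
        cluster_genes: dict[int, set] = {}
        for _, row in calls.iterrows():
            if row["gene"] != ".":
                cluster_genes.setdefault(int(row["group"]), set()).add(row["gene"])
        degdir = self.out / "degsets"
        degdir.mkdir(parents=True, exist_ok=True)
        outputs = [degdir / "deg_sets.json", degdir / "cluster_enrichment.tsv"]
        with open(outputs[0], "w") as fh:
            json.dump(
                {
                    "n_increased": len(degs.increased),
                    "n_decreased": len(degs.decreased),
                    "n_universe": len(degs.universe),
                    "increased": sorted(degs.increased),
                    "decreased": sorted(degs.decreased),
                },
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")
        if cluster_genes:
            # restrict to genes present in the DEG universe
            cluster_genes = {
                c: g & set(degs.universe) for c, g in cluster_genes.items()
            }
            summary = degsets_mod.cluster_deg_summary(cluster_genes, degs, table)
        else:
            summary = pd.DataFrame()
        summary.to_csv(outputs[1], sep="\t", index=False, float_format="%.6g")
        self._record("degsets", inputs, outputs)

    def mechanisms(self) -> None:
        p = self.config.params
        inputs = [
            self.sim / "deg_kd.tsv",
            self.sim / "deg_tsa.tsv",
            self.sim / "deg_tsa_control.tsv",
            self.sim / "ac_down_genes.txt",
            self.sim / "ac_up_genes.txt",
            self.sim / "bound_genes.txt",
        ]

        def gene_set(path):
            return frozenset(line.strip() for line in open(path) if line.strip())

        deg_kd = degsets_mod.filter_degs(
            degsets_mod.read_deg_table(inputs[0]), p.lfc_threshold, p.padj_threshold
        )
        deg_tsa = degsets_mod.filter_degs(
            degsets_mod.read_deg_table(inputs[1]), p.lfc_threshold, p.padj_threshold
        )
        tsa_ctrl = degsets_mod.filter_degs(
            degsets_mod.read_deg_table(inputs[2]), p.lfc_threshold, p.padj_threshold
        )
        mi = mech_mod.MechanismInputs(
            deg_kd=deg_kd,
            deg_tsa=deg_tsa,
            ac_down_genes=gene_set(inputs[3]),
            ac_up_genes=gene_set(inputs[4]),
            bound_genes=gene_set(inputs[5]),
            tsa_control_responders=frozenset(tsa_ctrl.degs),
        )
        mdir = self.out / "mechanisms"
        mdir.mkdir(parents=True, exist_ok=True)
        outputs = []
        for model_fn in (mech_mod.repression_model, mech_mod.recruitment_model):
            result = model_fn(mi)
            tsv = mdir / f"{result.model}.tsv"
            js = mdir / f"{result.model}_counts.json"
            mech_mod.write_mechanism_result(result, tsv, js)
            outputs += [tsv, js]
        self._record("mechanisms", inputs, outputs)

    def motifs(self) -> None:
        p = self.config.params
        inputs = [
            self.sim / "motif_center.tsv",
            self.sim / "motif_flank.tsv",
            self.sim / "peaks.narrowPeak",
            self.sim / "genome.fa",
            self.out / "signal" / "clusters.tsv",
        ]
        pwms = synth.builtin_pwms()
        fkh = pwms["FKH"]
        mdir = self.out / "motifs"
        mdir.mkdir(parents=True, exist_ok=True)
        # positional preference on the planted-geometry windows
        rows = []
        for geometry, path in (("center", inputs[0]), ("flank", inputs[1])):
            df = pd.read_csv(path, sep="\t")
            hits = []
            for _, r in df.iterrows():
                hits += [
                    h
                    for h in motifs_mod.scan_pwm(
                        r["sequence"], fkh, p.motif_score_fraction, r["peak"]
                    )
                    if abs(h.offset) <= p.motif_window_bp
                ]
            call = motifs_mod.positional_preference(
                hits, f"FKH_{geometry}", p.motif_window_bp, p.center_bp
            )
            rows.append(dataclasses.asdict(call))
        outputs = [mdir / "positional_preference.tsv", mdir / "cluster_zscores.tsv"]
        pd.DataFrame(rows).to_csv(outputs[0], sep="\t", index=False,
                                  float_format="%.6g")
        # cluster-wise motif presence z-scores on the genome peaks
        peaks = read_peaks(inputs[2])
        clusters = pd.read_csv(inputs[4], sep="\t")
        cluster_of = dict(zip(clusters["row_id"], clusters["cluster"]))
        half = p.motif_window_bp + fkh.length
        by_cluster: dict[int, list[tuple[str, str]]] = {}
        for pk in peaks:
            seq = fetch_sequence(
                inputs[3],
                GenomicInterval(pk.chrom, pk.summit - half, pk.summit + half + 1),
            )
            by_cluster.setdefault(cluster_of.get(pk.name, 0), []).append(
                (pk.name, seq)
            )
        z = motifs_mod.cluster_motif_zscores(
            by_cluster, list(pwms.values()), p.motif_score_fraction
        )
        z.sort_values(["motif", "cluster"]).to_csv(
            outputs[1], sep="\t", index=False, float_format="%.6g"
        )
        self._record("motifs", inputs, outputs)

    def binding_modes(self) -> None:
        p = self.config.params
        inputs = [
            self.sim / "tfA_peaks.narrowPeak",
            self.sim / "tfB_peaks.narrowPeak",
            self.sim / "track_a_control.bedGraph",
            self.sim / "track_a_bkd.bedGraph",
            self.sim / "track_b_control.bedGraph",
            self.sim / "track_b_akd.bedGraph",
        ]
        peaks_a = read_peaks(inputs[0])
        peaks_b = read_peaks(inputs[1])
        part = bm.partition_shared_unique(peaks_a, peaks_b)
        region_ids = [f"{r.chrom}:{r.start}-{r.end}" for r in part.shared]
        counts_a = bm.region_counts_from_tracks(
            part.shared, read_bedgraph(inputs[2]), read_bedgraph(inputs[3]), region_ids
        )
        counts_b = bm.region_counts_from_tracks(
            part.shared, read_bedgraph(inputs[4]), read_bedgraph(inputs[5]), region_ids
        )
        diff_a = bm.differential_binding(counts_a, p.diff_lfc_threshold, p.fdr)
        diff_b = bm.differential_binding(counts_b, p.diff_lfc_threshold, p.fdr)
        call_a = dict(zip(diff_a["region_id"], diff_a["call"]))
        lfc_a = dict(zip(diff_a["region_id"], diff_a["log2fc"]))
        call_b = dict(zip(diff_b["region_id"], diff_b["call"]))
        lfc_b = dict(zip(diff_b["region_id"], diff_b["log2fc"]))
        rows = []
        for rid, region in zip(region_ids, part.shared):
            mode_call = bm.classify_mode(
                rid, call_a[rid], call_b[rid],
                deltaA_on_Bkd=lfc_a[rid], deltaB_on_Akd=lfc_b[rid],
            )
            rows.append(
                {
                    "region_id": rid,
                    "chrom": region.chrom,
                    "start": region.start,
                    "end": region.end,
                    "partition": "shared",
                    "log2fc_A_on_Bkd": lfc_a[rid],
                    "log2fc_B_on_Akd": lfc_b[rid],
                    "call_A": call_a[rid],
                    "call_B": call_b[rid],
                    "mode": mode_call.mode,
                }
            )
        bdir = self.out / "binding_modes"
        bdir.mkdir(parents=True, exist_ok=True)
        outputs = [bdir / "binding_modes.tsv", bdir / "partition_summary.json"]
        pd.DataFrame(rows).to_csv(outputs[0], sep="\t", index=False,
                                  float_format="%.6g")
        with open(outputs[1], "w") as fh:
            json.dump(
                {
                    "n_shared": len(part.shared),
                    "n_A_unique": len(part.a_unique),
                    "n_B_unique": len(part.b_unique),
                },
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")
        self._record("binding_modes", inputs, outputs)


def run(config: RunConfig) -> dict:
    """Execute the configured stages and write ``manifest.json``.

    Returns the manifest.  Any stage failure aborts with the stage name
    and the offending input in the exception message.
    """
    problems = validate(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    config.outdir.mkdir(parents=True, exist_ok=True)
    runner = _Run(config)
    for stage in STAGES:  # dependency order, regardless of config order
        if stage not in config.stages:
            continue
        t0 = time.monotonic()
        logger.info("stage %s: start", stage)
        try:
            getattr(runner, stage)()
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        n_out = len(runner.manifest["stages"][stage]["outputs"])
        logger.info("stage %s: done in %.2fs, %d outputs",
                    stage, time.monotonic() - t0, n_out)
    manifest_path = config.outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(runner.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return runner.manifest
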