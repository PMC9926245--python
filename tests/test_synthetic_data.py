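import numpy as np
import pytest

from chromkd.degsets import filter_degs
from chromkd.genomic_io import read_bedgraph, read_gene_table, read_peaks
from chromkd.synthetic_data import (
    ScenarioConfig,
    generate_deg_tables,
    generate_genome,
    generate_motif_sequences,
    generate_pair_scenario,
    generate_tracks_and_peaks,
    substream,
)


class TestGenome:
    def test_deterministic_given_seed(self, tmp_path, small_config):
        g1 = generate_genome(small_config)
        g2 = generate_genome(small_config)
        p1 = g1.write(tmp_path / "a")
        p2 = g2.write(tmp_path / "b")
        for k in p1:
            assert p1[k].read_bytes() == p2[k].read_bytes()

    def test_zero_genes_degenerate(self):
        cfg = ScenarioConfig(seed=1, n_genes=0, n_chromosomes=1,
                             chrom_length=50_000)
        g = generate_genome(cfg)
        assert g.genes == []
        assert len(g.sequences["chr1"]) == 50_000

    def test_gene_intervals_pairwise_disjoint_over_seeds(self):
        for seed in range(20):
            cfg = ScenarioConfig(seed=seed, n_genes=30, n_chromosomes=1,
                                 chrom_length=400_000)
            genes = generate_genome(cfg).genes
            by_chrom: dict = {}
            for g in genes:
                by_chrom.setdefault(g.chrom, []).append((g.gene_start, g.gene_end))
            for ivs in by_chrom.values():
                ivs.sort()
                assert all(ivs[i][1] <= ivs[i + 1][0] for i in range(len(ivs) - 1))

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="packing"):
            generate_genome(ScenarioConfig(seed=0, n_genes=100, n_chromosomes=1,
                                           chrom_length=100_000))

    def test_written_files_readable(self, tmp_path, small_config):
        g = generate_genome(small_config)
        paths = g.write(tmp_path)
        assert read_gene_table(paths["genes"]) == g.genes


class TestTracksAndPeaks:
    def test_noiseless_limit_stable_peak(self):
        cfg = ScenarioConfig(seed=2, n_peaks=1, background_rate=0.0,
                             signal_class_props=(1.0, 0.0, 0.0),
                             n_chromosomes=1, chrom_length=50_000)
        sc = generate_tracks_and_peaks(cfg)
        (p,) = sc.peaks
        # stable class: KD and control tracks share the same expected bump;
        # only Poisson sampling differs, and both integrate near the amplitude
        c = sc.chip_control.integral(p.chrom, p.summit - 1000, p.summit + 1000)
        k = sc.chip_kd.integral(p.chrom, p.summit - 1000, p.summit + 1000)
        # expected total counts under the Gaussian bump: amp * sd * sqrt(2π) / bin
        expected = sc.truth.amplitude.iloc[0] * 150.0 * np.sqrt(2 * np.pi) / 10
        assert c == pytest.approx(expected, rel=0.3)
        assert k == pytest.approx(c, rel=0.3)
        # input is background only = empty at zero rate
        assert sc.input_control.integral(p.chrom, 0, 50_000) == 0.0

    def test_loss_class_halves_kd_amplitude(self):
        cfg = ScenarioConfig(seed=3, n_peaks=40, background_rate=0.0,
                             signal_class_props=(0.0, 0.0, 1.0),
                             n_chromosomes=1, chrom_length=400_000)
        sc = generate_tracks_and_peaks(cfg)
        ratios = []
        for p in sc.peaks:
            c = sc.chip_control.integral(p.chrom, p.summit - 600, p.summit + 600)
            k = sc.chip_kd.integral(p.chrom, p.summit - 600, p.summit + 600)
            if c > 0:
                ratios.append(k / c)
        assert np.median(ratios) == pytest.approx(0.5, abs=0.1)

    def test_amplitude_mean_matches_gamma(self):
        cfg = ScenarioConfig(seed=4, n_peaks=1000, n_chromosomes=7,
                             chrom_length=1_000_000)
        sc = generate_tracks_and_peaks(cfg)
        assert sc.truth.amplitude.mean() == pytest.approx(20.0, rel=0.05)

    def test_written_files_validate_against_readers(self, tmp_path, small_config):
        sc = generate_tracks_and_peaks(small_config)
        paths = sc.write(tmp_path)
        assert read_peaks(paths["peaks"]) == sc.peaks
        track = read_bedgraph(paths["chip_control"])
        p = sc.peaks[0]
        assert track.mean(p.chrom, p.start, p.end) == pytest.approx(
            sc.chip_control.mean(p.chrom, p.start, p.end)
        )


class TestDegTables:
    def test_zero_planted_degs_yield_empty_sets(self):
        hits = 0
        for seed in range(20):
            cfg = ScenarioConfig(seed=seed, n_repression=0, n_recruitment=0,
                                 n_null_genes=300)
            sc = generate_deg_tables(cfg)
            degs = filter_degs(sc.deg_kd)
            hits += not degs.increased and not degs.decreased
        assert hits == 20

    def test_planted_repression_gene_in_all_required_sets(self):
        sc = generate_deg_tables(ScenarioConfig(seed=9))
        rep = set(sc.truth[sc.truth["class"] == "repression"].gene_id)
        deg_kd = filter_degs(sc.deg_kd)
        deg_tsa = filter_degs(sc.deg_tsa)
        ctrl = filter_degs(sc.deg_tsa_control)
        for g in rep:
            assert g in deg_kd.decreased
            assert g in sc.ac_down_genes
            assert g in deg_tsa.increased
            assert g not in ctrl.degs

    def test_planted_recruitment_gene_consistency(self):
        sc = generate_deg_tables(ScenarioConfig(seed=10))
        rec = set(sc.truth[sc.truth["class"] == "recruitment"].gene_id)
        deg_kd = filter_degs(sc.deg_kd)
        deg_tsa = filter_degs(sc.deg_tsa)
        for g in rec:
            assert g in deg_kd.increased
            assert g in sc.ac_up_genes
            assert g in sc.bound_genes
            assert g not in deg_tsa.degs


class TestSubstreams:
    def test_named_substreams_independent(self):
        a1 = substream(5, "tracks").normal(size=10)
        a2 = substream(5, "tracks").normal(size=10)
        b = substream(5, "degs").normal(size=10)
        assert np.allclose(a1, a2)
        assert not np.allclose(a1, b)


class TestMotifAndPair:
    def test_motif_truth_matches_plant(self):
        sc = generate_motif_sequences(ScenarioConfig(seed=11), "center", 50)
        for row, (name, seq) in zip(sc.truth.itertuples(), sc.sequences):
            off = int(row.planted_offset)
            L = sc.pwm.length
            half = len(seq) // 2
            word = seq[half + off - L // 2 : half + off - L // 2 + L]
            rc = sc.pwm.consensus.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            assert word in (sc.pwm.consensus, rc)

    def test_absent_geometry_plants_nothing(self):
        sc = generate_motif_sequences(ScenarioConfig(seed=12), "absent", 30)
        assert sc.truth.planted_offset.isna().all()

    def test_pair_scenario_deterministic_write(self, tmp_path, small_config):
        p1 = generate_pair_scenario(small_config).write(tmp_path / "x")
        p2 = generate_pair_scenario(small_config).write(tmp_path / "y")
        for k in p1:
            assert p1[k].read_bytes() == p2[k].read_bytes()
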