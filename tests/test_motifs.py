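import math

import numpy as np
import pytest

from chromkd.motifs import (
    MotifHit,
    PWM,
    cluster_motif_zscores,
    positional_preference,
    read_jaspar_pwms,
    scan_pwm,
)
from chromkd.synthetic_data import ScenarioConfig, builtin_pwms, generate_motif_sequences

from oracles import scan_pwm_oracle

FKH = builtin_pwms()["FKH"]

RC = str.maketrans("ACGTN", "TGCAN")


def embed(consensus, offset, length=201, rng=None):
    """Random sequence with `consensus` centered at `offset` from the middle."""
    rng = rng or np.random.default_rng(0)
    seq = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)]))
    start = length // 2 + offset - len(consensus) // 2
    seq[start : start + len(consensus)] = list(consensus)
    return "".join(seq)


class TestPWM:
    def test_column_sums_enforced(self):
        bad = np.full((5, 4), 0.2)
        with pytest.raises(ValueError, match="sum to 1"):
            PWM("bad", bad)

    def test_from_counts_pseudocount(self):
        # consensus ACAC; rows are A,C,G,T counts per position
        counts = np.array(
            [[8, 0, 8, 0], [0, 8, 0, 8], [0, 0, 0, 0], [0, 0, 0, 0]]
        )
        pwm = PWM.from_counts("m", counts)
        # +0.8 total pseudocount split by uniform background: (8 + 0.2) / 8.8
        assert pwm.matrix[0, 0] == pytest.approx(8.2 / 8.8)
        assert pwm.matrix[0, 1] == pytest.approx(0.2 / 8.8)
        assert pwm.consensus == "ACAC"

    def test_jaspar_reader(self, tmp_path):
        f = tmp_path / "m.jaspar"
        f.write_text(
            ">M1\nA [ 10 0 0 10 ]\nC [ 0 10 0 0 ]\nG [ 0 0 10 0 ]\nT [ 0 0 0 0 ]\n"
        )
        (pwm,) = read_jaspar_pwms(f)
        assert pwm.name == "M1"
        assert pwm.length == 4
        assert pwm.consensus == "ACGA"


class TestScanPwm:
    def test_consensus_at_summit_scores_max(self):
        seq = embed(FKH.consensus, 0)
        hits = scan_pwm(seq, FKH, 0.99)
        assert len(hits) == 1
        assert hits[0].offset == 0
        assert hits[0].strand == "+"
        assert hits[0].score == pytest.approx(FKH.max_score)

    def test_all_n_sequence_yields_no_hits(self):
        assert scan_pwm("N" * 201, FKH, 0.5) == []

    def test_reverse_complement_found_on_minus_strand(self):
        seq = embed(FKH.consensus.translate(RC)[::-1], 10)
        hits = scan_pwm(seq, FKH, 0.99)
        assert len(hits) == 1
        assert hits[0].strand == "-"

    def test_matches_positionwise_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(30, 120))
            seq = "".join(np.array(list("ACGTN"))[
                rng.choice(5, size=n, p=[0.24, 0.24, 0.24, 0.24, 0.04])
            ])
            if rng.random() < 0.5:  # plant a consensus to guarantee some hits
                p = int(rng.integers(0, n - FKH.length))
                seq = seq[:p] + FKH.consensus + seq[p + FKH.length:]
            got = {
                (h.offset, h.strand, round(h.score, 9))
                for h in scan_pwm(seq, FKH, 0.8)
            }
            assert got == scan_pwm_oracle(seq, FKH, 0.8)

    def test_strand_symmetry(self, rng):
        """Scanning the reverse complement mirrors offsets and swaps strands."""
        for _ in range(20):
            seq = embed(FKH.consensus, int(rng.integers(-60, 60)), rng=rng)
            fwd = scan_pwm(seq, FKH, 0.8)
            rc = scan_pwm(seq.translate(RC)[::-1], FKH, 0.8)
            flip = {"+": "-", "-": "+"}
            # an odd-length window mirrors offset exactly; account for the
            # even-length motif center convention
            shift = FKH.length - 2 * (FKH.length // 2)  # 1 for odd L, 0 for even
            mirrored = sorted(
                (-h.offset + (1 - shift), flip[h.strand], round(h.score, 9))
                for h in rc
            )
            assert sorted(
                (h.offset, h.strand, round(h.score, 9)) for h in fwd
            ) == mirrored

    def test_sequence_shorter_than_pwm_rejected(self):
        with pytest.raises(ValueError):
            scan_pwm("ACG", FKH, 0.8)


def hits_at(offsets):
    return [MotifHit(f"p{i}", o, "+", 10.0) for i, o in enumerate(offsets)]


class TestPositionalPreference:
    def test_all_center_hits(self):
        call = positional_preference(hits_at([0] * 100))
        assert call.center_fraction == 1.0
        assert call.classification == "center_concentrated"

    def test_uniform_offsets_classified_uniform(self):
        offsets = list(range(-100, 101))  # exactly uniform
        call = positional_preference(hits_at(offsets))
        assert call.center_fraction == pytest.approx(41 / 201)
        assert call.classification == "uniform"

    def test_flank_only_offsets(self):
        offsets = [o for o in range(-100, 101) if abs(o) >= 40]
        assert positional_preference(hits_at(offsets)).classification == "flanking"

    def test_low_count_flagged_uniform(self):
        call = positional_preference(hits_at([0] * 5))
        assert call.low_count and call.classification == "uniform"

    def test_invariant_to_order_and_duplicates(self, rng):
        offsets = [int(o) for o in rng.integers(-100, 101, size=80)]
        a = positional_preference(hits_at(offsets))
        perm = list(offsets)
        rng.shuffle(perm)
        b = positional_preference(hits_at(perm))
        assert (a.center_fraction, a.p_center, a.classification) == (
            b.center_fraction, b.p_center, b.classification,
        )

    @pytest.mark.parametrize("geometry,expected", [
        ("center", "center_concentrated"), ("flank", "flanking"),
    ])
    def test_planted_geometry_recovered(self, geometry, expected):
        correct = 0
        for seed in range(10):
            sc = generate_motif_sequences(
                ScenarioConfig(seed=seed), geometry, n_peaks=500
            )
            hits = []
            for name, seq in sc.sequences:
                hits += [h for h in scan_pwm(seq, sc.pwm, 0.8, name)
                         if abs(h.offset) <= 100]
            call = positional_preference(hits, geometry)
            correct += call.classification == expected
        assert correct >= 9


class TestClusterZScores:
    @staticmethod
    def seqs(n, with_motif, rng):
        # motif-free background uses only A/C so neither the consensus nor
        # its reverse complement can occur by chance
        out = []
        for i in range(n):
            if with_motif:
                bg = "".join(np.array(list("AC"))[rng.integers(0, 2, size=201)])
                mid = 100 - FKH.length // 2
                seq = bg[:mid] + FKH.consensus + bg[mid + FKH.length:]
                out.append((f"s{i}", seq))
            else:
                out.append(
                    (f"s{i}", "".join(np.array(list("AC"))[
                        rng.integers(0, 2, size=201)]))
                )
        return out

    def test_two_cluster_plugin_arithmetic(self, rng):
        clusters = {
            1: self.seqs(50, True, rng),
            2: self.seqs(50, False, rng),
        }
        df = cluster_motif_zscores(clusters, [FKH], 0.9)
        za = float(df[df.cluster == 1].zscore.iloc[0])
        zb = float(df[df.cluster == 2].zscore.iloc[0])
        # motif in every peak of A, none of B: pooled 0.5 -> z = +/-7.07
        assert za == pytest.approx(50 * 0.5 / math.sqrt(50 * 0.25), rel=1e-6)
        assert za == pytest.approx(7.0710678, rel=1e-4)
        assert zb == pytest.approx(-za, rel=1e-6)

    def test_degenerate_pooled_rate_flagged(self, rng):
        clusters = {1: self.seqs(10, True, rng), 2: self.seqs(10, True, rng)}
        df = cluster_motif_zscores(clusters, [FKH], 0.9)
        assert df.degenerate.all()
        assert df.zscore.isna().all()

    def test_weighted_zscores_sum_to_zero(self, rng):
        clusters = {
            1: self.seqs(30, True, rng) + self.seqs(10, False, rng),
            2: self.seqs(5, True, rng) + self.seqs(35, False, rng),
            3: self.seqs(20, True, rng) + self.seqs(20, False, rng),
        }
        df = cluster_motif_zscores(clusters, [FKH], 0.9)
        total = 0.0
        for _, r in df.iterrows():
            sigma = math.sqrt(r.n_peaks * r.pooled_rate * (1 - r.pooled_rate))
            total += r.zscore * sigma
        assert abs(total) < 1e-6

    def test_planted_enrichment_sign(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            clusters = {
                1: self.seqs(30, True, r) + self.seqs(20, False, r),   # 60%
                2: self.seqs(5, True, r) + self.seqs(45, False, r),    # 10%
            }
            df = cluster_motif_zscores(clusters, [FKH], 0.9)
            assert float(df[df.cluster == 1].zscore.iloc[0]) > 0
            assert float(df[df.cluster == 2].zscore.iloc[0]) < 0

    def test_requires_two_clusters(self, rng):
        with pytest.raises(ValueError):
            cluster_motif_zscores({1: self.seqs(5, True, rng)}, [FKH])
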