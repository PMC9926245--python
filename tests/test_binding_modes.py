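import itertools
import math

import numpy as np
import pytest

from chromkd.binding_modes import (
    CALLS,
    MODES,
    MOTIF_PRESENCE,
    RegionCounts,
    classify_mode,
    differential_binding,
    partition_shared_unique,
    region_counts_from_tracks,
)
from chromkd.genomic_io import GenomicInterval, Peak, SignalTrack
from chromkd.synthetic_data import ScenarioConfig, generate_pair_scenario

from oracles import binomial_two_sided_oracle, partition_oracle


def peak(chrom, start, end, name="p"):
    return Peak(GenomicInterval(chrom, start, end), (end - start) // 2, name=name)


def random_peaks(rng, n, span=20_000):
    out = []
    for i in range(n):
        s = int(rng.integers(0, span))
        out.append(peak(str(rng.choice(["chr1", "chr2"])), s, s + int(rng.integers(50, 400)), f"p{i}"))
    return out


class TestPartition:
    def test_overlapping_pair_merges(self):
        part = partition_shared_unique(
            [peak("chr1", 100, 200)], [peak("chr1", 150, 250)]
        )
        assert [(r.chrom, r.start, r.end) for r in part.shared] == [("chr1", 100, 250)]
        assert part.a_unique == [] and part.b_unique == []

    def test_disjoint_sets_all_unique(self):
        part = partition_shared_unique(
            [peak("chr1", 100, 200)], [peak("chr1", 300, 400)]
        )
        assert part.shared == []
        assert len(part.a_unique) == len(part.b_unique) == 1

    def test_chained_overlaps_form_one_region(self):
        a = [peak("chr1", 0, 100), peak("chr1", 180, 300)]
        b = [peak("chr1", 90, 200)]
        part = partition_shared_unique(a, b)
        assert [(r.start, r.end) for r in part.shared] == [(0, 300)]

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(50):
            a = random_peaks(rng, 40)
            b = random_peaks(rng, 40)
            part = partition_shared_unique(a, b)
            o_shared, o_au, o_bu = partition_oracle(a, b)
            assert sorted((r.chrom, r.start, r.end) for r in part.shared) == o_shared
            assert sorted((r.chrom, r.start, r.end) for r in part.a_unique) == o_au
            assert sorted((r.chrom, r.start, r.end) for r in part.b_unique) == o_bu

    def test_symmetry_under_swap(self, rng):
        a = random_peaks(rng, 60)
        b = random_peaks(rng, 60)
        ab = partition_shared_unique(a, b)
        ba = partition_shared_unique(b, a)
        key = lambda rs: sorted((r.chrom, r.start, r.end) for r in rs)
        assert key(ab.shared) == key(ba.shared)
        assert key(ab.a_unique) == key(ba.b_unique)
        assert key(ab.b_unique) == key(ba.a_unique)

    def test_every_peak_in_exactly_one_region(self, rng):
        a = random_peaks(rng, 50)
        b = random_peaks(rng, 50)
        part = partition_shared_unique(a, b)

        def overlaps_partner(p, partners):
            return any(
                q.chrom == p.chrom and p.start < q.end and q.start < p.end
                for q in partners
            )

        n_linked = sum(overlaps_partner(p, b) for p in a) + sum(
            overlaps_partner(p, a) for p in b
        )
        assert n_linked + len(part.a_unique) + len(part.b_unique) == 100
        # and every linked peak is contained in some shared region span
        for p in a + b:
            if overlaps_partner(p, b if p in a else a):
                assert any(
                    r.chrom == p.chrom and r.start <= p.start and p.end <= r.end
                    for r in part.shared
                )


class TestDifferentialBinding:
    def test_pseudocount_arithmetic(self):
        rc = RegionCounts("r", count_control=100, count_kd=25,
                          library_control=1e6, library_kd=1e6)
        df = differential_binding([rc])
        assert df.log2fc.iloc[0] == pytest.approx(math.log2(25.5 / 100.5))

    def test_identity_unchanged(self):
        rc = RegionCounts("r", 50, 50, 1e6, 1e6)
        df = differential_binding([rc])
        assert df.log2fc.iloc[0] == 0.0
        assert df.call.iloc[0] == "unchanged"

    def test_p_matches_enumeration_on_grid(self):
        for c_ctrl in range(0, 51, 7):
            for c_kd in range(0, 51, 7):
                rc = RegionCounts("r", c_ctrl, c_kd, 2e6, 1e6)
                p = differential_binding([rc]).p_value.iloc[0]
                expected = binomial_two_sided_oracle(
                    c_kd, c_kd + c_ctrl, 1e6 / 3e6
                )
                assert p == pytest.approx(expected, abs=1e-12)

    def test_p_invariant_to_library_scaling(self):
        a = RegionCounts("r", 30, 80, 1e6, 2e6)
        b = RegionCounts("r", 30, 80, 5e6, 10e6)
        assert differential_binding([a]).p_value.iloc[0] == pytest.approx(
            differential_binding([b]).p_value.iloc[0], rel=1e-12
        )

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            RegionCounts("r", 1, 1, 0, 1e6)


class TestClassifyMode:
    @pytest.mark.parametrize(
        "calls,expected",
        [
            (("loss", "loss"), "cooperative"),
            (("gain", "gain"), "competitive"),
            (("gain", "unchanged"), "competitive"),
            (("unchanged", "gain"), "competitive"),
            (("unchanged", "unchanged"), "independent"),
            (("loss", "unchanged"), "asymmetric"),
            (("loss", "gain"), "asymmetric"),
            (("gain", "loss"), "asymmetric"),
        ],
    )
    def test_rule_table(self, calls, expected):
        assert classify_mode("r", *calls).mode == expected

    def test_cooperative_site_annotation(self):
        assert classify_mode("r", "loss", "loss", "adjacent").site_annotation == "adjacent_site"
        assert classify_mode("r", "loss", "loss", "A_motif_center").site_annotation == "shared_site"
        assert classify_mode("r", "gain", "gain", "adjacent").site_annotation is None

    def test_every_combination_maps_to_exactly_one_mode(self):
        for a, b, m in itertools.product(CALLS, CALLS, MOTIF_PRESENCE):
            call = classify_mode("r", a, b, m)
            assert call.mode in MODES

    def test_unknown_call_rejected(self):
        with pytest.raises(ValueError):
            classify_mode("r", "loss", "bogus")


class TestRegionCountsFromTracks:
    def test_integration_and_library(self):
        ctrl = SignalTrack({"chr1": [(0, 100, 2.0), (200, 300, 1.0)]})
        kd = SignalTrack({"chr1": [(0, 100, 4.0)]})
        (rc,) = region_counts_from_tracks(
            [GenomicInterval("chr1", 0, 100)], ctrl, kd
        )
        assert rc.count_control == 200
        assert rc.count_kd == 400
        assert rc.library_control == 300
        assert rc.library_kd == 400


class TestPlantedRecovery:
    def test_modes_recovered_on_synthetic_regions(self):
        cfg = ScenarioConfig(seed=17, n_pair_regions=120)
        sc = generate_pair_scenario(cfg)
        regions = [
            GenomicInterval(r.chrom, r.start, r.end)
            for r in sc.truth.itertuples()
        ]
        rids = list(sc.truth.region_id)
        da = differential_binding(region_counts_from_tracks(
            regions, sc.track_a_control, sc.track_a_bkd, rids))
        db = differential_binding(region_counts_from_tracks(
            regions, sc.track_b_control, sc.track_b_akd, rids))
        call_a = dict(zip(da.region_id, da.call))
        call_b = dict(zip(db.region_id, db.call))
        correct = sum(
            classify_mode(r.region_id, call_a[r.region_id], call_b[r.region_id]).mode
            == r.mode
            for r in sc.truth.itertuples()
        )
        assert correct / len(rids) >= 0.9
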