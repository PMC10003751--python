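"""ROH calling vs a brute-force oracle, totals, sharing, containment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irdscape.model import GT_AA, GT_AB, GT_BB, MarkerTrack, RohSegment, VariantRecord
from irdscape.roh import (
    RohParams,
    autozygosity_by_genotype_class,
    call_roh,
    call_roh_bruteforce,
    shared_roh,
    total_autozygosity,
    variant_in_roh,
)
from irdscape.simulate import SimConfig, simulate_marker_track

SMALL = RohParams(
    window_markers=8, max_het_per_window=1, min_length_bp=10, min_markers=5,
    stitch_gap_bp=40,
)


def _track(genotypes, spacing=10):
    gt = np.asarray(genotypes, dtype=np.int8)
    pos = np.arange(1, gt.size * spacing, spacing, dtype=np.int64)[: gt.size]
    return MarkerTrack("p", "1", pos, gt)


class TestCallRoh:
    def test_all_het_track_yields_nothing(self):
        assert call_roh(_track([GT_AB] * 200), SMALL) == []

    def test_clean_homozygous_run_is_called(self):
        gt = [GT_AB] * 30 + [GT_AA] * 60 + [GT_AB] * 30
        (seg,) = call_roh(_track(gt), SMALL)
        assert seg.n_het == 0 and seg.n_markers == 60

    def test_boundaries_at_outermost_homozygous_markers(self):
        # run flanked by het markers: segment must start on the first hom
        gt = [GT_AB] * 20 + [GT_AA] * 40 + [GT_AB] * 20
        track = _track(gt)
        (seg,) = call_roh(track, SMALL)
        assert seg.start == int(track.positions[20])
        assert seg.end == int(track.positions[59])

    def test_nearby_segments_are_stitched(self):
        # two 30-marker runs split by one het marker, gap below stitch_gap_bp
        gt = [GT_AB] * 12 + [GT_AA] * 30 + [GT_AB] + [GT_AA] * 30 + [GT_AB] * 12
        segs = call_roh(_track(gt), SMALL)
        assert len(segs) == 1
        assert segs[0].n_het >= 1

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError):
            MarkerTrack("p", "1", np.array([10, 5]), np.array([0, 0]))

    @given(
        st.lists(
            st.sampled_from([GT_AA, GT_AB, GT_BB, -1]), min_size=1, max_size=500
        ),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=80)
    def test_matches_bruteforce_oracle(self, genotypes, pos_seed):
        """The windowed caller equals exhaustive interval enumeration."""
        rng = np.random.default_rng(pos_seed)
        pos = np.cumsum(rng.integers(1, 25, size=len(genotypes)))
        track = MarkerTrack("p", "1", pos, np.asarray(genotypes, dtype=np.int8))
        assert call_roh(track, SMALL) == call_roh_bruteforce(track, SMALL)

    def test_planted_interval_recovered(self):
        """A 9.5 Mb planted homozygous block is recovered almost exactly."""
        config = SimConfig()
        planted = (20_000_000, 29_499_999)
        for seed in range(5):
            track = simulate_marker_track(
                "p", "6", [planted], config, seed=seed, chrom_length=50_000_000
            )
            (seg,) = call_roh(track)
            overlap = min(seg.end, planted[1]) - max(seg.start, planted[0]) + 1
            assert overlap / (planted[1] - planted[0] + 1) >= 0.95


class TestTotalAutozygosity:
    def test_empty_is_zero(self):
        assert total_autozygosity([]) == 0.0

    def test_single_segment_mb(self):
        seg = RohSegment("p", "1", 1_000_001, 5_500_000, 1500, 3)
        assert total_autozygosity([seg]) == pytest.approx(4.5)

    def test_additive_over_chromosomes(self):
        segs = [
            RohSegment("p", "1", 1, 1_000_000, 300, 0),
            RohSegment("p", "2", 1, 1_000_000, 300, 0),
        ]
        assert total_autozygosity(segs) == pytest.approx(2.0)

    def test_overlap_is_error(self):
        segs = [
            RohSegment("p", "1", 1, 1_000_000, 300, 0),
            RohSegment("p", "1", 500_000, 1_500_000, 300, 0),
        ]
        with pytest.raises(ValueError, match="overlap"):
            total_autozygosity(segs)

    def test_x_chromosome_excluded_by_default(self):
        segs = [RohSegment("p", "X", 1, 10_000_000, 3000, 0)]
        assert total_autozygosity(segs) == 0.0


def _seg(pid, start, end, chrom="1"):
    return RohSegment(pid, chrom, start, end, n_markers=100, n_het=0)


class TestSharedRoh:
    def test_nested_intervals_intersect(self):
        sets = {
            "a": [_seg("a", 1, 101)],
            "b": [_seg("b", 11, 91)],
            "c": [_seg("c", 21, 81)],
        }
        (region,) = shared_roh(sets, min_patients=3)
        assert (region.start, region.end) == (21, 81)
        assert region.minimal_critical_region == (21, 81)
        assert region.patients == ("a", "b", "c")

    def test_disjoint_segments_share_nothing(self):
        sets = {"a": [_seg("a", 1, 100)], "b": [_seg("b", 200, 300)]}
        assert shared_roh(sets, min_patients=2) == []

    def test_min_patients_below_two_rejected(self):
        with pytest.raises(ValueError):
            shared_roh({"a": [], "b": []}, min_patients=1)

    def test_regions_supported_by_enough_patients(self):
        rng = np.random.default_rng(0)
        sets = {}
        for i in range(12):
            start = int(rng.integers(1, 5_000_000))
            sets[f"p{i}"] = [_seg(f"p{i}", start, start + int(rng.integers(1, 3_000_000)))]
        for region in shared_roh(sets, min_patients=4):
            assert len(region.patients) >= 4

    def test_simulated_founder_carriers_recovered(self):
        """8 carriers of one founder interval among 50 patients localize it."""
        config = SimConfig()
        planted = (40_000_000, 49_499_999)
        hits = 0
        for seed in range(5):
            sets = {}
            for i in range(50):
                intervals = [planted] if i < 8 else []
                track = simulate_marker_track(
                    f"p{i}", "6", intervals, config,
                    seed=seed * 1000 + i, chrom_length=80_000_000,
                )
                sets[f"p{i}"] = call_roh(track)
            regions = shared_roh(sets, min_patients=8)
            midpoint = (planted[0] + planted[1]) // 2
            if any(r.start <= midpoint <= r.end for r in regions):
                hits += 1
        assert hits >= 5 * 0.95


class TestVariantInRoh:
    SEG = [_seg("p", 1_000_000, 2_000_000, chrom="6")]

    def _variant(self, start, end):
        return VariantRecord(
            variant_id="v", gene="EYS", chrom="6", start=start, end=end,
            ref="A", alt="G",
        )

    def test_contained_variant(self):
        assert variant_in_roh(self._variant(1_500_000, 1_500_000), self.SEG)

    def test_one_bp_outside(self):
        assert not variant_in_roh(self._variant(2_000_001, 2_000_001), self.SEG)
        assert not variant_in_roh(self._variant(1_999_999, 2_000_001), self.SEG)


class TestByGenotypeClass:
    def test_single_patient_per_class(self):
        stats = autozygosity_by_genotype_class(
            {"a": 10.0, "b": 3.0}, {"a": "AR_hom", "b": "AR_comp_het"}
        )
        assert stats["AR_hom"]["median"] == 10.0
        assert stats["AR_comp_het"]["median"] == 3.0

    def test_lower_median_convention(self):
        stats = autozygosity_by_genotype_class(
            {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0},
            {k: "AR_hom" for k in "abcd"},
        )
        assert stats["AR_hom"]["median"] == 2.0

    def test_order_invariance(self):
        totals = {f"p{i}": float(i) for i in range(10)}
        classes = {f"p{i}": "AR_hom" if i % 2 else "unsolved" for i in range(10)}
        a = autozygosity_by_genotype_class(totals, classes)
        rev = dict(reversed(list(classes.items())))
        assert autozygosity_by_genotype_class(totals, rev) == a

    def test_hom_patients_show_more_autozygosity(self, small_cohort):
        """Patients whose causal genotype is homozygous carry the planted
        causal ROH on top of background, so their median total is higher."""
        _config, (_p, _v, _g, truth) = small_cohort
        totals = {
            pid: sum((e - s + 1) / 1e6 for _c, s, e in ivals)
            for pid, ivals in truth.planted_roh.items()
        }
        classes = dict(zip(truth.table["patient_id"], truth.table["genotype_class"]))
        classes = {k: v for k, v in classes.items() if v in ("AR_hom", "AR_comp_het")}
        stats = autozygosity_by_genotype_class(totals, classes)
        assert stats["AR_hom"]["median"] > stats["AR_comp_het"]["median"]
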