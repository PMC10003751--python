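"""Depth normalization, CNV calling, breakpoints, deletion/junction arithmetic."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from irdscape.cnv import (
    CnvParams,
    call_cnv,
    deletion_length,
    junction_product_size,
    normalize_depth,
    refine_breakpoints,
)
from irdscape.model import CnvCall, CopyState, CoverageMatrix
from irdscape.simulate import SimConfig, simulate_coverage

GENE_MODEL = [
    ("EYS", i, "6", 65_000_000 + i * 10_000, 65_000_000 + i * 10_000 + 200)
    for i in range(1, 21)
]
SAMPLES = [f"s{i}" for i in range(16)]


def _matrix(depth):
    depth = np.asarray(depth, dtype=float)
    return CoverageMatrix(
        exons=GENE_MODEL[: depth.shape[0]],
        samples=SAMPLES[: depth.shape[1]],
        depth=depth,
    )


class TestNormalizeDepth:
    def test_identical_samples_give_unit_ratios(self):
        m = _matrix(np.full((10, 10), 100.0))
        np.testing.assert_allclose(normalize_depth(m), 1.0)

    def test_library_size_normalization(self):
        # one sample at half depth genome-wide is not a deletion
        depth = np.full((10, 10), 100.0)
        depth[:, 3] = 50.0
        ratios = normalize_depth(_matrix(depth))
        np.testing.assert_allclose(ratios[:, 3], 1.0)

    def test_all_zero_exon_masked_with_warning(self):
        depth = np.full((10, 10), 100.0)
        depth[4, :] = 0.0
        with pytest.warns(UserWarning, match="masking"):
            ratios = normalize_depth(_matrix(depth))
        assert np.isnan(ratios[4]).all()
        assert np.isfinite(ratios[[i for i in range(10) if i != 4]]).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            normalize_depth(_matrix(np.full((5, 4), 100.0)))

    def test_simulated_hom_del_ratio_below_threshold(self):
        """Planted zero-copy exons land under the hom-del band almost always."""
        hits = 0
        for seed in range(100):
            cov = simulate_coverage(
                GENE_MODEL, SAMPLES, {"s0": (0, (13, 14))}, SimConfig(), seed=seed
            )
            ratios = normalize_depth(cov)
            j = SAMPLES.index("s0")
            rows = [i for i, e in enumerate(GENE_MODEL) if 13 <= e[1] <= 14]
            if np.all(ratios[rows, j] < 0.15):
                hits += 1
        assert hits >= 95


class TestCallCnv:
    def test_flat_ratios_yield_no_calls(self):
        m = _matrix(np.full((10, 10), 100.0))
        assert call_cnv(m, normalize_depth(m)) == []

    def test_two_exon_hom_del(self):
        depth = np.full((20, 16), 100.0)
        rows = [i for i, e in enumerate(GENE_MODEL) if 13 <= e[1] <= 14]
        depth[rows, 0] = 0.0
        m = _matrix(depth)
        (call,) = call_cnv(m, normalize_depth(m))
        assert (call.first_exon, call.last_exon) == (13, 14)
        assert call.copy_state is CopyState.HOM_DEL
        assert call.patient_id == "s0"

    def test_single_exon_het_del(self):
        depth = np.full((20, 16), 100.0)
        depth[7, 2] = 50.0
        m = _matrix(depth)
        (call,) = call_cnv(m, normalize_depth(m))
        assert call.first_exon == call.last_exon == GENE_MODEL[7][1]
        assert call.copy_state is CopyState.HET_DEL

    def test_breakpoint_intervals_fall_in_flanking_introns(self):
        depth = np.full((20, 16), 100.0)
        rows = [i for i, e in enumerate(GENE_MODEL) if 13 <= e[1] <= 14]
        depth[rows, 0] = 0.0
        m = _matrix(depth)
        (call,) = call_cnv(m, normalize_depth(m))
        exon12_end = next(e[4] for e in GENE_MODEL if e[1] == 12)
        exon13_start = next(e[3] for e in GENE_MODEL if e[1] == 13)
        exon14_end = next(e[4] for e in GENE_MODEL if e[1] == 14)
        exon15_start = next(e[3] for e in GENE_MODEL if e[1] == 15)
        assert call.breakpoint_left == (exon12_end + 1, exon13_start)
        assert call.breakpoint_right == (exon14_end, exon15_start - 1)

    def test_invariant_to_sample_order(self):
        depth = np.full((20, 16), 100.0)
        depth[5, 3] = 0.0
        m = _matrix(depth)
        calls = call_cnv(m, normalize_depth(m))
        perm = np.arange(16)[::-1]
        m2 = CoverageMatrix(
            exons=m.exons,
            samples=[m.samples[i] for i in perm],
            depth=m.depth[:, perm],
        )
        calls2 = call_cnv(m2, normalize_depth(m2))
        key = lambda c: (c.patient_id, c.first_exon)
        assert sorted(calls, key=key) == sorted(calls2, key=key)


class TestDeletionLength:
    def test_printed_coordinates_give_107_5_kb(self):
        assert deletion_length(65_665_873, 65_773_340) == (107_468, 107.5)

    @pytest.mark.parametrize(
        "start,end,bp,kb", [((10), 10, 1, 0.0), (1, 1000, 1000, 1.0), (1, 50, 50, 0.1)]
    )
    def test_small_intervals(self, start, end, bp, kb):
        assert deletion_length(start, end) == (bp, kb)

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            deletion_length(10, 9)

    @given(st.integers(1, 10**9), st.integers(0, 10**6))
    def test_agrees_with_interval_arithmetic(self, start, span):
        bp, kb = deletion_length(start, start + span)
        assert bp == len(range(start, start + span + 1))
        assert kb == pytest.approx(bp / 1000, abs=0.05)


class TestRefineBreakpoints:
    def _call(self, state=CopyState.HOM_DEL):
        return CnvCall("s0", "EYS", 13, 14, state)

    def test_step_function_gives_width_one_intervals(self):
        pos = np.arange(1, 2001)
        depth = np.where((pos >= 800) & (pos <= 1200), 0.0, 100.0)
        left, right = refine_breakpoints(pos, depth, self._call(), (800, 1200))
        assert left == (800, 800)
        assert right == (1200, 1200)

    def test_noisy_interval_contains_true_breakpoint(self):
        """Under negative-binomial noise the uncertainty interval still
        brackets the planted breakpoints nearly always."""
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            pos = np.arange(1, 3001)
            mean = np.where((pos >= 1000) & (pos <= 2000), 0.0, 100.0)
            lam = rng.gamma(shape=100.0, scale=np.maximum(mean, 1e-12) / 100.0)
            depth = rng.poisson(lam).astype(float)
            left, right = refine_breakpoints(pos, depth, self._call(), (1000, 2000))
            if left[0] <= 1000 <= left[1] and right[0] <= 2000 <= right[1]:
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_duplication_intervals_bracket_gain(self):
        pos = np.arange(1, 2001)
        depth = np.where((pos >= 700) & (pos <= 1400), 150.0, 100.0)
        left, right = refine_breakpoints(
            pos, depth, self._call(CopyState.DUP), (700, 1400)
        )
        assert left[0] <= 700 <= left[1]
        assert right[0] <= 1400 <= right[1]

    def test_no_transition_falls_back_to_intron_bounds(self):
        pos = np.arange(1, 101)
        depth = np.full(100, 100.0)  # no deletion signal at all
        left, right = refine_breakpoints(
            pos, depth, self._call(), (40, 60),
            intron_bounds=((30, 40), (60, 70)),
        )
        assert left == (30, 40)
        assert right == (60, 70)


class TestJunctionProduct:
    def test_template_minus_deletion(self):
        # solved template span reproducing the published carrier product
        assert junction_product_size(1, 107_720, (127, 107_594)) == 252

    def test_no_deletion_gives_full_template(self):
        assert junction_product_size(101, 400, None) == 300

    def test_primers_adjacent_to_breakpoints(self):
        # 20 bp primers hugging both breakpoints: product is their sum
        left_start, right_end = 81, 220
        deletion = (101, 200)
        assert junction_product_size(left_start, right_end, deletion) == 40

    def test_primer_inside_deletion_rejected(self):
        with pytest.raises(ValueError, match="flank"):
            junction_product_size(150, 400, (101, 200))


class TestEndToEndFalsePositives:
    def test_no_cnv_simulations_rarely_call_hom_dels(self):
        """On CNV-free cohorts the hom-del false-positive rate per sample
        stays under 1% at default thresholds."""
        fp_samples = 0
        total_samples = 0
        for seed in range(100):
            cov = simulate_coverage(GENE_MODEL, SAMPLES, {}, SimConfig(), seed=seed)
            calls = call_cnv(cov, normalize_depth(cov))
            flagged = {c.patient_id for c in calls if c.copy_state is CopyState.HOM_DEL}
            fp_samples += len(flagged)
            total_samples += len(SAMPLES)
        assert fp_samples / total_samples < 0.01

    def test_planted_deletions_recovered(self):
        """>=95% sensitivity for planted hom and het deletions."""
        hom_hits = het_hits = 0
        for seed in range(100):
            cov = simulate_coverage(
                GENE_MODEL, SAMPLES,
                {"s0": (0, (13, 14)), "s1": (1, (5, 6))},
                SimConfig(), seed=seed,
            )
            calls = call_cnv(cov, normalize_depth(cov))
            if any(
                c.patient_id == "s0" and c.copy_state is CopyState.HOM_DEL
                and c.first_exon <= 13 and c.last_exon >= 14
                for c in calls
            ):
                hom_hits += 1
            # event-level recovery: any het-del call overlapping exons 5-6
            if any(
                c.patient_id == "s1" and c.copy_state is CopyState.HET_DEL
                and c.first_exon <= 6 and c.last_exon >= 5
                for c in calls
            ):
                het_hits += 1
        assert hom_hits >= 95
        assert het_hits >= 95
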