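"""Segmentation, copy-state assignment, gene-level calls, summaries."""

import numpy as np
import pandas as pd
import pytest

from cnevolve import (
    GenomeLayout,
    PeakSet,
    WindowTrack,
    assign_copy_states,
    cnv_summary,
    gene_copy_numbers,
    infer_minimal_ploidy,
    profile_agreement,
    segment_track,
)
from cnevolve.calls import CLASS_HIGH, CLASS_NORMAL, STATE_UNDETERMINED
from tests.conftest import make_profile


@pytest.fixture
def one_arm():
    return GenomeLayout(("chr2L",), (9000,), 1000)


class TestSegmentTrack:
    def test_constant_track_is_one_segment_per_arm(self, small_layout):
        track = WindowTrack(small_layout, np.ones(20))
        segments, segmented = segment_track(track, baseline_ploidy=2)
        assert len(segments) == 2
        assert {s.arm for s in segments} == {"chr2L", "chrX"}
        np.testing.assert_allclose(segmented.values, 1.0)

    def test_step_function_recovers_three_segments(self, one_arm):
        values = np.array([1, 1, 1, 1.5, 1.5, 1.5, 1, 1, 1])
        segments, segmented = segment_track(
            WindowTrack(one_arm, values), baseline_ploidy=2
        )
        assert [s.median for s in segments] == [1.0, 1.5, 1.0]
        assert [(s.start, s.end) for s in segments] == [
            (0, 3000),
            (3000, 6000),
            (6000, 9000),
        ]

    def test_masked_windows_break_segments(self, one_arm):
        values = np.ones(9)
        track = WindowTrack(one_arm, values)
        track.mask_reason[4] = 3
        segments, _ = segment_track(track, baseline_ploidy=2)
        assert len(segments) == 2
        assert [(s.window_lo, s.window_hi) for s in segments] == [(0, 4), (5, 9)]

    def test_sub_threshold_step_not_split(self, one_arm):
        values = np.array([1, 1, 1, 1.2, 1.2, 1.2, 1, 1, 1])  # step < 0.25
        segments, _ = segment_track(WindowTrack(one_arm, values), baseline_ploidy=2)
        assert len(segments) == 1

    def test_idempotent_on_segmented_track(self, one_arm):
        rng = np.random.default_rng(3)
        values = np.array([1, 1, 1, 1.5, 1.5, 1.5, 1, 1, 1]) + rng.normal(0, 0.03, 9)
        _, segmented = segment_track(WindowTrack(one_arm, values), baseline_ploidy=2)
        segments2, resegmented = segment_track(segmented, baseline_ploidy=2)
        np.testing.assert_allclose(resegmented.values, segmented.values)

    def test_noisy_planted_boundaries_within_one_window(self):
        layout = GenomeLayout(("a",), (200_000,), 1000)
        rng = np.random.default_rng(7)
        hit = total = 0
        for _ in range(10):
            values = np.ones(200)
            values[60:100] = 1.5
            values[150:170] = 0.5
            noisy = values + rng.normal(0, 0.05, 200)
            segments, _ = segment_track(WindowTrack(layout, noisy), baseline_ploidy=2)
            bounds = {s.window_lo for s in segments} | {s.window_hi for s in segments}
            for true_b in (60, 100, 150, 170):
                total += 1
                hit += any(abs(true_b - b) <= 1 for b in bounds)
        assert hit / total >= 0.95


class TestAssignCopyStates:
    @pytest.mark.parametrize(
        "ratio,ploidy,state,cls",
        [(1.0, 2, 2, "normal"), (1.5, 2, 3, "high"), (0.5, 2, 1, "low")],
    )
    def test_diploid_states(self, one_arm, ratio, ploidy, state, cls):
        track = WindowTrack(one_arm, np.full(9, ratio))
        prof = assign_copy_states(track, ploidy)
        assert (prof.states == state).all()
        assert (prof.classes == cls).all()

    def test_tetraploid_off_baseline_peak(self, one_arm):
        # Ratio 1.29 against a modal peak at 1.03 on a tetraploid ladder:
        # round(1.29 * 4 / 1.03) = 5, one copy above baseline.
        est = infer_minimal_ploidy(
            PeakSet([0.58, 0.77, 1.03, 1.29], [800, 900, 5000, 700])
        )
        track = WindowTrack(one_arm, np.full(9, 1.29))
        prof = assign_copy_states(track, est)
        assert (prof.states == 5).all()
        assert (prof.classes == CLASS_HIGH).all()

    def test_half_copy_ties_round_away_from_zero(self, one_arm):
        track = WindowTrack(one_arm, np.full(9, 1.25))  # 2.5 copies on diploid
        prof = assign_copy_states(track, 2)
        assert (prof.states == 3).all()

    def test_scale_invariance(self, one_arm):
        track = WindowTrack(one_arm, np.full(9, 1.5))
        a = assign_copy_states(track, 2, baseline_peak=1.0)
        b = assign_copy_states(WindowTrack(one_arm, np.full(9, 3.0)), 2, baseline_peak=2.0)
        assert (a.states == b.states).all()

    def test_masked_windows_undetermined(self, one_arm):
        track = WindowTrack(one_arm, np.ones(9))
        track.mask_reason[0] = 1
        prof = assign_copy_states(track, 2)
        assert prof.states[0] == STATE_UNDETERMINED
        assert prof.classes[0] == "undetermined"

    def test_negative_median_rejected(self, one_arm):
        with pytest.raises(ValueError, match="negative"):
            assign_copy_states(WindowTrack(one_arm, np.full(9, -0.1)), 2)


class TestGeneCopyNumbers:
    def genes(self, **kw):
        base = {
            "gene_id": ["g1"],
            "arm": ["chr2L"],
            "start": [500],
            "end": [2500],
            "strand": ["+"],
            "tss": [500],
        }
        base.update(kw)
        return pd.DataFrame(base)

    def test_gene_inside_one_segment(self, one_arm):
        prof = make_profile(one_arm, [2] * 9, 2)
        out = gene_copy_numbers(prof, self.genes())
        assert out.loc[0, "state"] == 2 and out.loc[0, "class"] == CLASS_NORMAL

    def test_tss_rule_for_spanning_gene(self, one_arm):
        prof = make_profile(one_arm, [2, 2, 3, 3, 3, 3, 3, 3, 3], 2)
        # TSS in window 0 (state 2), body reaches window 2 (state 3)
        out = gene_copy_numbers(prof, self.genes())
        assert out.loc[0, "state"] == 2
        # Same gene, minus strand: TSS at the right end, in window 2
        out = gene_copy_numbers(
            prof, self.genes(strand=["-"], tss=[2499])
        )
        assert out.loc[0, "state"] == 3

    def test_any_undetermined_window_undetermines_gene(self, one_arm):
        prof = make_profile(one_arm, [2, -1, 2, 2, 2, 2, 2, 2, 2], 2)
        out = gene_copy_numbers(prof, self.genes())
        assert out.loc[0, "state"] == STATE_UNDETERMINED

    def test_unknown_arm_is_error(self, one_arm):
        prof = make_profile(one_arm, [2] * 9, 2)
        with pytest.raises(KeyError, match="chr9"):
            gene_copy_numbers(prof, self.genes(arm=["chr9"]))


class TestProfileAgreement:
    def test_identical_profiles(self, one_arm):
        a = make_profile(one_arm, [2, 2, 3, 3, 2, 2, 2, 2, 2], 2)
        assert profile_agreement(a, a) == 1.0

    def test_partial_agreement_excludes_undetermined(self, one_arm):
        a = make_profile(one_arm, [2, 2, 2, 2, -1, -1, -1, -1, -1], 2)
        b = make_profile(one_arm, [2, 2, 2, 3, -1, -1, -1, -1, -1], 2)
        assert profile_agreement(a, b) == pytest.approx(0.75)

    def test_layout_mismatch_is_error(self, one_arm, small_layout):
        a = make_profile(one_arm, [2] * 9, 2)
        b = make_profile(small_layout, [2] * 20, 2)
        with pytest.raises(ValueError, match="layout"):
            profile_agreement(a, b)

    def test_replicate_cultures_agree(self, default_dataset):
        # Two independent count realizations of the same underlying genome
        # should yield nearly identical copy-number structure, as observed
        # for resequenced cultures of the same line.
        from cnevolve import SimulationConfig, analyze_line
        from cnevolve.simulate import simulate_window_counts

        ds = default_dataset
        cfg2 = SimulationConfig(**{**ds.config.to_dict(), "seed": ds.config.seed + 1000})
        tracks2, _ = simulate_window_counts(ds.truth, cfg2, ds.masks)
        auto = ~ds.layout.arm_windows_mask(["chrX"])
        p1, *_ = analyze_line(ds.count_tracks[0], ds.masks, auto)
        p2, *_ = analyze_line(tracks2[0], ds.masks, auto)
        assert profile_agreement(p1, p2) >= 0.99


class TestCnvSummary:
    def test_all_normal_profile(self, one_arm):
        summary = cnv_summary([make_profile(one_arm, [2] * 9, 2)])
        row = summary.iloc[0]
        assert row["n_segments_high"] == 0 and row["fraction_high"] == 0.0

    def test_single_high_block_fractions(self):
        layout = GenomeLayout(("a",), (100_000,), 1000)
        states = np.full(100, 2)
        states[10:20] = 3
        summary = cnv_summary([make_profile(layout, states, 2)])
        row = summary.iloc[0]
        assert row["fraction_high"] == pytest.approx(0.10)
        assert row["n_segments_high"] == 1
        assert row["median_length_high"] == pytest.approx(10_000)

    def test_class_fractions_sum_to_one(self, default_dataset):
        ds = default_dataset
        summary = cnv_summary([ds.truth.profile(i) for i in range(4)])
        frac_cols = [c for c in summary.columns if c.startswith("fraction_")]
        sums = summary.iloc[:4][frac_cols].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0)

    def test_planted_registry_matches_truth(self):
        layout = GenomeLayout(("a",), (100_000,), 1000)
        states = np.full(100, 2)
        states[5:15] = 3   # 10 kb gain
        states[40:44] = 3  # 4 kb gain
        states[60:80] = 1  # 20 kb loss
        summary = cnv_summary([make_profile(layout, states, 2)])
        row = summary.iloc[0]
        assert row["n_segments_high"] == 2 and row["n_segments_low"] == 1
        assert row["median_length_high"] == pytest.approx(7_000)
        assert row["median_length_low"] == pytest.approx(20_000)
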