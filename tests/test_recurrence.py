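"""Recurrence counts, permutation/exact nulls, BH, Stouffer, regions, Fisher.

Monte-Carlo estimates are compared against hand-written enumeration
oracles on tiny instances; the closed-form (Poisson-binomial) path must
agree with enumeration exactly.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnevolve.calls import exclude_arms
from cnevolve import (
    GenomeLayout,
    PermutationConfig,
    bh_adjust,
    fisher_enrichment,
    merge_significant_regions,
    permutation_null,
    recurrence_counts,
    stouffer_combine,
)
from tests.conftest import make_profile


@pytest.fixture
def tiny_layout():
    return GenomeLayout(("a",), (10_000,), 1000)


def profiles_one_gain_each(layout, windows):
    """Each line diploid with a single 1-window gain at the given index."""
    out = []
    for w in windows:
        states = np.full(layout.n_windows, 2)
        states[w] = 3
        out.append(make_profile(layout, states, 2))
    return out


class TestRecurrenceCounts:
    def test_all_normal(self, tiny_layout):
        profs = [make_profile(tiny_layout, [2] * 10, 2) for _ in range(3)]
        k_gain, k_loss = recurrence_counts(profs)
        assert (k_gain == 0).all() and (k_loss == 0).all()

    def test_shared_gain_window(self, tiny_layout):
        profs = profiles_one_gain_each(tiny_layout, [5, 5, 5])
        k_gain, _ = recurrence_counts(profs)
        assert k_gain[5] == 3 and k_gain.sum() == 3

    def test_undetermined_windows_do_not_count(self, tiny_layout):
        profs = profiles_one_gain_each(tiny_layout, [5, 5])
        profs[0].states[5] = -1
        k_gain, _ = recurrence_counts(profs)
        assert k_gain[5] == 1


class TestPermutationNull:
    def test_k_zero_gives_p_one(self, tiny_layout):
        profs = [make_profile(tiny_layout, [2] * 10, 2) for _ in range(3)]
        null = permutation_null(profs, method="exact")
        assert (null["p_gain"] == 1.0).all()

    def test_exact_matches_enumeration(self, tiny_layout):
        # 3 lines, 10 windows, one gained window each, all coinciding:
        # P(K >= 3) = (1/10)^3 under independent uniform relocation.
        profs = profiles_one_gain_each(tiny_layout, [4, 4, 4])
        null = permutation_null(profs, method="exact")
        assert null["p_gain"][4] == pytest.approx(1e-3, rel=1e-12)
        # every other window: P(K >= 0) = 1
        assert null["p_gain"][0] == 1.0

    def test_shuffle_within_monte_carlo_error(self, tiny_layout):
        profs = profiles_one_gain_each(tiny_layout, [4, 4, 4])
        n_perm = 20_000
        null = permutation_null(
            profs, PermutationConfig(n_permutations=n_perm, seed=5), method="shuffle"
        )
        p_exact = 1e-3
        se = math.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(null["p_gain"][4] - p_exact) <= 3 * se + 1 / n_perm

    def test_shuffle_p_strictly_positive_and_at_most_one(self, tiny_layout):
        profs = profiles_one_gain_each(tiny_layout, [1, 2, 3])
        null = permutation_null(
            profs, PermutationConfig(n_permutations=200, seed=1), method="shuffle"
        )
        for key in ("p_gain", "p_loss"):
            assert (null[key] > 0).all() and (null[key] <= 1).all()

    def test_exact_matches_full_enumeration_two_changed_windows(self):
        # 2 lines x 6 windows, each with 2 gained windows: enumerate all
        # C(6,2)^2 placements and compare the per-window tail exactly.
        layout = GenomeLayout(("a",), (6_000,), 1000)
        profs = []
        for ws in ([0, 1], [1, 2]):
            states = np.full(6, 2)
            states[ws] = 3
            profs.append(make_profile(layout, states, 2))
        k_obs = recurrence_counts(profs)[0]
        null = permutation_null(profs, method="exact")
        placements = list(itertools.combinations(range(6), 2))
        for w in range(6):
            hits = total = 0
            for a in placements:
                for b in placements:
                    total += 1
                    k = (w in a) + (w in b)
                    hits += k >= k_obs[w]
            assert null["p_gain"][w] == pytest.approx(hits / total, rel=1e-12)

    def test_requires_two_lines(self, tiny_layout):
        with pytest.raises(ValueError, match="2 lines"):
            permutation_null([make_profile(tiny_layout, [2] * 10, 2)])


class TestBhAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.05]), [0.05])

    def test_step_up_worked_example(self):
        # Hand step-up: q_i = min over j>=i of p_(j) * m / j, all 0.04.
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=30)
    )
    def test_matches_hand_step_up_oracle(self, pvals):
        def oracle(ps):
            m = len(ps)
            order = np.argsort(ps)
            q = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, ps[i] * m / rank)
                q[i] = running
            return q

        np.testing.assert_allclose(bh_adjust(pvals), oracle(pvals), rtol=1e-12)


class TestStoufferCombine:
    def test_null_center(self):
        assert stouffer_combine([0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)

    def test_two_sigma_pair(self):
        # z = 1.9991 each, Z = 2.8271, upper tail 2.3484e-3.
        assert stouffer_combine([0.0228, 0.0228]) == pytest.approx(
            0.0023484207, rel=1e-6
        )

    def test_monotone_in_replication(self):
        previous = 1.0
        for n in range(1, 8):
            combined = stouffer_combine([0.3] * n)
            assert combined < previous
            previous = combined

    def test_degenerate_p_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            p = stouffer_combine([1.0, 0.5])
        assert 0 < p < 1

    def test_weights_change_result(self):
        assert stouffer_combine([0.01, 0.5], weights=[1, 10]) > stouffer_combine(
            [0.01, 0.5], weights=[10, 1]
        )


class TestMergeSignificantRegions:
    def test_no_significant_windows(self, tiny_layout):
        q = np.ones(10)
        out = merge_significant_regions(q, q, tiny_layout)
        assert len(out) == 0

    def test_contiguous_run_becomes_one_region(self):
        layout = GenomeLayout(("a",), (30_000,), 1000)
        q = np.ones(30)
        p = np.ones(30) * 0.5
        q[10:20] = 0.01
        p[10:20] = 0.001
        out = merge_significant_regions(q, p, layout)
        assert len(out) == 1
        region = out.iloc[0]
        assert (region["start"], region["end"]) == (10_000, 20_000)
        assert region["length"] == 10_000 and region["ge_min_length"]
        assert region["n_windows"] == 10
        assert region["combined_p"] == pytest.approx(
            stouffer_combine([0.001] * 10), rel=1e-12
        )

    def test_masked_windows_bridge_without_contributing(self):
        layout = GenomeLayout(("a",), (10_000,), 1000)
        q = np.ones(10)
        p = np.full(10, 0.5)
        q[[2, 3, 6, 7]] = 0.01
        p[[2, 3, 6, 7]] = 0.001
        masked = np.zeros(10, dtype=bool)
        masked[[4, 5]] = True
        out = merge_significant_regions(q, p, layout, masked)
        assert len(out) == 1
        assert out.iloc[0]["n_windows"] == 4
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (2000, 8000)

    def test_arm_boundary_breaks_region(self, small_layout):
        q = np.full(20, 0.01)
        p = np.full(20, 0.001)
        out = merge_significant_regions(q, p, small_layout)
        assert len(out) == 2
        assert set(out["arm"]) == {"chr2L", "chrX"}


class TestFisherEnrichment:
    def test_balanced_table(self):
        assert fisher_enrichment(5, 5, 5, 5) == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        # Two-sided exact p: sum of hypergeometric pmf over the support
        # for tables as or more extreme than the observed one.
        def pmf(k, M, K, n):
            return math.comb(K, k) * math.comb(M - K, n - k) / math.comb(M, n)

        a, b, c, d = 10, 90, 1, 899
        M, K, n = a + b + c + d, a + c, a + b
        p_obs = pmf(a, M, K, n)
        expected = sum(
            pmf(k, M, K, n)
            for k in range(max(0, n + K - M), min(K, n) + 1)
            if pmf(k, M, K, n) <= p_obs * (1 + 1e-9)
        )
        assert fisher_enrichment(a, b, c, d) == pytest.approx(expected, rel=1e-9)

    def test_transpose_symmetry(self):
        assert fisher_enrichment(10, 90, 1, 899) == pytest.approx(
            fisher_enrichment(10, 1, 90, 899), rel=1e-12
        )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(0, 0, 0, 0)


class TestNullCalibration:
    def test_exchangeable_null_yields_no_fdr_hits(self):
        # Lines with only private single-window changes (the exchangeable
        # null the shuffle/exact machinery assumes): after BH at 0.05 no
        # window should be called recurrent in the vast majority of seeds.
        from cnevolve import SimulationConfig
        from cnevolve.simulate import simulate_genome_and_profiles

        bad_seeds = 0
        for seed in range(20):
            cfg = SimulationConfig(
                seed=seed,
                n_driver_regions=0,
                private_segment_rate=200,
                segment_length_mean=1,
            )
            _, truth = simulate_genome_and_profiles(cfg)
            profs = [
                exclude_arms(truth.profile(i), ["chrX"])
                for i in range(cfg.n_lines)
            ]
            null = permutation_null(profs, method="exact")
            n_sig = 0
            for direction in ("gain", "loss"):
                q = bh_adjust(null[f"p_{direction}"])
                n_sig += int((q < 0.05).sum())
            bad_seeds += n_sig > 0
        assert bad_seeds <= 1

    def test_segmented_null_calibrated_under_rotation(self):
        # With long private segments the per-window exchangeable null is
        # anti-conservative; the segment-preserving circular-shift null
        # restores calibration on exactly the same data.
        from cnevolve import SimulationConfig
        from cnevolve.simulate import simulate_genome_and_profiles

        bad_seeds = 0
        for seed in range(5):
            cfg = SimulationConfig(seed=seed, n_driver_regions=0)
            _, truth = simulate_genome_and_profiles(cfg)
            profs = [
                exclude_arms(truth.profile(i), ["chrX"])
                for i in range(cfg.n_lines)
            ]
            null = permutation_null(
                profs,
                PermutationConfig(n_permutations=500, seed=seed),
                method="rotate",
            )
            n_sig = 0
            for direction in ("gain", "loss"):
                q = bh_adjust(null[f"p_{direction}"])
                n_sig += int((q < 0.05).sum())
            bad_seeds += n_sig > 0
        assert bad_seeds <= 1
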