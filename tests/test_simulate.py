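"""Generator contracts: planted structure, noise model, determinism, round trips."""

import numpy as np
import pandas as pd
import pytest

from cnevolve import (
    SimulationConfig,
    cluster_density_peaks,
    compute_psi,
    simulate_dataset,
    simulate_genome_and_profiles,
    simulate_window_counts,
)
from cnevolve.simulate import simulate_complexes, simulate_expression, simulate_junctions
from cnevolve.tracks import normalize_track


class TestConfigValidation:
    def test_bad_ploidy_rejected(self):
        with pytest.raises(ValueError, match="1..8"):
            SimulationConfig(ploidies=[2, 9] + [2] * 6)

    def test_probability_bounds(self):
        with pytest.raises(ValueError, match="driver_penetrance"):
            SimulationConfig(driver_penetrance=1.5)

    def test_excessive_altered_fraction_rejected(self):
        with pytest.raises(ValueError, match="0.9"):
            SimulationConfig(
                n_driver_regions=50, private_segment_rate=50, segment_length_mean=40
            )


class TestGenomeAndProfiles:
    def test_zero_rates_give_flat_baseline(self):
        cfg = SimulationConfig(
            seed=0, n_driver_regions=0, private_segment_rate=0, sexes=["female"] * 8
        )
        _, truth = simulate_genome_and_profiles(cfg)
        for li in range(cfg.n_lines):
            assert (truth.states[li] == cfg.ploidies[li]).all()

    def test_full_penetrance_drivers_in_every_line(self):
        cfg = SimulationConfig(
            seed=1,
            n_driver_regions=3,
            driver_penetrance=1.0,
            private_segment_rate=0,
            n_lines=10,
            sexes=["female"] * 10,
        )
        _, truth = simulate_genome_and_profiles(cfg)
        assert len(truth.drivers) == 3
        for d in truth.drivers.itertuples(index=False):
            assert d.carriers == ",".join(str(i) for i in range(10))
            delta = 1 if d.direction == "gain" else -1
            for li in range(10):
                expected = cfg.ploidies[li] + delta
                assert (truth.states[li, d.window_lo : d.window_hi] == expected).all()

    def test_drivers_always_shared_by_two_lines(self):
        for seed in range(5):
            cfg = SimulationConfig(seed=seed, driver_penetrance=0.3)
            _, truth = simulate_genome_and_profiles(cfg)
            for d in truth.drivers.itertuples(index=False):
                assert len(d.carriers.split(",")) >= 2

    def test_male_x_is_halved(self):
        cfg = SimulationConfig(
            seed=2, n_driver_regions=0, private_segment_rate=0,
            sexes=["male", "female"] * 4,
        )
        _, truth = simulate_genome_and_profiles(cfg)
        x_sel = truth.layout.arm_windows_mask(["chrX"])
        assert (truth.states[0, x_sel] == cfg.ploidies[0] // 2).all()
        assert (truth.states[1, x_sel] == cfg.ploidies[1]).all()

    def test_private_segment_count_matches_poisson_rate(self):
        # Mean private segments per line over replicates should sit within
        # 3 standard errors of the configured Poisson rate.
        rate = 5.0
        counts = []
        for seed in range(300):
            cfg = SimulationConfig(
                seed=seed,
                n_lines=1,
                ploidies=[2],
                sexes=["female"],
                n_driver_regions=0,
                private_segment_rate=rate,
                segment_length_mean=5,
                n_genes=1,
                n_complexes=1,
            )
            _, truth = simulate_genome_and_profiles(cfg)
            changed = truth.states[0] != 2
            # segments = runs of changed windows (undercounts only when two
            # segments collide, rare at this density)
            n_runs = int(np.diff(np.concatenate([[0], changed.view(np.int8)])).clip(0).sum())
            counts.append(n_runs)
        se = rate**0.5 / len(counts) ** 0.5
        assert abs(np.mean(counts) - rate) <= 3 * se + 0.15  # collision slack


class TestWindowCounts:
    def test_zero_state_means_zero_counts(self):
        cfg = SimulationConfig(seed=0, n_lines=1, ploidies=[1], sexes=["female"],
                               n_driver_regions=0, private_segment_rate=0)
        _, truth = simulate_genome_and_profiles(cfg)
        truth.states[0][:] = 0
        tracks, _ = simulate_window_counts(truth, cfg)
        assert (tracks[0].values == 0).all()

    def test_deterministic_limit_proportional_to_state(self):
        cfg = SimulationConfig(
            seed=0, dispersion=0.0, n_lines=1, ploidies=[2], sexes=["female"],
            gc_profile=np.full(2000, 0.375), mappability_profile=np.ones(2000),
            n_driver_regions=0, private_segment_rate=0,
        )
        _, truth = simulate_genome_and_profiles(cfg)
        truth.states[0][:100] = 4
        tracks, _ = simulate_window_counts(truth, cfg)
        assert np.allclose(tracks[0].values[:100], cfg.mean_depth * 2)
        assert np.allclose(tracks[0].values[100:], cfg.mean_depth)

    def test_planted_two_state_density_ratio(self):
        # Diploid line with a 4-copy segment over 20% of windows: the two
        # normalized density peaks should sit at ratio 2 (within noise).
        ratios = []
        for seed in range(10):
            cfg = SimulationConfig(
                seed=seed, n_lines=1, ploidies=[2], sexes=["female"],
                n_driver_regions=0, private_segment_rate=0, mean_depth=100.0,
            )
            _, truth = simulate_genome_and_profiles(cfg)
            n = truth.layout.n_windows
            truth.states[0][: n // 5] = 4
            tracks, masks = simulate_window_counts(truth, cfg)
            from cnevolve.calls import segment_track
            from cnevolve.tracks import apply_masks

            norm = normalize_track(apply_masks(tracks[0], masks))
            # cluster per-window segment medians: each copy state collapses
            # into a narrow peak regardless of counting noise
            _, segmented = segment_track(norm, baseline_ploidy=2)
            peaks = cluster_density_peaks(
                segmented.values[~segmented.masked], min_windows=100
            )
            assert len(peaks) == 2
            ratios.append(peaks.centers[1] / peaks.centers[0])
        assert np.mean(ratios) == pytest.approx(2.0, abs=0.05)


class TestExpression:
    def gene_table(self, states, ploidy=2):
        n = len(states)
        return pd.DataFrame(
            {
                "gene_id": [f"g{i:05d}" for i in range(n)],
                "state": states,
                "class": ["high" if s > ploidy else "low" if s < ploidy else "normal"
                          for s in states],
            }
        )

    def test_doubled_copy_doubles_fpkm_in_noiseless_proportional_limit(self):
        cfg = SimulationConfig(seed=0, dosage_exponent=1.0, expression_noise_sd=0.0)
        genes = self.gene_table([2, 4])
        expr = simulate_expression(genes, cfg, ploidy=2, baselines=np.array([3.0, 3.0]))
        assert expr["FPKM"].iloc[1] == pytest.approx(2 * expr["FPKM"].iloc[0])

    def test_zero_exponent_makes_expression_dose_independent(self):
        cfg = SimulationConfig(seed=0, dosage_exponent=0.0, expression_noise_sd=0.0)
        genes = self.gene_table([1, 2, 3, 4])
        expr = simulate_expression(genes, cfg, ploidy=2, baselines=np.full(4, 3.0))
        assert expr["FPKM"].nunique() == 1

    def test_zero_copy_gene_is_silent(self):
        cfg = SimulationConfig(seed=0)
        genes = self.gene_table([0, 2])
        expr = simulate_expression(genes, cfg, ploidy=2, baselines=np.full(2, 3.0))
        assert expr["FPKM"].iloc[0] == 0.0


class TestComplexesGenerator:
    def test_full_coherence_all_flagged(self):
        from cnevolve import coherence_flag

        cfg = SimulationConfig(seed=3, coherent_complex_fraction=1.0)
        _, truth = simulate_genome_and_profiles(cfg)
        copies = truth.gene_copies(0)
        catalog, flags = simulate_complexes(copies, cfg)
        classes = dict(zip(copies["gene_id"], copies["class"]))
        for cluster_id, grp in catalog.groupby("cluster_id"):
            if flags[cluster_id]:
                member_classes = [classes[g] for g in grp["gene_id"]]
                assert coherence_flag(member_classes)

    def test_background_class_expectation(self):
        # Incoherent complexes draw members uniformly: high-member count
        # per complex should match size x background frequency on average.
        cfg = SimulationConfig(seed=4, coherent_complex_fraction=0.0, n_complexes=300)
        _, truth = simulate_genome_and_profiles(cfg)
        copies = truth.gene_copies(0)
        catalog, _ = simulate_complexes(copies, cfg)
        classes = dict(zip(copies["gene_id"], copies["class"]))
        bg_high = (copies["class"] == "high").mean()
        merged = catalog.assign(cls=catalog["gene_id"].map(classes))
        obs = (merged["cls"] == "high").mean()
        assert obs == pytest.approx(bg_high, abs=0.03)


class TestJunctions:
    def test_noiseless_male_psi_one_female_zero(self):
        cfg = SimulationConfig(seed=0, junction_exclusion_depth=0.0)
        male = simulate_junctions("male", cfg)
        assert all(
            compute_psi(r.inclusion, r.exclusion) == 1.0
            for r in male.itertuples(index=False)
            if r.inclusion + r.exclusion > 0
        )
        female = simulate_junctions("female", cfg)
        assert all(
            compute_psi(r.inclusion, r.exclusion) == 0.0
            for r in female.itertuples(index=False)
            if r.inclusion + r.exclusion > 0
        )

    def test_poisson_male_psi_high(self):
        cfg = SimulationConfig(
            seed=1, n_junction_events=100,
            junction_inclusion_depth=50, junction_exclusion_depth=2,
        )
        male = simulate_junctions("male", cfg)
        psi = [compute_psi(r.inclusion, r.exclusion) for r in male.itertuples(index=False)]
        assert np.median(psi) >= 0.9

    def test_unknown_sex_rejected(self):
        with pytest.raises(ValueError, match="sex"):
            simulate_junctions("unknown", SimulationConfig())


class TestDeterminism:
    def test_identical_seed_bitwise_identical_outputs(self):
        a = simulate_dataset(SimulationConfig(seed=42))
        b = simulate_dataset(SimulationConfig(seed=42))
        assert (a.truth.states == b.truth.states).all()
        assert a.truth.sexes == b.truth.sexes
        for ta, tb in zip(a.count_tracks, b.count_tracks):
            assert (ta.values == tb.values).all()
        pd.testing.assert_frame_equal(a.expression[0], b.expression[0])
        pd.testing.assert_frame_equal(a.complexes, b.complexes)
        pd.testing.assert_frame_equal(a.junctions[0], b.junctions[0])

    def test_different_seed_differs(self):
        a = simulate_dataset(SimulationConfig(seed=1))
        b = simulate_dataset(SimulationConfig(seed=2))
        assert not (a.truth.states == b.truth.states).all()


class TestRoundTrips:
    def test_generated_tables_round_trip_through_io(self, tmp_path, default_dataset):
        from cnevolve import io as cio

        ds = default_dataset
        cio.write_window_track(tmp_path / "c.bed", ds.count_tracks[0])
        back = cio.read_window_track(tmp_path / "c.bed")
        np.testing.assert_allclose(back.values, ds.count_tracks[0].values, rtol=1e-9)
        assert back.layout == ds.layout

        cio.write_expression(tmp_path / "e.tsv", ds.expression[0])
        back_e = cio.read_expression(tmp_path / "e.tsv")
        np.testing.assert_allclose(back_e["FPKM"], ds.expression[0]["FPKM"], rtol=1e-9)

        cio.write_complexes(tmp_path / "k.tsv", ds.complexes)
        back_k = cio.read_complexes(tmp_path / "k.tsv")
        pd.testing.assert_frame_equal(back_k, ds.complexes[["cluster_id", "gene_id"]])

        cio.write_yaml(tmp_path / "cfg.yaml", ds.config.to_dict())
        raw = cio.read_yaml(tmp_path / "cfg.yaml")
        assert SimulationConfig(**raw).to_dict() == ds.config.to_dict()
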