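"""Replicated synthetic studies: the quantitative summaries the analysis
scripts, the acceptance checks and the test suite all share.

Every function here generates its own data through
:class:`~cnevolve.simulate.SimulationConfig` (seeded), runs the relevant
part of the pipeline, and returns plain records -- no file I/O.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .breakpoints import detect_breakpoints, hotspot_counts, hotspot_permutation_test
from .calls import exclude_arms, gene_copy_numbers, profile_agreement
from .complexes import coherence_permutation_test
from .dosage import dosage_slope
from .pipeline import analyze_line
from .recurrence import bh_adjust, merge_significant_regions, permutation_null
from .sex import classify_sex, coverage_ratio
from .simulate import (
    SimulationConfig,
    simulate_complexes,
    simulate_expression,
    simulate_genome_and_profiles,
    simulate_window_counts,
)

__all__ = [
    "analyze_dataset_lines",
    "ploidy_sex_recovery",
    "driver_recovery",
    "dosage_slope_recovery",
    "fdr_null_calibration",
    "coherence_study",
    "hotspot_study",
    "replicate_agreement",
]


def _autosome_selector(layout):
    return ~layout.arm_windows_mask(["chrX"])


def analyze_dataset_lines(truth, tracks, masks):
    """Run the per-line calling chain for every line; returns profiles,
    ploidy estimates and X:A ratios."""
    auto = _autosome_selector(truth.layout)
    autosome_names = [a for a in truth.layout.arm_names if a != "chrX"]
    profiles, estimates, x_a = [], [], []
    for track in tracks:
        profile, ratios, _, estimate = analyze_line(track, masks, auto)
        profiles.append(profile)
        estimates.append(estimate)
        x_a.append(coverage_ratio(ratios, ["chrX"], autosome_names))
    return profiles, estimates, x_a


def ploidy_sex_recovery(n_seeds: int = 20, base_seed: int = 0, **config_kwargs):
    """Fraction of lines whose minimal ploidy and DNA sex are recovered."""
    records = []
    for k in range(n_seeds):
        cfg = SimulationConfig(seed=base_seed + k, **config_kwargs)
        _, truth = simulate_genome_and_profiles(cfg)
        tracks, masks = simulate_window_counts(truth, cfg)
        _, estimates, x_a = analyze_dataset_lines(truth, tracks, masks)
        for li, est in enumerate(estimates):
            records.append(
                {
                    "seed": cfg.seed,
                    "line": li,
                    "true_ploidy": truth.ploidies[li],
                    "called_ploidy": est.minimal_ploidy,
                    "confidence": est.confidence_note,
                    "true_sex": truth.sexes[li],
                    "called_sex": classify_sex(x_a[li]).dna_sex,
                    "x_a": x_a[li],
                }
            )
    return pd.DataFrame(records)


def driver_recovery(n_seeds: int = 10, base_seed: int = 0, alpha: float = 0.05,
                    n_lines: int = 19, **config_kwargs):
    """For each seed: are all planted drivers overlapped by an FDR-significant
    recurrent region of the right direction? Returns per-driver records.

    Defaults to 19 lines -- the cross-line power of the recurrence test
    depends directly on the panel size, and a driver carried by ~70% of
    8 lines is statistically indistinguishable from a ~20%-per-line
    changed-window background."""
    records = []
    for k in range(n_seeds):
        cfg = SimulationConfig(seed=base_seed + k, n_lines=n_lines, **config_kwargs)
        _, truth = simulate_genome_and_profiles(cfg)
        tracks, masks = simulate_window_counts(truth, cfg)
        profiles, _, _ = analyze_dataset_lines(truth, tracks, masks)
        autosomal = [exclude_arms(p, ["chrX"]) for p in profiles]
        null = permutation_null(autosomal, method="exact")
        regions = []
        for direction in ("gain", "loss"):
            q = bh_adjust(null[f"p_{direction}"])
            regions.append(
                merge_significant_regions(
                    q,
                    null[f"p_{direction}"],
                    truth.layout,
                    ~autosomal[0].determined,
                    direction,
                    alpha=alpha,
                )
            )
        regions = pd.concat([r for r in regions if len(r)], ignore_index=True) \
            if any(len(r) for r in regions) else regions[0]
        for d in truth.drivers.itertuples(index=False):
            overlapped = bool(
                len(regions)
                and (
                    (regions["arm"] == d.arm)
                    & (regions["direction"] == d.direction)
                    & (regions["start"] < d.end)
                    & (regions["end"] > d.start)
                ).any()
            )
            records.append(
                {
                    "seed": cfg.seed,
                    "driver": d.driver,
                    "direction": d.direction,
                    "n_carriers": len(d.carriers.split(",")),
                    "recovered": overlapped,
                    "n_regions": int(len(regions)),
                }
            )
    return pd.DataFrame(records)


def dosage_slope_recovery(betas=(0.0, 0.5, 0.7, 1.0), n_seeds: int = 20,
                          base_seed: int = 0, line: int = 0, **config_kwargs):
    """Recovered dose-response slope per planted exponent."""
    records = []
    for beta in betas:
        for k in range(n_seeds):
            cfg = SimulationConfig(
                seed=base_seed + k, dosage_exponent=beta,
                expression_noise_sd=0.2, n_genes=2000, **config_kwargs,
            )
            _, truth = simulate_genome_and_profiles(cfg)
            copies = truth.gene_copies(line)
            expr = simulate_expression(
                copies, cfg, ploidy=truth.ploidies[line],
                baselines=truth.gene_baselines,
            )
            slope, rho = dosage_slope(expr, copies, truth.ploidies[line])
            records.append({"beta": beta, "seed": cfg.seed, "slope": slope, "rho": rho})
    return pd.DataFrame(records)


def fdr_null_calibration(n_seeds: int = 20, base_seed: int = 0, alpha: float = 0.05):
    """Significant-window count per seed under the exchangeable null
    (private single-window changes only, no shared drivers)."""
    records = []
    for k in range(n_seeds):
        cfg = SimulationConfig(
            seed=base_seed + k,
            n_driver_regions=0,
            private_segment_rate=200,
            segment_length_mean=1,
        )
        _, truth = simulate_genome_and_profiles(cfg)
        profiles = [
            exclude_arms(truth.profile(i), ["chrX"]) for i in range(cfg.n_lines)
        ]
        null = permutation_null(profiles, method="exact")
        n_sig = sum(
            int((bh_adjust(null[f"p_{d}"]) < alpha).sum()) for d in ("gain", "loss")
        )
        n_tested = int(profiles[0].determined.sum())
        records.append({"seed": cfg.seed, "n_significant": n_sig, "n_tested": n_tested})
    return pd.DataFrame(records)


def coherence_study(coherent_fraction: float, n_seeds: int = 20, base_seed: int = 0,
                    n_perm: int = 500, line: int = 0):
    """Coherent-complex permutation p per seed at a planted coherent fraction."""
    records = []
    for k in range(n_seeds):
        cfg = SimulationConfig(
            seed=base_seed + k, coherent_complex_fraction=coherent_fraction
        )
        _, truth = simulate_genome_and_profiles(cfg)
        copies = truth.gene_copies(line)
        catalog, _ = simulate_complexes(copies, cfg)
        observed, p = coherence_permutation_test(
            catalog, copies, n_perm=n_perm, seed=cfg.seed + 10_000
        )
        records.append({"seed": cfg.seed, "observed_coherent": observed, "p": p})
    return pd.DataFrame(records)


def hotspot_study(seed: int = 0, min_lines: int = 5, n_perm: int = 10_000,
                  **config_kwargs):
    """Breakpoint hotspot count and permutation p on called profiles."""
    cfg = SimulationConfig(seed=seed, **config_kwargs)
    _, truth = simulate_genome_and_profiles(cfg)
    tracks, masks = simulate_window_counts(truth, cfg)
    profiles, _, _ = analyze_dataset_lines(truth, tracks, masks)
    tables = [detect_breakpoints(p) for p in profiles]
    n_hot, p = hotspot_permutation_test(
        tables, profiles[0].determined, min_lines=min_lines, n_perm=n_perm, seed=seed
    )
    n_breakpoints = int(np.unique(np.concatenate(tables)).size) if tables else 0
    return {
        "n_breakpoint_windows": n_breakpoints,
        "n_hotspots": n_hot,
        "p": p,
    }


def replicate_agreement(seed: int = 0, line: int = 0):
    """Copy-state agreement between two count realizations of one genome.

    Both replicate cultures are called on a common ploidy baseline (the
    first replicate's estimate), as one would when comparing resequenced
    cultures of a known line; otherwise a borderline peak ladder can
    flip the minimal-ploidy call between replicates and make absolute
    states incomparable even though the structure is identical."""
    cfg = SimulationConfig(seed=seed)
    _, truth = simulate_genome_and_profiles(cfg)
    tracks_a, masks = simulate_window_counts(truth, cfg)
    cfg_b = SimulationConfig(**{**cfg.to_dict(), "seed": cfg.seed + 1000})
    tracks_b, _ = simulate_window_counts(truth, cfg_b, masks)
    auto = _autosome_selector(truth.layout)
    prof_a, _, _, est_a = analyze_line(tracks_a[line], masks, auto)
    prof_b, *_ = analyze_line(
        tracks_b[line], masks, auto, assume_ploidy=est_a.minimal_ploidy
    )
    return profile_agreement(prof_a, prof_b)
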