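"""End-to-end orchestration: simulate -> tracks -> ploidy/sex -> calls ->
{recurrence, breakpoints, dosage, complexes}, with a run manifest.

Each stage writes its outputs under the run directory and records them in
a manifest (path, sha256, stage parameters, seed), so a run is fully
re-derivable from the manifest alone. Stage toggles let independent
branches run or be skipped; a failing stage aborts its dependents but not
its siblings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .calls import (
    assign_copy_states,
    cnv_summary,
    exclude_arms,
    gene_copy_numbers,
    segment_track,
)
from .breakpoints import detect_breakpoints, hotspot_counts, hotspot_permutation_test
from .complexes import coherence_permutation_test, coherence_report
from .dosage import center_by_normal, dosage_response_test
from .ploidy import cluster_density_peaks, infer_minimal_ploidy
from .recurrence import (
    PermutationConfig,
    bh_adjust,
    merge_significant_regions,
    permutation_null,
    recurrence_counts,
)
from .sex import classify_sex, compute_psi, coverage_ratio
from .simulate import SimulationConfig, simulate_dataset
from .tracks import WindowTrack, apply_masks, normalize_track

logger = logging.getLogger("cnevolve")

__all__ = ["RunConfig", "run_pipeline", "analyze_line", "scaled_min_peak_windows"]


@dataclass
class RunConfig:
    """One reproducible run: simulation parameters, stage toggles, thresholds."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: str = "results/run"
    seed: int | None = None  # overrides simulation.seed when set
    stages: dict = field(
        default_factory=lambda: {
            "recurrence": True,
            "breakpoints": True,
            "dosage": True,
            "complexes": True,
        }
    )
    alpha: float = 0.05
    min_hotspot_lines: int = 5
    n_perm_breakpoints: int = 2000
    n_perm_complexes: int = 1000
    min_segment_windows: int = 3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = cio.read_yaml(path)
        sim = SimulationConfig(**raw.pop("simulation", {}))
        known = {k: raw[k] for k in raw if k in cls.__dataclass_fields__}
        known["simulation"] = sim
        return cls(**known)


def scaled_min_peak_windows(n_unmasked: int) -> int:
    """Peak support threshold: 0.5% of unmasked windows, floor 50, cap 500.

    The fixed 500-window rule matches a full 1 kb-windowed genome
    (~1.2e5 windows); smaller synthetic genomes scale it down.
    """
    return int(min(500, max(50, round(0.005 * n_unmasked))))


def _refine_peak_centers(peaks, values, refine_values=None):
    """Replace peak centers (cluster means) with member medians.

    Cluster means get dragged by mis-segmented straggler values between
    two copy states; the median of the (well-estimated) values assigned
    to each peak is robust to that tail and recovers the state's true
    density ratio. ``values`` determine the support counts,
    ``refine_values`` (default: same) the centers; a peak with no
    refine-value members keeps its original center.
    """
    from .ploidy import PeakSet

    if refine_values is None:
        refine_values = values
    assignment = np.argmin(np.abs(values[:, None] - peaks.centers[None, :]), axis=1)
    refine_assignment = np.argmin(
        np.abs(refine_values[:, None] - peaks.centers[None, :]), axis=1
    )
    centers, counts = [], []
    for j in range(len(peaks)):
        n = int((assignment == j).sum())
        if n == 0:
            continue
        members = refine_values[refine_assignment == j]
        center = float(np.median(members)) if members.size else float(peaks.centers[j])
        centers.append(center)
        counts.append(n)
    order = np.argsort(centers)
    centers = list(np.asarray(centers, dtype=float)[order])
    counts = list(np.asarray(counts, dtype=np.int64)[order])
    i = 1
    while i < len(centers):  # refinement can collapse two peaks onto one center
        if centers[i] - centers[i - 1] <= 1e-9:
            centers[i - 1] = (
                centers[i - 1] * counts[i - 1] + centers[i] * counts[i]
            ) / (counts[i - 1] + counts[i])
            counts[i - 1] += counts.pop(i)
            centers.pop(i)
        else:
            i += 1
    return PeakSet(np.asarray(centers), np.asarray(counts))


def analyze_line(
    count_track,
    masks,
    autosome_selector,
    min_segment_windows=3,
    provisional_threshold=0.125,
    assume_ploidy=None,
):
    """Single-line analysis: mask, segment, peak-cluster, infer ploidy,
    re-segment on the ploidy baseline, and call integer copy states.

    Peak clustering runs on *segment-median* values (each window carries
    the median of its provisional segment), which concentrates every copy
    state into a narrow peak regardless of per-window counting noise --
    the same order of operations as segment-then-cluster read-depth
    callers. The provisional segmentation uses a fixed ratio threshold
    (default 0.125, half a copy unit at ploidy 4) because the ploidy is
    not yet known; the final segmentation re-runs at half a copy unit of
    the inferred ploidy.

    The normalization anchor and the ploidy peaks are estimated from
    autosomal windows only: a halved male X would otherwise inject a peak
    at 0.5 that corrupts the adjacent-spacing estimate.
    ``assume_ploidy`` overrides the inferred minimal ploidy (for
    ambiguous ladders, or to hold a known baseline fixed across
    replicate cultures); the peak-based anchor is still used.
    Returns ``(profile, ratio_track, peaks, estimate)``.
    """
    from .ploidy import PeakSet

    masked = apply_masks(count_track, masks)
    auto_ok = ~masked.masked & autosome_selector
    med = float(np.median(masked.values[auto_ok]))
    if med <= 0:
        raise ValueError("non-positive median count")
    provisional = WindowTrack(masked.layout, masked.values / med, masked.mask_reason)
    prov_segments, prov_seg = segment_track(
        provisional,
        threshold=provisional_threshold,
        min_segment_windows=min_segment_windows,
    )
    min_peak = scaled_min_peak_windows(int(auto_ok.sum()))
    raw_peaks = cluster_density_peaks(prov_seg.values[auto_ok], min_windows=min_peak)
    # Center refinement uses only windows from long segments: a short
    # segment's median is noisy (se ~ sigma/sqrt(n)) and a cloud of such
    # stragglers between two copy states biases the peak centers.
    long_seg = np.zeros(masked.layout.n_windows, dtype=bool)
    for s in prov_segments:
        if s.n_windows >= 8:
            long_seg[s.window_lo : s.window_hi] = True
    refine_vals = prov_seg.values[auto_ok & long_seg]
    if refine_vals.size == 0:
        refine_vals = prov_seg.values[auto_ok]
    raw_peaks = _refine_peak_centers(raw_peaks, prov_seg.values[auto_ok], refine_vals)
    anchor = float(raw_peaks.centers[raw_peaks.modal_index])
    ratios = WindowTrack(masked.layout, provisional.values / anchor, masked.mask_reason)
    peaks = PeakSet(raw_peaks.centers / anchor, raw_peaks.counts)
    estimate = infer_minimal_ploidy(peaks)
    ploidy = estimate.minimal_ploidy if assume_ploidy is None else int(assume_ploidy)
    _, segmented = segment_track(
        ratios,
        baseline_ploidy=ploidy,
        min_segment_windows=min_segment_windows,
    )
    profile = assign_copy_states(segmented, ploidy, baseline_peak=estimate.baseline_peak)
    return profile, ratios, peaks, estimate


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic study; returns the manifest dict.

    Stage order: simulate -> tracks -> ploidy/sex -> calls, then the
    independent branches (recurrence, breakpoints, dosage, complexes).
    The manifest lists every output file with its checksum plus the stage
    parameters and seed. Identical config + seed reproduces identical
    checksums.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    if config.seed is not None:
        sim = SimulationConfig(**{**sim.to_dict(), "seed": config.seed})
    manifest = {
        "seed": sim.seed,
        "parameters": {
            "alpha": config.alpha,
            "min_hotspot_lines": config.min_hotspot_lines,
            "n_perm_breakpoints": config.n_perm_breakpoints,
            "n_perm_complexes": config.n_perm_complexes,
            "min_segment_windows": config.min_segment_windows,
            "simulation": sim.to_dict(),
        },
        "stages": {},
        "outputs": [],
    }

    def record(stage, path: Path):
        manifest["outputs"].append(
            {"stage": stage, "path": str(path), "sha256": _sha256(path)}
        )

    def run_stage(name, fn, *deps_ok):
        t0 = time.time()
        if not all(deps_ok):
            manifest["stages"][name] = {"status": "skipped_failed_dependency"}
            return False
        try:
            fn()
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.time() - t0, 3),
            }
            return True
        except Exception as exc:  # stage failure must not kill siblings
            logger.exception("stage %s failed", name)
            manifest["stages"][name] = {"status": f"failed: {exc}"}
            return False

    state: dict = {}

    def stage_simulate():
        ds = simulate_dataset(sim)
        state["ds"] = ds
        cio.write_yaml(out / "config.yaml", manifest["parameters"])
        record("simulate", out / "config.yaml")
        for li, track in enumerate(ds.count_tracks):
            p = out / f"counts_{ds.truth.line_names[li]}.bed"
            cio.write_window_track(p, track)
            record("simulate", p)
        cio.write_mask_track(out / "masks.tsv", ds.masks)
        record("simulate", out / "masks.tsv")
        ds.truth.drivers.to_csv(out / "truth_drivers.tsv", sep="\t", index=False)
        record("simulate", out / "truth_drivers.tsv")

    def stage_calls():
        ds = state["ds"]
        autosomes = ~ds.layout.arm_windows_mask(["chrX"])
        profiles, estimates, sex_rows = [], [], []
        for li, track in enumerate(ds.count_tracks):
            profile, ratios, peaks, estimate = analyze_line(
                track, ds.masks, autosomes, config.min_segment_windows
            )
            profiles.append(profile)
            estimates.append(estimate)
            x_a = coverage_ratio(ratios, ["chrX"], [a for a in ds.layout.arm_names if a != "chrX"])
            junc = ds.junctions[li]
            psi = [
                compute_psi(r.inclusion, r.exclusion)
                for r in junc.itertuples(index=False)
            ]
            markers = pd.DataFrame(
                {"marker": junc["event_id"], "kind": "psi", "value": psi}
            )
            call = classify_sex(x_a, markers=markers)
            sex_rows.append(
                {
                    "line": ds.truth.line_names[li],
                    "minimal_ploidy": estimate.minimal_ploidy,
                    "confidence": estimate.confidence_note,
                    "x_a_ratio": round(x_a, 4),
                    "dna_sex": call.dna_sex,
                    "marker_sex": call.marker_sex,
                    "final_sex": call.final_sex,
                    "true_ploidy": ds.truth.ploidies[li],
                    "true_sex": ds.truth.sexes[li],
                }
            )
            p = out / f"calls_{ds.truth.line_names[li]}.tsv"
            cio.write_calls(p, profile)
            record("calls", p)
        pd.DataFrame(sex_rows).to_csv(out / "ploidy_sex.tsv", sep="\t", index=False)
        record("calls", out / "ploidy_sex.tsv")
        summary = cnv_summary(profiles, names=state["ds"].truth.line_names)
        summary.to_csv(out / "cnv_summary.tsv", sep="\t", index=False)
        record("calls", out / "cnv_summary.tsv")
        state["profiles"] = profiles
        state["estimates"] = estimates

    def stage_recurrence():
        ds, profiles = state["ds"], state["profiles"]
        # The X is excluded: a male line's halved X is sex, not acquired CNV.
        autosomal = [exclude_arms(p, ["chrX"]) for p in profiles]
        null = permutation_null(
            autosomal, PermutationConfig(seed=sim.seed, alpha=config.alpha), method="exact"
        )
        regions = []
        for direction in ("gain", "loss"):
            p = null[f"p_{direction}"]
            q = bh_adjust(p)
            masked = ~autosomal[0].determined
            regions.append(
                merge_significant_regions(
                    q, p, ds.layout, masked, direction, alpha=config.alpha
                )
            )
        non_empty = [r for r in regions if len(r)]
        regions = (
            pd.concat(non_empty, ignore_index=True) if non_empty else regions[0]
        )
        regions.to_csv(out / "recurrent_regions.tsv", sep="\t", index=False)
        record("recurrence", out / "recurrent_regions.tsv")
        state["regions"] = regions

    def stage_breakpoints():
        ds, profiles = state["ds"], state["profiles"]
        tables = [detect_breakpoints(p) for p in profiles]
        eligible = profiles[0].determined
        n_hot, p = hotspot_permutation_test(
            tables,
            eligible,
            min_lines=config.min_hotspot_lines,
            n_perm=config.n_perm_breakpoints,
            seed=sim.seed,
        )
        counts = hotspot_counts(tables, ds.layout.n_windows)
        tab = ds.layout.window_table()
        tab["n_lines_breaking"] = counts
        tab[tab["n_lines_breaking"] > 0].to_csv(
            out / "breakpoints.tsv", sep="\t", index=False
        )
        record("breakpoints", out / "breakpoints.tsv")
        state["hotspots"] = {"n_hotspots": n_hot, "p": p}
        (out / "hotspots.json").write_text(json.dumps(state["hotspots"]))
        record("breakpoints", out / "hotspots.json")

    def stage_dosage():
        ds, profiles = state["ds"], state["profiles"]
        rows = []
        for li, profile in enumerate(profiles):
            genes = gene_copy_numbers(profile, ds.truth.genes)
            try:
                centered = center_by_normal(ds.expression[li], genes)
                result = dosage_response_test(centered, profile.baseline_ploidy)
            except ValueError:
                continue
            for r in result.per_state.itertuples(index=False):
                rows.append({"line": ds.truth.line_names[li], **r._asdict(),
                             "slope": result.slope})
        pd.DataFrame(rows).to_csv(out / "dosage.tsv", sep="\t", index=False)
        record("dosage", out / "dosage.tsv")

    def stage_complexes():
        ds = state["ds"]
        profile = state["profiles"][ds.complex_line]
        genes = gene_copy_numbers(profile, ds.truth.genes)
        report = coherence_report(ds.complexes, genes)
        report.to_csv(out / "complex_report.tsv", sep="\t", index=False)
        record("complexes", out / "complex_report.tsv")
        observed, p = coherence_permutation_test(
            ds.complexes, genes, n_perm=config.n_perm_complexes, seed=sim.seed
        )
        (out / "complex_coherence.json").write_text(
            json.dumps({"observed_coherent": observed, "p": p})
        )
        record("complexes", out / "complex_coherence.json")

    ok_sim = run_stage("simulate", stage_simulate)
    ok_calls = run_stage("calls", stage_calls, ok_sim)
    if config.stages.get("recurrence", True):
        run_stage("recurrence", stage_recurrence, ok_calls)
    if config.stages.get("breakpoints", True):
        run_stage("breakpoints", stage_breakpoints, ok_calls)
    if config.stages.get("dosage", True):
        run_stage("dosage", stage_dosage, ok_calls)
    if config.stages.get("complexes", True):
        run_stage("complexes", stage_complexes, ok_calls)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["ok"] = all(
        v["status"] == "ok" or v["status"].startswith("skipped")
        for v in manifest["stages"].values()
    )
    return manifest
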