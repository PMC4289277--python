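"""Synthetic multi-line genomes with planted copy-number structure.

The generator emulates the statistical structure the analysis assumes: a
shared windowed genome over several chromosome arms (X last), one integer
copy-state profile per cell line on a ploidy-2 or ploidy-4 baseline,
*driver* segments planted at shared coordinates in a random subset of
lines plus *private* segments per line, overdispersed (negative-binomial)
window read counts with a mild unimodal GC bias and mappability gaps,
gene expression with a tunable sublinear dose response, protein complexes
with a tunable coherent fraction, and sex-specific splice-junction counts.
Male lines carry a halved X. Everything is driven by one global seed
through a documented stream-splitting scheme, so outputs are bit-identical
across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .calls import (
    CLASS_HIGH,
    CLASS_LOW,
    CLASS_NORMAL,
    CLASS_UNDETERMINED,
    STATE_UNDETERMINED,
    CopyNumberProfile,
)
from .tracks import GenomeLayout, MaskTrack, WindowTrack

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "simulate_genome_and_profiles",
    "simulate_window_counts",
    "simulate_expression",
    "simulate_complexes",
    "simulate_junctions",
    "simulate_dataset",
]

_AUTOSOME_NAMES = ("chr2L", "chr2R", "chr3L", "chr3R", "chr4", "chr5", "chr6")

# Named sub-streams of the global seed; each stage draws from its own
# independent stream so adding draws to one stage never shifts another.
_STREAMS = ("genome", "masks", "counts", "genes", "expression", "complexes", "junctions")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe the baseline conditions used throughout the test
    suite and the analysis scripts: a 2 Mb genome (5 arms x 400 x 1 kb
    windows, X last), 8 lines alternating diploid/tetraploid, 6 shared
    driver regions at penetrance 0.7, 6 private segments per line
    (geometric mean length 40 windows; together roughly a fifth of the
    genome altered per line), gains outnumbering losses 4:1,
    depth 200 reads/window with negative-binomial dispersion 0.002, a
    sublinear dose-response exponent of 0.7, and 30% coherent complexes.
    """

    n_arms: int = 5
    windows_per_arm: int = 400
    window_size: int = 1000
    n_lines: int = 8
    ploidies: list | None = None  # per line; default alternates 2, 4
    sexes: list | None = None  # per line; default random male/female
    n_driver_regions: int = 6
    driver_penetrance: float = 0.7
    private_segment_rate: float = 6.0
    segment_length_mean: float = 40.0  # geometric mean, in windows
    gain_fraction: float = 0.8
    driver_edge_jitter: int = 0  # windows; per-carrier endpoint wobble
    mean_depth: float = 200.0
    dispersion: float = 0.002  # NB: var = mu + dispersion * mu^2
    gc_optimum: float = 0.375
    gc_bias_width: float = 0.15
    gc_profile: np.ndarray | None = None
    mappability_profile: np.ndarray | None = None
    low_mappability_fraction: float = 0.02
    gc_outlier_fraction: float = 0.02
    n_genes: int = 1500
    dosage_exponent: float = 0.7  # beta: 1 proportional, <1 buffered
    expression_noise_sd: float = 0.5  # log2 units
    baseline_log2_fpkm_mean: float = 5.0
    baseline_log2_fpkm_sd: float = 1.0
    n_complexes: int = 120
    complex_size_mean: float = 6.0
    coherent_complex_fraction: float = 0.3
    n_junction_events: int = 20
    junction_inclusion_depth: float = 50.0
    junction_exclusion_depth: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_arms", "windows_per_arm", "window_size", "n_lines",
                     "n_genes", "n_complexes", "n_junction_events"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("driver_penetrance", "gain_fraction",
                     "coherent_complex_fraction", "low_mappability_fraction",
                     "gc_outlier_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_driver_regions < 0 or self.private_segment_rate < 0:
            raise ValueError("driver/private rates must be non-negative")
        if self.ploidies is None:
            self.ploidies = [2 if i % 2 == 0 else 4 for i in range(self.n_lines)]
        if len(self.ploidies) != self.n_lines:
            raise ValueError("ploidies must have one entry per line")
        if any(not 1 <= p <= 8 for p in self.ploidies):
            raise ValueError("ploidies must lie in 1..8")
        if self.sexes is not None and len(self.sexes) != self.n_lines:
            raise ValueError("sexes must have one entry per line")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        n_windows = self.n_arms * self.windows_per_arm
        worst = (self.n_driver_regions + self.private_segment_rate) * self.segment_length_mean
        if worst > 0.9 * n_windows:
            raise ValueError(
                "config rejected: expected altered fraction exceeds 0.9 of the genome"
            )

    # -- seed splitting ---------------------------------------------------
    def rng(self, stream: str, index: int | None = None) -> np.random.Generator:
        """Generator for a named stage stream (optionally per-line/item)."""
        key = [self.seed, _STREAMS.index(stream)]
        if index is not None:
            key.append(index)
        return np.random.default_rng(np.random.SeedSequence(key))

    def layout(self) -> GenomeLayout:
        names = list(_AUTOSOME_NAMES[: self.n_arms - 1]) + ["chrX"]
        lengths = [self.windows_per_arm * self.window_size] * self.n_arms
        return GenomeLayout(tuple(names), tuple(lengths), self.window_size)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("gc_profile", "mappability_profile"):
            if d[key] is not None:
                d[key] = [float(x) for x in d[key]]
        return d


@dataclass
class SyntheticTruth:
    """Planted ground truth, aligned 1:1 with the generated windows."""

    layout: GenomeLayout
    line_names: list
    ploidies: list
    sexes: list
    states: np.ndarray  # (n_lines, n_windows) integer copy states
    drivers: pd.DataFrame  # arm, start, end, direction, carriers
    genes: pd.DataFrame  # gene_id, arm, start, end, strand, tss
    gene_baselines: np.ndarray  # per-gene baseline log2 FPKM

    def profile(self, line: int) -> CopyNumberProfile:
        return CopyNumberProfile(self.layout, self.states[line], self.ploidies[line])

    def gene_copies(self, line: int) -> pd.DataFrame:
        """True per-gene copy table for one line (TSS-window state)."""
        from .calls import gene_copy_numbers

        return gene_copy_numbers(self.profile(line), self.genes)


def _geometric_length(rng, mean: float) -> int:
    return int(rng.geometric(1.0 / max(mean, 1.0)))


def _place_segment(rng, layout: GenomeLayout, arm_indices, length: int):
    """Uniform placement of a segment of ``length`` windows on one arm."""
    ai = int(rng.choice(arm_indices))
    n = int(layout.arm_n_windows[ai])
    length = min(length, n)
    lo = int(rng.integers(0, n - length + 1))
    off = int(layout.arm_offsets[ai])
    return ai, off + lo, off + lo + length


def simulate_genome_and_profiles(config: SimulationConfig):
    """Plant per-line integer copy states; returns ``(layout, truth)``.

    Baseline state equals the line's ploidy. Drivers occupy shared
    coordinates on autosomal arms; each line carries a given driver with
    probability ``driver_penetrance`` (carrier sets are redrawn until at
    least two lines share the driver, so recurrence is always defined).
    Private segments are Poisson in number, geometric in length, uniform
    in position. Gains add one copy, losses remove one (floored at zero).
    Male lines have their X-window states halved (rounded down).
    """
    layout = config.layout()
    rng = config.rng("genome")
    n_windows = layout.n_windows
    n_lines = config.n_lines
    ploidies = list(config.ploidies)
    states = np.tile(np.array(ploidies)[:, None], (1, n_windows)).astype(np.int64)

    x_index = layout.arm_names.index("chrX")
    autosome_indices = [i for i in range(len(layout.arm_names)) if i != x_index]

    if config.sexes is None:
        sexes = ["male" if rng.random() < 0.5 else "female" for _ in range(n_lines)]
    else:
        sexes = list(config.sexes)

    # Private segments first; drivers afterwards overwrite, so planted
    # driver coordinates are exact in every carrier.
    all_arm_indices = list(range(len(layout.arm_names)))
    for li in range(n_lines):
        for _ in range(int(rng.poisson(config.private_segment_rate))):
            length = _geometric_length(rng, config.segment_length_mean)
            _, lo, hi = _place_segment(rng, layout, all_arm_indices, length)
            delta = 1 if rng.random() < config.gain_fraction else -1
            states[li, lo:hi] = max(0, ploidies[li] + delta)

    driver_rows = []
    for di in range(config.n_driver_regions):
        # Drivers are planted at >= 8 windows (8 kb). The segmenter's
        # 3-window minimum bounds the caller's resolution, and a masked
        # (low-mappability) window can split a driver into fragments: at
        # 8 windows at least one fragment always stays above the minimum,
        # so a planted driver is recoverable by construction. Recurrent
        # driver regions of interest in this kind of data are themselves
        # tens of kb.
        length = max(8, _geometric_length(rng, config.segment_length_mean))
        ai, lo, hi = _place_segment(rng, layout, autosome_indices, length)
        delta = 1 if rng.random() < config.gain_fraction else -1
        while True:
            carriers = np.flatnonzero(rng.random(n_lines) < config.driver_penetrance)
            if carriers.size >= 2:
                break
        off = int(layout.arm_offsets[ai])
        arm_hi = off + int(layout.arm_n_windows[ai])
        for li in carriers:
            lo_c, hi_c = lo, hi
            if config.driver_edge_jitter > 0:
                # Line-specific endpoints wobble around the shared core:
                # the same selected region, reached through independent
                # rearrangement events with nearby but not identical breaks.
                j = config.driver_edge_jitter
                lo_c = max(off, lo + int(rng.integers(-j, j + 1)))
                hi_c = min(arm_hi, hi + int(rng.integers(-j, j + 1)))
                if hi_c - lo_c < 3:
                    lo_c, hi_c = lo, hi
            states[li, lo_c:hi_c] = max(0, ploidies[li] + delta)
        driver_rows.append(
            {
                "driver": f"driver{di}",
                "arm": layout.arm_names[ai],
                "start": int(layout.window_starts[lo]),
                "end": int(layout.window_ends[hi - 1]),
                "window_lo": lo,
                "window_hi": hi,
                "direction": "gain" if delta > 0 else "loss",
                "carriers": ",".join(str(c) for c in carriers),
            }
        )

    x_sel = layout.arm_windows_mask(["chrX"])
    for li in range(n_lines):
        if sexes[li] == "male":
            states[li, x_sel] = states[li, x_sel] // 2

    genes, baselines = _simulate_gene_models(config, layout)
    truth = SyntheticTruth(
        layout=layout,
        line_names=[f"line{li}" for li in range(n_lines)],
        ploidies=ploidies,
        sexes=sexes,
        states=states,
        drivers=pd.DataFrame(
            driver_rows,
            columns=[
                "driver", "arm", "start", "end",
                "window_lo", "window_hi", "direction", "carriers",
            ],
        ),
        genes=genes,
        gene_baselines=baselines,
    )
    return layout, truth


def _simulate_gene_models(config: SimulationConfig, layout: GenomeLayout):
    rng = config.rng("genes")
    n = config.n_genes
    arm_idx = rng.integers(0, len(layout.arm_names), size=n)
    lengths_bp = rng.integers(1, 6, size=n) * layout.window_size
    rows = []
    for gi in range(n):
        ai = int(arm_idx[gi])
        arm_len = layout.arm_lengths[ai]
        length = int(min(lengths_bp[gi], arm_len))
        start = int(rng.integers(0, arm_len - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append(
            {
                "gene_id": f"g{gi:05d}",
                "arm": layout.arm_names[ai],
                "start": start,
                "end": start + length,
                "strand": strand,
                "tss": start if strand == "+" else start + length - 1,
            }
        )
    baselines = rng.normal(
        config.baseline_log2_fpkm_mean, config.baseline_log2_fpkm_sd, size=n
    )
    return pd.DataFrame(rows), baselines


def default_mask_profiles(config: SimulationConfig, layout: GenomeLayout) -> MaskTrack:
    """Mappability mostly 1.0 with a few poor windows; GC tight around 0.375
    with occasional out-of-range outliers."""
    rng = config.rng("masks")
    n = layout.n_windows
    mappability = (
        np.ones(n)
        if config.mappability_profile is None
        else np.asarray(config.mappability_profile, dtype=float).copy()
    )
    if config.mappability_profile is None:
        low = rng.random(n) < config.low_mappability_fraction
        mappability[low] = rng.uniform(0.3, 0.89, size=int(low.sum()))
    if config.gc_profile is None:
        gc = np.clip(rng.normal(config.gc_optimum, 0.02, size=n), 0.0, 1.0)
        out = rng.random(n) < config.gc_outlier_fraction
        n_out = int(out.sum())
        lo_side = rng.random(n_out) < 0.5
        extremes = np.where(
            lo_side, rng.uniform(0.18, 0.295, n_out), rng.uniform(0.455, 0.6, n_out)
        )
        gc[out] = extremes
    else:
        gc = np.asarray(config.gc_profile, dtype=float).copy()
    return MaskTrack(layout, mappability, gc)


def gc_bias(gc: np.ndarray, optimum: float, width: float) -> np.ndarray:
    """Unimodal multiplicative GC bias, 1.0 at the optimum."""
    return np.exp(-((np.asarray(gc) - optimum) ** 2) / (2 * width**2))


def simulate_window_counts(
    truth: SyntheticTruth, config: SimulationConfig, masks: MaskTrack | None = None
):
    """Overdispersed window read counts for every line.

    Count mean is ``mean_depth x (state / ploidy) x gc_bias x mappability``;
    the noise is negative-binomial with ``var = mu + dispersion * mu^2``
    (``dispersion = 0`` gives the deterministic limit, counts equal to the
    mean). Returns ``(tracks, masks)``; windows are emitted regardless of
    mappability -- flagging them is :func:`cnevolve.tracks.apply_masks`'s job.
    """
    layout = truth.layout
    if masks is None:
        masks = default_mask_profiles(config, layout)
    bias = gc_bias(masks.gc, config.gc_optimum, config.gc_bias_width)
    tracks = []
    for li in range(len(truth.line_names)):
        rng = config.rng("counts", li)
        mu = (
            config.mean_depth
            * truth.states[li]
            / truth.ploidies[li]
            * bias
            * masks.mappability
        )
        if config.dispersion == 0:
            counts = mu.astype(float)
        else:
            size = 1.0 / config.dispersion
            p = size / (size + mu)
            counts = np.where(
                mu > 0, rng.negative_binomial(size, np.where(mu > 0, p, 1.0)), 0.0
            ).astype(float)
        tracks.append(WindowTrack(layout, counts))
    return tracks, masks


def simulate_expression(
    gene_copies: pd.DataFrame,
    config: SimulationConfig,
    ploidy: int,
    baselines: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """FPKM per gene under the planted dose-response exponent.

    ``log2 FPKM = baseline + beta * log2(state / ploidy) + N(0, noise)``;
    zero-copy genes get FPKM 0. Gene order must match the truth gene table
    when per-gene ``baselines`` are supplied.
    """
    if rng is None:
        rng = config.rng("expression")
    n = len(gene_copies)
    if baselines is None:
        baselines = rng.normal(
            config.baseline_log2_fpkm_mean, config.baseline_log2_fpkm_sd, size=n
        )
    states = gene_copies["state"].to_numpy(dtype=float)
    determined = gene_copies["state"].to_numpy() != STATE_UNDETERMINED
    dose = np.zeros(n)
    positive = determined & (states > 0)
    dose[positive] = config.dosage_exponent * np.log2(states[positive] / ploidy)
    noise = (
        rng.normal(0.0, config.expression_noise_sd, size=n)
        if config.expression_noise_sd > 0
        else np.zeros(n)
    )
    log2_fpkm = baselines + dose + noise
    fpkm = np.power(2.0, log2_fpkm)
    fpkm[~positive] = 0.0
    return pd.DataFrame({"gene_id": gene_copies["gene_id"], "FPKM": fpkm})


def simulate_complexes(
    gene_copies: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
):
    """Complex membership with a planted coherent fraction.

    A coherent complex draws its changed members (at least two) from a
    single direction's gene pool and pads with normal-class genes; the
    rest draw members uniformly, so their class composition follows the
    genome background. Returns ``(catalog, truth_flags)`` where
    ``truth_flags`` maps cluster_id -> planted coherence.
    """
    if rng is None:
        rng = config.rng("complexes")
    classes = gene_copies["class"].to_numpy()
    ids = gene_copies["gene_id"].to_numpy()
    pools = {
        CLASS_HIGH: ids[classes == CLASS_HIGH],
        CLASS_LOW: ids[classes == CLASS_LOW],
        CLASS_NORMAL: ids[classes == CLASS_NORMAL],
    }
    rows, flags = [], {}
    for ci in range(config.n_complexes):
        cluster = f"c{ci:04d}"
        size = 3 + int(rng.poisson(max(config.complex_size_mean - 3, 0)))
        coherent = rng.random() < config.coherent_complex_fraction
        if coherent:
            direction = CLASS_HIGH if rng.random() < config.gain_fraction else CLASS_LOW
            if pools[direction].size < 2:
                direction = (
                    CLASS_HIGH if pools[CLASS_HIGH].size >= 2 else CLASS_LOW
                )
            n_changed = min(
                max(2, int(rng.binomial(size, 0.6))), size, int(pools[direction].size)
            )
            if n_changed < 2:
                coherent = False  # not enough changed genes in any direction
        if coherent:
            members = list(rng.choice(pools[direction], size=n_changed, replace=False))
            n_pad = size - n_changed
            if n_pad > 0:
                members += list(
                    rng.choice(pools[CLASS_NORMAL], size=min(n_pad, pools[CLASS_NORMAL].size), replace=False)
                )
        else:
            members = list(rng.choice(ids, size=min(size, ids.size), replace=False))
        flags[cluster] = bool(coherent)
        for g in members:
            rows.append({"cluster_id": cluster, "gene_id": g})
    return pd.DataFrame(rows), flags


def simulate_junctions(
    sex: str,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sex-specific splice-junction coverage (Poisson counts).

    Male samples have inclusion >> exclusion (PSI near 1); female samples
    the reverse. A zero exclusion depth gives the noiseless PSI = 1 limit.
    """
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    if rng is None:
        rng = config.rng("junctions")
    n = config.n_junction_events
    lam_inc = config.junction_inclusion_depth
    lam_exc = config.junction_exclusion_depth
    if sex == "female":
        lam_inc, lam_exc = lam_exc, lam_inc
    inc = rng.poisson(lam_inc, size=n) if lam_inc > 0 else np.zeros(n, dtype=np.int64)
    exc = rng.poisson(lam_exc, size=n) if lam_exc > 0 else np.zeros(n, dtype=np.int64)
    return pd.DataFrame(
        {"event_id": [f"e{i:03d}" for i in range(n)], "inclusion": inc, "exclusion": exc}
    )


@dataclass
class SyntheticDataset:
    """One full synthetic study: truth plus every observable layer."""

    config: SimulationConfig
    layout: GenomeLayout
    truth: SyntheticTruth
    count_tracks: list
    masks: MaskTrack
    expression: list  # per line DataFrame(gene_id, FPKM)
    complexes: pd.DataFrame  # catalog for complex_line
    complex_truth: dict
    complex_line: int
    junctions: list  # per line DataFrame


def simulate_dataset(config: SimulationConfig, complex_line: int = 0) -> SyntheticDataset:
    """Generate the complete study: profiles, counts, expression, complexes,
    junctions. Per-gene expression baselines are shared across lines so
    between-line comparisons see the same gene-specific effects."""
    layout, truth = simulate_genome_and_profiles(config)
    tracks, masks = simulate_window_counts(truth, config)
    expression = []
    for li in range(config.n_lines):
        rng = config.rng("expression", li)
        expression.append(
            simulate_expression(
                truth.gene_copies(li),
                config,
                ploidy=truth.ploidies[li],
                baselines=truth.gene_baselines,
                rng=rng,
            )
        )
    catalog, flags = simulate_complexes(truth.gene_copies(complex_line), config)
    junctions = [
        simulate_junctions(truth.sexes[li], config, config.rng("junctions", li))
        for li in range(config.n_lines)
    ]
    return SyntheticDataset(
        config=config,
        layout=layout,
        truth=truth,
        count_tracks=tracks,
        masks=masks,
        expression=expression,
        complexes=catalog,
        complex_truth=flags,
        complex_line=complex_line,
        junctions=junctions,
    )
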