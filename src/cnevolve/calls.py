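"""Integer copy-state calling from normalized density tracks.

A normalized ratio track is partitioned into segments (maximal runs of
windows whose median densities differ by at least half a copy unit),
each window inherits its segment median, and medians are converted to
integer copy states on the line's ploidy baseline. Gene-level states are
taken at the transcription start site, with genes touching any
undetermined window left uncalled.

The segmenter here is a deliberately simple, deterministic greedy merge;
the scientific content of the pipeline sits downstream of segmentation,
and a transparent stand-in with configurable thresholds is preferred over
re-implementing a penalized-regression segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ploidy import PloidyEstimate, _round_half_away
from .tracks import GenomeLayout, WindowTrack

__all__ = [
    "STATE_UNDETERMINED",
    "CLASS_HIGH",
    "CLASS_NORMAL",
    "CLASS_LOW",
    "CLASS_UNDETERMINED",
    "Segment",
    "CopyNumberProfile",
    "segment_track",
    "assign_copy_states",
    "gene_copy_numbers",
    "profile_agreement",
    "cnv_summary",
]

STATE_UNDETERMINED = -1
CLASS_HIGH = "high"
CLASS_NORMAL = "normal"
CLASS_LOW = "low"
CLASS_UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class Segment:
    """Maximal run of windows sharing a density level on one arm."""

    arm: str
    start: int  # bp, half-open
    end: int
    median: float
    n_windows: int
    window_lo: int  # global window index range [lo, hi)
    window_hi: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CopyNumberProfile:
    """Per-window integer copy states for one line.

    ``states`` holds integers >= 0, or ``STATE_UNDETERMINED`` (-1) for
    masked windows. Class is derived: high above the baseline ploidy, low
    below, normal at it.
    """

    layout: GenomeLayout
    states: np.ndarray
    baseline_ploidy: int

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.shape != (self.layout.n_windows,):
            raise ValueError("states must have one entry per window")
        if self.baseline_ploidy < 1:
            raise ValueError("baseline_ploidy must be >= 1")

    @property
    def determined(self) -> np.ndarray:
        return self.states != STATE_UNDETERMINED

    @property
    def classes(self) -> np.ndarray:
        out = np.full(self.states.shape, CLASS_UNDETERMINED, dtype=object)
        det = self.determined
        out[det & (self.states > self.baseline_ploidy)] = CLASS_HIGH
        out[det & (self.states == self.baseline_ploidy)] = CLASS_NORMAL
        out[det & (self.states < self.baseline_ploidy)] = CLASS_LOW
        return out

    def to_frame(self) -> pd.DataFrame:
        """5-column per-window call table (chrom, start, end, state, class)."""
        tab = self.layout.window_table()
        tab["state"] = self.states
        tab["class"] = self.classes
        return tab


def _runs(mask: np.ndarray):
    """Yield (lo, hi) index ranges of maximal True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    splits = np.flatnonzero(np.diff(idx) > 1)
    lo = 0
    for s in list(splits) + [idx.size - 1]:
        yield int(idx[lo]), int(idx[s]) + 1
        lo = s + 1


def _greedy_segments(values: np.ndarray, threshold: float, min_windows: int):
    """Partition one unmasked run into segments of near-constant median.

    Left-to-right greedy growth (a window extends the current segment when
    it stays within ``threshold`` of the running median), followed by
    absorption of segments shorter than ``min_windows`` into the
    neighbouring segment with the closer median, and a final merge of
    adjacent segments whose medians differ by less than ``threshold``.
    Returns a list of (lo, hi) offsets within the run.
    """
    n = values.size
    bounds = []
    lo = 0
    for i in range(1, n):
        if abs(values[i] - np.median(values[lo:i])) >= threshold:
            bounds.append((lo, i))
            lo = i
    bounds.append((lo, n))

    def medians(bs):
        return [float(np.median(values[a:b])) for a, b in bs]

    # Absorb short segments (shortest first, deterministic tie-break on index).
    changed = True
    while changed and len(bounds) > 1:
        changed = False
        meds = medians(bounds)
        sizes = [b - a for a, b in bounds]
        order = sorted(range(len(bounds)), key=lambda k: (sizes[k], k))
        for k in order:
            if sizes[k] >= min_windows:
                continue
            left = k - 1 if k > 0 else None
            right = k + 1 if k + 1 < len(bounds) else None
            if left is None and right is None:
                continue
            if right is None or (
                left is not None
                and abs(meds[k] - meds[left]) <= abs(meds[k] - meds[right])
            ):
                tgt = left
            else:
                tgt = right
            a = min(bounds[k][0], bounds[tgt][0])
            b = max(bounds[k][1], bounds[tgt][1])
            bounds[min(k, tgt)] = (a, b)
            del bounds[max(k, tgt)]
            changed = True
            break

    # Merge adjacent segments whose medians are within the threshold.
    changed = True
    while changed and len(bounds) > 1:
        changed = False
        meds = medians(bounds)
        for k in range(len(bounds) - 1):
            if abs(meds[k + 1] - meds[k]) < threshold:
                bounds[k] = (bounds[k][0], bounds[k + 1][1])
                del bounds[k + 1]
                changed = True
                break
    return bounds


def segment_track(
    ratio_track: WindowTrack,
    baseline_ploidy: int = 2,
    min_segment_windows: int = 3,
    threshold: float | None = None,
):
    """Partition a normalized track into constant-level segments.

    Masked windows break segments (no bridging across unmappable gaps).
    Adjacent segment medians differ by at least half a copy unit
    (``0.5 / baseline_ploidy`` in ratio units) unless ``threshold``
    overrides that. Returns ``(segments, segmented_track)`` where the
    track carries each window's segment median (masked windows keep their
    original values). Re-segmenting the segmented track reproduces the
    same boundaries.
    """
    if threshold is None:
        threshold = 0.5 / baseline_ploidy
    layout = ratio_track.layout
    seg_values = ratio_track.values.copy()
    segments = []
    unmasked = ~ratio_track.masked
    arm_idx = layout.window_arm_index
    starts, ends = layout.window_starts, layout.window_ends
    for ai, arm in enumerate(layout.arm_names):
        sel = unmasked & (arm_idx == ai)
        for lo, hi in _runs(sel):
            vals = ratio_track.values[lo:hi]
            for a, b in _greedy_segments(vals, threshold, min_segment_windows):
                med = float(np.median(vals[a:b]))
                seg_values[lo + a : lo + b] = med
                segments.append(
                    Segment(
                        arm=arm,
                        start=int(starts[lo + a]),
                        end=int(ends[lo + b - 1]),
                        median=med,
                        n_windows=b - a,
                        window_lo=lo + a,
                        window_hi=lo + b,
                    )
                )
    segmented = WindowTrack(layout, seg_values, ratio_track.mask_reason.copy())
    return segments, segmented


def assign_copy_states(
    segmented_track: WindowTrack,
    ploidy: int | PloidyEstimate,
    baseline_peak: float | None = None,
) -> CopyNumberProfile:
    """Convert segment medians to integer copy states.

    ``state = round(median * ploidy / baseline_peak)``, with ties at half a
    copy rounded away from zero. Accepts a :class:`PloidyEstimate` (using
    its baseline peak) or a bare integer ploidy with ``baseline_peak``
    defaulting to 1.0. States are scale invariant under joint rescaling of
    the ratios and the baseline peak. Masked windows become undetermined.
    """
    if isinstance(ploidy, PloidyEstimate):
        n = ploidy.minimal_ploidy
        base = ploidy.baseline_peak if baseline_peak is None else baseline_peak
    else:
        n = int(ploidy)
        base = 1.0 if baseline_peak is None else baseline_peak
    if n < 1:
        raise ValueError("ploidy must be >= 1")
    if base <= 0:
        raise ValueError("baseline_peak must be positive")
    vals = segmented_track.values
    ok = ~segmented_track.masked
    if (vals[ok] < 0).any():
        raise ValueError("negative segment medians")
    states = np.full(vals.shape, STATE_UNDETERMINED, dtype=np.int64)
    scaled = vals[ok] * n / base
    states[ok] = np.floor(scaled + 0.5).astype(np.int64)  # half away from zero (>=0)
    return CopyNumberProfile(segmented_track.layout, states, n)


def gene_copy_numbers(profile: CopyNumberProfile, genes: pd.DataFrame) -> pd.DataFrame:
    """Per-gene copy state from the window containing the TSS.

    ``genes`` needs columns ``gene_id``, ``arm``, ``start``, ``end``,
    ``tss``, ``strand``. A gene overlapping *any* undetermined window is
    itself undetermined. Raises ``KeyError`` for genes on unknown arms.
    """
    layout = profile.layout
    states, classes = [], []
    prof_classes = profile.classes
    for row in genes.itertuples(index=False):
        widx = layout.windows_in_interval(row.arm, int(row.start), int(row.end))
        tss_w = layout.window_index(row.arm, int(row.tss))
        if widx.size and (profile.states[widx] == STATE_UNDETERMINED).any():
            states.append(STATE_UNDETERMINED)
            classes.append(CLASS_UNDETERMINED)
        else:
            states.append(int(profile.states[tss_w]))
            classes.append(prof_classes[tss_w])
    out = genes.copy()
    out["state"] = states
    out["class"] = classes
    return out


def exclude_arms(profile: CopyNumberProfile, arms) -> CopyNumberProfile:
    """Copy of a profile with all windows on the given arms undetermined.

    Used to drop the X from cross-line recurrence statistics: a male
    line's halved X is a sex difference, not an acquired copy change, and
    would otherwise appear as a genome-scale recurrent loss.
    """
    states = profile.states.copy()
    states[profile.layout.arm_windows_mask(list(arms))] = STATE_UNDETERMINED
    return CopyNumberProfile(profile.layout, states, profile.baseline_ploidy)


def profile_agreement(a: CopyNumberProfile, b: CopyNumberProfile) -> float:
    """Fraction of windows, determined in both profiles, with equal state."""
    if a.layout != b.layout:
        raise ValueError("profiles have different layouts")
    both = a.determined & b.determined
    if not both.any():
        raise ValueError("no window determined in both profiles")
    return float((a.states[both] == b.states[both]).mean())


def _class_runs(classes: np.ndarray, arm_idx: np.ndarray, target: str):
    """(lo, hi) window runs of one class, not crossing arm boundaries."""
    sel = classes == target
    for lo, hi in _runs(sel):
        # split runs that straddle an arm boundary
        cut = lo
        for i in range(lo + 1, hi):
            if arm_idx[i] != arm_idx[cut]:
                yield cut, i
                cut = i
        yield cut, hi


def cnv_summary(profiles, names=None) -> pd.DataFrame:
    """Genome-wide copy-change summary per line, plus a pooled row.

    For each profile: number of contiguous high/low blocks, genome
    fraction per class (over all windows, so the four class fractions sum
    to 1), and the median and 95th-percentile block length (bp) per
    changed class.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    if names is None:
        names = [f"line{i}" for i in range(len(profiles))]
    rows = []
    pooled = {CLASS_HIGH: [], CLASS_LOW: []}
    for name, prof in zip(names, profiles):
        layout = prof.layout
        sizes = (layout.window_ends - layout.window_starts).astype(float)
        total = sizes.sum()
        classes = prof.classes
        row = {"line": name}
        for cls in (CLASS_HIGH, CLASS_NORMAL, CLASS_LOW, CLASS_UNDETERMINED):
            row[f"fraction_{cls}"] = float(sizes[classes == cls].sum() / total)
        for cls in (CLASS_HIGH, CLASS_LOW):
            lengths = [
                float(sizes[lo:hi].sum())
                for lo, hi in _class_runs(classes, layout.window_arm_index, cls)
            ]
            pooled[cls].extend(lengths)
            row[f"n_segments_{cls}"] = len(lengths)
            row[f"median_length_{cls}"] = float(np.median(lengths)) if lengths else 0.0
            row[f"p95_length_{cls}"] = (
                float(np.percentile(lengths, 95)) if lengths else 0.0
            )
        rows.append(row)
    pooled_row = {"line": "pooled"}
    for cls in (CLASS_HIGH, CLASS_NORMAL, CLASS_LOW, CLASS_UNDETERMINED):
        pooled_row[f"fraction_{cls}"] = float(
            np.mean([r[f"fraction_{cls}"] for r in rows])
        )
    for cls in (CLASS_HIGH, CLASS_LOW):
        lengths = pooled[cls]
        pooled_row[f"n_segments_{cls}"] = len(lengths)
        pooled_row[f"median_length_{cls}"] = float(np.median(lengths)) if lengths else 0.0
        pooled_row[f"p95_length_{cls}"] = (
            float(np.percentile(lengths, 95)) if lengths else 0.0
        )
    return pd.DataFrame(rows + [pooled_row])
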