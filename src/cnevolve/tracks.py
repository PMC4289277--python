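"""Genome layout, window arithmetic, masking and track normalization.

All coordinates are 0-based half-open (BED convention). A genome is an
ordered set of chromosome arms tiled by fixed-size windows (default 1 kb);
the last window of an arm may be short. Per-window values (read counts or
density ratios) live in :class:`WindowTrack` objects alongside a mask that
records *why* a window is excluded from statistics (low mappability, GC
content out of range, user request, or a short terminal window).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MASK_NONE",
    "MASK_LOW_MAPPABILITY",
    "MASK_GC_OUT_OF_RANGE",
    "MASK_USER",
    "MASK_SHORT_WINDOW",
    "MASK_REASON_NAMES",
    "GenomeLayout",
    "WindowTrack",
    "MaskTrack",
    "bin_positions",
    "apply_masks",
    "normalize_track",
]

# Mask reason codes. 0 means the window participates in all statistics.
MASK_NONE = 0
MASK_LOW_MAPPABILITY = 1
MASK_GC_OUT_OF_RANGE = 2
MASK_USER = 3
MASK_SHORT_WINDOW = 4

MASK_REASON_NAMES = {
    MASK_NONE: "none",
    MASK_LOW_MAPPABILITY: "low_mappability",
    MASK_GC_OUT_OF_RANGE: "gc_out_of_range",
    MASK_USER: "user",
    MASK_SHORT_WINDOW: "short_window",
}


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome arms tiled by fixed-size windows.

    Parameters
    ----------
    arm_names
        Arm names in genome order (e.g. ``("chr2L", "chr2R", "chrX")``).
    arm_lengths
        Arm lengths in bp, parallel to ``arm_names``.
    window_size
        Window size in bp (default 1000).
    """

    arm_names: tuple
    arm_lengths: tuple
    window_size: int = 1000

    def __post_init__(self):
        if len(self.arm_names) != len(self.arm_lengths):
            raise ValueError("arm_names and arm_lengths must have equal length")
        if len(set(self.arm_names)) != len(self.arm_names):
            raise ValueError("duplicate arm names")
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if any(l <= 0 for l in self.arm_lengths):
            raise ValueError("arm lengths must be positive")
        object.__setattr__(self, "arm_names", tuple(self.arm_names))
        object.__setattr__(self, "arm_lengths", tuple(int(l) for l in self.arm_lengths))

    # -- derived geometry (computed once, cached on the instance) ----------
    @property
    def arm_n_windows(self) -> np.ndarray:
        """Number of windows per arm: ceil(arm_length / window_size)."""
        return -(-np.asarray(self.arm_lengths) // self.window_size)

    @property
    def n_windows(self) -> int:
        return int(self.arm_n_windows.sum())

    @property
    def arm_offsets(self) -> np.ndarray:
        """Index of the first window of each arm."""
        return np.concatenate([[0], np.cumsum(self.arm_n_windows)[:-1]])

    @property
    def window_arm_index(self) -> np.ndarray:
        """Per-window arm index."""
        return np.repeat(np.arange(len(self.arm_names)), self.arm_n_windows)

    @property
    def window_starts(self) -> np.ndarray:
        """Per-window start position (bp, within its arm)."""
        parts = [
            np.arange(n, dtype=np.int64) * self.window_size for n in self.arm_n_windows
        ]
        return np.concatenate(parts)

    @property
    def window_ends(self) -> np.ndarray:
        """Per-window end position, clipped at the arm end (last may be short)."""
        ends = self.window_starts + self.window_size
        lengths = np.asarray(self.arm_lengths)[self.window_arm_index]
        return np.minimum(ends, lengths)

    def arm_slice(self, arm: str) -> slice:
        """Window-index slice covering one arm."""
        i = self._arm_index(arm)
        off = self.arm_offsets
        n = self.arm_n_windows
        return slice(int(off[i]), int(off[i] + n[i]))

    def _arm_index(self, arm: str) -> int:
        try:
            return self.arm_names.index(arm)
        except ValueError:
            raise KeyError(f"unknown arm: {arm!r}") from None

    def window_index(self, arm: str, bp: int) -> int:
        """Global window index containing position ``bp`` on ``arm``."""
        i = self._arm_index(arm)
        if not 0 <= bp < self.arm_lengths[i]:
            raise ValueError(f"position {bp} outside arm {arm!r}")
        return int(self.arm_offsets[i] + bp // self.window_size)

    def windows_in_interval(self, arm: str, start: int, end: int) -> np.ndarray:
        """Global indices of windows overlapping half-open interval [start, end)."""
        i = self._arm_index(arm)
        if end <= start:
            return np.empty(0, dtype=np.int64)
        lo = max(0, start // self.window_size)
        hi = min(int(self.arm_n_windows[i]), -(-end // self.window_size))
        return np.arange(self.arm_offsets[i] + lo, self.arm_offsets[i] + hi)

    def window_table(self) -> pd.DataFrame:
        """BED-like table of all windows (chrom, start, end)."""
        return pd.DataFrame(
            {
                "chrom": np.asarray(self.arm_names)[self.window_arm_index],
                "start": self.window_starts,
                "end": self.window_ends,
            }
        )

    def arm_windows_mask(self, arms: Sequence[str]) -> np.ndarray:
        """Boolean selector for windows on any of the given arms."""
        idx = [self._arm_index(a) for a in arms]
        return np.isin(self.window_arm_index, idx)


@dataclass
class WindowTrack:
    """Per-window values over a :class:`GenomeLayout`, with mask reasons.

    ``values`` holds counts or density ratios; ``mask_reason`` holds one of
    the MASK_* codes. Masked windows keep their values but are excluded
    from every statistic computed downstream.
    """

    layout: GenomeLayout
    values: np.ndarray
    mask_reason: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.layout.n_windows,):
            raise ValueError(
                f"values shape {self.values.shape} != ({self.layout.n_windows},)"
            )
        if self.mask_reason is None:
            self.mask_reason = np.zeros(self.layout.n_windows, dtype=np.uint8)
        else:
            self.mask_reason = np.asarray(self.mask_reason, dtype=np.uint8)
            if self.mask_reason.shape != self.values.shape:
                raise ValueError("mask_reason shape mismatch")

    @property
    def masked(self) -> np.ndarray:
        return self.mask_reason != MASK_NONE

    @property
    def unmasked_values(self) -> np.ndarray:
        return self.values[~self.masked]

    def copy(self) -> "WindowTrack":
        return WindowTrack(self.layout, self.values.copy(), self.mask_reason.copy())


@dataclass
class MaskTrack:
    """Per-window mappability and GC fractions, both in [0, 1]."""

    layout: GenomeLayout
    mappability: np.ndarray
    gc: np.ndarray

    def __post_init__(self):
        self.mappability = np.asarray(self.mappability, dtype=float)
        self.gc = np.asarray(self.gc, dtype=float)
        n = self.layout.n_windows
        if self.mappability.shape != (n,) or self.gc.shape != (n,):
            raise ValueError("mask track arrays must have one entry per window")
        for name, arr in (("mappability", self.mappability), ("gc", self.gc)):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"{name} fractions must lie in [0, 1]")


def bin_positions(positions: Iterable, layout: GenomeLayout) -> WindowTrack:
    """Count (arm, bp) positions per window.

    Raises ``KeyError`` naming the arm if a position falls on an unknown arm.
    """
    counts = np.zeros(layout.n_windows, dtype=float)
    for arm, bp in positions:
        counts[layout.window_index(arm, int(bp))] += 1
    return WindowTrack(layout, counts)


def apply_masks(
    track: WindowTrack,
    mask_track: MaskTrack,
    mappability_min: float = 0.9,
    gc_range: tuple = (0.30, 0.45),
    flag_short_windows: bool = True,
) -> WindowTrack:
    """Flag windows failing mappability or GC criteria.

    A window is masked as ``low_mappability`` when its mappability is strictly
    below ``mappability_min`` and as ``gc_out_of_range`` when its GC fraction
    falls outside the *inclusive* ``gc_range`` bounds. Terminal windows
    shorter than half the window size are flagged ``short_window`` so edge
    effects stay out of density histograms. Values are retained; existing
    mask reasons are preserved (first reason wins).
    """
    if track.layout is not mask_track.layout and track.layout != mask_track.layout:
        raise ValueError("track and mask_track layouts differ")
    out = track.copy()
    fresh = out.mask_reason == MASK_NONE
    low_map = mask_track.mappability < mappability_min
    out.mask_reason[fresh & low_map] = MASK_LOW_MAPPABILITY
    fresh = out.mask_reason == MASK_NONE
    gc_bad = (mask_track.gc < gc_range[0]) | (mask_track.gc > gc_range[1])
    out.mask_reason[fresh & gc_bad] = MASK_GC_OUT_OF_RANGE
    if flag_short_windows:
        fresh = out.mask_reason == MASK_NONE
        short = (
            track.layout.window_ends - track.layout.window_starts
        ) < track.layout.window_size / 2
        out.mask_reason[fresh & short] = MASK_SHORT_WINDOW
    return out


def normalize_track(
    track: WindowTrack,
    min_separation: float = 0.167,
    min_peak_windows: int | None = None,
    anchor_selector: np.ndarray | None = None,
) -> WindowTrack:
    """Scale a count track so the modal density peak sits at 1.0.

    The anchor is the center of the largest cluster found by 1-D
    average-linkage peak clustering (:func:`cnevolve.ploidy.cluster_density_peaks`)
    of the unmasked values -- not the global mean, which would drift with the
    copy-number burden of the line. The operation is scale invariant.

    Parameters
    ----------
    min_peak_windows
        Minimum windows backing the anchor peak. ``None`` scales with the
        data: 0.5% of unmasked windows, floored at 50 and capped at 500
        (the fixed 500-window rule appropriate for full-genome 1 kb tracks).
    anchor_selector
        Optional boolean selector restricting which windows the anchor peak
        is estimated from (e.g. autosomal windows only, so a halved male X
        cannot become the modal peak). All windows are rescaled regardless.
    """
    from .ploidy import cluster_density_peaks  # local import avoids cycle at import time

    keep = ~track.masked
    if anchor_selector is not None:
        keep = keep & np.asarray(anchor_selector, dtype=bool)
    vals = track.values[keep]
    if vals.size == 0:
        raise ValueError("cannot normalize: all windows masked")
    med = np.median(vals)
    if med <= 0:
        raise ValueError("cannot normalize: non-positive median value")
    if min_peak_windows is None:
        min_peak_windows = int(min(500, max(50, round(0.005 * vals.size))))
        min_peak_windows = min(min_peak_windows, vals.size)
    provisional = vals / med
    peaks = cluster_density_peaks(
        provisional, min_separation=min_separation, min_windows=min_peak_windows
    )
    anchor = med * peaks.centers[int(np.argmax(peaks.counts))]
    return WindowTrack(track.layout, track.values / anchor, track.mask_reason.copy())
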