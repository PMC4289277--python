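"""Copy-state discontinuities and cross-line breakpoint hotspots.

A breakpoint is a transition between consecutive determined windows on one
arm whose copy states differ; it is assigned to the window on the left of
the transition (a fixed convention so breakpoints from different lines can
be matched window-to-window). A hotspot is a window where at least
``min_lines`` lines break; its excess over chance is assessed by a
permutation test that relocates each line's breakpoints uniformly over the
eligible (unmasked) windows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calls import STATE_UNDETERMINED, CopyNumberProfile

__all__ = [
    "detect_breakpoints",
    "hotspot_counts",
    "hotspot_permutation_test",
    "annotate_breakpoints",
]


def detect_breakpoints(profile: CopyNumberProfile) -> np.ndarray:
    """Window indices carrying a copy-state break in one line.

    Consecutive determined windows on the same arm are compared; masked
    runs are skipped, so a state change across an unmappable gap is
    recorded once, at the last determined window before the gap.
    """
    layout = profile.layout
    arm_idx = layout.window_arm_index
    det = profile.determined
    out = []
    for ai in range(len(layout.arm_names)):
        widx = np.flatnonzero(det & (arm_idx == ai))
        if widx.size < 2:
            continue
        st = profile.states[widx]
        change = np.flatnonzero(np.diff(st) != 0)
        out.extend(widx[change])  # left window of each transition
    return np.array(sorted(out), dtype=np.int64)


def hotspot_counts(tables, n_windows: int) -> np.ndarray:
    """Per-window count of distinct lines with a breakpoint there."""
    counts = np.zeros(n_windows, dtype=np.int64)
    for bp in tables:
        counts[np.unique(bp)] += 1
    return counts


def hotspot_permutation_test(
    tables,
    eligible: np.ndarray,
    min_lines: int = 5,
    n_perm: int = 10_000,
    seed: int = 0,
):
    """Count breakpoint hotspots and test the count against a uniform null.

    Null: each line's breakpoints are relocated uniformly (without
    replacement within the line) over the eligible windows; the global p
    is ``(1 + #permutations with >= observed hotspots) / (1 + n_perm)``.
    Returns ``(n_hotspots, p)``.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 lines")
    eligible = np.asarray(eligible, dtype=bool)
    elig_idx = np.flatnonzero(eligible)
    n_windows = eligible.size
    observed = int((hotspot_counts(tables, n_windows) >= min_lines).sum())
    m = [int(np.unique(bp).size) for bp in tables]
    if elig_idx.size == 0 or max(m, default=0) > elig_idx.size:
        raise ValueError("not enough eligible windows for relocation")
    rng = np.random.default_rng(seed)
    tail = 0
    block = max(1, min(n_perm, int(2e7 // max(1, elig_idx.size))))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        counts = np.zeros((b, n_windows), dtype=np.int16)
        for mi in m:
            if mi == 0:
                continue
            r = rng.random((b, elig_idx.size))
            pick = np.argpartition(r, mi - 1, axis=1)[:, :mi]
            rows = np.repeat(np.arange(b), mi)
            counts[rows, elig_idx[pick.ravel()]] += 1
        tail += int(((counts >= min_lines).sum(axis=1) >= observed).sum())
        done += b
    p = (1.0 + tail) / (1.0 + n_perm)
    return observed, float(p)


def annotate_breakpoints(
    boundaries: np.ndarray,
    layout,
    annotation: pd.DataFrame,
    flank_windows: int = 1,
) -> pd.DataFrame:
    """Flag breakpoints overlapping annotation intervals within +-1 window.

    ``annotation`` needs columns ``arm``, ``start``, ``end`` and
    ``feature`` (e.g. repeat class); strand is ignored. A breakpoint in
    window *w* is flagged for a feature class when any interval of that
    class overlaps the span of windows ``w - flank_windows`` through
    ``w + flank_windows``. Returns one row per breakpoint with one boolean
    column per feature class.
    """
    required = {"arm", "start", "end", "feature"}
    if not required.issubset(annotation.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    if (annotation["end"] <= annotation["start"]).any():
        raise ValueError("malformed annotation intervals (end <= start)")
    boundaries = np.asarray(boundaries, dtype=np.int64)
    arm_idx = layout.window_arm_index
    starts, ends = layout.window_starts, layout.window_ends
    features = sorted(annotation["feature"].unique())
    by_arm_feature = {
        key: grp[["start", "end"]].to_numpy()
        for key, grp in annotation.groupby(["arm", "feature"])
    }
    rows = []
    for w in boundaries:
        ai = int(arm_idx[w])
        arm = layout.arm_names[ai]
        lo_w = max(w - flank_windows, int(layout.arm_offsets[ai]))
        hi_w = min(
            w + flank_windows, int(layout.arm_offsets[ai] + layout.arm_n_windows[ai] - 1)
        )
        span = (int(starts[lo_w]), int(ends[hi_w]))
        row = {"window": int(w), "arm": arm, "start": int(starts[w]), "end": int(ends[w])}
        for feat in features:
            ivals = by_arm_feature.get((arm, feat))
            row[feat] = bool(
                ivals is not None
                and ((ivals[:, 0] < span[1]) & (ivals[:, 1] > span[0])).any()
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=["window", "arm", "start", "end", *features])
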