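"""Cross-line recurrence statistics for copy-number change.

For every window, count how many lines gained (class high) or lost (class
low) copy number, and ask whether that recurrence exceeds what independent,
line-wise random placement of the same number of changed windows would
produce. Two equivalent null computations are provided:

* ``shuffle`` -- Monte-Carlo: each permutation independently shuffles every
  line's per-window class labels over that line's determined windows
  (preserving its class counts), with the +1 pseudocount estimator.
* ``exact`` -- the closed-form equivalent under per-window label
  exchangeability: the count of changed lines at a window is a sum of
  independent Bernoulli draws with each line's genome-wide change
  frequency (a Poisson-binomial tail), evaluated exactly by convolution.

Per-window p-values are Benjamini-Hochberg adjusted, significant windows
merged into regions, and region-level p-values combined with Stouffer's
method. Gains and losses are tested separately (one-sided), matching the
separate reporting of recurrent high and low regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .calls import CLASS_HIGH, CLASS_LOW, CopyNumberProfile

__all__ = [
    "PermutationConfig",
    "recurrence_counts",
    "permutation_null",
    "bh_adjust",
    "stouffer_combine",
    "merge_significant_regions",
    "fisher_enrichment",
]


@dataclass(frozen=True)
class PermutationConfig:
    n_permutations: int = 1_000_000
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def _direction_masks(profiles, direction: str):
    """Per-line boolean arrays: changed-in-direction and determined."""
    target = {"gain": CLASS_HIGH, "loss": CLASS_LOW}[direction]
    changed, determined = [], []
    for p in profiles:
        cls = p.classes
        determined.append(p.determined)
        changed.append(cls == target)
    return np.array(changed), np.array(determined)


def recurrence_counts(profiles):
    """Per-window counts of lines with gained / lost copy number.

    Windows undetermined in a line do not contribute to that line's counts.
    Returns ``(k_gain, k_loss)`` integer arrays.
    """
    gain, _ = _direction_masks(profiles, "gain")
    loss, _ = _direction_masks(profiles, "loss")
    return gain.sum(axis=0), loss.sum(axis=0)


def _poisson_binomial_sf(k_obs: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """P(K >= k) for K a sum of independent Bernoulli(freqs), per window."""
    pmf = np.array([1.0])
    for f in freqs:
        pmf = np.convolve(pmf, [1 - f, f])
    sf = np.concatenate([np.cumsum(pmf[::-1])[::-1], [0.0]])  # sf[k] = P(K >= k)
    sf = np.minimum(sf, 1.0)
    return sf[np.clip(k_obs, 0, len(pmf))]


def _exact_pvalues(changed: np.ndarray, determined: np.ndarray, k_obs: np.ndarray):
    n_lines, n_windows = changed.shape
    freqs = np.array(
        [
            changed[i, determined[i]].mean() if determined[i].any() else 0.0
            for i in range(n_lines)
        ]
    )
    p = np.ones(n_windows)
    # Windows sharing the same set of contributing (determined) lines share
    # the same null; group by the determined-pattern column.
    patterns, inverse = np.unique(determined.T, axis=0, return_inverse=True)
    for g, pat in enumerate(patterns):
        sel = inverse == g
        if not pat.any():
            continue
        p[sel] = _poisson_binomial_sf(k_obs[sel], freqs[pat])
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _shuffle_pvalues(changed, determined, k_obs, n_perm, rng):
    n_lines, n_windows = changed.shape
    tail = np.zeros(n_windows, dtype=np.int64)
    det_idx = [np.flatnonzero(determined[i]) for i in range(n_lines)]
    m = [int(changed[i].sum()) for i in range(n_lines)]
    # Vectorized over permutations in blocks to bound memory.
    block = max(1, min(n_perm, int(2e7 // max(1, n_windows))))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        k_perm = np.zeros((b, n_windows), dtype=np.int16)
        for i in range(n_lines):
            if m[i] == 0 or det_idx[i].size == 0:
                continue
            r = rng.random((b, det_idx[i].size))
            pick = np.argpartition(r, m[i] - 1, axis=1)[:, : m[i]]
            rows = np.repeat(np.arange(b), m[i])
            k_perm[rows, det_idx[i][pick.ravel()]] += 1
        tail += (k_perm >= k_obs[None, :]).sum(axis=0)
        done += b
    return (1.0 + tail) / (1.0 + n_perm)


def _rotate_pvalues(changed, determined, k_obs, arm_index, n_perm, rng):
    """Segment-preserving null: circularly shift each line's labels within
    each arm (over that line's determined windows) by a random offset."""
    n_lines, n_windows = changed.shape
    arm_ids = np.unique(arm_index)
    # Per line and arm: positions of determined windows and their labels.
    per_line = []
    for i in range(n_lines):
        entries = []
        for a in arm_ids:
            pos = np.flatnonzero(determined[i] & (arm_index == a))
            if pos.size:
                entries.append((pos, changed[i, pos]))
        per_line.append(entries)
    tail = np.zeros(n_windows, dtype=np.int64)
    for _ in range(n_perm):
        k_perm = np.zeros(n_windows, dtype=np.int16)
        for entries in per_line:
            for pos, labels in entries:
                shift = int(rng.integers(0, pos.size))
                k_perm[pos] += np.roll(labels, shift)
        tail += k_perm >= k_obs
    return (1.0 + tail) / (1.0 + n_perm)


def permutation_null(
    profiles,
    config: PermutationConfig = PermutationConfig(),
    method: str = "exact",
):
    """Per-window one-sided recurrence p-values for gains and losses.

    ``method='shuffle'`` runs the Monte-Carlo label shuffle with the +1
    pseudocount estimator (p is never 0, never above 1); ``method='exact'``
    evaluates the equivalent Poisson-binomial tail in closed form. Both
    assume per-window label exchangeability within a line, which breaks
    spatial autocorrelation: for data with long segments the per-window
    tests are anti-conservative. ``method='rotate'`` is the
    segment-preserving sensitivity analysis -- each line's label vector is
    circularly shifted within each arm, keeping run structure intact.
    The method actually used is recorded in the returned dict.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 lines")
    if method not in ("exact", "shuffle", "rotate"):
        raise ValueError(f"unknown method: {method!r}")
    out = {"method": method}
    rng = np.random.default_rng(config.seed)
    arm_index = profiles[0].layout.window_arm_index
    for direction in ("gain", "loss"):
        changed, determined = _direction_masks(profiles, direction)
        changed = changed & determined
        k_obs = changed.sum(axis=0)
        if method == "exact":
            p = _exact_pvalues(changed, determined, k_obs)
        elif method == "shuffle":
            p = _shuffle_pvalues(changed, determined, k_obs, config.n_permutations, rng)
        else:
            p = _rotate_pvalues(
                changed, determined, k_obs, arm_index, config.n_permutations, rng
            )
        out[f"k_{direction}"] = k_obs
        out[f"p_{direction}"] = p
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def stouffer_combine(pvals, weights=None) -> float:
    """Combine one-sided p-values via Stouffer's Z.

    ``Z = sum(w_i * z_i) / sqrt(sum(w_i^2))`` with ``z_i`` the upper-tail
    normal quantile of each p. Unit weights by default. Degenerate p-values
    at 0 or 1 are clamped into the open interval with a warning.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != p.shape:
        raise ValueError("weights must parallel pvals")
    eps = np.finfo(float).tiny
    if ((p <= 0) | (p >= 1)).any():
        warnings.warn("p-values at 0 or 1 clamped into the open interval")
        p = np.clip(p, eps, 1 - 1e-16)
    z = stats.norm.isf(p)
    Z = float(np.sum(w * z) / np.sqrt(np.sum(w * w)))
    return float(stats.norm.sf(Z))


def merge_significant_regions(
    qvals: np.ndarray,
    pvals: np.ndarray,
    layout,
    masked: np.ndarray | None = None,
    direction: str = "gain",
    alpha: float = 0.05,
    min_report_length: int = 5000,
) -> pd.DataFrame:
    """Merge FDR-significant windows into maximal contiguous regions.

    Masked windows bridge a region (they neither break it nor contribute
    significant windows); region span runs from the first to the last
    significant window. Each region's combined p is the Stouffer
    combination of its member windows' (unadjusted) p-values. Regions are
    annotated with whether they reach ``min_report_length``.
    """
    q = np.asarray(qvals, dtype=float)
    p = np.asarray(pvals, dtype=float)
    if masked is None:
        masked = np.zeros(q.shape, dtype=bool)
    sig = (~masked) & (q < alpha)
    arm_idx = layout.window_arm_index
    starts, ends = layout.window_starts, layout.window_ends
    rows = []
    i, n = 0, q.size
    while i < n:
        if not sig[i]:
            i += 1
            continue
        members = [i]
        j = i + 1
        while j < n and arm_idx[j] == arm_idx[i] and (sig[j] or masked[j]):
            if sig[j]:
                members.append(j)
            j += 1
        members = np.array(members)
        region_start = int(starts[members[0]])
        region_end = int(ends[members[-1]])
        rows.append(
            {
                "arm": layout.arm_names[int(arm_idx[i])],
                "start": region_start,
                "end": region_end,
                "direction": direction,
                "n_windows": int(members.size),
                "combined_p": stouffer_combine(p[members]),
                "length": region_end - region_start,
                "ge_min_length": (region_end - region_start) >= min_report_length,
            }
        )
        i = int(members[-1]) + 1
    return pd.DataFrame(
        rows,
        columns=[
            "arm",
            "start",
            "end",
            "direction",
            "n_windows",
            "combined_p",
            "length",
            "ge_min_length",
        ],
    )


def fisher_enrichment(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    table = np.array([[a, b], [c, d]])
    if (table < 0).any():
        raise ValueError("table entries must be non-negative")
    if table.sum() == 0:
        raise ValueError("all-zero table")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
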