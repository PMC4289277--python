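"""Minimal-ploidy inference from DNA density peak structure.

Relative (ratiometric) DNA-Seq densities cannot reveal absolute ploidy, but
the density ratios of different copy-number segments form fractions over a
common denominator, and the smallest such denominator is the *minimal
ploidy*. Operationally: cluster the per-window density ratios into peaks,
estimate the unit spacing between consecutive copy states, and count how
many units the baseline (modal) peak sits above zero.

Peak clustering is weighted agglomerative average-linkage in one dimension.
For sorted, disjoint 1-D clusters the average pairwise dissimilarity between
two adjacent clusters equals the difference of their means, so the full
agglomeration can be carried out exactly as an adjacent-merge over value
bins, in near-linear time (see docs/methods.md for the argument).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PeakSet", "PloidyEstimate", "cluster_density_peaks", "infer_minimal_ploidy"]


@dataclass(frozen=True)
class PeakSet:
    """Density peaks: strictly increasing centers with window support counts."""

    centers: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        centers = np.asarray(self.centers, dtype=float)
        counts = np.asarray(self.counts, dtype=np.int64)
        if centers.ndim != 1 or centers.shape != counts.shape:
            raise ValueError("centers and counts must be 1-D and parallel")
        if centers.size and (np.diff(centers) <= 0).any():
            raise ValueError("peak centers must be strictly increasing")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return self.centers.size

    @property
    def modal_index(self) -> int:
        """Index of the peak with the largest support; ties break toward 1.0."""
        best = np.flatnonzero(self.counts == self.counts.max())
        if best.size > 1:
            return int(best[np.argmin(np.abs(self.centers[best] - 1.0))])
        return int(best[0])


@dataclass(frozen=True)
class PloidyEstimate:
    """Minimal ploidy call with its supporting peak geometry.

    ``confidence_note`` is ``"clean"`` when every peak sits on the unit-
    spacing ladder, ``"ambiguous"`` when some peak deviates from its nearest
    integer multiple by more than a quarter unit, and ``"indeterminate"``
    when only a single peak exists (no spacing information).
    """

    minimal_ploidy: int
    unit_spacing: float
    baseline_peak: float
    confidence_note: str

    def __post_init__(self):
        if not 1 <= self.minimal_ploidy <= 8:
            raise ValueError("minimal_ploidy must lie in 1..8")
        if self.confidence_note not in ("clean", "ambiguous", "indeterminate"):
            raise ValueError(f"bad confidence_note: {self.confidence_note!r}")


def cluster_density_peaks(
    ratios: np.ndarray,
    min_separation: float = 0.167,
    min_windows: int = 500,
    bin_resolution: float | None = None,
) -> PeakSet:
    """Cluster 1-D density ratios into peaks by average-linkage agglomeration.

    Values are pre-binned at ``bin_resolution`` (default ``min_separation/50``,
    far below the merge threshold, so binning cannot alter the outcome
    materially); bins are then agglomerated, always merging the closest
    adjacent pair, until no two adjacent cluster centers are closer than
    ``min_separation``. Clusters backed by fewer than ``min_windows`` windows
    are dropped. Centers are the means of member values.

    Raises ``ValueError`` when no cluster survives the support filter.
    """
    vals = np.asarray(ratios, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite ratio values to cluster")
    if min_separation <= 0:
        raise ValueError("min_separation must be positive")
    if bin_resolution is None:
        bin_resolution = min_separation / 50.0

    keys = np.round(vals / bin_resolution).astype(np.int64)
    uniq, inv = np.unique(keys, return_inverse=True)
    sums = np.bincount(inv, weights=vals)
    counts = np.bincount(inv).astype(np.int64)

    # Adjacent-merge agglomeration over sorted bins (exact 1-D average linkage).
    sums = list(sums)
    counts = list(counts)
    while len(sums) > 1:
        centers = [s / c for s, c in zip(sums, counts)]
        gaps = np.diff(centers)
        j = int(np.argmin(gaps))
        if gaps[j] >= min_separation:
            break
        sums[j] += sums.pop(j + 1)
        counts[j] += counts.pop(j + 1)

    centers = np.array([s / c for s, c in zip(sums, counts)])
    counts = np.array(counts, dtype=np.int64)
    keep = counts >= min_windows
    if not keep.any():
        raise ValueError(
            f"no density peak backed by >= {min_windows} windows "
            f"(largest cluster: {int(counts.max())})"
        )
    return PeakSet(centers[keep], counts[keep])


def _round_half_away(x: float) -> int:
    """Round half away from zero (np.round would round half to even)."""
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


def infer_minimal_ploidy(peaks: PeakSet, max_ploidy: int = 8) -> PloidyEstimate:
    """Infer minimal ploidy from a peak ladder.

    The unit spacing is the median of adjacent-peak differences -- a
    tolerance-based estimate rather than exact rationalization, which is
    brittle against the small peak-center wobble real density histograms
    show. The baseline is the modal peak; minimal ploidy is the baseline
    expressed in spacing units, capped at ``max_ploidy``. The estimate is
    invariant to rescaling all centers by a positive constant.
    """
    if len(peaks) == 0:
        raise ValueError("empty PeakSet")
    baseline = float(peaks.centers[peaks.modal_index])
    if len(peaks) == 1:
        return PloidyEstimate(1, baseline, baseline, "indeterminate")
    spacing = float(np.median(np.diff(peaks.centers)))
    ploidy = _round_half_away(baseline / spacing)
    ploidy = max(1, min(max_ploidy, ploidy))
    # Ladder check: every peak should sit near an integer multiple of the unit.
    multiples = peaks.centers / spacing
    deviation = np.abs(multiples - np.round(multiples)) * spacing
    note = "ambiguous" if (deviation > spacing / 4).any() else "clean"
    return PloidyEstimate(ploidy, spacing, baseline, note)
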