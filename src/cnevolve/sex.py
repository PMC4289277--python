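"""Sex inference from chromosome coverage ratios and expression markers.

In Drosophila the X:autosome DNA density ratio is ~1 in female-derived
cells and ~0.5 in male-derived cells; 0.75 is the decision boundary. DNA
evidence can be cross-checked against sex-determination markers: FPKM
levels of MSL-complex genes (roX1, roX2, msl-2; male-biased) or tra
(female-biased), and the proportion-spliced-in (PSI) of Sxl/tra splicing
events, where PSI near 1 is male-like splicing and near 0 female-like.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import WindowTrack

__all__ = [
    "SexCall",
    "DEFAULT_MARKER_THRESHOLDS",
    "mean_coverage",
    "coverage_ratio",
    "compute_psi",
    "classify_sex",
    "x_autosome_expression_test",
]

# Marker decision thresholds. ``male_fpkm`` markers vote male when FPKM is at
# least the threshold; ``female_fpkm`` markers vote female at/above theirs;
# ``psi`` markers vote male at PSI >= 0.5. The published calibration uses a
# panel of sexed whole-fly RNA-Seq references that is not shipped here, so
# these fixed cutoffs are a configurable stand-in.
DEFAULT_MARKER_THRESHOLDS = {"male_fpkm": 8.0, "female_fpkm": 3.0, "psi": 0.5}


@dataclass(frozen=True)
class SexCall:
    x_a_ratio: float
    y_a_ratio: float
    dna_sex: str  # male | female | ambiguous
    marker_sex: str  # male | female | ambiguous | not_assessed
    final_sex: str

    def __post_init__(self):
        if self.x_a_ratio < 0 or (not math.isnan(self.y_a_ratio) and self.y_a_ratio < 0):
            raise ValueError("coverage ratios must be non-negative")


def mean_coverage(read_length: float, n_mapped_reads: float, haploid_length: float) -> float:
    """Mean per-bp coverage: read length x mapped reads / haploid length."""
    if haploid_length <= 0:
        raise ValueError("haploid_length must be positive")
    return read_length * n_mapped_reads / haploid_length


def coverage_ratio(
    track: WindowTrack,
    numerator_arms,
    denominator_arms,
    numerator_region: tuple | None = None,
) -> float:
    """Ratio of mean per-window coverage between two disjoint arm sets.

    ``numerator_region`` optionally restricts the numerator to a single
    (arm, start, end) interval -- used for Y:A, where only a short
    repeat-free region of the Y scaffold is trusted.
    """
    num_set, den_set = set(numerator_arms), set(denominator_arms)
    if not num_set or not den_set:
        raise ValueError("both arm sets must be non-empty")
    if num_set & den_set:
        raise ValueError("numerator and denominator arm sets must be disjoint")
    layout = track.layout
    ok = ~track.masked
    if numerator_region is not None:
        arm, start, end = numerator_region
        num_sel = np.zeros(layout.n_windows, dtype=bool)
        num_sel[layout.windows_in_interval(arm, start, end)] = True
    else:
        num_sel = layout.arm_windows_mask(list(num_set))
    den_sel = layout.arm_windows_mask(list(den_set))
    den_vals = track.values[den_sel & ok]
    if den_vals.size == 0 or den_vals.mean() == 0:
        raise ValueError("zero denominator coverage")
    num_vals = track.values[num_sel & ok]
    if num_vals.size == 0:
        return 0.0
    return float(num_vals.mean() / den_vals.mean())


def compute_psi(inclusion_cov: float, exclusion_cov: float) -> float:
    """Proportion spliced in: inclusion / (inclusion + exclusion).

    Both coverages zero yields ``nan`` (a missing value, not 0); negative
    coverage is rejected.
    """
    if inclusion_cov < 0 or exclusion_cov < 0:
        raise ValueError("junction coverages must be non-negative")
    total = inclusion_cov + exclusion_cov
    if total == 0:
        return float("nan")
    return inclusion_cov / total


def _marker_votes(markers: pd.DataFrame, thresholds: dict) -> list:
    votes = []
    for row in markers.itertuples(index=False):
        value = float(row.value)
        if np.isnan(value):
            continue
        kind = row.kind
        if kind == "psi":
            votes.append("male" if value >= thresholds["psi"] else "female")
        elif kind == "male_fpkm":
            votes.append("male" if value >= thresholds["male_fpkm"] else "female")
        elif kind == "female_fpkm":
            votes.append("female" if value >= thresholds["female_fpkm"] else "male")
        else:
            raise ValueError(f"unknown marker kind: {kind!r}")
    return votes


def classify_sex(
    x_a: float,
    y_a: float = float("nan"),
    markers: pd.DataFrame | None = None,
    thresholds: dict | None = None,
) -> SexCall:
    """Call sex from the X:A DNA ratio, optionally checked against markers.

    DNA sex is female for X:A > 0.75, male below, ambiguous at exactly
    0.75. When a marker table (columns ``marker``, ``kind``, ``value``) is
    supplied, each marker votes male/female and the majority wins; the
    final call is the DNA call unless the markers contradict it, in which
    case the line is flagged ambiguous.
    """
    if x_a < 0:
        raise ValueError("x_a must be non-negative")
    if x_a > 0.75:
        dna_sex = "female"
    elif x_a < 0.75:
        dna_sex = "male"
    else:
        dna_sex = "ambiguous"

    if markers is None or len(markers) == 0:
        marker_sex = "not_assessed"
    else:
        votes = _marker_votes(markers, {**DEFAULT_MARKER_THRESHOLDS, **(thresholds or {})})
        n_male = votes.count("male")
        n_female = votes.count("female")
        if n_male > n_female:
            marker_sex = "male"
        elif n_female > n_male:
            marker_sex = "female"
        else:
            marker_sex = "ambiguous"

    if dna_sex == "ambiguous":
        final = "ambiguous"
    elif marker_sex in ("not_assessed", "ambiguous", dna_sex):
        final = dna_sex
    else:
        final = "ambiguous"
    return SexCall(x_a, y_a, dna_sex, marker_sex, final)


def x_autosome_expression_test(
    expression: pd.DataFrame,
    gene_arms: pd.Series | dict,
    x_arms=("chrX",),
    fpkm_min: float = 1.0,
):
    """Two-sample t-test of log2 FPKM: X-linked vs autosomal expressed genes.

    Used to ask whether the X is transcriptionally balanced against the
    autosomes (as it is in male lines with a working MSL/roX system).
    Returns ``(t_statistic, p_value)``.

    Parameters
    ----------
    expression
        Table with ``gene_id`` and ``FPKM`` columns.
    gene_arms
        Mapping gene_id -> arm name.
    """
    arms = pd.Series(gene_arms)
    expressed = expression[expression["FPKM"] > fpkm_min]
    log2 = np.log2(expressed["FPKM"].to_numpy())
    on_x = expressed["gene_id"].map(arms).isin(x_arms).to_numpy()
    x_vals, a_vals = log2[on_x], log2[~on_x]
    if x_vals.size < 2 or a_vals.size < 2:
        raise ValueError("need at least 2 expressed genes per group")
    t, p = stats.ttest_ind(x_vals, a_vals, equal_var=False)
    return float(t), float(p)
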