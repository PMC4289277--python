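"""Expression response to gene dose.

If transcription tracked gene dose one-to-one, a gene at copy state *c* in
a line of ploidy *N* would shift its log2 FPKM by ``log2(c/N)`` relative to
normal-copy genes. The operations here center expression on the
normal-class median, compare each copy state's distribution against that
dose-proportional expectation (Mann-Whitney U on expectation-shifted
normal-class values), and estimate the genome-wide dose-response slope --
1 for proportional response, below 1 for transcriptional buffering, 0 for
full compensation.

Only expressed genes (FPKM above a cutoff, default 1) enter any statistic.
All arithmetic is in log2 space, where the dose offsets are symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calls import CLASS_NORMAL, STATE_UNDETERMINED

__all__ = ["center_by_normal", "dosage_response_test", "dosage_slope", "DosageResult"]


@dataclass
class DosageResult:
    per_state: pd.DataFrame  # state, n, median, expected_offset, U, p, sublinear
    slope: float
    spearman_rho: float
    notes: list


def _expressed(expression: pd.DataFrame, fpkm_min: float) -> pd.DataFrame:
    return expression[expression["FPKM"] > fpkm_min]


def center_by_normal(
    expression: pd.DataFrame,
    gene_copies: pd.DataFrame,
    fpkm_min: float = 1.0,
) -> pd.DataFrame:
    """Center log2 FPKM of expressed genes on the normal-class median.

    Returns a table with ``gene_id``, ``state``, ``class`` and
    ``centered`` (log2 FPKM minus the expressed normal-class median, which
    is 0 by construction for the normal class). Centering is invariant to
    rescaling all FPKM by a constant. Raises when no expressed
    normal-class gene exists.
    """
    merged = _expressed(expression, fpkm_min).merge(
        gene_copies[["gene_id", "state", "class"]], on="gene_id"
    )
    merged = merged[merged["state"] != STATE_UNDETERMINED].copy()
    log2 = np.log2(merged["FPKM"].to_numpy())
    normal = log2[(merged["class"] == CLASS_NORMAL).to_numpy()]
    if normal.size == 0:
        raise ValueError("no expressed normal-class genes to center on")
    merged["centered"] = log2 - np.median(normal)
    return merged[["gene_id", "state", "class", "centered"]]


def dosage_response_test(
    centered: pd.DataFrame,
    ploidy: int,
    min_genes: int = 20,
) -> DosageResult:
    """Per-copy-state comparison against the dose-proportional expectation.

    For each non-normal state *c* with at least ``min_genes`` expressed
    genes, the expected offset is ``log2(c/N)``; a two-sided Mann-Whitney U
    compares the state's centered values against the normal-class values
    shifted by that offset. ``sublinear`` records whether the observed
    median falls short of the expectation (below it for gains, above it
    for losses -- both signatures of buffering). States below ``min_genes``
    are skipped with a notice.
    """
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    normal_vals = centered.loc[centered["class"] == CLASS_NORMAL, "centered"].to_numpy()
    if normal_vals.size == 0:
        raise ValueError("no normal-class genes")
    rows, notes = [], []
    states = sorted(s for s in centered["state"].unique() if s != ploidy and s > 0)
    for c in states:
        vals = centered.loc[centered["state"] == c, "centered"].to_numpy()
        if vals.size < min_genes:
            notes.append(f"state {c}: insufficient n ({vals.size} < {min_genes}); skipped")
            continue
        expected = float(np.log2(c / ploidy))
        u, p = stats.mannwhitneyu(
            vals, normal_vals + expected, alternative="two-sided"
        )
        med = float(np.median(vals))
        sublinear = med < expected if c > ploidy else med > expected
        rows.append(
            {
                "state": int(c),
                "n": int(vals.size),
                "median": med,
                "expected_offset": expected,
                "U": float(u),
                "p": float(p),
                "sublinear": bool(sublinear),
            }
        )
    slope, rho = float("nan"), float("nan")
    if len(centered["state"].unique()) >= 2:
        slope, rho = _slope_from_centered(centered, ploidy)
    per_state = pd.DataFrame(
        rows, columns=["state", "n", "median", "expected_offset", "U", "p", "sublinear"]
    )
    return DosageResult(per_state=per_state, slope=slope, spearman_rho=rho, notes=notes)


def _slope_from_centered(centered: pd.DataFrame, ploidy: int):
    sub = centered[centered["state"] > 0]
    x = np.log2(sub["state"].to_numpy() / ploidy)
    y = sub["centered"].to_numpy()
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 copy states for a slope")
    slope = float(stats.linregress(x, y).slope)
    if np.std(y) == 0:  # fully compensated, noiseless: correlation undefined
        return slope, 0.0
    rho = float(stats.spearmanr(x, y).statistic)
    return slope, rho


def dosage_slope(
    expression: pd.DataFrame,
    gene_copies: pd.DataFrame,
    ploidy: int,
    fpkm_min: float = 1.0,
):
    """Least-squares slope of log2 FPKM on log2(c/N), plus Spearman rho.

    Slope 1 means expression proportional to dose; below 1, buffered;
    0, fully compensated. Raises on degenerate input (a single state).
    """
    centered = center_by_normal(expression, gene_copies, fpkm_min=fpkm_min)
    return _slope_from_centered(centered, ploidy)
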