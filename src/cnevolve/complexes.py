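"""Protein-complex copy-number coherence.

The gene balance hypothesis predicts that when copy number of one complex
member changes, stoichiometry favours co-selected changes of the other
members in the same direction. These operations overlay per-gene copy
classes on complex membership: ternary class composition per complex,
one-sided hypergeometric enrichment against the genome background,
coherence calling (>90% of changed members in one direction, at least two
changed), a physical-proximity filter (complexes with two members within
500 kb on one arm are excluded, since linked passengers would mimic
coherence), and a catalog-level permutation test that reassigns the
genome-wide class multiset to genes without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calls import CLASS_HIGH, CLASS_LOW, CLASS_NORMAL, CLASS_UNDETERMINED

__all__ = [
    "complex_composition",
    "complex_enrichment_test",
    "coherence_flag",
    "proximity_filter",
    "coherence_permutation_test",
    "coherence_report",
]


def complex_composition(classes) -> tuple:
    """Ternary (frac_high, frac_normal, frac_low) over determined members.

    Undetermined members are excluded from the denominator; a complex with
    no determined member raises.
    """
    classes = [c for c in classes if c != CLASS_UNDETERMINED]
    if not classes:
        raise ValueError("all members undetermined")
    n = len(classes)
    return (
        classes.count(CLASS_HIGH) / n,
        classes.count(CLASS_NORMAL) / n,
        classes.count(CLASS_LOW) / n,
    )


def complex_enrichment_test(
    n_in_class: int, complex_size: int, background_in_class: int, universe_size: int
) -> float:
    """One-sided hypergeometric tail for class over-representation.

    Probability of drawing at least ``n_in_class`` members of the class in
    a complex of ``complex_size`` genes sampled without replacement from a
    universe of ``universe_size`` genes of which ``background_in_class``
    carry the class.
    """
    if complex_size > universe_size:
        raise ValueError("complex larger than gene universe")
    if not 0 <= n_in_class <= complex_size:
        raise ValueError("n_in_class outside [0, complex_size]")
    return float(
        stats.hypergeom.sf(n_in_class - 1, universe_size, background_in_class, complex_size)
    )


def coherence_flag(classes, threshold: float = 0.9, min_changed: int = 2) -> bool:
    """True when the changed members overwhelmingly share one direction.

    Requires at least ``min_changed`` changed (high or low) members and
    strictly more than ``threshold`` of them in the majority direction.
    """
    n_high = sum(1 for c in classes if c == CLASS_HIGH)
    n_low = sum(1 for c in classes if c == CLASS_LOW)
    changed = n_high + n_low
    if changed < min_changed:
        return False
    return max(n_high, n_low) / changed > threshold


def proximity_filter(coords, max_distance: int = 500_000) -> bool:
    """True (excluded) when any member pair sits within 500 kb on one arm.

    ``coords`` is an iterable of (arm, tss) pairs; members with missing
    coordinates (arm of None/NaN) are skipped. The distance bound is
    inclusive: a pair at exactly ``max_distance`` excludes the complex.
    """
    by_arm = {}
    for arm, tss in coords:
        if arm is None or (isinstance(arm, float) and np.isnan(arm)):
            continue
        by_arm.setdefault(arm, []).append(int(tss))
    for positions in by_arm.values():
        positions.sort()
        for a, b in zip(positions, positions[1:]):
            if b - a <= max_distance:
                return True
    return False


def coherence_report(
    catalog: pd.DataFrame,
    gene_copies: pd.DataFrame,
    threshold: float = 0.9,
    min_changed: int = 2,
    max_distance: int = 500_000,
) -> pd.DataFrame:
    """Per-complex composition, enrichment, coherence and proximity flags.

    ``catalog`` holds (cluster_id, gene_id) membership; ``gene_copies``
    supplies per-gene ``class`` plus ``arm``/``tss`` coordinates. The
    background for enrichment is the class composition of the determined
    gene universe.
    """
    gene_info = gene_copies.set_index("gene_id")
    universe = gene_info[gene_info["class"] != CLASS_UNDETERMINED]
    universe_size = len(universe)
    background = {
        cls: int((universe["class"] == cls).sum()) for cls in (CLASS_HIGH, CLASS_LOW)
    }
    rows = []
    for cluster_id, grp in catalog.groupby("cluster_id", sort=True):
        members = [g for g in grp["gene_id"] if g in gene_info.index]
        classes = [gene_info.at[g, "class"] for g in members]
        determined = [c for c in classes if c != CLASS_UNDETERMINED]
        row = {"cluster_id": cluster_id, "n_members": len(members), "n_determined": len(determined)}
        if determined:
            fh, fn, fl = complex_composition(classes)
            row.update(frac_high=fh, frac_normal=fn, frac_low=fl)
            row["p_high"] = complex_enrichment_test(
                sum(c == CLASS_HIGH for c in determined),
                len(determined),
                background[CLASS_HIGH],
                universe_size,
            )
            row["p_low"] = complex_enrichment_test(
                sum(c == CLASS_LOW for c in determined),
                len(determined),
                background[CLASS_LOW],
                universe_size,
            )
        else:
            row.update(
                frac_high=np.nan, frac_normal=np.nan, frac_low=np.nan,
                p_high=np.nan, p_low=np.nan,
            )
        row["coherent"] = coherence_flag(classes, threshold, min_changed)
        coords = [
            (gene_info.at[g, "arm"], gene_info.at[g, "tss"])
            for g in members
            if "arm" in gene_info.columns
        ]
        row["proximity_excluded"] = proximity_filter(coords, max_distance) if coords else False
        rows.append(row)
    return pd.DataFrame(rows)


def coherence_permutation_test(
    catalog: pd.DataFrame,
    gene_copies: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    apply_proximity: bool = False,
    threshold: float = 0.9,
    min_changed: int = 2,
    max_distance: int = 500_000,
):
    """Catalog-level test of the coherent-complex count.

    Each permutation reassigns the observed multiset of copy classes to
    the gene universe without replacement (so every permutation preserves
    the genome-wide class counts exactly) and recounts complexes passing
    the coherence flag. Proximity exclusion depends only on coordinates
    and is applied identically to the observed and permuted counts.
    Returns ``(observed_count, p)`` with the +1 pseudocount estimator.
    """
    gene_ids = gene_copies["gene_id"].to_numpy()
    class_arr = gene_copies["class"].to_numpy()
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    clusters = []
    excluded = []
    has_coords = {"arm", "tss"} <= set(gene_copies.columns)
    info = gene_copies.set_index("gene_id") if has_coords else None
    for cluster_id, grp in catalog.groupby("cluster_id", sort=True):
        members = [gene_pos[g] for g in grp["gene_id"] if g in gene_pos]
        if not members:
            continue
        clusters.append(np.array(members, dtype=np.int64))
        if apply_proximity and has_coords:
            coords = [
                (info.at[g, "arm"], info.at[g, "tss"])
                for g in grp["gene_id"]
                if g in gene_pos
            ]
            excluded.append(proximity_filter(coords, max_distance))
        else:
            excluded.append(False)

    code = np.zeros(len(gene_ids), dtype=np.int8)  # 0 normal/undet, 1 high, 2 low
    code[class_arr == CLASS_HIGH] = 1
    code[class_arr == CLASS_LOW] = 2
    undetermined = class_arr == CLASS_UNDETERMINED

    def count_coherent(codes, undet):
        n = 0
        for members, excl in zip(clusters, excluded):
            if excl:
                continue
            c = codes[members]
            u = undet[members]
            n_high = int(((c == 1) & ~u).sum())
            n_low = int(((c == 2) & ~u).sum())
            changed = n_high + n_low
            if changed >= min_changed and max(n_high, n_low) / changed > threshold:
                n += 1
        return n

    observed = count_coherent(code, undetermined)
    rng = np.random.default_rng(seed)
    tail = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(gene_ids))
        if count_coherent(code[perm], undetermined[perm]) >= observed:
            tail += 1
    p = (1.0 + tail) / (1.0 + n_perm)
    return observed, float(p)
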