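"""Text-format I/O for tracks, gene models, masks and tables.

Everything is plain tab-delimited text or standard genome-browser formats:
4-column BED-like window tables, bedGraph and fixed/variable-step wiggle
for signal, BED6 or GFF3 for gene models (GFF3's 1-based closed
coordinates are converted to 0-based half-open at this boundary), and
simple TSVs for masks, expression, complexes and per-window calls. All
round trips are lossless for the values written.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .chip import SignalTrack
from .tracks import GenomeLayout, MaskTrack, WindowTrack

__all__ = [
    "write_window_track",
    "read_window_track",
    "write_mask_track",
    "read_mask_track",
    "write_bedgraph",
    "read_bedgraph",
    "read_wiggle",
    "read_gene_models_bed6",
    "read_gene_models_gff3",
    "write_gene_models_bed6",
    "write_expression",
    "read_expression",
    "write_complexes",
    "read_complexes",
    "write_calls",
    "read_calls",
    "layout_from_window_table",
    "write_yaml",
    "read_yaml",
]


def write_window_track(path, track: WindowTrack, with_mask: bool = False):
    """Write chrom/start/end/value (+ optional mask_reason column) TSV."""
    tab = track.layout.window_table()
    tab["value"] = track.values
    if with_mask:
        tab["mask_reason"] = track.mask_reason
    tab.to_csv(path, sep="\t", index=False, header=False, float_format="%.10g")


def layout_from_window_table(tab: pd.DataFrame, window_size: int | None = None) -> GenomeLayout:
    """Reconstruct a GenomeLayout from a window table (chrom, start, end)."""
    arms = tab["chrom"].drop_duplicates().tolist()
    lengths = [int(tab.loc[tab["chrom"] == a, "end"].max()) for a in arms]
    if window_size is None:
        diffs = tab["end"] - tab["start"]
        window_size = int(diffs.max())
    return GenomeLayout(tuple(arms), tuple(lengths), window_size)


def read_window_track(path, layout: GenomeLayout | None = None) -> WindowTrack:
    """Read a window track written by :func:`write_window_track`."""
    tab = pd.read_csv(path, sep="\t", header=None)
    tab.columns = ["chrom", "start", "end", "value", "mask_reason"][: tab.shape[1]]
    if layout is None:
        layout = layout_from_window_table(tab)
    mask = (
        tab["mask_reason"].to_numpy(dtype=np.uint8)
        if "mask_reason" in tab.columns
        else None
    )
    return WindowTrack(layout, tab["value"].to_numpy(dtype=float), mask)


def write_mask_track(path, mask: MaskTrack):
    tab = mask.layout.window_table()
    tab["mappability"] = mask.mappability
    tab["gc"] = mask.gc
    tab.to_csv(path, sep="\t", index=False, header=False, float_format="%.10g")


def read_mask_track(path, layout: GenomeLayout | None = None) -> MaskTrack:
    tab = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "mappability", "gc"]
    )
    if layout is None:
        layout = layout_from_window_table(tab)
    return MaskTrack(
        layout,
        tab["mappability"].to_numpy(dtype=float),
        tab["gc"].to_numpy(dtype=float),
    )


# -- signal tracks -------------------------------------------------------


def write_bedgraph(path, track: SignalTrack):
    with open(path, "w") as fh:
        for arm in track.steps:
            starts, ends, values = track.steps[arm]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{arm}\t{s}\t{e}\t{v:.10g}\n")


def read_bedgraph(path) -> SignalTrack:
    """Read a bedGraph signal file (track/comment lines are skipped)."""
    track = SignalTrack()
    rows = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            arm, s, e, v = line.split("\t")[:4]
            rows.setdefault(arm, []).append((int(s), int(e), float(v)))
    for arm, items in rows.items():
        starts, ends, values = zip(*items)
        track.add(arm, starts, ends, values)
    return track


def read_wiggle(path) -> SignalTrack:
    """Read fixed-step and variable-step wiggle into a step-function track.

    fixedStep: values cover ``span`` bp (default: step) from each
    successive start; variableStep: each line gives a 1-based start and a
    value covering ``span`` bp (default 1). Wiggle coordinates are 1-based;
    they are converted to 0-based half-open here.
    """
    track = SignalTrack()
    rows: dict = {}
    mode = None
    arm = None
    step = span = start = None

    def parse_decl(line):
        fields = dict(f.split("=") for f in line.split()[1:])
        return fields

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            if line.startswith("fixedStep"):
                f = parse_decl(line)
                mode, arm = "fixed", f["chrom"]
                start = int(f["start"]) - 1
                step = int(f.get("step", 1))
                span = int(f.get("span", step))
                continue
            if line.startswith("variableStep"):
                f = parse_decl(line)
                mode, arm = "variable", f["chrom"]
                span = int(f.get("span", 1))
                continue
            if mode == "fixed":
                rows.setdefault(arm, []).append((start, start + span, float(line)))
                start += step
            elif mode == "variable":
                pos_s, val = line.split()[:2]
                pos = int(pos_s) - 1
                rows.setdefault(arm, []).append((pos, pos + span, float(val)))
            else:
                raise ValueError("wiggle data before any step declaration")
    for arm, items in rows.items():
        starts, ends, values = zip(*items)
        track.add(arm, starts, ends, values)
    return track


# -- gene models ---------------------------------------------------------


def _with_tss(genes: pd.DataFrame) -> pd.DataFrame:
    genes = genes.copy()
    genes["tss"] = np.where(genes["strand"] == "-", genes["end"] - 1, genes["start"])
    return genes


def read_gene_models_bed6(path) -> pd.DataFrame:
    """BED6 gene models -> (gene_id, arm, start, end, strand, tss)."""
    tab = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["arm", "start", "end", "gene_id", "score", "strand"],
        comment="#",
    )
    return _with_tss(tab[["gene_id", "arm", "start", "end", "strand"]])


def write_gene_models_bed6(path, genes: pd.DataFrame):
    out = genes[["arm", "start", "end", "gene_id"]].copy()
    out["score"] = 0
    out["strand"] = genes["strand"]
    out.to_csv(path, sep="\t", index=False, header=False)


def read_gene_models_gff3(path, feature: str = "gene") -> pd.DataFrame:
    """GFF3 gene models; 1-based closed coords become 0-based half-open."""
    tab = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=[
            "arm", "source", "type", "start", "end",
            "score", "strand", "phase", "attributes",
        ],
    )
    tab = tab[tab["type"] == feature].copy()
    ids = tab["attributes"].str.extract(r"ID=([^;]+)")[0]
    out = pd.DataFrame(
        {
            "gene_id": ids,
            "arm": tab["arm"],
            "start": tab["start"].astype(int) - 1,
            "end": tab["end"].astype(int),
            "strand": tab["strand"],
        }
    ).reset_index(drop=True)
    return _with_tss(out)


# -- simple tables -------------------------------------------------------


def write_expression(path, expression: pd.DataFrame):
    expression[["gene_id", "FPKM"]].to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_complexes(path, catalog: pd.DataFrame):
    cols = [c for c in ("cluster_id", "gene_id", "inclusion_p") if c in catalog.columns]
    catalog[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_complexes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_calls(path, profile):
    """Per-window 5-column call TSV (chrom, start, end, state, class)."""
    profile.to_frame().to_csv(path, sep="\t", index=False, header=False)


def read_calls(path, layout: GenomeLayout, baseline_ploidy: int):
    from .calls import CopyNumberProfile

    tab = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "state", "class"]
    )
    return CopyNumberProfile(layout, tab["state"].to_numpy(dtype=np.int64), baseline_ploidy)


def write_yaml(path, obj: dict):
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
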