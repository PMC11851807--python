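"""Percentile-outlier window selection, region merging and gene mapping.

Windows are ranked on a statistic (windowed weighted Fst, or the log
theta-pi ratio), the extreme ``ceil(fraction * n)`` windows of the chosen
tail are selected (ties at the threshold value are all included), selected
windows are merged into non-overlapping regions, regions are intersected
with a gene annotation (closed-interval, >= 1 bp overlap), and finally the
Fst gene set is intersected with the union of the two theta-pi-ratio tail
gene sets to produce the candidate list.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


@dataclass
class CandidateGeneSet:
    """Gene sets selected by each statistic and their intersection."""

    fst_genes: set[str]
    ratio_high_genes: set[str]
    ratio_low_genes: set[str]
    intersection_genes: set[str] = field(init=False)
    intersection_high: set[str] = field(init=False)
    intersection_low: set[str] = field(init=False)

    def __post_init__(self) -> None:
        self.intersection_high = self.fst_genes & self.ratio_high_genes
        self.intersection_low = self.fst_genes & self.ratio_low_genes
        self.intersection_genes = self.fst_genes & (
            self.ratio_high_genes | self.ratio_low_genes
        )


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------


def rank_threshold(
    values, fraction: float, tail: str = "top"
) -> tuple[float, np.ndarray]:
    """Select the extreme *fraction* of defined values.

    ``k = ceil(fraction * n_defined)`` values are taken from the stated
    tail; the threshold is the least extreme selected value and every
    value tied with it is also selected (so more than k indices may be
    returned).  NaN values are excluded before ranking.

    Returns ``(threshold, selected_indices)`` with indices into the input.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if tail not in {"top", "bottom"}:
        raise ValueError(f"tail must be 'top' or 'bottom', got {tail!r}")
    v = np.asarray(values, dtype=float)
    defined = np.flatnonzero(~np.isnan(v))
    if defined.size == 0:
        raise ValueError("no defined values to rank")
    k = math.ceil(fraction * defined.size)
    order = np.argsort(v[defined], kind="stable")
    if tail == "top":
        order = order[::-1]
    threshold = float(v[defined[order[k - 1]]])
    if tail == "top":
        selected = defined[v[defined] >= threshold]
    else:
        selected = defined[v[defined] <= threshold]
    return threshold, np.sort(selected)


def select_fst_windows(
    windows: pd.DataFrame, fraction: float = 0.05
) -> tuple[float, pd.DataFrame]:
    """Top-tail selection of windows by weighted Fst."""
    thr, idx = rank_threshold(windows["weighted_fst"], fraction, "top")
    sel = windows.iloc[idx].copy()
    sel["source_stat"] = "fst"
    sel["tail"] = "top"
    sel["value"] = sel["weighted_fst"]
    return thr, sel


def select_ratio_windows(
    windows: pd.DataFrame, fraction: float = 0.025
) -> dict:
    """Independent high- and low-tail selections by log theta-pi ratio.

    Returns ``{"high": (threshold, frame), "low": (threshold, frame)}``.
    A window selected by both tails (possible only in degenerate inputs)
    is flagged in the ``both_tails`` column.
    """
    thr_hi, idx_hi = rank_threshold(windows["log_ratio"], fraction, "top")
    thr_lo, idx_lo = rank_threshold(windows["log_ratio"], fraction, "bottom")
    overlap = set(idx_hi) & set(idx_lo)
    out = {}
    for tail, thr, idx in (("high", thr_hi, idx_hi), ("low", thr_lo, idx_lo)):
        sel = windows.iloc[idx].copy()
        sel["source_stat"] = "pi_ratio"
        sel["tail"] = tail
        sel["value"] = sel["log_ratio"]
        sel["both_tails"] = [i in overlap for i in idx]
        out[tail] = (thr, sel)
    return out


# ---------------------------------------------------------------------------
# regions and genes
# ---------------------------------------------------------------------------


def merge_windows(selected: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or book-ended selected windows into regions.

    Windows on the same chromosome merge when ``next.start <= current.end
    + 1``.  Returns a table of ``chrom, start, end, n_windows, peak_value``
    (and ``source_stat`` / ``tail`` when present in the input).
    """
    cols = ["chrom", "start", "end", "n_windows", "peak_value"]
    extra = [c for c in ("source_stat", "tail") if c in selected.columns]
    if selected.empty:
        return pd.DataFrame(columns=cols + extra)
    rows = []
    df = selected.sort_values(["chrom", "start"], kind="stable")
    for chrom, grp in df.groupby("chrom", sort=False):
        cur = None
        for _, w in grp.iterrows():
            if cur is not None and w["start"] <= cur["end"] + 1:
                cur["end"] = max(cur["end"], int(w["end"]))
                cur["n_windows"] += 1
                cur["peak_value"] = max(cur["peak_value"], float(w["value"]))
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {
                    "chrom": chrom,
                    "start": int(w["start"]),
                    "end": int(w["end"]),
                    "n_windows": 1,
                    "peak_value": float(w["value"]),
                }
                for c in extra:
                    cur[c] = w[c]
        rows.append(cur)
    return pd.DataFrame(rows, columns=cols + extra)


def genes_in_regions(regions: pd.DataFrame, genes: pd.DataFrame) -> set[str]:
    """Genes overlapping any region by at least one bp (closed intervals).

    *genes* needs columns ``gene_id, chrom, start, end`` (1-based
    inclusive).  A complete chromosome-name mismatch between the two
    inputs triggers a warning and an empty result.
    """
    if regions.empty or genes.empty:
        return set()
    shared = set(regions["chrom"]) & set(genes["chrom"])
    if not shared:
        warnings.warn(
            "no chromosome names shared between regions and genes; "
            "zero overlaps reported",
            stacklevel=2,
        )
        return set()
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in genes.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            # half-open tree intervals; +1 converts the inclusive end
            (int(s), int(e) + 1, g)
            for s, e, g in zip(grp["start"], grp["end"], grp["gene_id"])
        )
    hits: set[str] = set()
    for _, r in regions.iterrows():
        tree = trees.get(r["chrom"])
        if tree is None:
            continue
        for iv in tree.overlap(int(r["start"]), int(r["end"]) + 1):
            hits.add(iv.data)
    return hits


def intersect_candidates(
    fst_genes: set[str], ratio_high: set[str], ratio_low: set[str]
) -> CandidateGeneSet:
    """Intersect the Fst gene set with the union of the ratio tails."""
    return CandidateGeneSet(set(fst_genes), set(ratio_high), set(ratio_low))


# ---------------------------------------------------------------------------
# annotation input
# ---------------------------------------------------------------------------


def read_gff3(path: str | os.PathLike) -> pd.DataFrame:
    """Read gene features from a GFF3 file (1-based inclusive)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    rows = [
        (
            f.attributes.get("ID", [f.id])[0],
            f.seqid,
            f.start,
            f.end,
            f.strand or ".",
        )
        for f in db.features_of_type("gene")
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in annotation")
    return df


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED gene file, converting 0-based half-open to 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise ValueError("BED gene file needs >= 4 columns (chrom start end name)")
    out = pd.DataFrame(
        {
            "gene_id": df.iloc[:, 3],
            "chrom": df.iloc[:, 0],
            "start": df.iloc[:, 1].astype(int) + 1,
            "end": df.iloc[:, 2].astype(int),
            "strand": df.iloc[:, 5] if df.shape[1] > 5 else ".",
        }
    )
    if out["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in annotation")
    return out


def regions_to_bed(regions: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write regions as BED (converted to 0-based half-open)."""
    with open(path, "w") as fh:
        for _, r in regions.iterrows():
            name = f"{r.get('source_stat', 'region')}_{r.get('tail', '')}"
            fh.write(
                f"{r['chrom']}\t{int(r['start']) - 1}\t{int(r['end'])}\t{name}\n"
            )
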