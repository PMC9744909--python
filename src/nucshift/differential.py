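"""Per-gene promoter occupancy differences anchored on +1 nucleosome dyads.

The statistic for a gene is the mean, over a strand-oriented window upstream
of its +1 dyad (default -150..-50 bp, inclusive — the nucleosome-depleted
region), of the difference between a test and a reference occupancy track.
Genes are ranked by decreasing statistic; a blacklist removes genes whose
gain does not exceed a threshold (default +0.6 normalized occupancy units,
strict); blacklists from several comparisons merge as a plain set union.
Top-N selection optionally subtracts a per-gene baseline statistic (a
control comparison) before ranking.

Differences are computed on the linear normalized scale; log2 is reserved
for heatmap display.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .records import GeneAnchor
from .tracks import OccupancyTrack

DEFAULT_WINDOW = (-150, -50)
DEFAULT_BLACKLIST_THRESHOLD = 0.6
DEFAULT_TOP_N = 500

STAT_COLUMNS = [
    "gene_id", "chrom", "strand", "dyad", "stat",
    "baseline_stat", "adjusted_stat", "rank", "blacklisted", "excluded_reason",
]


class WindowOutOfBounds(ValueError):
    """The oriented window does not fit inside the chromosome."""


def relative_window_values(
    track_values: dict[str, np.ndarray] | OccupancyTrack,
    anchor: GeneAnchor,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> np.ndarray:
    """Signal over an oriented window relative to a gene's +1 dyad.

    ``window`` bounds are inclusive and strand-relative: negative = upstream
    of the +1 nucleosome on the gene's strand.  Index 0 of the result is
    always the most upstream (promoter-distal) position, so for a minus-strand
    gene the genomic slice is read in reverse.
    """
    values = track_values.values if isinstance(track_values, OccupancyTrack) else track_values
    lo, hi = window
    if lo > hi:
        raise ValueError(f"window lower bound {lo} exceeds upper bound {hi}")
    if anchor.chrom not in values:
        raise KeyError(f"gene {anchor.gene_id}: chromosome {anchor.chrom!r} not in track")
    arr = values[anchor.chrom]
    if anchor.strand == "+":
        g_lo, g_hi = anchor.dyad + lo, anchor.dyad + hi
        if g_lo < 0 or g_hi >= len(arr):
            raise WindowOutOfBounds(f"gene {anchor.gene_id}: window outside {anchor.chrom}")
        return arr[g_lo : g_hi + 1].copy()
    g_lo, g_hi = anchor.dyad - hi, anchor.dyad - lo
    if g_lo < 0 or g_hi >= len(arr):
        raise WindowOutOfBounds(f"gene {anchor.gene_id}: window outside {anchor.chrom}")
    return arr[g_lo : g_hi + 1][::-1].copy()


def window_stat(
    test_track: OccupancyTrack | dict[str, np.ndarray],
    ref_track: OccupancyTrack | dict[str, np.ndarray],
    anchors: Sequence[GeneAnchor],
    window: tuple[int, int] = DEFAULT_WINDOW,
    comparison: str = "",
) -> pd.DataFrame:
    """Per-gene mean occupancy difference (test - reference) over the window.

    Returns a GeneStatTable: one row per anchor with the statistic, plus
    ``excluded_reason`` set for genes whose window overruns the chromosome
    (their statistic is NaN and they take no part in ranking).
    """
    test_values = test_track.values if isinstance(test_track, OccupancyTrack) else test_track
    ref_values = ref_track.values if isinstance(ref_track, OccupancyTrack) else ref_track
    if set(test_values) != set(ref_values):
        raise ValueError(
            "test and reference tracks cover different chromosome sets: "
            f"{sorted(set(test_values) ^ set(ref_values))}"
        )
    ids = [a.gene_id for a in anchors]
    if len(set(ids)) != len(ids):
        raise ValueError("gene ids are not unique")
    rows = []
    for a in anchors:
        try:
            tv = relative_window_values(test_values, a, window)
            rv = relative_window_values(ref_values, a, window)
        except WindowOutOfBounds:
            warnings.warn(f"gene {a.gene_id}: window outside chromosome, excluded")
            rows.append((a.gene_id, a.chrom, a.strand, a.dyad, np.nan, "window_out_of_bounds"))
            continue
        rows.append((a.gene_id, a.chrom, a.strand, a.dyad, float(np.mean(tv - rv)), ""))
    table = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "dyad", "stat", "excluded_reason"]
    )
    table["baseline_stat"] = 0.0
    table["adjusted_stat"] = table["stat"]
    table["blacklisted"] = False
    table["rank"] = pd.array([pd.NA] * len(table), dtype="Int64")
    table.attrs["comparison"] = comparison
    table.attrs["window"] = tuple(window)
    return table[STAT_COLUMNS]


def _included(stats: pd.DataFrame) -> pd.DataFrame:
    return stats[stats["excluded_reason"] == ""]


def blacklist_genes(
    stats: pd.DataFrame,
    threshold: float = DEFAULT_BLACKLIST_THRESHOLD,
    column: str = "stat",
) -> set[str]:
    """Genes failing to achieve *more than* ``threshold`` occupancy gain.

    The comparison is strict: a gene exactly at the threshold is blacklisted.
    Excluded (out-of-bounds) genes are not part of the blacklist; they are
    already outside the analysis.
    """
    inc = _included(stats)
    return set(inc.loc[~(inc[column] > threshold), "gene_id"])


def merge_blacklists(lists: Sequence[set[str]]) -> set[str]:
    """Union of per-comparison blacklists ("merged without duplication")."""
    merged: set[str] = set()
    for s in lists:
        merged |= set(s)
    return merged


def order_genes(stats: pd.DataFrame, column: str = "stat") -> list[str]:
    """Gene ids by decreasing statistic; ties break lexicographically."""
    inc = _included(stats)
    ordered = inc.sort_values(
        [column, "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return ordered["gene_id"].tolist()


def annotate_ranks(
    stats: pd.DataFrame,
    blacklist: set[str] | None = None,
    column: str = "stat",
) -> pd.DataFrame:
    """Fill rank (1 = largest statistic) and blacklist flags into the table."""
    out = stats.copy()
    order = order_genes(out, column=column)
    rank_of = {g: i + 1 for i, g in enumerate(order)}
    out["rank"] = pd.array([rank_of.get(g) for g in out["gene_id"]], dtype="Int64")
    if blacklist is not None:
        out["blacklisted"] = out["gene_id"].isin(blacklist)
    return out


def top_n_genes(
    stats: pd.DataFrame,
    n: int = DEFAULT_TOP_N,
    baseline_stats: pd.DataFrame | None = None,
) -> list[str]:
    """The n genes with the largest (baseline-adjusted) occupancy gain.

    With ``baseline_stats`` given (a control comparison's GeneStatTable),
    the per-gene baseline statistic is subtracted before ranking.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    work = stats.copy()
    if baseline_stats is not None:
        base = baseline_stats.set_index("gene_id")["stat"]
        missing = set(work.loc[work["excluded_reason"] == "", "gene_id"]) - set(base.index)
        if missing:
            raise ValueError(f"baseline stats missing genes: {sorted(missing)[:10]}")
        work["baseline_stat"] = base.reindex(work["gene_id"]).to_numpy()
        work["adjusted_stat"] = work["stat"] - work["baseline_stat"]
    else:
        work["adjusted_stat"] = work["stat"]
    order = order_genes(work, column="adjusted_stat")
    if len(order) < n:
        warnings.warn(f"only {len(order)} genes available for top-{n} selection")
        return order
    return order[:n]


def write_stats(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_stats(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    table["excluded_reason"] = table["excluded_reason"].fillna("")
    return table
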