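"""+1-dyad-anchored signal matrices, log2 heatmaps and average profiles.

Rows are genes, columns strand-oriented positions relative to the +1
nucleosome dyad (upstream on the left).  Differential heatmaps show
log2((test + pseudocount) / (ref + pseudocount)); per-gene statistics stay
on the linear scale elsewhere.  The numeric TSV matrix is the load-bearing
artifact; the rendered PNG is decorative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .records import GeneAnchor
from .tracks import OccupancyTrack

DEFAULT_FLANK = 500
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class AnchoredMatrix:
    gene_ids: list[str]
    positions: np.ndarray  # -flank..+flank inclusive, 1-bp step
    values: np.ndarray  # shape (n_genes, 2*flank + 1)
    label: str = ""
    pseudocount: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.positions)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.positions)} positions"
            )

    @property
    def flank(self) -> int:
        return int(self.positions[-1])

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


def anchored_matrix(
    track: OccupancyTrack | dict[str, np.ndarray],
    anchors: Sequence[GeneAnchor],
    flank: int = DEFAULT_FLANK,
    label: str = "",
) -> AnchoredMatrix:
    """Per-gene signal around the +1 dyad, strand-oriented.

    Row g, column j holds the track value at ``dyad + j`` for plus-strand
    genes and ``dyad - j`` for minus-strand genes, j in -flank..+flank.
    Genes whose window overruns a chromosome end are dropped with a warning.
    """
    if flank <= 0:
        raise ValueError(f"flank must be positive, got {flank}")
    values = track.values if isinstance(track, OccupancyTrack) else track
    positions = np.arange(-flank, flank + 1)
    rows: list[np.ndarray] = []
    kept: list[str] = []
    for a in anchors:
        if a.chrom not in values:
            raise KeyError(f"gene {a.gene_id}: chromosome {a.chrom!r} not in track")
        arr = values[a.chrom]
        lo, hi = a.dyad - flank, a.dyad + flank
        if lo < 0 or hi >= len(arr):
            warnings.warn(f"gene {a.gene_id}: +/-{flank} bp window outside {a.chrom}, dropped")
            continue
        window = arr[lo : hi + 1]
        rows.append(window[::-1].copy() if a.strand == "-" else window.copy())
        kept.append(a.gene_id)
    data = np.vstack(rows) if rows else np.empty((0, len(positions)))
    return AnchoredMatrix(gene_ids=kept, positions=positions, values=data, label=label)


def log2_ratio_matrix(
    test: AnchoredMatrix,
    ref: AnchoredMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    label: str = "",
) -> AnchoredMatrix:
    """Entrywise log2((test + pc) / (ref + pc)) of two aligned matrices."""
    if test.gene_ids != ref.gene_ids:
        raise ValueError("matrices cover different gene sets")
    if not np.array_equal(test.positions, ref.positions):
        raise ValueError("matrices cover different position ranges")
    with np.errstate(divide="ignore"):
        values = np.log2((test.values + pseudocount) / (ref.values + pseudocount))
    return AnchoredMatrix(
        gene_ids=list(test.gene_ids),
        positions=test.positions.copy(),
        values=values,
        label=label or f"log2({test.label or 'test'}/{ref.label or 'ref'})",
        pseudocount=pseudocount,
    )


def assemble_heatmap(
    matrix: AnchoredMatrix,
    ordering: Sequence[str],
    blacklist: set[str] | None = None,
    png_path: str | Path | None = None,
) -> AnchoredMatrix:
    """Reorder matrix rows by ``ordering`` and drop blacklisted genes.

    ``ordering`` must cover every non-blacklisted gene of the matrix (it may
    additionally contain genes absent from the matrix, e.g. a genome-wide
    ranking applied to a subset matrix).  Pure row selection: surviving
    entries are untouched.
    """
    blacklist = blacklist or set()
    matrix_genes = set(matrix.gene_ids)
    missing = matrix_genes - blacklist - set(ordering)
    if missing:
        raise ValueError(f"ordering is missing matrix genes: {sorted(missing)[:10]}")
    order = [g for g in ordering if g in matrix_genes and g not in blacklist]
    if not order:
        warnings.warn("all genes blacklisted: heatmap is empty")
    index = {g: i for i, g in enumerate(matrix.gene_ids)}
    rows = [index[g] for g in order]
    selected = AnchoredMatrix(
        gene_ids=order,
        positions=matrix.positions.copy(),
        values=matrix.values[rows] if rows else np.empty((0, len(matrix.positions))),
        label=matrix.label,
        pseudocount=matrix.pseudocount,
    )
    if png_path is not None:
        plot_heatmap(selected, png_path)
    return selected


def plot_heatmap(matrix: AnchoredMatrix, path: str | Path) -> None:
    """Render rows with a diverging color scale symmetric about zero."""
    fig, ax = plt.subplots(figsize=(4, 6))
    if matrix.values.size:
        vmax = float(np.nanmax(np.abs(matrix.values))) or 1.0
    else:
        vmax = 1.0
    im = ax.imshow(
        matrix.values if matrix.values.size else np.zeros((1, len(matrix.positions))),
        aspect="auto",
        cmap="RdBu_r",
        vmin=-vmax,
        vmax=vmax,
        extent=(matrix.positions[0], matrix.positions[-1], len(matrix.gene_ids), 0),
        interpolation="nearest",
    )
    ax.set_xlabel("position relative to +1 dyad (bp)")
    ax.set_ylabel("genes")
    ax.set_title(matrix.label)
    fig.colorbar(im, ax=ax, label="log2 occupancy ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def average_profile(
    tracks: dict[str, OccupancyTrack | dict[str, np.ndarray]],
    anchors: Sequence[GeneAnchor],
    gene_set: set[str] | None = None,
    flank: int = DEFAULT_FLANK,
) -> pd.DataFrame:
    """Column-wise mean anchored signal per condition over a gene subset.

    Returns a table with a ``position`` column and one column per condition
    label.  ``gene_set=None`` means all anchors.
    """
    anchor_ids = {a.gene_id for a in anchors}
    if gene_set is None:
        subset = list(anchors)
    else:
        if not gene_set:
            raise ValueError("gene_set is empty")
        unknown = set(gene_set) - anchor_ids
        if unknown:
            raise ValueError(f"gene_set contains unknown genes: {sorted(unknown)[:10]}")
        subset = [a for a in anchors if a.gene_id in gene_set]
    out: dict[str, np.ndarray] = {}
    positions = None
    for label, track in tracks.items():
        m = anchored_matrix(track, subset, flank=flank, label=label)
        if m.values.size == 0:
            raise ValueError(f"no usable genes for condition {label!r}")
        positions = m.positions
        out[label] = m.values.mean(axis=0)
    table = pd.DataFrame({"position": positions})
    for label, curve in out.items():
        table[label] = curve
    return table


def plot_profiles(profile: pd.DataFrame, path: str | Path, window: tuple[int, int] | None = None) -> None:
    """Line plot of average occupancy per condition; optional window shading."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for column in profile.columns:
        if column == "position":
            continue
        ax.plot(profile["position"], profile[column], label=column, lw=1.2)
    if window is not None:
        ax.axvspan(window[0], window[1], color="0.85", zorder=0)
    ax.set_xlabel("position relative to +1 dyad (bp)")
    ax.set_ylabel("normalized occupancy")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_matrix(matrix: AnchoredMatrix, path: str | Path) -> None:
    """Matrix as TSV: header row of positions, one row per gene."""
    table = pd.DataFrame(matrix.values, columns=[str(p) for p in matrix.positions])
    table.insert(0, "gene_id", matrix.gene_ids)
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_matrix(path: str | Path, label: str = "") -> AnchoredMatrix:
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    positions = np.array([int(c) for c in table.columns[1:]])
    return AnchoredMatrix(
        gene_ids=table["gene_id"].tolist(),
        positions=positions,
        values=table.iloc[:, 1:].to_numpy(float),
        label=label,
    )
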