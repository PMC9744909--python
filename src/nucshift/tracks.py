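"""Smoothed, library-size-normalized nucleosome occupancy tracks.

Each filtered fragment is summarized by its midpoint (the dyad estimate) and
extended into a fixed-width footprint around it: the midpoint contributes 1
to every base in ``[m - width//2, m - width//2 + width)`` (default width 40,
i.e. [m-20, m+20)), truncated at chromosome ends.  The raw track is scaled
linearly so every library corresponds to the same effective fragment count
(default 10,000,000), then smoothed with a centered moving average of
``smooth_width`` bp (default 20; edge windows shrink to the available
positions).  Output is at 1-bp resolution.

Order of operations is extend -> scale -> smooth; scaling commutes with
smoothing, extension does not.  For an even smoothing width w the window at
position i covers [i - w//2, i + w - w//2 - 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .records import FragmentRecord

DEFAULT_WIDTH = 40
DEFAULT_SMOOTH_WIDTH = 20
DEFAULT_TARGET_COUNT = 10_000_000


@dataclass
class OccupancyTrack:
    """Per-chromosome 1-bp signal in normalized effective-fragment units.

    ``values`` holds the smoothed signal; ``raw`` the scaled-but-unsmoothed
    footprint coverage (kept so normalization invariants stay checkable).
    """

    values: dict[str, np.ndarray]
    raw: dict[str, np.ndarray]
    width: int = DEFAULT_WIDTH
    smooth_width: int = DEFAULT_SMOOTH_WIDTH
    target_count: float = DEFAULT_TARGET_COUNT
    n_fragments_used: int = 0

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.values.items()}

    def total_raw_signal(self) -> float:
        return float(sum(v.sum() for v in self.raw.values()))

    def effective_fragment_count(self) -> float:
        """Sum of the unsmoothed track divided by the footprint width.

        Equals ``target_count`` exactly whenever no footprint window was
        truncated at a chromosome end.
        """
        return self.total_raw_signal() / self.width


def fragment_midpoints(records: Iterable[FragmentRecord]) -> list[tuple[str, int]]:
    """Dyad estimates: floor((start + end) / 2) of each template interval."""
    return [(r.chrom, r.midpoint) for r in records]


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with truncated (shrinking) edge windows."""
    if window <= 1:
        return x.astype(float, copy=True)
    n = len(x)
    csum = np.concatenate(([0.0], np.cumsum(x, dtype=float)))
    idx = np.arange(n)
    lo = np.maximum(idx - window // 2, 0)
    hi = np.minimum(idx + (window - window // 2), n)  # exclusive
    return (csum[hi] - csum[lo]) / (hi - lo)


def build_track(
    midpoints: Sequence[tuple[str, int]],
    chrom_lengths: dict[str, int],
    width: int = DEFAULT_WIDTH,
    smooth_width: int = DEFAULT_SMOOTH_WIDTH,
    target_count: float = DEFAULT_TARGET_COUNT,
) -> OccupancyTrack:
    """Build the normalized smoothed occupancy track from fragment midpoints."""
    if width < 1:
        raise ValueError("width must be >= 1")
    if smooth_width < 1:
        raise ValueError("smooth_width must be >= 1")
    by_chrom: dict[str, list[int]] = {c: [] for c in chrom_lengths}
    for i, (chrom, pos) in enumerate(midpoints):
        if chrom not in chrom_lengths:
            raise ValueError(f"midpoint {i}: unknown chromosome {chrom!r}")
        if not 0 <= pos < chrom_lengths[chrom]:
            raise ValueError(
                f"midpoint {i}: position {pos} outside {chrom} "
                f"(length {chrom_lengths[chrom]})"
            )
        by_chrom[chrom].append(pos)

    n_used = len(midpoints)
    if n_used == 0:
        warnings.warn("no fragments: emitting an all-zero track")
        scale = 0.0
    else:
        scale = target_count / n_used

    raw: dict[str, np.ndarray] = {}
    smoothed: dict[str, np.ndarray] = {}
    half = width // 2
    for chrom, length in chrom_lengths.items():
        diff = np.zeros(length + 1, dtype=float)
        if by_chrom[chrom]:
            pos = np.asarray(by_chrom[chrom], dtype=np.int64)
            lo = np.clip(pos - half, 0, length)
            hi = np.clip(pos - half + width, 0, length)
            np.add.at(diff, lo, 1.0)
            np.add.at(diff, hi, -1.0)
        coverage = np.cumsum(diff[:-1]) * scale
        raw[chrom] = coverage
        smoothed[chrom] = moving_average(coverage, smooth_width)
    return OccupancyTrack(
        values=smoothed,
        raw=raw,
        width=width,
        smooth_width=smooth_width,
        target_count=target_count,
        n_fragments_used=n_used,
    )


# ---------------------------------------------------------------------------
# track io
# ---------------------------------------------------------------------------

def _runs(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run-length encode an array: (starts, ends, run values)."""
    n = len(values)
    if n == 0:
        return np.array([], int), np.array([], int), np.array([], float)
    change = np.flatnonzero(np.diff(values) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    return starts, ends, values[starts]


def write_track(track: OccupancyTrack, path: str | Path, format: str = "bedGraph") -> None:
    """Write the smoothed track as run-length bedGraph or bigWig."""
    fmt = format.lower()
    if fmt == "bedgraph":
        with open(path, "w") as fh:
            for chrom, values in track.values.items():
                starts, ends, vals = _runs(values)
                for s, e, v in zip(starts, ends, vals):
                    fh.write(f"{chrom}\t{s}\t{e}\t{float(v)!r}\n")
    elif fmt == "bigwig":
        import pyBigWig

        bw = pyBigWig.open(str(path), "w")
        bw.addHeader([(c, len(v)) for c, v in track.values.items()])
        for chrom, values in track.values.items():
            starts, ends, vals = _runs(values)
            if len(starts):
                bw.addEntries(
                    [chrom] * len(starts),
                    starts.tolist(),
                    ends=ends.tolist(),
                    values=vals.astype(float).tolist(),
                )
        bw.close()
    else:
        raise ValueError(f"unknown track format {format!r}")


def read_track(
    path: str | Path,
    chrom_lengths: dict[str, int] | None = None,
    format: str | None = None,
) -> dict[str, np.ndarray]:
    """Read a track back into per-chromosome arrays.

    With ``chrom_lengths`` omitted, chromosome extents are inferred from the
    last covered interval.
    """
    if format is None:
        format = "bigwig" if str(path).endswith((".bw", ".bigwig")) else "bedgraph"
    fmt = format.lower()
    if fmt == "bigwig":
        import pyBigWig

        bw = pyBigWig.open(str(path))
        out = {}
        for chrom, length in bw.chroms().items():
            out[chrom] = np.nan_to_num(np.asarray(bw.values(chrom, 0, length), dtype=float))
        bw.close()
        return out
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            intervals.setdefault(fields[0], []).append(
                (int(fields[1]), int(fields[2]), float(fields[3]))
            )
    out = {}
    for chrom, ivals in intervals.items():
        length = (
            chrom_lengths[chrom] if chrom_lengths is not None else max(e for _, e, _ in ivals)
        )
        arr = np.zeros(length, dtype=float)
        for s, e, v in ivals:
            arr[s:e] = v
        out[chrom] = arr
    if chrom_lengths is not None:
        for chrom, length in chrom_lengths.items():
            out.setdefault(chrom, np.zeros(length, dtype=float))
    return out
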