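"""Core record types shared across the pipeline.

A :class:`FragmentRecord` is one aligned paired-end MNase fragment: the two
mate intervals, pair-level flags and per-mate edit distances. For a concordant
same-chromosome pair the *template* interval ``[start, end)`` spans from the
leftmost mate start to the rightmost mate end, and its midpoint estimates the
nucleosome dyad protected by the fragment.

A :class:`GeneAnchor` places a gene's +1 nucleosome dyad (the midpoint of the
first well-positioned nucleosome downstream of the TSS) on the genome; all
promoter-relative coordinates in the pipeline are oriented by its strand.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FragmentRecord:
    """One aligned read pair.

    Coordinates are 0-based half-open, one interval per mate.  ``concordant``
    mirrors the aligner's proper-pair call; ``ambiguous`` marks multi-mapping
    (mapping quality 0) pairs; ``nm1``/``nm2`` are per-mate mismatch (edit
    distance) counts.
    """

    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    name: str = "."
    concordant: bool = True
    ambiguous: bool = False
    nm1: int = 0
    nm2: int = 0

    @property
    def chrom(self) -> str:
        return self.chrom1

    @property
    def start(self) -> int:
        """Template start (leftmost mate start)."""
        return self.start1

    @property
    def end(self) -> int:
        """Template end (rightmost mate end)."""
        return self.end2

    @property
    def template_length(self) -> int:
        """Insert size of the sequenced template.

        Defined as ``end - start`` for same-chromosome pairs and 0 for
        inter-chromosomal pairs, for which no template interval exists.
        """
        if self.chrom1 != self.chrom2:
            return 0
        return self.end2 - self.start1

    @property
    def midpoint(self) -> int:
        """Dyad estimate: floor of the template-interval center."""
        return (self.start1 + self.end2) // 2


@dataclass(frozen=True)
class GeneAnchor:
    """A gene's +1 nucleosome dyad position (0-based) and strand."""

    gene_id: str
    chrom: str
    strand: str
    dyad: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.dyad < 0:
            raise ValueError(f"gene {self.gene_id}: dyad must be >= 0")
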