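"""Readers and writers for the formats the pipeline exchanges.

Fragments travel either as coordinate-sorted BAM (proper-pair flag =
concordance, MAPQ 0 = ambiguous, NM tag = per-mate mismatches) or as a
10-column BEDPE dialect::

    chrom1  start1  end1  chrom2  start2  end2  name  flagword  nm1  nm2

with ``flagword`` bit 0x1 = concordant and bit 0x2 = ambiguous.  Anchors are
6-column BED holding the +1 dyad as a 1-bp interval.  All intervals are
0-based half-open.  Parsers are strict: a malformed line raises
:class:`FormatError` naming the line number.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import FragmentRecord, GeneAnchor

BEDPE_COLUMNS = (
    "chrom1 start1 end1 chrom2 start2 end2 name flagword nm1 nm2".split()
)

_FLAG_CONCORDANT = 0x1
_FLAG_AMBIGUOUS = 0x2


class FormatError(ValueError):
    """A file did not conform to its declared dialect."""


def detect_dialect(path: str | Path) -> str:
    """Guess the fragment dialect ('BAM' or 'BEDPE') from the file suffix."""
    return "BAM" if str(path).endswith(".bam") else "BEDPE"


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

def write_fragments(
    records: Sequence[FragmentRecord],
    path: str | Path,
    dialect: str = "BEDPE",
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    """Write fragment records; BAM requires ``chrom_lengths`` for the header."""
    dialect = dialect.upper()
    if dialect == "BEDPE":
        _write_bedpe(records, path)
    elif dialect == "BAM":
        if chrom_lengths is None:
            raise ValueError("BAM output requires chrom_lengths for the header")
        _write_bam(records, path, chrom_lengths)
    else:
        raise ValueError(f"unknown fragment dialect {dialect!r}")


def read_fragments(path: str | Path, dialect: str | None = None) -> list[FragmentRecord]:
    """Read fragment records from BAM or the BEDPE dialect."""
    if dialect is None:
        dialect = detect_dialect(path)
    dialect = dialect.upper()
    if dialect == "BEDPE":
        return _read_bedpe(path)
    if dialect == "BAM":
        return _read_bam(path)
    raise ValueError(f"unknown fragment dialect {dialect!r}")


def _write_bedpe(records: Sequence[FragmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(BEDPE_COLUMNS) + "\n")
        for r in records:
            flag = (_FLAG_CONCORDANT if r.concordant else 0) | (
                _FLAG_AMBIGUOUS if r.ambiguous else 0
            )
            fh.write(
                f"{r.chrom1}\t{r.start1}\t{r.end1}\t{r.chrom2}\t{r.start2}\t"
                f"{r.end2}\t{r.name}\t{flag}\t{r.nm1}\t{r.nm2}\n"
            )


def _read_bedpe(path: str | Path) -> list[FragmentRecord]:
    records: list[FragmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise FormatError(
                    f"{path}:{lineno}: expected 10 tab-separated fields, got {len(fields)}"
                )
            try:
                start1, end1 = int(fields[1]), int(fields[2])
                start2, end2 = int(fields[4]), int(fields[5])
                flag, nm1, nm2 = int(fields[7]), int(fields[8]), int(fields[9])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate field ({exc})")
            if end1 < start1 or end2 < start2 or start1 < 0 or start2 < 0:
                raise FormatError(f"{path}:{lineno}: invalid mate interval")
            records.append(
                FragmentRecord(
                    chrom1=fields[0],
                    start1=start1,
                    end1=end1,
                    chrom2=fields[3],
                    start2=start2,
                    end2=end2,
                    name=fields[6],
                    concordant=bool(flag & _FLAG_CONCORDANT),
                    ambiguous=bool(flag & _FLAG_AMBIGUOUS),
                    nm1=nm1,
                    nm2=nm2,
                )
            )
    return records


def _write_bam(
    records: Sequence[FragmentRecord],
    path: str | Path,
    chrom_lengths: dict[str, int],
) -> None:
    chroms = list(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(chrom_lengths[c])} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    segments = []
    for r in records:
        for is_read1 in (True, False):
            a = pysam.AlignedSegment()
            a.query_name = r.name
            chrom = r.chrom1 if is_read1 else r.chrom2
            start = r.start1 if is_read1 else r.start2
            end = r.end1 if is_read1 else r.end2
            a.reference_id = tid[chrom]
            a.reference_start = start
            a.cigar = [(0, end - start)]
            a.mapping_quality = 0 if r.ambiguous else 60
            # FR orientation: read1 forward with reverse mate, read2 reverse
            flag = 0x1 | (0x2 if r.concordant else 0)
            flag |= (0x40 | 0x20) if is_read1 else (0x80 | 0x10)
            a.flag = flag
            mate_chrom = r.chrom2 if is_read1 else r.chrom1
            a.next_reference_id = tid[mate_chrom]
            a.next_reference_start = r.start2 if is_read1 else r.start1
            tlen = r.template_length
            a.template_length = tlen if is_read1 else -tlen
            a.set_tag("NM", int(r.nm1 if is_read1 else r.nm2))
            segments.append(a)
    segments.sort(key=lambda a: (a.reference_id, a.reference_start, a.query_name))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for a in segments:
            bam.write(a)


def _read_bam(path: str | Path) -> list[FragmentRecord]:
    mates: dict[str, dict[bool, pysam.AlignedSegment]] = {}
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for seg in bam.fetch(until_eof=True):
            mates.setdefault(seg.query_name, {})[seg.is_read1] = seg
    records = []
    for name, pair in mates.items():
        if set(pair) != {True, False}:
            raise FormatError(f"{path}: unpaired alignment for query {name!r}")
        r1, r2 = pair[True], pair[False]
        records.append(
            FragmentRecord(
                chrom1=r1.reference_name,
                start1=r1.reference_start,
                end1=r1.reference_end,
                chrom2=r2.reference_name,
                start2=r2.reference_start,
                end2=r2.reference_end,
                name=name,
                concordant=r1.is_proper_pair,
                ambiguous=r1.mapping_quality == 0,
                nm1=int(r1.get_tag("NM")),
                nm2=int(r2.get_tag("NM")),
            )
        )
    records.sort(key=lambda r: (r.chrom1, r.start1, r.end2, r.name))
    return records


# ---------------------------------------------------------------------------
# anchors and gene lists
# ---------------------------------------------------------------------------

def write_anchors(anchors: Sequence[GeneAnchor], path: str | Path) -> None:
    """Write +1 dyad anchors as BED6 (dyad as a 1-bp interval)."""
    with open(path, "w") as fh:
        for a in anchors:
            fh.write(f"{a.chrom}\t{a.dyad}\t{a.dyad + 1}\t{a.gene_id}\t0\t{a.strand}\n")


def read_anchors(path: str | Path) -> list[GeneAnchor]:
    anchors: list[GeneAnchor] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate ({exc})")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} is not < end {end}")
            if fields[5] not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: strand must be + or -, got {fields[5]!r}")
            gene_id = fields[3]
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            anchors.append(GeneAnchor(gene_id=gene_id, chrom=fields[0], strand=fields[5], dyad=start))
    return anchors


def write_gene_list(gene_ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in gene_ids:
            fh.write(f"{g}\n")


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-id-per-line gene list; duplicates collapse with a warning."""
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    unique = set(ids)
    if len(unique) < len(ids):
        warnings.warn(f"{path}: {len(ids) - len(unique)} duplicate gene ids collapsed")
    return unique


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()),
        str(path),
        "fasta",
    )


def write_chrom_sizes(chrom_lengths: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom/length table (.chrom.sizes or .fai work)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected at least 2 columns")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer length ({exc})")
    return sizes
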