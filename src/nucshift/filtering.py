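"""Read-pair filtering for mononucleosome-sized fragments.

A pair is kept iff it is concordant, both mates map to the same chromosome,
it is not ambiguously mapped, its insert size lies inside [min_insert,
max_insert] (bounds inclusive: 120 and 200 bp are *not* outside the range),
and neither mate carries more than ``max_mismatch`` mismatches.  Removal is
attributed to the first failing predicate in that order, so the per-class
report is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .records import FragmentRecord

REMOVAL_CLASSES = (
    "discordant",
    "inter_chromosomal",
    "ambiguous",
    "insert_out_of_range",
    "excess_mismatch",
)


@dataclass
class FilterReport:
    """Counts of kept pairs and removals attributed per class."""

    input_pairs: int = 0
    kept_pairs: int = 0
    removed: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in REMOVAL_CLASSES}
    )
    min_retained_insert: int | None = None
    max_retained_insert: int | None = None

    def check(self) -> None:
        if self.input_pairs != self.kept_pairs + sum(self.removed.values()):
            raise AssertionError("filter report does not partition the input")


def classify_pair(
    record: FragmentRecord,
    min_insert: int = 120,
    max_insert: int = 200,
    max_mismatch: int = 4,
) -> str | None:
    """Return the first failing removal class for a pair, or None if kept."""
    if not record.concordant:
        return "discordant"
    if record.chrom1 != record.chrom2:
        return "inter_chromosomal"
    if record.ambiguous:
        return "ambiguous"
    if not (min_insert <= record.template_length <= max_insert):
        return "insert_out_of_range"
    if record.nm1 > max_mismatch or record.nm2 > max_mismatch:
        return "excess_mismatch"
    return None


def filter_pairs(
    records: Sequence[FragmentRecord],
    min_insert: int = 120,
    max_insert: int = 200,
    max_mismatch: int = 4,
) -> tuple[list[FragmentRecord], FilterReport]:
    """Apply the pair filter, preserving input order among kept records."""
    report = FilterReport(input_pairs=len(records))
    kept: list[FragmentRecord] = []
    for index, record in enumerate(records):
        if record.concordant and record.chrom1 == record.chrom2 and record.end2 <= record.start1:
            raise ValueError(
                f"record {index} ({record.name}): concordant pair with template "
                f"end {record.end2} <= start {record.start1}"
            )
        failing = classify_pair(record, min_insert, max_insert, max_mismatch)
        if failing is None:
            kept.append(record)
            tlen = record.template_length
            if report.min_retained_insert is None or tlen < report.min_retained_insert:
                report.min_retained_insert = tlen
            if report.max_retained_insert is None or tlen > report.max_retained_insert:
                report.max_retained_insert = tlen
        else:
            report.removed[failing] += 1
    report.kept_pairs = len(kept)
    report.check()
    return kept, report


def report_to_table(report: FilterReport) -> pd.DataFrame:
    """Flatten a FilterReport to a two-column metric/value table."""
    rows = [("input_pairs", report.input_pairs), ("kept_pairs", report.kept_pairs)]
    rows += [(f"removed_{c}", report.removed[c]) for c in REMOVAL_CLASSES]
    rows += [
        ("min_retained_insert", -1 if report.min_retained_insert is None else report.min_retained_insert),
        ("max_retained_insert", -1 if report.max_retained_insert is None else report.max_retained_insert),
    ]
    return pd.DataFrame(rows, columns=["metric", "value"])


def write_report(report: FilterReport, path: str | Path) -> None:
    report_to_table(report).to_csv(path, sep="\t", index=False)
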