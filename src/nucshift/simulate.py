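"""Synthetic paired-end MNase-seq data with known promoter structure.

The generator lays out a toy multi-chromosome genome with evenly spaced,
non-overlapping genes.  Each gene contributes a phased nucleosome array
downstream of its +1 dyad (sources at +1, +1+spacing, +1+2*spacing, ...,
strand-oriented) and a weak nucleosome-depleted-region (NDR) source spread
uniformly over a window upstream of the +1 dyad.  Protected-fragment
midpoints are drawn from these sources; a uniform background source keeps
coverage nonzero between genes.

A "perturbed" condition models conditional depletion of a chromatin factor
that keeps promoters open: for a chosen subset of genes the NDR source weight
is raised by ``ndr_fill_effect``, so their promoters gain occupancy relative
to baseline.  Filter-failing read pairs (discordant, inter-chromosomal,
short/long insert, high-mismatch) are injected at configured rates with
ground-truth class labels, each failing exactly one filter predicate.

Everything is deterministic given ``SimulationConfig.seed``; the two
conditions use independent substreams of the same seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io
from .records import FragmentRecord, GeneAnchor

CONTAMINANT_CLASSES = (
    "discordant",
    "inter_chromosomal",
    "insert_short",
    "insert_long",
    "excess_mismatch",
)

CONDITIONS = ("baseline", "perturbed")

_ROMAN = (
    "I II III IV V VI VII VIII IX X XI XII XIII XIV XV XVI XVII XVIII XIX XX".split()
)


class SizingError(ValueError):
    """The requested gene count does not fit in the configured genome."""


def _chrom_name(i: int) -> str:
    return f"chr{_ROMAN[i]}" if i < len(_ROMAN) else f"chr{i + 1}"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic MNase-seq study.

    Defaults are the package's reference study conditions: 3000 genes on a
    16 x 400 kb genome, 500 of them (fraction 1/6) gaining NDR occupancy in
    the perturbed condition with a 5x NDR source weight (0.5 baseline + 2.0
    fill), and 2e5 read pairs per sample.  The baseline NDR weight of 0.5
    per gene (spread over the 141-bp NDR window, against point-like
    nucleosome sources of weight 1.0) puts the per-bp NDR trough at roughly
    a quarter of the +1 peak, comparable to promoter NDR depth in yeast
    MNase maps.
    """

    n_chromosomes: int = 16
    chrom_length: int = 400_000
    n_genes: int = 3000
    gene_footprint: int = 2000  # bp of genome reserved per gene
    flank: int = 1000  # min distance of any dyad from a chromosome end
    ndr_window: tuple[int, int] = (-160, -20)  # relative to +1 dyad, inclusive
    nucleosome_spacing: int = 165
    n_nucleosomes: int = 4  # phased array length downstream of +1
    dyad_jitter_sd: float = 10.0
    fragment_length_mean: float = 150.0
    fragment_length_sd: float = 15.0
    fragment_length_range: tuple[int, int] = (121, 199)
    read_length: int = 100
    n_fragments_per_sample: int = 200_000
    affected_gene_fraction: float = 1.0 / 6.0
    ndr_fill_effect: float = 2.0
    nucleosome_weight: float = 1.0
    ndr_weight: float = 0.5
    background_rate: float = 0.10  # fraction of clean fragments from background
    contaminant_rates: dict[str, float] = field(
        default_factory=lambda: {
            "discordant": 0.01,
            "inter_chromosomal": 0.005,
            "insert_short": 0.01,
            "insert_long": 0.01,
            "excess_mismatch": 0.005,
        }
    )
    seed: int = 101

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        rates = {c: self.contaminant_rates.get(c, 0.0) for c in CONTAMINANT_CLASSES}
        unknown = set(self.contaminant_rates) - set(CONTAMINANT_CLASSES)
        if unknown:
            raise ValueError(f"unknown contaminant classes: {sorted(unknown)}")
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"contaminant rate {name} must be in [0,1], got {value}")
        if sum(rates.values()) >= 1.0:
            raise ValueError("sum of contaminant rates must be < 1")
        if not 0.0 <= self.affected_gene_fraction <= 1.0:
            raise ValueError("affected_gene_fraction must be in [0,1]")
        if not 0.0 <= self.background_rate < 1.0:
            raise ValueError("background_rate must be in [0,1)")
        if self.nucleosome_spacing <= 0:
            raise ValueError("nucleosome_spacing must be > 0")
        if self.n_chromosomes < 1 or self.chrom_length < 2 * self.flank:
            raise ValueError("genome must have >=1 chromosome of length >= 2*flank")
        if rates["inter_chromosomal"] > 0 and self.n_chromosomes < 2:
            raise ValueError("inter_chromosomal contaminants require >= 2 chromosomes")
        lo, hi = self.fragment_length_range
        if not 0 < lo <= hi:
            raise ValueError("fragment_length_range must satisfy 0 < lo <= hi")
        # genome capacity: per-chromosome check happens in make_annotation,
        # but the aggregate constraint is cheap to state here
        usable = self.n_chromosomes * (self.chrom_length - 2 * self.flank)
        if self.n_genes * self.gene_footprint > usable:
            raise SizingError(
                f"{self.n_genes} genes x {self.gene_footprint} bp footprint exceed "
                f"usable genome ({usable} bp after {self.flank} bp flanks); "
                "increase chrom_length/n_chromosomes or reduce n_genes"
            )

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {_chrom_name(i): self.chrom_length for i in range(self.n_chromosomes)}

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """What the generator knows and the analysis should recover."""

    affected_gene_ids: frozenset[str]
    ndr_weights: pd.DataFrame  # columns: gene_id, baseline, perturbed
    labels: list[str]  # per emitted record: "clean" or a contaminant class


def _gene_counts_per_chrom(config: SimulationConfig) -> list[int]:
    base, extra = divmod(config.n_genes, config.n_chromosomes)
    counts = [base + (1 if i < extra else 0) for i in range(config.n_chromosomes)]
    usable = config.chrom_length - 2 * config.flank
    for i, count in enumerate(counts):
        if count * config.gene_footprint > usable:
            raise SizingError(
                f"{count} genes x {config.gene_footprint} bp do not fit on "
                f"{_chrom_name(i)} ({usable} usable bp)"
            )
    return counts


def make_annotation(config: SimulationConfig) -> tuple[dict[str, str], list[GeneAnchor]]:
    """Build the toy genome and the +1-dyad gene annotation.

    Genes occupy disjoint ``gene_footprint``-bp slots with the dyad at the
    slot center, at least ``flank`` bp from chromosome ends; strands
    alternate.  Sequence content is random and carries no signal (fragment
    coordinates are simulated directly), but gives the pipeline a real FASTA
    to work from.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    bases = np.frombuffer(b"ACGT", dtype="S1")
    genome: dict[str, str] = {}
    anchors: list[GeneAnchor] = []
    counts = _gene_counts_per_chrom(config)
    gene_index = 0
    width = len(str(max(config.n_genes, 1) - 1)) if config.n_genes else 1
    for i in range(config.n_chromosomes):
        chrom = _chrom_name(i)
        seq = bases[rng.integers(0, 4, size=config.chrom_length)]
        genome[chrom] = seq.tobytes().decode("ascii")
        for j in range(counts[i]):
            dyad = config.flank + j * config.gene_footprint + config.gene_footprint // 2
            strand = "+" if gene_index % 2 == 0 else "-"
            anchors.append(
                GeneAnchor(
                    gene_id=f"g{gene_index:0{max(width, 4)}d}",
                    chrom=chrom,
                    strand=strand,
                    dyad=dyad,
                )
            )
            gene_index += 1
    return genome, anchors


def affected_genes(config: SimulationConfig, anchors: Sequence[GeneAnchor]) -> frozenset[str]:
    """The gene subset whose NDRs fill in the perturbed condition.

    Drawn from a dedicated substream of the seed so it is identical across
    conditions and independent of fragment sampling.
    """
    n_affected = round(config.affected_gene_fraction * len(anchors))
    rng = np.random.default_rng([config.seed, 1])
    ids = [a.gene_id for a in anchors]
    chosen = rng.choice(len(ids), size=n_affected, replace=False)
    return frozenset(ids[i] for i in chosen)


def source_table(
    config: SimulationConfig,
    anchors: Sequence[GeneAnchor],
    condition: str,
    affected: frozenset[str] | None = None,
) -> pd.DataFrame:
    """Midpoint source table: one row per nucleosome / NDR / background source.

    Columns: gene_id (background rows use ''), chrom, kind (nuc|ndr|bg),
    lo, hi (inclusive sampling bounds; nuc rows hold the dyad center in both),
    weight.  Expected per-source fragment shares are weight / sum(weight) —
    the exact object on which effect monotonicity holds.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    if affected is None:
        affected = affected_genes(config, anchors)
    rows = []
    wlo, whi = config.ndr_window
    for a in anchors:
        sign = 1 if a.strand == "+" else -1
        for k in range(config.n_nucleosomes):
            center = a.dyad + sign * k * config.nucleosome_spacing
            rows.append((a.gene_id, a.chrom, "nuc", center, center, config.nucleosome_weight))
        ndr_w = config.ndr_weight
        if condition == "perturbed" and a.gene_id in affected:
            ndr_w += config.ndr_fill_effect
        # strand-oriented NDR interval, inclusive bounds
        g_lo, g_hi = sorted((a.dyad + sign * wlo, a.dyad + sign * whi))
        rows.append((a.gene_id, a.chrom, "ndr", g_lo, g_hi, ndr_w))
    gene_weight = sum(r[5] for r in rows)
    if config.background_rate > 0 and gene_weight > 0:
        bg_total = gene_weight * config.background_rate / (1.0 - config.background_rate)
        per_chrom = bg_total / config.n_chromosomes
        for i in range(config.n_chromosomes):
            rows.append(("", _chrom_name(i), "bg", 0, config.chrom_length - 1, per_chrom))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "kind", "lo", "hi", "weight"])


def _truncated_normal_lengths(
    rng: np.random.Generator, n: int, config: SimulationConfig
) -> np.ndarray:
    """Integer fragment lengths ~ round(Normal) truncated by rejection."""
    lo, hi = config.fragment_length_range
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = np.rint(
            rng.normal(config.fragment_length_mean, config.fragment_length_sd, size=n - filled)
        ).astype(np.int64)
        ok = draw[(draw >= lo) & (draw <= hi)]
        out[filled : filled + len(ok)] = ok
        filled += len(ok)
    return out


def simulate_fragments(
    config: SimulationConfig,
    anchors: Sequence[GeneAnchor],
    condition: str = "baseline",
) -> tuple[list[FragmentRecord], GroundTruth]:
    """Draw one sample of aligned read pairs for ``condition``.

    Returns coordinate-sorted records plus a :class:`GroundTruth` whose
    ``labels`` list is aligned with the returned record order.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    config.validate()
    affected = affected_genes(config, anchors)
    sources = source_table(config, anchors, condition, affected)
    rng = np.random.default_rng([config.seed, 2 + CONDITIONS.index(condition)])

    n_total = config.n_fragments_per_sample
    rates = [config.contaminant_rates.get(c, 0.0) for c in CONTAMINANT_CLASSES]
    probs = rates + [1.0 - sum(rates)]
    class_counts = rng.multinomial(n_total, probs)
    n_by_class = dict(zip(CONTAMINANT_CLASSES, class_counts[:-1]))
    n_clean = int(class_counts[-1])

    chrom_names = list(config.chrom_lengths)
    clen = config.chrom_length
    raw: list[tuple[FragmentRecord, str]] = []
    serial = 0

    def next_name() -> str:
        nonlocal serial
        name = f"frag{serial:07d}"
        serial += 1
        return name

    def concordant_record(chrom: str, start: int, length: int, nm1: int = 0, nm2: int = 0,
                          concordant: bool = True) -> FragmentRecord:
        start = int(np.clip(start, 0, clen - length))
        end = start + length
        rl = min(length, config.read_length)
        return FragmentRecord(
            chrom1=chrom, start1=start, end1=start + rl,
            chrom2=chrom, start2=end - rl, end2=end,
            name=next_name(), concordant=concordant, ambiguous=False,
            nm1=nm1, nm2=nm2,
        )

    # --- clean fragments --------------------------------------------------
    if n_clean > 0 and len(sources) > 0:
        weights = sources["weight"].to_numpy(float)
        picks = rng.choice(len(sources), size=n_clean, p=weights / weights.sum())
        kind = sources["kind"].to_numpy()[picks]
        lo = sources["lo"].to_numpy(np.int64)[picks]
        hi = sources["hi"].to_numpy(np.int64)[picks]
        chrom_of = sources["chrom"].to_numpy()[picks]
        pos = np.empty(n_clean, dtype=np.int64)
        is_nuc = kind == "nuc"
        pos[is_nuc] = np.rint(
            lo[is_nuc] + rng.normal(0.0, config.dyad_jitter_sd, size=int(is_nuc.sum()))
        ).astype(np.int64)
        flat = ~is_nuc  # ndr and bg sources sample uniformly on [lo, hi]
        pos[flat] = rng.integers(lo[flat], hi[flat] + 1)
        lengths = _truncated_normal_lengths(rng, n_clean, config)
        starts = pos - lengths // 2
        for i in range(n_clean):
            raw.append((concordant_record(chrom_of[i], starts[i], int(lengths[i])), "clean"))

    # --- contaminants: each fails exactly its own filter predicate --------
    for _ in range(n_by_class["discordant"]):
        chrom = chrom_names[rng.integers(len(chrom_names))]
        length = int(rng.integers(120, 201))
        start = int(rng.integers(config.flank, clen - config.flank))
        raw.append((concordant_record(chrom, start, length, concordant=False), "discordant"))
    for _ in range(n_by_class["inter_chromosomal"]):
        i1, i2 = rng.choice(len(chrom_names), size=2, replace=False)
        s1 = int(rng.integers(config.flank, clen - config.flank))
        s2 = int(rng.integers(config.flank, clen - config.flank))
        rl = config.read_length
        raw.append((
            FragmentRecord(
                chrom1=chrom_names[i1], start1=s1, end1=s1 + rl,
                chrom2=chrom_names[i2], start2=s2, end2=s2 + rl,
                name=next_name(), concordant=True, ambiguous=False, nm1=0, nm2=0,
            ),
            "inter_chromosomal",
        ))
    for _ in range(n_by_class["insert_short"]):
        chrom = chrom_names[rng.integers(len(chrom_names))]
        length = int(rng.integers(60, 120))
        start = int(rng.integers(config.flank, clen - config.flank))
        raw.append((concordant_record(chrom, start, length), "insert_short"))
    for _ in range(n_by_class["insert_long"]):
        chrom = chrom_names[rng.integers(len(chrom_names))]
        length = int(rng.integers(201, 281))
        start = int(rng.integers(config.flank, clen - config.flank))
        raw.append((concordant_record(chrom, start, length), "insert_long"))
    for _ in range(n_by_class["excess_mismatch"]):
        chrom = chrom_names[rng.integers(len(chrom_names))]
        length = int(rng.integers(120, 201))
        start = int(rng.integers(config.flank, clen - config.flank))
        nm_bad = int(rng.integers(5, 9))
        nm_ok = int(rng.integers(0, 5))
        if rng.integers(2):
            nm1, nm2 = nm_bad, nm_ok
        else:
            nm1, nm2 = nm_ok, nm_bad
        raw.append((concordant_record(chrom, start, length, nm1=nm1, nm2=nm2), "excess_mismatch"))

    chrom_order = {c: i for i, c in enumerate(chrom_names)}
    raw.sort(key=lambda item: (chrom_order[item[0].chrom1], item[0].start1,
                               item[0].end2, item[0].name))
    records = [r for r, _ in raw]
    labels = [lab for _, lab in raw]

    base_tab = source_table(config, anchors, "baseline", affected)
    pert_tab = source_table(config, anchors, "perturbed", affected)

    def ndr_by_gene(tab: pd.DataFrame) -> pd.Series:
        ndr = tab[tab["kind"] == "ndr"]
        return ndr.set_index("gene_id")["weight"]

    weights = pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in anchors],
        }
    )
    weights["baseline"] = ndr_by_gene(base_tab).reindex(weights["gene_id"]).to_numpy()
    weights["perturbed"] = ndr_by_gene(pert_tab).reindex(weights["gene_id"]).to_numpy()

    truth = GroundTruth(affected_gene_ids=affected, ndr_weights=weights, labels=labels)
    return records, truth


def write_sample(
    records: Sequence[FragmentRecord],
    path: str | Path,
    dialect: str = "BEDPE",
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    """Write a simulated sample; see :func:`nucshift.io.write_fragments`."""
    io.write_fragments(records, path, dialect=dialect, chrom_lengths=chrom_lengths)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Ground truth NDR weights and affected flags as a TSV."""
    table = truth.ndr_weights.copy()
    table["affected"] = table["gene_id"].isin(truth.affected_gene_ids)
    table.to_csv(path, sep="\t", index=False)
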