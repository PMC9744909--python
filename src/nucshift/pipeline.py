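"""End-to-end driver: filter -> tracks -> stats -> blacklist -> heatmaps -> profiles.

A :class:`PipelineConfig` (usually loaded from YAML) declares samples,
comparisons and parameters; :func:`run_pipeline` executes every stage and
writes all intermediate artifacts plus a provenance record, so reruns with
an identical config reproduce byte-identical numeric outputs.

Config file layout::

    samples:
      wt:     {path: wt.bedpe,     condition: WT}
      degron: {path: degron.bedpe, condition: Degron}
    comparisons:
      - {name: degron_vs_wt, test: degron, ref: wt}
      - {name: rescue_vs_wt, test: rescue, ref: wt, baseline: null}
    anchors: anchors.bed
    chrom_sizes: genome.chrom.sizes
    # optional: filter/track/analysis parameter overrides, gene_list, outdir
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, differential, io, matrices, tracks
from .filtering import filter_pairs, write_report

log = logging.getLogger(__name__)


@dataclass
class SampleSpec:
    sample_id: str
    path: str
    condition: str = ""
    dialect: str | None = None  # inferred from suffix when None


@dataclass
class ComparisonSpec:
    name: str
    test: str  # sample id
    ref: str  # sample id
    baseline: str | None = None  # name of another comparison


@dataclass
class PipelineConfig:
    samples: dict[str, SampleSpec]
    comparisons: list[ComparisonSpec]
    anchors: str
    chrom_sizes: str
    outdir: str = "nucshift_out"
    min_insert: int = 120
    max_insert: int = 200
    max_mismatch: int = 4
    width: int = tracks.DEFAULT_WIDTH
    smooth_width: int = tracks.DEFAULT_SMOOTH_WIDTH
    target_count: float = tracks.DEFAULT_TARGET_COUNT
    window: tuple[int, int] = differential.DEFAULT_WINDOW
    blacklist_threshold: float = differential.DEFAULT_BLACKLIST_THRESHOLD
    top_n: int = differential.DEFAULT_TOP_N
    flank: int = matrices.DEFAULT_FLANK
    pseudocount: float = matrices.DEFAULT_PSEUDOCOUNT
    ordering_comparison: str | None = None  # default: first comparison
    top_comparison: str | None = None  # comparison supplying the top-N set
    gene_list: str | None = None  # optional extra gene set for profiles
    write_tracks: bool = True
    write_pngs: bool = True
    seed: int = 0  # recorded for provenance; the pipeline itself is deterministic

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        samples = {
            sid: SampleSpec(sample_id=sid, **spec)
            for sid, spec in (data.pop("samples", {}) or {}).items()
        }
        comparisons = [ComparisonSpec(**c) for c in data.pop("comparisons", []) or []]
        if "window" in data:
            data["window"] = tuple(data["window"])
        config = cls(samples=samples, comparisons=comparisons, **data)
        config.validate()
        return config

    def validate(self) -> None:
        if not self.samples:
            raise ValueError("config declares no samples")
        if not self.comparisons:
            raise ValueError("config declares no comparisons")
        names = [c.name for c in self.comparisons]
        if len(set(names)) != len(names):
            raise ValueError("comparison names are not unique")
        by_name = {c.name: c for c in self.comparisons}
        for c in self.comparisons:
            for sid in (c.test, c.ref):
                if sid not in self.samples:
                    raise ValueError(f"comparison {c.name}: unknown sample {sid!r}")
            if c.baseline is not None and c.baseline not in by_name:
                raise ValueError(f"comparison {c.name}: unknown baseline {c.baseline!r}")
        # baseline graph must be acyclic
        for c in self.comparisons:
            seen = {c.name}
            cursor = c.baseline
            while cursor is not None:
                if cursor in seen:
                    raise ValueError(f"baseline cycle involving comparison {cursor!r}")
                seen.add(cursor)
                cursor = by_name[cursor].baseline
        for path_attr in ("anchors", "chrom_sizes", "gene_list"):
            value = getattr(self, path_attr)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{path_attr} file not found: {value}")
        for spec in self.samples.values():
            if not Path(spec.path).exists():
                raise FileNotFoundError(f"sample {spec.sample_id}: file not found: {spec.path}")
        ordering = self.ordering_comparison or self.comparisons[0].name
        if ordering not in by_name:
            raise ValueError(f"ordering_comparison {ordering!r} is not a comparison")
        top = self.top_comparison or ordering
        if top not in by_name:
            raise ValueError(f"top_comparison {top!r} is not a comparison")

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["samples"] = {k: dataclasses.asdict(v) for k, v in self.samples.items()}
        data["comparisons"] = [dataclasses.asdict(c) for c in self.comparisons]
        data["window"] = list(self.window)
        return data

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class PipelineResult:
    outdir: Path
    stats: dict[str, object] = field(default_factory=dict)  # comparison -> GeneStatTable
    blacklists: dict[str, set[str]] = field(default_factory=dict)
    merged_blacklist: set[str] = field(default_factory=set)
    ordering: list[str] = field(default_factory=list)
    top_genes: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage of the analysis for every declared comparison."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(outdir=outdir)

    chrom_lengths = io.read_chrom_sizes(config.chrom_sizes)
    anchors = io.read_anchors(config.anchors)
    log.info("loaded %d anchors on %d chromosomes", len(anchors), len(chrom_lengths))

    # stage 1-2: filter and build one track per sample
    sample_tracks: dict[str, tracks.OccupancyTrack] = {}
    for sid, spec in config.samples.items():
        records = io.read_fragments(spec.path, spec.dialect)
        kept, report = filter_pairs(
            records,
            min_insert=config.min_insert,
            max_insert=config.max_insert,
            max_mismatch=config.max_mismatch,
        )
        log.info("sample %s: %d/%d pairs kept", sid, report.kept_pairs, report.input_pairs)
        report_path = outdir / f"{sid}.filter_report.tsv"
        write_report(report, report_path)
        result.outputs[f"filter_report:{sid}"] = str(report_path)
        midpoints = tracks.fragment_midpoints(kept)
        track = tracks.build_track(
            midpoints,
            chrom_lengths,
            width=config.width,
            smooth_width=config.smooth_width,
            target_count=config.target_count,
        )
        sample_tracks[sid] = track
        if config.write_tracks:
            track_path = outdir / f"{sid}.occupancy.bedgraph"
            tracks.write_track(track, track_path)
            result.outputs[f"track:{sid}"] = str(track_path)

    # stage 3: per-comparison window statistics and blacklists
    for comp in config.comparisons:
        stats = differential.window_stat(
            sample_tracks[comp.test],
            sample_tracks[comp.ref],
            anchors,
            window=config.window,
            comparison=comp.name,
        )
        blacklist = differential.blacklist_genes(stats, threshold=config.blacklist_threshold)
        stats = differential.annotate_ranks(stats, blacklist=blacklist)
        result.stats[comp.name] = stats
        result.blacklists[comp.name] = blacklist
        stats_path = outdir / f"{comp.name}.stats.tsv"
        differential.write_stats(stats, stats_path)
        result.outputs[f"stats:{comp.name}"] = str(stats_path)
        bl_path = outdir / f"{comp.name}.blacklist.txt"
        io.write_gene_list(sorted(blacklist), bl_path)
        result.outputs[f"blacklist:{comp.name}"] = str(bl_path)
        log.info("comparison %s: %d genes blacklisted", comp.name, len(blacklist))

    # stage 4: merged blacklist across all comparisons
    result.merged_blacklist = differential.merge_blacklists(list(result.blacklists.values()))
    merged_path = outdir / "merged_blacklist.txt"
    io.write_gene_list(sorted(result.merged_blacklist), merged_path)
    result.outputs["merged_blacklist"] = str(merged_path)
    log.info("merged blacklist: %d genes", len(result.merged_blacklist))

    # stage 5: ordering from the designated comparison, applied to all heatmaps
    ordering_name = config.ordering_comparison or config.comparisons[0].name
    result.ordering = differential.order_genes(result.stats[ordering_name])
    ordering_path = outdir / "gene_ordering.txt"
    io.write_gene_list(result.ordering, ordering_path)
    result.outputs["ordering"] = str(ordering_path)

    # stage 6: differential heatmap per comparison
    for comp in config.comparisons:
        test_m = matrices.anchored_matrix(
            sample_tracks[comp.test], anchors, flank=config.flank, label=comp.test
        )
        ref_m = matrices.anchored_matrix(
            sample_tracks[comp.ref], anchors, flank=config.flank, label=comp.ref
        )
        ratio = matrices.log2_ratio_matrix(
            test_m, ref_m, pseudocount=config.pseudocount, label=comp.name
        )
        png = (outdir / f"{comp.name}.heatmap.png") if config.write_pngs else None
        heat = matrices.assemble_heatmap(
            ratio, result.ordering, blacklist=result.merged_blacklist, png_path=png
        )
        heat_path = outdir / f"{comp.name}.heatmap.tsv"
        matrices.write_matrix(heat, heat_path)
        result.outputs[f"heatmap:{comp.name}"] = str(heat_path)
        if png is not None:
            result.outputs[f"heatmap_png:{comp.name}"] = str(png)

    # stage 7: top-N promoters with optional baseline subtraction
    top_name = config.top_comparison or ordering_name
    top_comp = next(c for c in config.comparisons if c.name == top_name)
    baseline_stats = result.stats[top_comp.baseline] if top_comp.baseline else None
    result.top_genes = differential.top_n_genes(
        result.stats[top_name], n=config.top_n, baseline_stats=baseline_stats
    )
    top_path = outdir / f"top{config.top_n}_genes.txt"
    io.write_gene_list(result.top_genes, top_path)
    result.outputs["top_genes"] = str(top_path)

    # stage 8: average profiles (top-N set, all genes, optional external list)
    track_by_label = {
        (spec.condition or sid): sample_tracks[sid] for sid, spec in config.samples.items()
    }
    profile_sets: dict[str, set[str] | None] = {
        f"top{config.top_n}": set(result.top_genes),
        "all_genes": None,
    }
    if config.gene_list:
        profile_sets["gene_list"] = io.read_gene_list(config.gene_list)
    for set_name, gene_set in profile_sets.items():
        profile = matrices.average_profile(
            track_by_label, anchors, gene_set=gene_set, flank=config.flank
        )
        prof_path = outdir / f"profile_{set_name}.tsv"
        profile.to_csv(prof_path, sep="\t", index=False, float_format="%.10g")
        result.outputs[f"profile:{set_name}"] = str(prof_path)
        if config.write_pngs:
            png_path = outdir / f"profile_{set_name}.png"
            matrices.plot_profiles(profile, png_path, window=config.window)
            result.outputs[f"profile_png:{set_name}"] = str(png_path)

    # provenance: everything needed to rerun
    provenance = {
        "nucshift_version": __version__,
        "config": config.to_dict(),
        "config_sha256": config.config_hash(),
        "seed": config.seed,
        "outputs": dict(sorted(result.outputs.items())),
    }
    prov_path = outdir / "provenance.json"
    with open(prov_path, "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    result.outputs["provenance"] = str(prov_path)
    return result
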