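# nucshift

Differential promoter nucleosome occupancy analysis from paired-end
MNase-seq fragments.

MNase digestion of crosslinked chromatin leaves ~150 bp of
nucleosome-protected DNA; sequencing both ends of those fragments places
each surviving nucleosome on the genome, with the fragment midpoint
estimating the nucleosome dyad. `nucshift` turns aligned MNase read pairs
into normalized occupancy tracks and asks, gene by gene, whether the
nucleosome-depleted region (NDR) upstream of the +1 nucleosome gains
occupancy in a test condition (for example after conditional depletion of a
chromatin factor that keeps promoters open) relative to a wild-type
reference. It is aimed at chromatin and regulatory-genomics groups running
promoter-architecture perturbation experiments in yeast-scale genomes.

## Method

For each sample:

1. **Filter** read pairs: keep a pair iff it is concordant, both mates map
   to the same chromosome, it is not ambiguously mapped, its insert size
   lies in [120, 200] bp (bounds inclusive) and neither mate has more than
   4 mismatches. Removals are attributed to the first failing rule, so the
   per-class report is deterministic.
2. **Occupancy track.** Each kept fragment is reduced to its midpoint *m*
   (dyad estimate) and extended over the footprint window [*m*−20, *m*+20).
   The summed coverage is scaled so every library corresponds to
   10,000,000 effective fragments, then smoothed with a centered 20-bp
   moving average, at 1-bp output resolution.

For each comparison (test vs reference condition), with each gene anchored
at its +1 nucleosome dyad and oriented by strand:

3. **Window statistic.** s(g) = mean over positions −150..−50 (the NDR
   side, upstream of the +1 dyad) of (test − reference) occupancy.
4. **Blacklist.** Genes that do not achieve more than a +0.6 occupancy
   difference are removed from heatmaps; per-comparison blacklists merge
   without duplication.
5. **Ranking / top-N.** Genes are ordered by decreasing s(g) (one
   designated comparison's order applies to every heatmap); the top 500
   promoters are selected, optionally after subtracting a per-gene baseline
   statistic from a control comparison.
6. **Outputs.** log2-ratio heatmap matrices centered on the +1 dyad,
   average occupancy profiles over gene sets, per-gene statistic tables,
   and a provenance record — all as plain TSV/JSON plus decorative PNGs.

A synthetic paired-end MNase-seq generator (`nucshift.simulate`) emulates
the data structure this analysis assumes — phased nucleosome arrays
downstream of +1 dyads, promoter NDRs, a perturbed condition in which a
known gene subset's NDRs fill in, and injected filter-failing read pairs —
with full ground truth, so the entire pipeline is testable without any
sequencing download.

## Worked example

```python
from nucshift import simulate, filtering, tracks, differential

cfg = simulate.SimulationConfig(n_chromosomes=2, chrom_length=60_000,
                                n_genes=40, n_fragments_per_sample=8000,
                                seed=5)
_, anchors = simulate.make_annotation(cfg)
built = {}
for cond in simulate.CONDITIONS:          # "baseline", "perturbed"
    records, truth = simulate.simulate_fragments(cfg, anchors, cond)
    kept, report = filtering.filter_pairs(records)
    print(cond, "kept", report.kept_pairs, "of", report.input_pairs)
    built[cond] = tracks.build_track(tracks.fragment_midpoints(kept),
                                     cfg.chrom_lengths)

stats = differential.window_stat(built["perturbed"], built["baseline"], anchors)
top = differential.top_n_genes(stats, 10)
print("top10 recovered", len(set(top) & truth.affected_gene_ids), "of",
      len(truth.affected_gene_ids), "perturbed genes")
```

prints

```
baseline kept 7680 of 8000
perturbed kept 7702 of 8000
top10 recovered 7 of 7
```

i.e. ~4% of pairs fail the filter (matching the injected contaminant
rates), and the ten highest promoter occupancy gains include all seven
genes whose NDRs were filled by the simulated perturbation; their mean
window statistic (≈2.6×10⁴ normalized occupancy units) stands far above
the unperturbed genes (≈−75).

The same analysis runs from the shell: `nucshift simulate` writes a
synthetic study (FASTA, BED6 anchors, BEDPE/BAM samples, ground truth),
and `nucshift run --config pipeline.yaml` executes
filter → tracks → statistics → blacklists → heatmaps → top-N → profiles
for every declared comparison. Individual stages are available as
`nucshift filter|track|stats|heatmap|profile`.

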