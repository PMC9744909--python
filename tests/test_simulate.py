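"""Synthetic MNase-seq generator: construction constraints, determinism,
contaminant class rates and the NDR-fill perturbation."""

import numpy as np
import pandas as pd
import pytest

from nucshift import SimulationConfig, filtering, simulate
from nucshift.simulate import SizingError


def ndr_fragment_counts(records, truth, anchors, config):
    """Brute-force count of fragment midpoints inside each gene's NDR window."""
    wlo, whi = config.ndr_window
    counts = {}
    by_chrom = {}
    for r, lab in zip(records, truth.labels):
        if lab == "clean":
            by_chrom.setdefault(r.chrom, []).append(r.midpoint)
    for chrom in by_chrom:
        by_chrom[chrom] = np.sort(np.array(by_chrom[chrom]))
    for a in anchors:
        sign = 1 if a.strand == "+" else -1
        lo, hi = sorted((a.dyad + sign * wlo, a.dyad + sign * whi))
        mids = by_chrom.get(a.chrom, np.array([]))
        counts[a.gene_id] = int(
            np.searchsorted(mids, hi, "right") - np.searchsorted(mids, lo, "left")
        )
    return counts


class TestMakeAnnotation:
    def test_anchor_count_spacing_and_flanks(self):
        config = SimulationConfig(
            n_chromosomes=1, chrom_length=100_000, n_genes=10,
            n_fragments_per_sample=100,
            contaminant_rates={"inter_chromosomal": 0.0},
        )
        _, anchors = simulate.make_annotation(config)
        assert len(anchors) == 10
        dyads = sorted(a.dyad for a in anchors)
        assert all(b - a >= config.gene_footprint for a, b in zip(dyads, dyads[1:]))
        assert all(config.flank <= a.dyad <= config.chrom_length - config.flank
                   for a in anchors)

    def test_deterministic_for_fixed_seed(self, small_config):
        g1, a1 = simulate.make_annotation(small_config)
        g2, a2 = simulate.make_annotation(small_config)
        assert g1 == g2
        assert a1 == a2

    def test_zero_genes_gives_empty_annotation(self):
        config = SimulationConfig(
            n_chromosomes=1, chrom_length=10_000, n_genes=0,
            n_fragments_per_sample=10,
            contaminant_rates={"inter_chromosomal": 0.0},
        )
        genome, anchors = simulate.make_annotation(config)
        assert anchors == []
        assert len(genome) == 1 and len(next(iter(genome.values()))) == 10_000

    def test_genome_too_small_raises_sizing_error(self):
        with pytest.raises(SizingError, match="footprint"):
            SimulationConfig(n_chromosomes=1, chrom_length=10_000, n_genes=100,
                             contaminant_rates={})


class TestSimulateFragments:
    def test_contaminant_free_sample_is_all_clean(self):
        config = SimulationConfig(
            n_chromosomes=1, chrom_length=100_000, n_genes=10,
            n_fragments_per_sample=10_000,
            contaminant_rates={c: 0.0 for c in simulate.CONTAMINANT_CLASSES},
        )
        _, anchors = simulate.make_annotation(config)
        records, truth = simulate.simulate_fragments(config, anchors, "baseline")
        assert len(records) == 10_000
        assert set(truth.labels) == {"clean"}
        lo, hi = config.fragment_length_range
        assert all(lo <= r.template_length <= hi for r in records)
        assert all(r.nm1 == 0 and r.nm2 == 0 for r in records)

    def test_records_sorted_and_deterministic(self, small_config, small_study):
        records, truth = small_study["samples"]["baseline"]
        keys = [(r.chrom1, r.start1) for r in records]
        # chromosome blocks in genome order, positions nondecreasing within
        chroms = list(small_config.chrom_lengths)
        order = {c: i for i, c in enumerate(chroms)}
        assert keys == sorted(keys, key=lambda k: (order[k[0]], k[1]))
        again, truth2 = simulate.simulate_fragments(
            small_config, small_study["anchors"], "baseline"
        )
        assert again == records
        assert truth2.labels == truth.labels

    def test_contaminant_rates_within_three_binomial_se(self, small_config, small_study):
        records, truth = small_study["samples"]["baseline"]
        n = len(records)
        labels = pd.Series(truth.labels)
        for cls, rate in small_config.contaminant_rates.items():
            observed = (labels == cls).sum()
            se = np.sqrt(rate * (1 - rate) * n)
            assert abs(observed - rate * n) <= 3 * se, (cls, observed, rate * n)

    def test_affected_set_size_and_membership(self, small_config, small_study):
        truth = small_study["samples"]["perturbed"][1]
        all_ids = {a.gene_id for a in small_study["anchors"]}
        expected = round(small_config.affected_gene_fraction * small_config.n_genes)
        assert len(truth.affected_gene_ids) == expected
        assert truth.affected_gene_ids <= all_ids

    def test_zero_effect_gives_null_ndr_difference(self):
        """With ndr_fill_effect=0 the conditions differ only by sampling noise."""
        config = SimulationConfig(
            n_chromosomes=2, chrom_length=100_000, n_genes=80,
            n_fragments_per_sample=40_000, ndr_fill_effect=0.0, seed=31,
        )
        _, anchors = simulate.make_annotation(config)
        totals = {}
        for cond in simulate.CONDITIONS:
            records, truth = simulate.simulate_fragments(config, anchors, cond)
            counts = ndr_fragment_counts(records, truth, anchors, config)
            totals[cond] = sum(counts[g] for g in truth.affected_gene_ids)
        # two-sample difference in affected-gene NDR fragment totals,
        # compared against the Poisson/binomial standard error of the totals
        diff = totals["perturbed"] - totals["baseline"]
        se = np.sqrt(totals["perturbed"] + totals["baseline"])
        assert abs(diff) <= 4 * se

    def test_large_effect_raises_affected_ndr_counts(self):
        """Affected genes accumulate more NDR fragments than unaffected ones,
        verified by direct counting over the emitted records."""
        config = SimulationConfig(seed=17)  # defaults: 5x NDR weight, 2e5 pairs
        _, anchors = simulate.make_annotation(config)
        records, truth = simulate.simulate_fragments(config, anchors, "perturbed")
        counts = ndr_fragment_counts(records, truth, anchors, config)
        aff = truth.affected_gene_ids
        mean_aff = np.mean([counts[g] for g in aff])
        mean_un = np.mean([c for g, c in counts.items() if g not in aff])
        assert mean_aff > mean_un

    def test_effect_monotone_in_source_weight_table(self, small_config):
        """Raising ndr_fill_effect never lowers any affected gene's expected
        NDR fragment share (checked exactly on the source-weight table)."""
        _, anchors = simulate.make_annotation(small_config)
        affected = simulate.affected_genes(small_config, anchors)
        shares = []
        for effect in (0.0, 0.5, 1.0, 2.0, 4.0):
            config = small_config.replace(ndr_fill_effect=effect)
            tab = simulate.source_table(config, anchors, "perturbed", affected)
            ndr = tab[(tab["kind"] == "ndr") & tab["gene_id"].isin(affected)]
            shares.append(ndr.set_index("gene_id")["weight"] / tab["weight"].sum())
        for prev, cur in zip(shares, shares[1:]):
            assert (cur.to_numpy() >= prev.to_numpy()).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="sum of contaminant rates"):
            SimulationConfig(contaminant_rates={"discordant": 0.6, "insert_short": 0.5})
        with pytest.raises(ValueError, match="affected_gene_fraction"):
            SimulationConfig(affected_gene_fraction=1.5)
        with pytest.raises(ValueError, match="condition"):
            config = SimulationConfig(n_genes=10, n_chromosomes=1,
                                      chrom_length=50_000, n_fragments_per_sample=10,
                                      contaminant_rates={})
            _, anchors = simulate.make_annotation(config)
            simulate.simulate_fragments(config, anchors, "mutant")


class TestWriteSample:
    def test_bedpe_round_trip_identity(self, tmp_path, small_study):
        from nucshift import io

        records = small_study["samples"]["baseline"][0][:1000]
        path = tmp_path / "sample.bedpe"
        simulate.write_sample(records, path)
        assert io.read_fragments(path) == records

    def test_bam_round_trip_identity(self, tmp_path, small_config, small_study):
        from nucshift import io

        records = small_study["samples"]["baseline"][0][:1000]
        path = tmp_path / "sample.bam"
        simulate.write_sample(records, path, dialect="BAM",
                              chrom_lengths=small_config.chrom_lengths)
        back = io.read_fragments(path)
        assert sorted(back, key=lambda r: r.name) == sorted(records, key=lambda r: r.name)

    def test_empty_sample_is_valid_file_with_header(self, tmp_path):
        from nucshift import io

        path = tmp_path / "empty.bedpe"
        simulate.write_sample([], path)
        text = path.read_text()
        assert text.startswith("#")
        assert io.read_fragments(path) == []

    def test_bedpe_and_bam_give_identical_filter_outcomes(self, tmp_path, small_config, small_study):
        from nucshift import io

        records = small_study["samples"]["perturbed"][0][:2000]
        p_bedpe = tmp_path / "s.bedpe"
        p_bam = tmp_path / "s.bam"
        simulate.write_sample(records, p_bedpe)
        simulate.write_sample(records, p_bam, dialect="BAM",
                              chrom_lengths=small_config.chrom_lengths)
        kept1, rep1 = filtering.filter_pairs(io.read_fragments(p_bedpe))
        kept2, rep2 = filtering.filter_pairs(io.read_fragments(p_bam))
        assert rep1.removed == rep2.removed
        assert sorted(r.name for r in kept1) == sorted(r.name for r in kept2)
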