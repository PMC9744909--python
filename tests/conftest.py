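"""Shared fixtures: small synthetic studies generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from nucshift import SimulationConfig, filtering, simulate, tracks


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast two-chromosome study used by most unit tests."""
    return SimulationConfig(
        n_chromosomes=2,
        chrom_length=60_000,
        n_genes=40,
        n_fragments_per_sample=20_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """Annotation plus baseline and perturbed samples for the small config."""
    genome, anchors = simulate.make_annotation(small_config)
    samples = {
        cond: simulate.simulate_fragments(small_config, anchors, cond)
        for cond in simulate.CONDITIONS
    }
    return {"config": small_config, "genome": genome, "anchors": anchors, "samples": samples}


@pytest.fixture(scope="session")
def recovery_study():
    """The reference recovery conditions: 3000 genes, 500 perturbed, 2e5 pairs.

    Session-scoped because simulation plus track building at this scale takes
    tens of seconds and several tests share it.
    """
    config = SimulationConfig(seed=2024)
    genome, anchors = simulate.make_annotation(config)
    built = {}
    truths = {}
    for cond in simulate.CONDITIONS:
        records, truth = simulate.simulate_fragments(config, anchors, cond)
        kept, _ = filtering.filter_pairs(records)
        built[cond] = tracks.build_track(
            tracks.fragment_midpoints(kept), config.chrom_lengths
        )
        truths[cond] = truth
    return {
        "config": config,
        "anchors": anchors,
        "tracks": built,
        "affected": truths["perturbed"].affected_gene_ids,
        "truths": truths,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
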