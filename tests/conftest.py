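"""Shared fixtures: one simulated dataset reused across the suite."""

from __future__ import annotations

import pytest

from terrakit import simdata


@pytest.fixture(scope="session")
def sim_cfg() -> simdata.SimConfig:
    return simdata.default_config(seed=11)


@pytest.fixture(scope="session")
def sim_genome(sim_cfg):
    """(genome, truth) for the standard six-arm condition."""
    return simdata.simulate_genome(sim_cfg)


@pytest.fixture(scope="session")
def sim_truth(sim_genome):
    return sim_genome[1]


@pytest.fixture(scope="session")
def sim_short_reads(sim_genome, sim_cfg):
    _, truth = sim_genome
    records, truth = simdata.simulate_short_reads(truth, sim_cfg)
    return records


@pytest.fixture(scope="session")
def sim_long_reads(sim_genome, sim_cfg):
    genome, truth = sim_genome
    return simdata.simulate_long_reads(truth, sim_cfg, genome)


@pytest.fixture(scope="session")
def sim_evidence(sim_genome, sim_cfg):
    """(enrichment tracks, cage clusters, long-read 5' ends)."""
    from terrakit.annotate import cluster_cage_tags, log2_enrichment

    _, truth = sim_genome
    capture, control = simdata.simulate_coverage(truth, sim_cfg)
    enrichment = {
        sid: log2_enrichment(capture[sid], control[sid]) for sid in capture
    }
    cage = cluster_cage_tags(simdata.simulate_cage_tags(truth, sim_cfg))
    fiveprime = [
        (r.seq_id, r.tss, r.strand) for r in truth.regions for _ in range(3)
    ]
    return enrichment, cage, fiveprime
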