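"""Shared fixtures: one small ground-truthed world and its pipeline run.

The small world (150 kb genomes, 12 core genes) exercises every feature of
the generator — all four loci, cas operons in all three states, an IS
disruption, terminal degeneracy, an anti-CRISPR array and a self-targeting
spacer — while staying fast enough to build once per session.
"""
from __future__ import annotations

import pytest

from crispratlas.pipeline import PipelineConfig, run_all
from crispratlas.synthetic_data import WorldConfig, generate_world

SMALL_SEED = 3


@pytest.fixture(scope="session")
def small_config() -> WorldConfig:
    return WorldConfig(genome_length=150_000, n_core_genes=12)


@pytest.fixture(scope="session")
def small_world(small_config):
    """(genomes, elements, truth) for the standard small test world."""
    return generate_world(small_config, seed=SMALL_SEED)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """Full pipeline report bundle over the small world."""
    cfg = PipelineConfig(synth=small_config, seed=SMALL_SEED)
    return run_all(cfg)


@pytest.fixture(scope="session")
def genomes_by_id(small_world):
    genomes, _, _ = small_world
    return {g.genome_id: g for g in genomes}
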