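"""Shared fixtures: one default end-to-end run and small synthetic datasets."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from circleaf import pipeline, simdata


@pytest.fixture(scope="session")
def default_result() -> pipeline.PipelineResult:
    """The full pipeline under default study conditions (seed 0)."""
    return pipeline.run_pipeline()


@pytest.fixture(scope="session")
def small_config() -> simdata.SimConfig:
    return simdata.SimConfig(
        seed=7,
        n_chromosomes=2,
        chromosome_length=30_000,
        n_genes=20,
        n_circ_exonic=6,
        n_circ_intronic=2,
        n_circ_intergenic=2,
        depth=2_000,
        n_mirnas=4,
        n_sponge_triples=2,
        n_db_decoys=5,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config) -> simdata.SimulatedDataset:
    return simdata.simulate_dataset(small_config)
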