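"""Shared fixtures: small planted collections and pipeline runs.

Heavy artifacts (simulated collections, ANI matrices, pipeline output) are
session-scoped so independent tests can share them without recomputation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from magpop.ani import pairwise_ani_matrix
from magpop.pipeline import PipelineConfig, run_pipeline
from magpop.simulate import (
    DiseaseConfig,
    SimConfig,
    simulate_cohort_tables,
    simulate_genome_collection,
    simulate_quality_metadata,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """3 species x 2 units x 3 MAGs at the default distance bands."""
    return SimConfig(
        n_species=3, units_per_species=2, mags_per_unit=3,
        genome_length=20_000, n_samples=20, rng_seed=101,
    )


@pytest.fixture(scope="session")
def small_collection(small_cfg):
    records, truth = simulate_genome_collection(small_cfg)
    return records, truth


@pytest.fixture(scope="session")
def small_ani(small_collection):
    """Sketch and exact-Hamming ANI matrices for the small collection."""
    records, _ = small_collection
    genomes = {r.mag_id: r.sequence for r in records}
    return (
        pairwise_ani_matrix(genomes, method="sketch"),
        pairwise_ani_matrix(genomes, method="exact_hamming"),
    )


@pytest.fixture(scope="session")
def small_metadata(small_collection):
    _, truth = small_collection
    return simulate_quality_metadata(truth, np.random.default_rng(7))


@pytest.fixture(scope="session")
def small_tables(small_collection, small_cfg):
    _, truth = small_collection
    return simulate_cohort_tables(truth, small_cfg, np.random.default_rng(8))


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """The same small synthetic pipeline run twice with one seed."""
    base = tmp_path_factory.mktemp("pipeline")
    sim = SimConfig(
        n_species=4, units_per_species=2, mags_per_unit=8, n_samples=40,
        disease_configs=(
            DiseaseConfig("disease_planted", 0.30, species_beta=1.0,
                          unit_log_or=np.log(0.56)),
            DiseaseConfig("disease_null", 0.30),
        ),
    )
    cfg = PipelineConfig(
        outdir=str(base / "run1"), seed=7, sim=sim,
        min_mags_gun=3, min_mags_candidate=5, min_cases=3, min_carriers=3,
        max_ngun=60.0,
    )
    m1 = run_pipeline(cfg)
    m2 = run_pipeline(dataclasses.replace(cfg, outdir=str(base / "run2")))
    return cfg, m1, m2
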