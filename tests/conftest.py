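"""Shared fixtures: a small, fast simulation config and derived datasets.

Session-scoped fixtures cache the expensive simulations so the whole suite
runs one small genome; tests that need the full default study conditions
build their own config.
"""

import numpy as np
import pandas as pd
import pytest

from heteromics.simulate import (
    SimConfig, homoeolog_pairs, simulate_annotation, simulate_counts,
    simulate_methylome, simulate_sirna_reads,
)


def small_config(seed: int = 1, **overrides) -> SimConfig:
    """A reduced-size configuration for fast unit tests."""
    defaults = dict(
        n_genes=40, n_te=60, n_clusters=40, chrom_length=300_000,
        n_dmrs_per_context=12, n_pattern_loci=10, seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def cfg():
    return small_config()


@pytest.fixture(scope="session")
def annotation(cfg):
    return simulate_annotation(cfg)


@pytest.fixture(scope="session")
def pair_table(annotation):
    return homoeolog_pairs(annotation)


@pytest.fixture(scope="session")
def counts_sim(cfg, annotation):
    em, truth = simulate_counts(cfg, gene_ids=list(annotation.genes["id"]))
    return em, truth


@pytest.fixture(scope="session")
def methylome_sim(cfg, annotation):
    return simulate_methylome(cfg, annotation)


@pytest.fixture(scope="session")
def sirna_sim(cfg, annotation):
    return simulate_sirna_reads(cfg, annotation)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
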