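"""Shared fixtures: one small simulated cohort reused across test modules."""

import logging

import numpy as np
import pytest

from exwaskit.impute import ImputationParams, impute_cohort
from exwaskit.simulate import (
    SimulationConfig,
    default_architecture,
    partition_cohort,
    simulate_annotations,
    simulate_haplotype_panel,
    simulate_phenotypes,
)

logging.getLogger("exwaskit").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_individuals=300, n_sites=1200, region_length=1_200_000, seed=11
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_haplotype_panel(small_config)


@pytest.fixture(scope="session")
def small_split(small_panel):
    return partition_cohort(small_panel, ref_fraction=0.41, n_holdout=40, seed=12)


@pytest.fixture(scope="session")
def small_annotations(small_panel):
    return simulate_annotations(small_panel, n_genes=30, seed=13)


@pytest.fixture(scope="session")
def small_architecture(small_annotations):
    return default_architecture(small_annotations, seed=14, n_shared=4, n_crea=1, n_cys=1, n_urate=2, n_uacr=1)


@pytest.fixture(scope="session")
def small_cohort(small_panel, small_annotations, small_architecture):
    biomarkers, truth = simulate_phenotypes(
        small_panel.genotypes(),
        small_annotations,
        small_architecture,
        seed=15,
        panel_maf=small_panel.maf,
    )
    return biomarkers, truth


@pytest.fixture(scope="session")
def chunk_params() -> ImputationParams:
    return ImputationParams(chunk_size=600, overlap=150_000, trim=75_000)


@pytest.fixture(scope="session")
def holdout_imputation(small_panel, small_split, chunk_params):
    ref = small_panel.subset_individuals(small_split.panel_ids)
    hold = small_panel.subset_individuals(small_split.holdout_ids)
    dm = impute_cohort(hold.haplotypes, ref, small_split.array_site_mask, chunk_params)
    truth = hold.genotypes()[:, dm.site_index].astype(float)
    return dm, truth, ref


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
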