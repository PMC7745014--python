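"""Shared fixtures: synthetic cohorts at two scales.

The "small" configuration (16^3 grid, 3 sources) is for statistics-level
Monte Carlo loops where image geometry is irrelevant; the "default"
configuration is the full 81-subject, 8-network study emulation.
"""

import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from sbmgm import (
    SimulationConfig,
    build_matrix,
    generate_cohort,
    make_mask,
    synthesize_matrix,
    synthesize_volumes,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


SMALL_CFG = SimulationConfig(
    grid_shape=(16, 16, 16),
    voxel_size_mm=8.0,
    k_true=3,
    blobs_per_source=2,
    blob_fwhm_mm=30.0,
    seed=0,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SMALL_CFG


def reseed(cfg: SimulationConfig, seed: int) -> SimulationConfig:
    return dataclasses.replace(cfg, seed=seed)


@pytest.fixture(scope="session")
def default_cfg() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_cfg):
    """(config, ground truth, data matrix) of the full-size study emulation."""
    truth = generate_cohort(default_cfg)
    x = synthesize_matrix(truth, default_cfg)
    return default_cfg, truth, x


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, default_cfg, default_cohort):
    """Cohort materialized on disk as NIfTI volumes + subject TSV."""
    out = tmp_path_factory.mktemp("cohort")
    _, truth, _ = default_cohort
    synthesize_volumes(truth, default_cfg, out_dir=out)
    return out


@pytest.fixture(scope="session")
def default_matrix(default_cohort):
    """GMDataMatrix built through the gmio path (volumes -> mask -> matrix)."""
    cfg, truth, _ = default_cohort
    volumes, _ = synthesize_volumes(truth, cfg)
    mask = make_mask(volumes, 0.2)
    return build_matrix(volumes, mask)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
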