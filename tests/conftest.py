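"""Shared fixtures: tiny synthetic cohorts and grids, generated in-process."""

from __future__ import annotations

import numpy as np
import pytest

from fcnm import VolumeGrid, make_cohort
from fcnm.pipeline import ConnectomeEngine, RunConfig
from fcnm.synthetic import GroundTruth, PlantedDesign, box_voxels


@pytest.fixture(scope="session")
def small_grid() -> VolumeGrid:
    return VolumeGrid.pseudo_mni(shape=(10, 12, 10), voxel_size_mm=3.0)


@pytest.fixture(scope="session")
def tiny_design() -> tuple[PlantedDesign, GroundTruth]:
    """6 subjects, T=40, one planted network on a 10x12x10 grid."""
    networks = {"a": box_voxels((2, 3, 2), (6, 7, 6))}
    design = PlantedDesign(
        grid_shape=(10, 12, 10),
        networks=networks,
        loadings={"a": 1.0},
        n_subjects=6,
        n_timepoints=40,
        rng_seed=42,
    )
    truth = GroundTruth(
        grid=design.grid(),
        networks=networks,
        source_network_label={"increase": "a"},
        target_network_labels={"increase": ["a"]},
        foci_per_contrast=[2],
    )
    return design, truth


@pytest.fixture(scope="session")
def tiny_cohort(tiny_design):
    design, _ = tiny_design
    cohort, grid = make_cohort(design, with_motion=False)
    return cohort, grid


@pytest.fixture(scope="session")
def tiny_engine(tiny_cohort):
    cohort, _ = tiny_cohort
    return ConnectomeEngine(cohort, RunConfig(fwhm_mm=0.0, n_null=0))
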