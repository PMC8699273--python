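"""Shared fixtures: meshes, layouts, forward solutions and the one
expensive session-scoped artifact (the B1 1%-noise assessment)."""

import numpy as np
import pytest

from dotiqa.config import StudyConfig
from dotiqa.forward_model import (FDSettings, OpticalProperties,
                                  assemble_fem_system, boundary_measurements,
                                  solve_fluence)
from dotiqa.mesh import build_disc_mesh, place_optodes
from dotiqa.study import (StudyMeshes, assess_case, build_study_meshes,
                          discretization_calibration)


@pytest.fixture(scope="session")
def cfg() -> StudyConfig:
    return StudyConfig()


@pytest.fixture(scope="session")
def meshes(cfg) -> StudyMeshes:
    return build_study_meshes(cfg)


@pytest.fixture(scope="session")
def fine_mesh(meshes):
    return meshes.fine


@pytest.fixture(scope="session")
def coarse_mesh(meshes):
    return meshes.coarse


@pytest.fixture(scope="session")
def fd_settings(cfg) -> FDSettings:
    return cfg.fd


@pytest.fixture(scope="session")
def homogeneous_forward(meshes, fd_settings):
    """Fluence fields and boundary data of the homogeneous fine-mesh disc."""
    props = OpticalProperties.homogeneous(meshes.fine.n_nodes, 0.01, 1.0)
    system = assemble_fem_system(meshes.fine, props, fd_settings)
    fields = [solve_fluence(system, n)
              for n in meshes.fine_layout.source_nodes]
    data = boundary_measurements(fields, meshes.fine_layout)
    return system, fields, data


@pytest.fixture(scope="session")
def calibration(meshes, cfg):
    return discretization_calibration(meshes, cfg)


@pytest.fixture(scope="session")
def small_mesh():
    """32-boundary-node disc for cheap optode/Jacobian tests."""
    return build_disc_mesh(8, 2, 40.0)


@pytest.fixture(scope="session")
def small_layout(small_mesh):
    return place_optodes(small_mesh, 16, 16, 0.0)


@pytest.fixture(scope="session")
def b1_one_percent(cfg, meshes):
    """Scores and raw optical-property images of the B1 grid at 1% noise."""
    return assess_case("B1", "1pct", cfg, meshes, return_images=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20211208)
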