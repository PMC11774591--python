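"""Shared fixtures: meshes and flow fields are expensive, so they are built
once per session and reused read-only across tests."""

import pytest

from mcelsim import unconfined, confined, generate_mesh, generate_construct_mesh
from mcelsim.flow import solve_flow


@pytest.fixture(scope="session")
def spec_unconfined():
    return unconfined()


@pytest.fixture(scope="session")
def spec_confined():
    return confined()


@pytest.fixture(scope="session")
def construct_mesh_unconfined(spec_unconfined):
    return generate_construct_mesh(spec_unconfined, "default")


@pytest.fixture(scope="session")
def construct_mesh_confined(spec_confined):
    return generate_construct_mesh(spec_confined, "default")


@pytest.fixture(scope="session")
def full_mesh_unconfined(spec_unconfined):
    return generate_mesh(spec_unconfined, "default")


@pytest.fixture(scope="session")
def full_mesh_confined(spec_confined):
    return generate_mesh(spec_confined, "default")


@pytest.fixture(scope="session")
def flow_unconfined(full_mesh_unconfined):
    return solve_flow(full_mesh_unconfined, Re=0.1, k_star=1e-8)


@pytest.fixture(scope="session")
def flow_confined(full_mesh_confined):
    return solve_flow(full_mesh_confined, Re=0.1, k_star=1e-8)


@pytest.fixture(scope="session")
def construct_mesh_unconfined_fine(spec_unconfined):
    return generate_construct_mesh(spec_unconfined, "fine")


@pytest.fixture(scope="session")
def full_mesh_unconfined_fine(spec_unconfined):
    return generate_mesh(spec_unconfined, "fine")
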