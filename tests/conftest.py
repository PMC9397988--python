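"""Shared fixtures: one default BMI x TL sweep and one coarse solve per
session feed the behavioral and acceptance tests without re-solving."""

import pytest

import patraction as pt
from patraction import analysis, fem, verify


@pytest.fixture(scope="session")
def default_sweep():
    """Full default sweep: 4 BMI phantoms driven to TL9, TL1-9 recorded."""
    return analysis.run_sweep()


@pytest.fixture(scope="session")
def coarse_case():
    """One fast normal-BMI solve on a coarse mesh for solver-behavior tests."""
    spec = pt.PhantomSpec(mesh_target_edge_mm=8.0)
    mesh = pt.mesh_geometry(pt.build_phantom(spec))
    materials = pt.MaterialTable()
    protocol = pt.TractionProtocol()
    scene = fem.build_scene(mesh, materials, protocol,
                            mat_thickness_mm=spec.mat_thickness_mm)
    sol = fem.solve_traction(mesh, materials, protocol, tl=9, scene=scene)
    return spec, scene, sol


@pytest.fixture(scope="session")
def verification_checks():
    """Analytic verification suite results (patch, beam, Hertz, oracle)."""
    return verify.run_all()


@pytest.fixture(scope="session")
def table_stress():
    return analysis.reference_table("stress")


@pytest.fixture(scope="session")
def table_strain():
    return analysis.reference_table("strain")


def make_coarse_spec(**overrides):
    """A small but ROI-valid phantom spec for fast functional tests."""
    base = dict(mesh_target_edge_mm=6.0)
    base.update(overrides)
    return pt.PhantomSpec(**base)
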