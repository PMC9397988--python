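"""Solver verification: element integrals, analytic benchmarks, contact."""

import numpy as np
import pytest

import patraction as pt
from patraction import fem
from patraction.materials import plane_strain_matrix

from conftest import make_coarse_spec


# -- element level ----------------------------------------------------------

def test_single_element_stiffness_matches_symbolic_integration():
    """One distorted quadratic triangle against exact sympy integration."""
    import sympy as sp

    p0, p1, p2 = (0.0, 0.0), (2.0, 0.1), (0.3, 1.5)
    corners = np.array([p0, p1, p2])
    coords6 = np.vstack([corners,
                         0.5 * (corners[[0, 1, 2]] + corners[[1, 2, 0]])])
    E_mod, nu = 7.0, 0.3
    D = plane_strain_matrix(E_mod, nu)
    ke = fem.element_stiffness(coords6, D)

    xi, eta = sp.symbols("xi eta")
    lam = 1 - xi - eta
    N = [lam * (2 * lam - 1), xi * (2 * xi - 1), eta * (2 * eta - 1),
         4 * xi * lam, 4 * xi * eta, 4 * eta * lam]
    # affine mapping from the straight-sided corners
    J = sp.Matrix([[p1[0] - p0[0], p1[1] - p0[1]],
                   [p2[0] - p0[0], p2[1] - p0[1]]])
    detJ = J.det()
    Jinv = J.inv()
    B = sp.zeros(3, 12)
    for a in range(6):
        dref = sp.Matrix([sp.diff(N[a], xi), sp.diff(N[a], eta)])
        # rows of J are d(x,y)/dxi_l, so dN/dx = J^{-1} dN/dxi
        dN = Jinv * dref            # [dN/dx, dN/dy]
        B[0, 2 * a] = dN[0]
        B[1, 2 * a + 1] = dN[1]
        B[2, 2 * a] = dN[1]
        B[2, 2 * a + 1] = dN[0]
    integrand = B.T * sp.Matrix(D) * B * detJ
    ke_exact = np.array([
        [float(sp.integrate(integrand[i, j], (eta, 0, 1 - xi), (xi, 0, 1)))
         for j in range(12)] for i in range(12)])
    assert np.allclose(ke, ke_exact, rtol=1e-9, atol=1e-9)


def test_stiffness_symmetry_and_rigid_body_nullspace():
    mesh = pt.mesh_geometry(pt.build_phantom(make_coarse_spec()))
    K = fem.assemble_stiffness(mesh, pt.MaterialTable())
    asym = abs(K - K.T).max()
    assert asym <= 1e-12 * abs(K).max()
    n = mesh.n_nodes
    tx = np.zeros(2 * n)
    tx[0::2] = 1.0
    ty = np.zeros(2 * n)
    ty[1::2] = 1.0
    rot = np.empty(2 * n)
    rot[0::2] = -mesh.points[:, 1]
    rot[1::2] = mesh.points[:, 0]
    knorm = abs(K).max()
    for mode in (tx, ty, rot):
        assert np.linalg.norm(K @ mode) <= 1e-9 * knorm * np.linalg.norm(mode)


def test_missing_material_raises_with_region():
    mesh = pt.mesh_geometry(pt.build_phantom(make_coarse_spec()))
    mesh.region_id = mesh.region_id.copy()
    mesh.region_id[0] = 99
    with pytest.raises(KeyError, match="99"):
        fem.assemble_stiffness(mesh, pt.MaterialTable())


# -- analytic benchmarks ----------------------------------------------------

def test_patch_test_exact(verification_checks):
    c = next(c for c in verification_checks if "patch" in c.name)
    assert c.rel_err <= 1e-9


def test_cantilever_matches_beam_theory(verification_checks):
    c = next(c for c in verification_checks if "cantilever" in c.name)
    assert c.rel_err <= 0.05


def test_energy_balance_frictionless(verification_checks):
    c = next(c for c in verification_checks if "energy" in c.name)
    assert c.rel_err <= 0.01


def test_dense_oracle_equivalence(verification_checks):
    c = next(c for c in verification_checks if "oracle" in c.name)
    assert c.rel_err <= 1e-10


def test_hertz_line_contact(verification_checks):
    for c in verification_checks:
        if "Hertz" in c.name:
            assert c.rel_err <= 0.10, c


# -- equivalent scalars -----------------------------------------------------

def test_von_mises_pure_states():
    assert fem.von_mises(np.array([5.0, 0, 0, 0])) == pytest.approx(5.0)
    assert fem.von_mises(np.array([2.0, 2.0, 0, 2.0])) == pytest.approx(0.0)
    tau = 1.7
    assert fem.von_mises(np.array([0, 0, tau, 0])) == \
        pytest.approx(np.sqrt(3) * tau)


def test_equivalent_strain_pure_shear():
    g = 0.02
    assert fem.equivalent_strain(np.array([0.0, 0.0, g])) == \
        pytest.approx(g / np.sqrt(3))


def test_equivalent_strain_of_uniaxial():
    e = 0.01
    # deviatoric of (e,0,0): sqrt(2/3 * (2/3 e^2 + 1/9 e^2 + 1/9 e^2))
    expect = np.sqrt(2.0 / 3.0 * (4 + 1 + 1) / 9.0) * e
    assert fem.equivalent_strain(np.array([e, 0.0, 0.0])) == \
        pytest.approx(expect)


# -- traction solves --------------------------------------------------------

def test_no_response_below_contact_onset(coarse_case):
    _, scene, sol = coarse_case
    for tl in range(5):
        st = sol.at_level(tl)
        assert np.linalg.norm(st.u) == 0.0
        assert abs(st.sigma).max() == 0.0


def test_contact_force_monotone_after_onset(coarse_case):
    _, scene, sol = coarse_case
    fy = [st.contact_force[1] for st in sol.levels]
    assert all(b >= a - 1e-9 for a, b in zip(fy, fy[1:]))
    assert fy[-1] > 0


def test_converged_residuals_below_tolerance(coarse_case):
    _, scene, sol = coarse_case
    for st in sol.levels:
        if st.contact_active:
            scale = max(np.linalg.norm(st.contact_force), 1e-8)
            assert st.residual <= 1e-5 * max(scale, 1.0)


def test_foundation_overlap_bounded_by_mat_thickness(coarse_case):
    spec, scene, sol = coarse_case
    assert not scene.hard_contact
    for st in sol.levels:
        assert st.max_penetration <= spec.mat_thickness_mm


def test_hard_contact_penetration_and_complementarity():
    """Bare-roller (no mat) solve honors the hard-contact tolerances."""
    spec = make_coarse_spec(mesh_target_edge_mm=8.0)
    mesh = pt.mesh_geometry(pt.build_phantom(spec))
    protocol = pt.TractionProtocol(include_mat=False)
    contact = pt.ContactSpec()
    scene = fem.build_scene(mesh, pt.MaterialTable(), protocol, contact)
    assert scene.hard_contact
    # small-strain mode at the first engaged level: the bare roller (no foam
    # spreading) locally crushes the thin fat layer beyond what the
    # geometry-updating mode can represent with linear elastic tissue
    sol = fem.solve_traction(mesh, pt.MaterialTable(), protocol, tl=5,
                             contact=contact, scene=scene,
                             settings=fem.SolverSettings(kinematics="small"))
    st = sol.at_level(5)
    assert st.contact_force[1] > 0
    assert st.max_penetration <= contact.gap_tol_mm
    assert st.complementarity <= contact.comp_tol


def test_solution_bit_reproducible():
    spec = make_coarse_spec(mesh_target_edge_mm=8.0)
    runs = []
    for _ in range(2):
        mesh = pt.mesh_geometry(pt.build_phantom(spec))
        scene = fem.build_scene(mesh, pt.MaterialTable(),
                                pt.TractionProtocol(),
                                mat_thickness_mm=spec.mat_thickness_mm)
        sol = fem.solve_traction(mesh, pt.MaterialTable(),
                                 pt.TractionProtocol(), tl=6, scene=scene)
        runs.append(sol.at_level(6))
    assert np.array_equal(runs[0].u, runs[1].u)
    assert np.array_equal(runs[0].sigma, runs[1].sigma)


def test_small_strain_mode_matches_updated_at_low_lift():
    """Just past onset the geometric update is a small correction."""
    spec = make_coarse_spec(mesh_target_edge_mm=8.0)
    mesh = pt.mesh_geometry(pt.build_phantom(spec))
    mats = pt.MaterialTable()
    protocol = pt.TractionProtocol()
    vals = {}
    for mode in ("updated", "small"):
        scene = fem.build_scene(mesh, mats, protocol,
                                mat_thickness_mm=spec.mat_thickness_mm)
        sol = fem.solve_traction(mesh, mats, protocol, tl=5, scene=scene,
                                 settings=fem.SolverSettings(kinematics=mode))
        from patraction.analysis import disc_average
        vals[mode] = disc_average(sol.at_level(5), scene.mesh, "L2-L3")
    assert vals["small"] == pytest.approx(vals["updated"], rel=0.15)


def test_recover_fields_shapes_and_consistency(coarse_case):
    _, scene, sol = coarse_case
    st = sol.at_level(9)
    fields = fem.recover_fields(st, scene.mesh, scene.materials)
    n = scene.mesh.n_nodes
    assert fields["stress"].shape == (n, 4)
    assert fields["strain"].shape == (n, 3)
    assert fields["von_mises"].shape == (n,)
    assert np.all(fields["von_mises"] >= 0)
    assert np.all(fields["eq_strain"] >= 0)


def test_disc_stress_converged_with_mesh():
    """Halving the default target edge moves disc means by < 5%."""
    mats = pt.MaterialTable()
    protocol = pt.TractionProtocol()
    from patraction.analysis import disc_average
    res = {}
    for edge in (4.0, 2.0):
        spec = pt.PhantomSpec(mesh_target_edge_mm=edge)
        mesh = pt.mesh_geometry(pt.build_phantom(spec))
        scene = fem.build_scene(mesh, mats, protocol,
                                mat_thickness_mm=spec.mat_thickness_mm)
        sol = fem.solve_traction(mesh, mats, protocol, tl=9, scene=scene)
        st = sol.at_level(9)
        res[edge] = np.array([disc_average(st, scene.mesh, d)
                              for d in pt.DISC_LEVELS])
    rel = np.abs(res[2.0] - res[4.0]) / res[4.0]
    assert rel.max() <= 0.05
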