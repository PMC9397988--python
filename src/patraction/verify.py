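"""Analytic verification suite for the plane-strain contact solver.

Five classical checks, each against an independent closed form:

* patch test — a linear displacement field prescribed on the whole boundary
  of a distorted-free rectangle must be reproduced exactly (quadratic
  elements contain linear fields), giving a spatially constant stress equal
  to the plane-strain Hooke value to machine precision;
* slender cantilever — tip deflection vs Euler-Bernoulli PL^3/3EI;
* Hertz line contact — a rigid cylinder pressed into a deep elastic block vs
  the half-width and peak-pressure closed forms b = sqrt(4PR/(pi E*)),
  p0 = 2P/(pi b);
* dense-oracle equivalence — the sparse path vs numpy's dense solve on a
  small (<= 200 DOF) system;
* energy balance — external work of the applied load vs stored strain
  energy on a frictionless linear solve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import fem
from .materials import plane_strain_matrix
from .phantom import LabeledMesh, _structured_t6
from .regions import SOFT_TISSUE

__all__ = ["rectangle_mesh", "patch_test", "cantilever_test", "hertz_test",
           "dense_oracle_test", "energy_balance_test", "run_all"]


@dataclass(frozen=True)
class Check:
    name: str
    value: float
    reference: float
    rel_err: float
    tol: float

    @property
    def passed(self) -> bool:
        return self.rel_err <= self.tol

    def __str__(self) -> str:
        flag = "ok " if self.passed else "FAIL"
        return (f"[{flag}] {self.name}: value={self.value:.6g} "
                f"ref={self.reference:.6g} rel_err={self.rel_err:.3e} "
                f"(tol {self.tol:g})")


def rectangle_mesh(xs: np.ndarray, ys: np.ndarray,
                   region_id: int = SOFT_TISSUE.id) -> LabeledMesh:
    """Structured T6 rectangle on the given (possibly graded) grid lines."""
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    corner_y = np.tile(ys, (len(xs), 1))
    quad_region = np.full((len(xs) - 1, len(ys) - 1), region_id, np.int64)
    points, tris, region = _structured_t6(xs, corner_y, quad_region)
    NY = 2 * (len(ys) - 1) + 1
    NX = 2 * (len(xs) - 1) + 1
    ii, jj = np.arange(NX), np.arange(NY)
    boundaries = {
        "bottom": ii * NY + 0,
        "top": ii * NY + (NY - 1),
        "left": jj,
        "right": (NX - 1) * NY + jj,
    }
    return LabeledMesh(points, tris, region, boundaries)


def _uniform_table(E: float, nu: float):
    """Material table mapping every region to one elastic law (no nu cap)."""
    from .materials import Material, MaterialTable
    table = MaterialTable(nu_cap=0.4999999)
    for lab in list(table.entries):
        table.entries[lab] = Material(E, nu, 1000.0)
    return table


def _boundary_nodes(mesh: LabeledMesh) -> np.ndarray:
    return np.unique(np.concatenate([mesh.boundaries[k]
                                     for k in ("bottom", "top", "left",
                                               "right")]))


def patch_test(E: float = 17.0, nu: float = 0.49) -> list[Check]:
    """Linear-field reproduction: constant stress to machine precision."""
    mesh = rectangle_mesh(np.linspace(0, 2, 4), np.linspace(0, 1, 3))
    table = _uniform_table(E, nu)
    K = fem.assemble_stiffness(mesh, table)
    A = np.array([[1.3e-3, 0.4e-3], [-0.2e-3, 0.9e-3]])   # u = A x
    bnd = _boundary_nodes(mesh)
    fixed_dofs = np.concatenate([2 * bnd, 2 * bnd + 1])
    vals = mesh.points[bnd] @ A.T
    fixed_vals = np.concatenate([vals[:, 0], vals[:, 1]])
    u = fem.solve_dirichlet(K, np.zeros(K.shape[0]), fixed_dofs, fixed_vals)
    # recover stress at quadrature points
    detJ, B = fem._element_geometry(mesh.points, mesh.tris)
    ue = u.reshape(-1, 2)[mesh.tris].reshape(mesh.n_elems, 12)
    eps = np.einsum("eqki,ei->eqk", B, ue)
    D = plane_strain_matrix(E, nu)
    sig = np.einsum("kl,eql->eqk", D, eps)
    exx, eyy, gxy = A[0, 0], A[1, 1], A[0, 1] + A[1, 0]
    sig_exact = D @ np.array([exx, eyy, gxy])
    err = np.abs(sig - sig_exact).max() / np.abs(sig_exact).max()
    return [Check("patch test (uniform stress)", float(np.abs(sig).max()),
                  float(np.abs(sig_exact).max()), float(err), 1e-9)]


def cantilever_test(L: float = 100.0, h: float = 5.0, E: float = 1000.0,
                    P: float = -0.1) -> list[Check]:
    """Slender cantilever tip deflection vs Euler-Bernoulli PL^3/(3EI).

    nu = 0 makes plane strain coincide with the beam-theory assumptions.
    """
    nu = 1e-9   # plane strain == plane stress as nu -> 0
    nx, ny = 50, 4
    mesh = rectangle_mesh(np.linspace(0, L, nx + 1),
                          np.linspace(-h / 2, h / 2, ny + 1))
    table = _uniform_table(E, nu)
    K = fem.assemble_stiffness(mesh, table)
    left = mesh.boundaries["left"]
    fixed_dofs = np.concatenate([2 * left, 2 * left + 1])
    # distribute the tip load over the right edge nodes (consistent lumping
    # is unnecessary at 5% tolerance as long as the resultant is P)
    right = mesh.boundaries["right"]
    f = np.zeros(K.shape[0])
    w = np.ones(len(right))
    w[0] = w[-1] = 0.5            # trapezoidal edge weights
    f[2 * right + 1] = P * w / w.sum()
    u = fem.solve_dirichlet(K, f, fixed_dofs, np.zeros(len(fixed_dofs)))
    tip = u.reshape(-1, 2)[right, 1].mean()
    I = h ** 3 / 12.0
    ref = P * L ** 3 / (3 * E * I)
    checks = [Check("cantilever tip deflection", float(tip), float(ref),
                    float(abs(tip - ref) / abs(ref)), 0.05)]
    # energy balance on the same frictionless solve: W = 1/2 f.u = U
    W = 0.5 * float(f @ u)
    U = 0.5 * float(u @ (K @ u))
    checks.append(Check("energy balance (work vs strain energy)", U, W,
                        float(abs(W - U) / abs(W)), 0.01))
    return checks


def energy_balance_test() -> list[Check]:
    return [c for c in cantilever_test() if c.name.startswith("energy")]


def dense_oracle_test(seed: int = 0) -> list[Check]:
    """Sparse direct path vs dense numpy solve on a <= 200 DOF system."""
    rng = np.random.default_rng(seed)
    mesh = rectangle_mesh(np.linspace(0, 3, 4), np.linspace(0, 2, 3))
    table = _uniform_table(23.5, 0.3)
    K = fem.assemble_stiffness(mesh, table)
    n = K.shape[0]
    assert n <= 200
    left = mesh.boundaries["left"]
    fixed = np.concatenate([2 * left, 2 * left + 1])
    f = rng.normal(size=n)
    u_sparse = fem.solve_dirichlet(K, f, fixed, np.zeros(len(fixed)))
    free = np.ones(n, bool)
    free[fixed] = False
    Kd = K.toarray()
    u_dense = np.zeros(n)
    u_dense[free] = np.linalg.solve(Kd[np.ix_(free, free)], f[free])
    err = np.linalg.norm(u_sparse - u_dense) / np.linalg.norm(u_dense)
    return [Check("dense-oracle equivalence", float(np.linalg.norm(u_sparse)),
                  float(np.linalg.norm(u_dense)), float(err), 1e-10)]


def hertz_test(R: float = 10.0, E: float = 100.0, nu: float = 0.3,
               depth: float = 0.2) -> list[Check]:
    """Rigid cylinder on a deep elastic block vs Hertz line contact.

    The cylinder is driven ``depth`` into the block with the penalty contact
    machinery; the measured resultant P closes the Hertz relations
    b = sqrt(4 P R / (pi E*)) and p0 = 2P/(pi b) with E* = E/(1-nu^2).
    """
    # graded grid: fine near the contact (|x| < 4), geometric growth outside
    h = 0.35
    x_f = np.arange(0.0, 4.0 + h / 2, h)
    x_c = [4.0]
    while x_c[-1] < 20.0:
        x_c.append(x_c[-1] + min((x_c[-1] - 3.0) * 0.4 + h, 4.0))
    xs = np.unique(np.concatenate([-np.array(x_c[1:])[::-1], -x_f[::-1],
                                   x_f, np.array(x_c[1:])]))
    ys = np.unique(np.concatenate([
        np.arange(20.0, 16.0 - h / 2, -h * 1.0)[::-1],
        np.linspace(0.0, 16.0, 14)]))
    mesh = rectangle_mesh(xs, ys)
    table = _uniform_table(E, nu)
    K = fem.assemble_stiffness(mesh, table)
    n = K.shape[0]
    bottom = mesh.boundaries["bottom"]
    fixed = np.concatenate([2 * bottom, 2 * bottom + 1])
    free = np.ones(n, bool)
    free[fixed] = False
    top = mesh.boundaries["top"]
    order = np.argsort(mesh.points[top, 0])
    top = top[order]
    trib = fem._trib_lengths(mesh.points, top)
    kappa = 1e3 * E
    cy = 20.0 + R - depth

    u = np.zeros(n)
    for _ in range(60):
        pos = mesh.points + u.reshape(-1, 2)
        d = pos[top] - np.array([0.0, cy])
        r = np.linalg.norm(d, axis=1)
        pen = R - r
        act = np.flatnonzero(pen > 0)
        fvec = np.zeros(n)
        rows, cols, vals = [], [], []
        for i in act:
            nvec = d[i] / r[i]
            kpen = kappa * trib[i]
            fn = kpen * pen[i]
            node = top[i]
            fvec[2 * node:2 * node + 2] += fn * nvec
            for a in range(2):
                for b in range(2):
                    rows.append(2 * node + a)
                    cols.append(2 * node + b)
                    vals.append(kpen * nvec[a] * nvec[b])
        Rres = K @ u - fvec
        scale = max(np.linalg.norm(fvec[free]), 1e-8)
        if np.linalg.norm(Rres[free]) <= 1e-8 * scale:
            break
        A = K + sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        import scipy.sparse.linalg as spla
        Aff = A[free][:, free].tocsc()
        du = np.zeros(n)
        du[free] = spla.splu(Aff).solve(-Rres[free])
        u = u + du

    pos = mesh.points + u.reshape(-1, 2)
    d = pos[top] - np.array([0.0, cy])
    r = np.linalg.norm(d, axis=1)
    pen = R - r
    act = np.flatnonzero(pen > 0)
    pressures = kappa * pen[act]
    P = float(np.sum(kappa * trib[act] * pen[act]
                     * (-d[act, 1] / r[act])))       # vertical resultant
    Estar = E / (1 - nu ** 2)
    b_ref = np.sqrt(4 * P * R / (np.pi * Estar))
    p0_ref = 2 * P / (np.pi * b_ref)
    x_act = mesh.points[top[act], 0]
    b_meas = float(np.abs(x_act).max()) + 0.5 * h / 2
    p0_meas = float(pressures.max())
    return [
        Check("Hertz contact half-width", b_meas, float(b_ref),
              float(abs(b_meas - b_ref) / b_ref), 0.10),
        Check("Hertz peak pressure", p0_meas, float(p0_ref),
              float(abs(p0_meas - p0_ref) / p0_ref), 0.10),
    ]


def run_all() -> list[Check]:
    """Run the full verification suite; returns all checks."""
    checks: list[Check] = []
    checks += patch_test()
    checks += cantilever_test()
    checks += dense_oracle_test()
    checks += hertz_test()
    return checks
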