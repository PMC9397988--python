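"""Quasi-static plane-strain FEM with frictionless roller contact.

Discretization: 6-node quadratic triangles (3-point quadrature), chosen to
behave well at the near-incompressible Poisson ratios (nu = 0.49) that
dominate the tissue table. The traction schedule is applied incrementally
(one increment per traction level by default, automatic bisection on
non-convergence); in the default updated-Lagrangian mode the geometry is
updated after every increment, small-strain kinematics within each, which
captures the first-order geometric nonlinearity of a 62 mm lift without a
full finite-strain formulation. A strict small-strain single-step mode is
kept for verification against linear closed forms.

Contact: the bed mat rides on the rollers as a unilateral elastic foundation
(effective indenter radius = roller + pad thickness; contact stiffness = the
pad's constrained modulus per thickness in series with the interface
penalty), acting as rigid master against the posterior-skin slave nodes.
Tangential behavior is exactly frictionless. With the mat disabled, the bare
roller meets the skin through "hard" contact approximated by a regularized
penalty with augmented-Lagrange multiplier updates and a complementarity
post-check. The sparse direct factorization and fixed assembly order make
every solve bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import MaterialTable
from .phantom import LabeledMesh
from .protocol import (ContactSpec, SKIN_MAT_CLEARANCE_MM, TractionProtocol,
                       roller_centers)
from .regions import ID_TO_LABEL, MAT

__all__ = [
    "BoundarySpec", "SolverSettings", "Scene", "FieldSolution", "LevelState",
    "assemble_stiffness", "solve_traction", "recover_fields", "build_scene",
    "von_mises", "equivalent_strain", "solve_dirichlet", "element_stiffness",
]


# ---------------------------------------------------------------------------
# T6 element tables
# ---------------------------------------------------------------------------

#: 3-point quadrature (exact for quadratics on straight-sided elements).
QP = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
QW = np.full(3, 1 / 6)


def _dshape(xi: float, eta: float) -> np.ndarray:
    """(6, 2) gradients of the T6 shape functions at (xi, eta)."""
    lam = 1.0 - xi - eta
    return np.array([
        [1 - 4 * lam, 1 - 4 * lam],
        [4 * xi - 1, 0.0],
        [0.0, 4 * eta - 1],
        [4 * (lam - xi), -4 * xi],
        [4 * eta, 4 * xi],
        [-4 * eta, 4 * (lam - eta)],
    ])


_DSHAPE = np.stack([_dshape(*q) for q in QP])          # (3, 6, 2)

# Quadrature-point -> node linear extrapolation (6, 3): fit a plane through
# the three quadrature values, evaluate at the element nodes.
_NODES_REF = np.array([[0, 0], [1, 0], [0, 1], [.5, 0], [.5, .5], [0, .5]])
_M = np.column_stack([np.ones(3), QP])
_EXTRAP = np.column_stack([np.ones(6), _NODES_REF]) @ np.linalg.inv(_M)


def _element_geometry(points: np.ndarray, tris: np.ndarray):
    """Per-element jacobians and strain-displacement matrices.

    Returns detJ (E,) and B (E, 3qp, 3, 12) for straight-sided T6 elements
    (affine mapping from the corner nodes).
    """
    p0 = points[tris[:, 0]]
    p1 = points[tris[:, 1]]
    p2 = points[tris[:, 2]]
    J = np.stack([p1 - p0, p2 - p0], axis=1)            # (E, 2, 2) rows dx/dxi
    detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    invJ = np.empty_like(J)
    invJ[:, 0, 0] = J[:, 1, 1]
    invJ[:, 0, 1] = -J[:, 0, 1]
    invJ[:, 1, 0] = -J[:, 1, 0]
    invJ[:, 1, 1] = J[:, 0, 0]
    invJ /= detJ[:, None, None]
    # J rows are d(x,y)/dxi_l, so dxi_l/dx_k = invJ[k, l]:
    # dN/dx_k = dN/dxi_l * dxi_l/dx_k ; (q,6,l),(e,k,l)->(e,q,6,k)
    dNdx = np.einsum("qnl,ekl->eqnk", _DSHAPE, invJ)
    E, Q = len(tris), len(QP)
    B = np.zeros((E, Q, 3, 12))
    B[:, :, 0, 0::2] = dNdx[:, :, :, 0]
    B[:, :, 1, 1::2] = dNdx[:, :, :, 1]
    B[:, :, 2, 0::2] = dNdx[:, :, :, 1]
    B[:, :, 2, 1::2] = dNdx[:, :, :, 0]
    return detJ, B


def element_stiffness(coords6: np.ndarray, D: np.ndarray) -> np.ndarray:
    """12x12 stiffness of a single straight-sided T6 element."""
    detJ, B = _element_geometry(np.asarray(coords6, float),
                                np.arange(6, dtype=np.int64)[None, :])
    ke = np.einsum("q,qki,kl,qlj->ij", QW * detJ[0], B[0], D, B[0])
    return ke


def _element_D(mesh: LabeledMesh, materials: MaterialTable):
    """(E, 3, 3) constitutive matrices and (E,) capped Poisson ratios."""
    ids = mesh.region_id
    uniq = np.unique(ids)
    D = np.empty((len(ids), 3, 3))
    nu = np.empty(len(ids))
    for rid in uniq:
        if rid not in ID_TO_LABEL:
            raise KeyError(f"mesh region id {rid} has no label")
        lab = ID_TO_LABEL[rid]
        mask = ids == rid
        D[mask] = materials.operator(lab)
        nu[mask] = materials.capped_nu(lab)
    return D, nu


def assemble_stiffness(mesh: LabeledMesh, materials: MaterialTable,
                       points: np.ndarray | None = None) -> sp.csr_matrix:
    """Assemble the global symmetric stiffness operator (no constraints).

    Before boundary conditions its nullspace is spanned by the three planar
    rigid-body modes. Raises KeyError naming any region without a material.
    """
    pts = mesh.points if points is None else points
    detJ, B = _element_geometry(pts, mesh.tris)
    if np.any(detJ <= 0):
        raise RuntimeError("mesh contains inverted elements")
    D, _ = _element_D(mesh, materials)
    ke = np.einsum("q,eqki,ekl,eqlj->eij", QW, B, D, B) * detJ[:, None, None]
    edof = np.empty((mesh.n_elems, 12), dtype=np.int64)
    edof[:, 0::2] = 2 * mesh.tris
    edof[:, 1::2] = 2 * mesh.tris + 1
    rows = np.repeat(edof, 12, axis=1).ravel()
    cols = np.tile(edof, (1, 12)).ravel()
    K = sp.coo_matrix((ke.ravel(), (rows, cols)),
                      shape=(2 * mesh.n_nodes, 2 * mesh.n_nodes))
    return K.tocsr()


def _internal_force(mesh: LabeledMesh, points: np.ndarray,
                    sigma_inplane: np.ndarray) -> np.ndarray:
    """Assembled nodal force of a stored stress field (in-plane components)."""
    detJ, B = _element_geometry(points, mesh.tris)
    fe = np.einsum("q,eqki,eqk->ei", QW, B, sigma_inplane) * detJ[:, None]
    f = np.zeros(2 * mesh.n_nodes)
    edof = np.empty((mesh.n_elems, 12), dtype=np.int64)
    edof[:, 0::2] = 2 * mesh.tris
    edof[:, 1::2] = 2 * mesh.tris + 1
    np.add.at(f, edof.ravel(), fe.ravel())
    return f


def solve_dirichlet(K: sp.csr_matrix, f: np.ndarray, fixed_dofs: np.ndarray,
                    fixed_vals: np.ndarray) -> np.ndarray:
    """Direct solve with prescribed displacements (deterministic ordering)."""
    n = K.shape[0]
    free = np.ones(n, dtype=bool)
    free[fixed_dofs] = False
    u = np.zeros(n)
    u[fixed_dofs] = fixed_vals
    rhs = f[free] - K[free][:, ~free] @ u[~free]
    lu = spla.splu(K[free][:, free].tocsc())
    u[free] = lu.solve(rhs)
    return u


# ---------------------------------------------------------------------------
# Scene: phantom + mat + boundary conditions + contact bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundarySpec:
    """Zero-translation node sets on the anterior aspect of both body ends.

    ``anterior_fraction`` selects the anterior-most share of each end face
    (cranial and caudal) to fix; nodes are free to rotate (they are point
    supports). The default restrains most of each end cross-section: the
    end faces stand in for the adjacent thorax and pelvis removed by the
    segment truncation, and a small patch would let the whole segment swing
    vertically instead of deforming locally. The rigid driven boundaries
    (roller arcs) are part of the traction protocol, not of this spec.
    """

    anterior_fraction: float = 0.90

    def __post_init__(self) -> None:
        if not 0 < self.anterior_fraction <= 1:
            raise ValueError("anterior_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class SolverSettings:
    rtol: float = 1.0e-6
    max_newton: int = 150
    max_bisect: int = 6
    #: "updated" = updated-Lagrangian stepping; "small" = one linear-kinematic
    #: increment straight to the target level (verification mode).
    kinematics: str = "updated"
    increments_per_level: int = 1

    def __post_init__(self) -> None:
        if self.kinematics not in ("updated", "small"):
            raise ValueError("kinematics must be 'updated' or 'small'")
        if self.rtol <= 0 or self.max_newton < 1 or self.increments_per_level < 1:
            raise ValueError("invalid solver settings")


@dataclass
class Scene:
    """Assembled contact scene: positioned phantom, BCs and the roller pair.

    The bed mat is represented as a unilateral elastic foundation riding on
    the rollers: the effective rigid indenter radius grows by the mat
    thickness and the contact stiffness is the foam pad's constrained
    modulus per unit thickness (in series with the interface penalty), so
    the pad's spacing and compliance are retained without meshing the strip.
    With ``include_mat=False`` the bare roller meets the skin through hard
    (augmented-Lagrange) contact instead.
    """

    mesh: LabeledMesh                  # phantom in bed coordinates
    materials: MaterialTable
    protocol: TractionProtocol
    contact: ContactSpec
    fixed_dofs: np.ndarray
    #: slave skin nodes (ordered by x) and their tributary lengths
    skin_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    skin_trib: np.ndarray = field(default_factory=lambda: np.empty(0))
    #: y of the mat underside at rest (roller clearance datum)
    mat_underside_y: float = 0.0
    #: effective rigid indenter radius (roller + mat wrap), mm
    radius_eff: float = 25.0
    #: contact stiffness density, MPa/mm^2
    penalty_roller: float = 0.0
    #: True when the pair approximates hard contact (multiplier updates
    #: drive penetration below gap_tol); False for the foundation law whose
    #: overlap is the physical foam compression.
    hard_contact: bool = False


def _trib_lengths(points: np.ndarray, ordered_nodes: np.ndarray) -> np.ndarray:
    """Consistent (Simpson) tributary lengths along a quadratic boundary.

    Boundary node arrays alternate corner/midside; each 3-node edge of
    straight length L contributes (L/6, 2L/3, L/6) so a uniform penalty
    penetration produces the consistent uniform-traction load vector.
    """
    x = points[ordered_nodes]
    trib = np.zeros(len(ordered_nodes))
    if len(ordered_nodes) < 3:
        return trib
    L = np.linalg.norm(x[2::2] - x[0:-2:2], axis=1)
    trib[0:-2:2] += L / 6.0
    trib[1::2] += 2.0 * L / 3.0
    trib[2::2] += L / 6.0
    return trib


def build_scene(phantom_mesh: LabeledMesh, materials: MaterialTable,
                protocol: TractionProtocol,
                contact: ContactSpec | None = None,
                boundary: BoundarySpec | None = None,
                mat_thickness_mm: float = 10.0) -> Scene:
    """Position the phantom over the mat and set up contact and supports.

    The subject is placed 0.1 mm above the mat top (mat top at y = 0, mat
    underside at y = -thickness, the datum for the roller clearance). With
    the mat enabled the contact pair is the foam-wrapped roller (effective
    radius R + thickness, foundation stiffness = constrained foam modulus /
    thickness in series with the interface penalty) against the posterior
    skin; without it, the bare roller meets the skin with hard contact.
    """
    contact = contact or ContactSpec()
    boundary = boundary or BoundarySpec()
    skin_y = phantom_mesh.points[phantom_mesh.boundaries["posterior_skin"], 1].min()
    mesh = phantom_mesh.translated(0.0, SKIN_MAT_CLEARANCE_MM - skin_y)

    E_skin = materials.lookup_by_id(1).E        # SKIN
    h_ref = mesh.target_edge_mm or 5.0
    kappa_pen = contact.penalty_factor * E_skin / h_ref
    if protocol.include_mat:
        m = materials.lookup(MAT)
        M_mat = m.E * (1 - m.nu) / ((1 + m.nu) * (1 - 2 * m.nu))
        k_found = M_mat / mat_thickness_mm
        pen_roll = 1.0 / (1.0 / k_found + 1.0 / kappa_pen)
        radius_eff = protocol.roller_radius_mm + mat_thickness_mm
        mat_underside_y = -mat_thickness_mm
        hard = False
    else:
        pen_roll = kappa_pen
        radius_eff = protocol.roller_radius_mm
        mat_underside_y = float(
            mesh.points[mesh.boundaries["posterior_skin"], 1].min())
        hard = True

    fixed_nodes = []
    for face in ("cranial_face", "caudal_face"):
        nodes = mesh.boundaries[face]
        y = mesh.points[nodes, 1]
        cut = y.max() - boundary.anterior_fraction * (y.max() - y.min())
        sel = nodes[y >= cut]
        if len(sel) == 0:
            raise RuntimeError(f"empty fixed node set on {face}")
        fixed_nodes.append(sel)
    fixed = np.unique(np.concatenate(fixed_nodes))
    fixed_dofs = np.sort(np.concatenate([2 * fixed, 2 * fixed + 1]))

    skin = mesh.boundaries["posterior_skin"]
    if np.intersect1d(fixed, skin).size:
        raise RuntimeError("fixed node sets intersect the skin contact surface")

    return Scene(
        mesh=mesh, materials=materials, protocol=protocol, contact=contact,
        fixed_dofs=fixed_dofs,
        skin_nodes=skin, skin_trib=_trib_lengths(mesh.points, skin),
        mat_underside_y=mat_underside_y, radius_eff=radius_eff,
        penalty_roller=pen_roll, hard_contact=hard,
    )


# ---------------------------------------------------------------------------
# Contact evaluation
# ---------------------------------------------------------------------------

def _new_multipliers(scene: Scene) -> dict[str, np.ndarray]:
    return {"roller": np.zeros((len(scene.protocol.roller_center_x),
                                len(scene.skin_nodes)))}


def _ramp(s: float, s0: float) -> tuple[float, float]:
    """C1-regularized positive part: traction and slope for the Newton
    tangent. Quadratic blend on [0, s0] removes the kink at contact onset
    (s0 is a tiny pressure, penalty * ~1e-3 mm of penetration)."""
    if s <= 0.0:
        return 0.0, 0.0
    if s < s0:
        return s * s / (2.0 * s0), s / s0
    return s - 0.5 * s0, 1.0


def _contact_system(scene: Scene, pos: np.ndarray, lift: float,
                    lam: dict[str, np.ndarray]):
    """Contact forces and tangent at current nodal positions.

    The normal traction at a slave skin node is t = max(0, lambda + kappa *
    pen) against each (foam-wrapped) rigid roller circle, with the positive
    part C1-regularized. For hard contact the outer Uzawa loop updates
    lambda so the converged penetration falls below the gap tolerance; for
    the foundation law lambda stays zero and the overlap is the physical
    foam compression.

    Returns (f, Kc_triplets, diag, pens): assembled force vector, tangent
    triplets, diagnostics, and signed penetrations for the multiplier
    update.
    """
    n_dof = 2 * len(pos)
    f = np.zeros(n_dof)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    diag = {"roller_active": 0, "max_penetration": 0.0,
            "roller_force": np.zeros(2), "pairs": []}

    slave, trib = scene.skin_nodes, scene.skin_trib
    R = scene.radius_eff
    kappa = scene.penalty_roller
    # physical roller center (the foam wrap enlarges the radius, not the
    # center): apex sits initial_clearance below the mat underside at rest
    centers = roller_centers(scene.protocol, 0, scene.mat_underside_y)
    centers[:, 1] += lift     # continuous lift (sub-increments included)
    pen_roller = np.full((len(centers), len(slave)), -np.inf)
    s0 = kappa * 1e-3
    for ci, c in enumerate(centers):
        d = pos[slave] - c
        r = np.linalg.norm(d, axis=1)
        pen = R - r
        ok = r > 1e-9
        pen_roller[ci, ok] = pen[ok]
        s_all = lam["roller"][ci] + kappa * pen
        act = np.flatnonzero((s_all > 0) & ok)
        diag["roller_active"] += int(np.count_nonzero(pen[act] > 0))
        for idx in act:
            trac, slope = _ramp(float(s_all[idx]), s0)
            node = slave[idx]
            n_vec = d[idx] / r[idx]
            fn = trac * trib[idx]
            f[2 * node:2 * node + 2] += fn * n_vec
            diag["roller_force"] += fn * n_vec
            diag["max_penetration"] = max(diag["max_penetration"],
                                          max(pen[idx], 0.0))
            diag["pairs"].append((-pen[idx], trac))
            # consistent tangent: penalty along n plus the curvature
            # (normal-rotation) term, clamped so overshooting iterates
            # cannot make the tangent indefinite
            kn = slope * kappa * trib[idx]
            kt = min(fn / max(r[idx], 0.5 * R), 0.5 * kn)
            nn = np.outer(n_vec, n_vec)
            kmat = kn * nn - kt * (np.eye(2) - nn)
            for a in range(2):
                for b in range(2):
                    rows.append(2 * node + a)
                    cols.append(2 * node + b)
                    vals.append(kmat[a, b])
    return f, (rows, cols, vals), diag, {"roller": pen_roller}


# ---------------------------------------------------------------------------
# Incremental solve
# ---------------------------------------------------------------------------

@dataclass
class LevelState:
    """Converged state at one traction level."""

    tl: int
    lift_mm: float
    u: np.ndarray                       # total displacement (n_nodes, 2)
    points: np.ndarray                  # current nodal positions
    sigma: np.ndarray                   # (E, 3qp, 4): sxx, syy, txy, szz
    eps: np.ndarray                     # (E, 3qp, 3): exx, eyy, gxy
    newton_iters: int
    residual: float
    contact_force: np.ndarray           # resultant roller force (N per mm)
    contact_active: int                 # slave nodes carrying contact force
    max_penetration: float
    complementarity: float


@dataclass
class FieldSolution:
    """Sequence of converged traction-level states on one scene."""

    scene: Scene
    levels: list[LevelState]
    log: list[str] = field(default_factory=list)

    def at_level(self, tl: int) -> LevelState:
        for st in self.levels:
            if st.tl == tl:
                return st
        raise KeyError(f"no state recorded for traction level {tl}")


class ConvergenceError(RuntimeError):
    pass


def _newton_increment(scene: Scene, K: sp.csr_matrix, free: np.ndarray,
                      pts: np.ndarray, fint0: np.ndarray, lift: float,
                      settings: SolverSettings, lam: dict[str, np.ndarray]):
    """Solve one increment with an augmented-Lagrange outer loop.

    Inner semi-smooth Newton iterations converge the equilibrium for the
    current multipliers; the outer Uzawa updates lambda <- max(0, lambda +
    kappa * pen) until the residual penetration drops below the hard-contact
    tolerance. Returns (d, lam, diag, total_iters, resnorm).
    """
    n_dof = 2 * len(pts)
    d = np.zeros(n_dof)
    total_it = 0
    gap_tol = scene.contact.gap_tol_mm
    lu = None
    for outer in range(scene.contact.max_augment):
        converged = False
        resnorm = np.inf
        res_prev = np.inf
        rebuild = True
        for _ in range(settings.max_newton):
            pos = pts + d.reshape(-1, 2)
            fc, trip, diag, pens = _contact_system(scene, pos, lift, lam)
            R = K @ d + fint0 - fc
            scale = max(float(np.linalg.norm(fc[free])),
                        float(np.linalg.norm(fint0[free])), 1e-8)
            resnorm = float(np.linalg.norm(R[free]))
            if resnorm <= settings.rtol * scale:
                converged = True
                break
            total_it += 1
            # modified Newton: reuse the factorization while progress holds
            if resnorm > 0.7 * res_prev:
                rebuild = True
            if rebuild or lu is None:
                if trip[0]:
                    Kc = sp.coo_matrix((trip[2], (trip[0], trip[1])),
                                       shape=(n_dof, n_dof)).tocsr()
                    A = K + Kc
                else:
                    A = K
                lu = spla.splu(A[free][:, free].tocsc())
                rebuild = False
            delta = np.zeros(n_dof)
            delta[free] = lu.solve(-R[free])
            # backtracking only on clear residual growth (chatter guard)
            step = 1.0
            for _ in range(3):
                d_try = d + step * delta
                fc_t, _, _, _ = _contact_system(
                    scene, pts + d_try.reshape(-1, 2), lift, lam)
                r_t = float(np.linalg.norm((K @ d_try + fint0 - fc_t)[free]))
                if r_t < 1.5 * resnorm or step < 0.3:
                    break
                step *= 0.5
            d = d + step * delta
            res_prev = resnorm
        if not converged:
            raise ConvergenceError(
                f"contact Newton did not converge in {settings.max_newton} "
                f"iterations (residual {resnorm:.3e} at lift {lift:.3f} mm)")
        if not scene.hard_contact:
            # foundation law: the overlap is the physical foam compression
            return d, lam, diag, total_it, resnorm
        max_pen = float(np.max(pens["roller"], initial=-np.inf))
        # converged when penetration is below the hard-contact tolerance and
        # the complementarity defect |gap * traction| is small everywhere
        # (this also rules out stale multipliers pushing on separated nodes)
        comp = max((abs(g * p) for g, p in diag["pairs"]), default=0.0)
        if max_pen <= gap_tol and comp <= scene.contact.comp_tol:
            return d, lam, diag, total_it, resnorm
        lam = {"roller": np.maximum(0.0, lam["roller"]
                                    + scene.penalty_roller * pens["roller"])}
    raise ConvergenceError(
        f"augmented-Lagrange loop did not reach penetration <= {gap_tol} mm "
        f"in {scene.contact.max_augment} updates (lift {lift:.3f} mm)")


def solve_traction(mesh: LabeledMesh, materials: MaterialTable,
                   protocol: TractionProtocol,
                   boundary: BoundarySpec | None = None, tl: int = 9,
                   contact: ContactSpec | None = None,
                   settings: SolverSettings | None = None,
                   scene: Scene | None = None) -> FieldSolution:
    """Drive the rollers from rest to traction level ``tl``.

    One increment per level by default (with automatic bisection on
    non-convergence); a LevelState snapshot is recorded at every integer
    level so a single run yields the whole stress-vs-TL curve.
    """
    settings = settings or SolverSettings()
    if scene is None:
        scene = build_scene(mesh, materials, protocol, contact, boundary)
    if not 0 <= tl <= scene.protocol.n_levels:
        raise ValueError(f"traction level {tl} out of range")

    n_dof = 2 * scene.mesh.n_nodes
    free = np.ones(n_dof, dtype=bool)
    free[scene.fixed_dofs] = False

    pts = scene.mesh.points.copy()
    E, Q = scene.mesh.n_elems, len(QP)
    sigma = np.zeros((E, Q, 4))
    eps = np.zeros((E, Q, 3))
    u_total = np.zeros((len(pts), 2))
    D, nu_e = _element_D(scene.mesh, scene.materials)
    sol = FieldSolution(scene=scene, levels=[])

    def record(level: int, lift: float, diag, iters: int, resnorm: float):
        comp = max((abs(g * p) for g, p in diag["pairs"]), default=0.0)
        sol.levels.append(LevelState(
            tl=level, lift_mm=lift, u=u_total.copy(), points=pts.copy(),
            sigma=sigma.copy(), eps=eps.copy(), newton_iters=iters,
            residual=resnorm, contact_force=diag["roller_force"].copy(),
            contact_active=diag["roller_active"],
            max_penetration=diag["max_penetration"], complementarity=comp))
        sol.log.append(
            f"TL{level}: lift={lift:7.3f} mm  newton={iters:3d}  "
            f"residual={resnorm:.3e}  active={diag['roller_active']}  "
            f"Fy={diag['roller_force'][1]:.4f} N/mm  "
            f"overlap_max={diag['max_penetration']:.2e} mm")

    lam = _new_multipliers(scene)

    def apply_increment(lift0: float, lift1: float, depth: int) -> tuple:
        nonlocal pts, sigma, eps, u_total, lam
        K = assemble_stiffness(scene.mesh, scene.materials, points=pts)
        fint0 = _internal_force(scene.mesh, pts, sigma[:, :, :3])
        try:
            d, lam_new, diag, iters, resnorm = _newton_increment(
                scene, K, free, pts, fint0, lift1, settings,
                {k: v.copy() for k, v in lam.items()})
        except ConvergenceError:
            if depth >= settings.max_bisect:
                raise
            mid = 0.5 * (lift0 + lift1)
            apply_increment(lift0, mid, depth + 1)
            return apply_increment(mid, lift1, depth + 1)
        lam = lam_new
        du = d.reshape(-1, 2)
        _, B = _element_geometry(pts, scene.mesh.tris)
        d_eps = np.einsum("eqki,ei->eqk", B,
                          du[scene.mesh.tris].reshape(len(B), 12))
        d_sig = np.einsum("ekl,eql->eqk", D, d_eps)
        sigma[:, :, :3] += d_sig
        sigma[:, :, 3] += nu_e[:, None] * (d_sig[:, :, 0] + d_sig[:, :, 1])
        eps += d_eps
        u_total = u_total + du
        if settings.kinematics == "updated":
            pts = pts + du
            a = _signed_areas(pts, scene.mesh.tris)
            if np.any(a <= 0):
                raise ConvergenceError(
                    "element inversion after geometry update; rerun with "
                    "finer increments (increments_per_level)")
        return diag, iters, resnorm

    schedule = scene.protocol.schedule()
    if settings.kinematics == "small":
        diag, iters, resnorm = apply_increment(0.0, schedule[tl], 0)
        record(tl, schedule[tl], diag, iters, resnorm)
        return sol

    per = settings.increments_per_level
    prev = 0.0
    for level in range(0, tl + 1):
        if level == 0:
            lifts = [0.0]
        else:
            lifts = np.linspace(schedule[level - 1], schedule[level], per + 1)[1:]
        for lift in lifts:
            diag, iters, resnorm = apply_increment(prev, float(lift), 0)
            prev = float(lift)
        record(level, float(schedule[level]), diag, iters, resnorm)
    return sol


def _signed_areas(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    a, b, c = (points[tris[:, k]] for k in range(3))
    return 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                  - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0]))


# ---------------------------------------------------------------------------
# Field recovery
# ---------------------------------------------------------------------------

def von_mises(sigma4: np.ndarray) -> np.ndarray:
    """Von Mises scalar from (sxx, syy, txy, szz) stacked on the last axis."""
    sxx, syy, txy, szz = (sigma4[..., k] for k in range(4))
    return np.sqrt(0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2
                          + (szz - sxx) ** 2) + 3.0 * txy ** 2)


def equivalent_strain(eps3: np.ndarray) -> np.ndarray:
    """Von-Mises-equivalent strain sqrt(2/3 e:e) of the deviatoric strain.

    Plane strain: ezz = 0 and the engineering shear gxy enters as exy = g/2.
    """
    exx, eyy, gxy = (eps3[..., k] for k in range(3))
    tr = (exx + eyy) / 3.0
    dxx, dyy, dzz = exx - tr, eyy - tr, -tr
    ee = dxx ** 2 + dyy ** 2 + dzz ** 2 + 2.0 * (0.5 * gxy) ** 2
    return np.sqrt(2.0 / 3.0 * ee)


def element_nodal_values(qp_values: np.ndarray) -> np.ndarray:
    """Extrapolate (E, 3qp, ...) quadrature values to (E, 6, ...) nodes."""
    return np.einsum("nq,eq...->en...", _EXTRAP, qp_values)


def nodal_average(mesh: LabeledMesh, elem_nodal: np.ndarray,
                  elements: np.ndarray | None = None) -> np.ndarray:
    """Average element-nodal values to mesh nodes (optionally restricted to a
    subset of elements, e.g. one tissue region)."""
    els = np.arange(mesh.n_elems) if elements is None else elements
    shape = (mesh.n_nodes,) + elem_nodal.shape[2:]
    acc = np.zeros(shape)
    cnt = np.zeros(mesh.n_nodes)
    idx = mesh.tris[els].ravel()
    np.add.at(acc, idx, elem_nodal[els].reshape((-1,) + elem_nodal.shape[2:]))
    np.add.at(cnt, idx, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = acc / np.where(cnt > 0, cnt, np.nan)[(...,) + (None,) * (acc.ndim - 1)]
    return out


def recover_fields(state: LevelState, mesh: LabeledMesh,
                   materials: MaterialTable) -> dict[str, np.ndarray]:
    """Nodal stress/strain tensors and equivalent scalars for one level.

    Quadrature-point values are linearly extrapolated to element nodes and
    averaged across the elements sharing each node. Von Mises uses the full
    3D tensor including the plane-strain szz.
    """
    sig_n = element_nodal_values(state.sigma)
    eps_n = element_nodal_values(state.eps)
    stress = nodal_average(mesh, sig_n)
    strain = nodal_average(mesh, eps_n)
    return {
        "displacement": state.u,
        "stress": stress,
        "strain": strain,
        "von_mises": von_mises(stress),
        "eq_strain": equivalent_strain(strain),
    }
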