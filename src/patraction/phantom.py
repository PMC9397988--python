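"""Synthetic mid-sagittal lumbar phantom: geometry and labeled meshing.

The phantom stands in for a segmented mid-sagittal MRI of the lower back of a
supine subject. It is a layered slab in the (x, y) plane, x increasing
craniocaudally (head -> sacrum) and y anteriorly; the posterior skin is the
y-minimum surface facing the bed mat and rollers. Because the subject lies
supine, the posterior skin is modeled flat (the back flattened against the
mat) and the lumbar lordosis lives in the spine: the vertebral column follows
an anterior-convex arc, carried by a paraspinal muscle band whose thickness
grows by the lordosis bump toward mid-lumbar levels.

Layer stack from the skin inward: skin (~1 mm), subcutaneous fat (13/26/52/86
mm across the four BMI classes), soft tissue, muscle, then the spinal-canal
strips (epidural fat, CSF, cord) and the vertebral column (seven vertebral
bodies T12..S alternating with the six lumbar discs T12-L1..L5-S), and
finally an anterior soft-tissue band. Optionally the sacrum extends through
the anterior band, anchoring the caudal end of the column to the anterior
boundary the way the sacrum/pelvis mass does.

BMI variants are produced exactly as higher-BMI anatomies are derived from a
normal-BMI scan: the fat layer is dilated outward (posteriorly, i.e. normal
to the flat skin) and the ~1 mm skin recovered outside it, leaving every
deeper tissue untouched.

Meshing is a structured, conforming, mapped triangulation into 6-node
quadratic triangles: layer interfaces and vertebra/disc boundaries coincide
with mesh lines, so region interfaces share nodes by construction and every
element carries exactly one region label.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .regions import (
    CORD, CSF, DISC, DISC_LEVELS, EPIDURAL_FAT, MAT, MUSCLE,
    RegionLabel, SKIN, SOFT_TISSUE, SUBCUT_FAT, VERTEBRA, VERTEBRA_LEVELS,
)

__all__ = [
    "PhantomSpec", "Geometry", "LabeledMesh", "BMI_FAT_THICKNESS_MM",
    "bmi_class_fat_thickness", "build_phantom", "dilate_fat",
    "mesh_geometry", "build_mat_mesh",
]

#: Subcutaneous fat thickness (mm) defining the four BMI-class phantoms.
BMI_FAT_THICKNESS_MM: dict[str, float] = {
    "normal": 13.0,
    "overweight": 26.0,
    "moderate_obese": 52.0,
    "extreme_obese": 86.0,
}
#: The extreme-obese class is also referred to as "severe obese".
_BMI_ALIASES = {"severe_obese": "extreme_obese"}


def bmi_class_fat_thickness(class_name: str) -> float:
    """Fat-layer thickness (mm) for a named BMI class.

    normal -> 13, overweight -> 26, moderate_obese -> 52, extreme_obese -> 86.
    """
    name = _BMI_ALIASES.get(class_name, class_name)
    try:
        return BMI_FAT_THICKNESS_MM[name]
    except KeyError:
        raise ValueError(
            f"unknown BMI class {class_name!r}; valid classes: "
            f"{sorted(BMI_FAT_THICKNESS_MM)}") from None


@dataclass(frozen=True)
class PhantomSpec:
    """All geometric parameters of the synthetic phantom (lengths in mm)."""

    body_length_mm: float = 380.0
    skin_mm: float = 1.0
    fat_mm: float = 13.0
    muscle_mm: float = 30.0
    soft_tissue_mm: float = 15.0
    anterior_soft_mm: float = 25.0
    lordosis_depth_mm: float = 20.0
    lordosis_span_mm: float = 270.0
    vertebra_height_mm: float = 30.0
    vertebra_depth_mm: float = 35.0
    disc_height_mm: float = 10.0
    epidural_fat_mm: float = 4.0
    csf_mm: float = 4.0
    cord_mm: float = 8.0
    canal_enabled: bool = True
    #: Extend the sacrum through the anterior band (pelvis anchoring).
    sacrum_anchor: bool = False
    mat_thickness_mm: float = 10.0
    mesh_target_edge_mm: float = 4.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = ["body_length_mm", "skin_mm", "fat_mm", "muscle_mm",
                    "soft_tissue_mm", "anterior_soft_mm", "lordosis_span_mm",
                    "vertebra_height_mm", "vertebra_depth_mm",
                    "disc_height_mm", "mat_thickness_mm",
                    "mesh_target_edge_mm"]
        if self.canal_enabled:
            positive += ["epidural_fat_mm", "csf_mm", "cord_mm"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, "
                                 f"got {getattr(self, name)}")
        if self.lordosis_span_mm > self.body_length_mm:
            raise ValueError(
                "self-intersecting lordosis parameters: lordosis_span_mm="
                f"{self.lordosis_span_mm} exceeds body_length_mm="
                f"{self.body_length_mm}")
        if self.lordosis_depth_mm <= -self.muscle_mm:
            raise ValueError(
                "self-intersecting lordosis parameters: lordosis_depth_mm="
                f"{self.lordosis_depth_mm} collapses the muscle band "
                f"(muscle_mm={self.muscle_mm})")
        if self.column_length_mm > self.body_length_mm:
            raise ValueError(
                f"vertebral column ({self.column_length_mm} mm) does not fit "
                f"in body_length_mm={self.body_length_mm}")

    @property
    def column_length_mm(self) -> float:
        return (len(VERTEBRA_LEVELS) * self.vertebra_height_mm
                + len(DISC_LEVELS) * self.disc_height_mm)

    @property
    def margin_mm(self) -> float:
        """Soft-tissue margin between each body end and the column."""
        return 0.5 * (self.body_length_mm - self.column_length_mm)

    @property
    def canal_mm(self) -> float:
        if not self.canal_enabled:
            return 0.0
        return self.epidural_fat_mm + self.csf_mm + self.cord_mm


class Geometry:
    """Labeled planar regions of the phantom as a layered stack.

    The geometry is functional: every band interface is a y(x) profile and
    region membership is resolved from (band, x). ``y = 0`` is pinned at the
    fat / soft-tissue interface so that changing the fat thickness (the BMI
    dilation) only extends the skin+fat layers posteriorly and leaves every
    deeper tissue coordinate bit-identical.
    """

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        x0 = spec.margin_mm
        segments: list[tuple[float, float, RegionLabel]] = []
        x = x0
        for i, lv in enumerate(VERTEBRA_LEVELS):
            segments.append((x, x + spec.vertebra_height_mm, VERTEBRA(lv)))
            x += spec.vertebra_height_mm
            if i < len(DISC_LEVELS):
                segments.append((x, x + spec.disc_height_mm, DISC(DISC_LEVELS[i])))
                x += spec.disc_height_mm
        self.column_segments = segments
        self.column_x = (x0, x)

    # -- profiles ----------------------------------------------------------
    def lordosis_bump(self, x: np.ndarray) -> np.ndarray:
        """Anterior offset of the spine (mm): a smooth sin^2 lordotic arc."""
        s = self.spec
        x = np.asarray(x, float)
        c = 0.5 * s.body_length_mm
        lo, hi = c - 0.5 * s.lordosis_span_mm, c + 0.5 * s.lordosis_span_mm
        t = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
        return s.lordosis_depth_mm * np.sin(np.pi * t) ** 2

    def segment_label(self, x: float) -> RegionLabel:
        """Column-band region at craniocaudal position x (SOFT_TISSUE in the
        margins beyond the column)."""
        for (a, b, lab) in self.column_segments:
            if a <= x < b or (x == b == self.column_x[1]):
                return lab
        return SOFT_TISSUE

    def bands(self) -> list[dict]:
        """Bottom-up list of layer bands.

        Each band: name, y_bot(x), y_top(x) callables and a resolve(x) ->
        RegionLabel for element labeling.
        """
        s = self.spec
        out: list[dict] = []

        def const(v):
            return lambda x: np.full_like(np.asarray(x, float), v)

        y_fat_bot = -s.fat_mm
        y_skin_bot = y_fat_bot - s.skin_mm
        out.append(dict(name="skin", y_bot=const(y_skin_bot),
                        y_top=const(y_fat_bot), resolve=lambda x: SKIN))
        out.append(dict(name="fat", y_bot=const(y_fat_bot), y_top=const(0.0),
                        resolve=lambda x: SUBCUT_FAT))
        out.append(dict(name="soft_tissue", y_bot=const(0.0),
                        y_top=const(s.soft_tissue_mm),
                        resolve=lambda x: SOFT_TISSUE))
        base = s.soft_tissue_mm

        def muscle_top(x, base=base):
            return base + s.muscle_mm + self.lordosis_bump(x)

        out.append(dict(name="muscle", y_bot=const(base), y_top=muscle_top,
                        resolve=lambda x: MUSCLE))
        prev = muscle_top
        cx0, cx1 = self.column_x

        def in_column(x):
            return cx0 <= x <= cx1

        if s.canal_enabled:
            for nm, lab, th in (("epidural_fat", EPIDURAL_FAT, s.epidural_fat_mm),
                                ("csf", CSF, s.csf_mm),
                                ("cord", CORD, s.cord_mm)):
                def top(x, prev=prev, th=th):
                    return prev(x) + th
                out.append(dict(
                    name=nm, y_bot=prev, y_top=top,
                    resolve=(lambda x, lab=lab:
                             lab if in_column(x) else SOFT_TISSUE)))
                prev = top

        def column_top(x, prev=prev):
            return prev(x) + s.vertebra_depth_mm

        out.append(dict(name="column", y_bot=prev, y_top=column_top,
                        resolve=lambda x: self.segment_label(x)))

        def anterior_top(x):
            return column_top(x) + s.anterior_soft_mm

        sac = self.column_segments[-1]

        def resolve_anterior(x):
            if s.sacrum_anchor and sac[0] <= x <= sac[1]:
                return VERTEBRA("S")
            return SOFT_TISSUE

        out.append(dict(name="anterior", y_bot=column_top, y_top=anterior_top,
                        resolve=resolve_anterior))
        return out

    # -- derived quantities ------------------------------------------------
    def region_area(self, label: RegionLabel, n_sample: int = 4001) -> float:
        """Exact-to-quadrature polygonal area (mm^2) of one region."""
        s = self.spec
        x = np.linspace(0.0, s.body_length_mm, n_sample)
        total = 0.0
        for band in self.bands():
            th = band["y_top"](x) - band["y_bot"](x)
            xm = 0.5 * (x[1:] + x[:-1])
            thm = 0.5 * (th[1:] + th[:-1])
            mask = np.array([band["resolve"](v) == label for v in xm])
            total += float(np.sum(thm[mask] * np.diff(x)[mask]))
        return total

    def posterior_skin_y(self) -> float:
        s = self.spec
        return -(s.fat_mm + s.skin_mm)

    def total_depth_mm(self, x: float = None) -> float:
        s = self.spec
        if x is None:
            x = 0.5 * s.body_length_mm
        top = self.bands()[-1]["y_top"](np.asarray([x]))[0]
        return top - self.posterior_skin_y()


def build_phantom(spec: PhantomSpec) -> Geometry:
    """Construct the labeled planar geometry of the phantom.

    Raises ValueError for geometrically inconsistent parameters (the
    PhantomSpec validators name the offending parameter).
    """
    return Geometry(spec)


def dilate_fat(geometry: Geometry, new_fat_mm: float) -> Geometry:
    """Thicken the subcutaneous fat layer to ``new_fat_mm``.

    This is the planar analogue of the isometric dilation used to derive
    higher-BMI anatomies from a normal-BMI scan: fat and skin are pushed
    outward normal to the (flat) original skin surface, the skin keeps its
    original thickness, and every deeper tissue is bit-identical. Dilations
    compose exactly: 13 -> 26 -> 52 equals 13 -> 52.
    """
    if new_fat_mm < geometry.spec.fat_mm:
        raise ValueError(
            f"fat can only be dilated: requested {new_fat_mm} mm < current "
            f"{geometry.spec.fat_mm} mm")
    return Geometry(dataclasses.replace(geometry.spec, fat_mm=float(new_fat_mm)))


# ---------------------------------------------------------------------------
# Labeled mesh
# ---------------------------------------------------------------------------

@dataclass
class LabeledMesh:
    """Conforming 6-node-triangle mesh with per-element region labels.

    points: (n_nodes, 2) coordinates in mm.
    tris:   (n_elem, 6) connectivity; corners (0,1,2) counter-clockwise then
            midside nodes on edges (0-1), (1-2), (2-0) (VTK/Gmsh ordering).
    region_id: (n_elem,) integer region of each element.
    boundaries: named ordered node-index arrays (e.g. "posterior_skin",
            "anterior", "cranial_face", "caudal_face"; mat meshes use
            "mat_top", "mat_bottom", "mat_ends").
    """

    points: np.ndarray
    tris: np.ndarray
    region_id: np.ndarray
    boundaries: dict[str, np.ndarray] = field(default_factory=dict)
    target_edge_mm: float | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def n_elems(self) -> int:
        return len(self.tris)

    def signed_areas(self) -> np.ndarray:
        p = self.points
        a, b, c = (p[self.tris[:, k]] for k in range(3))
        return 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                      - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0]))

    def region_ids_present(self) -> np.ndarray:
        return np.unique(self.region_id)

    def region_elements(self, label: RegionLabel) -> np.ndarray:
        return np.flatnonzero(self.region_id == label.id)

    def region_nodes(self, label: RegionLabel) -> np.ndarray:
        els = self.region_elements(label)
        return np.unique(self.tris[els])

    def region_area(self, label: RegionLabel) -> float:
        return float(self.signed_areas()[self.region_elements(label)].sum())

    def validate(self, min_disc_nodes: int = 50) -> None:
        """Raise AssertionError if any mesh invariant is violated."""
        areas = self.signed_areas()
        assert np.all(areas > 0), "inverted or zero-area elements present"
        assert self.tris.max() < self.n_nodes
        # conformity: midside nodes bisect their corner edges (shared by
        # construction in the structured mesher, but re-checked here)
        p = self.points
        for (e0, e1, m) in ((0, 1, 3), (1, 2, 4), (2, 0, 5)):
            mid = 0.5 * (p[self.tris[:, e0]] + p[self.tris[:, e1]])
            assert np.allclose(mid, p[self.tris[:, m]], atol=1e-9), \
                "midside nodes off their edges"
        for lv in DISC_LEVELS:
            if DISC(lv).id in self.region_id:
                n = len(self.region_nodes(DISC(lv)))
                assert n >= min_disc_nodes, \
                    f"disc {lv} has only {n} nodes (< {min_disc_nodes})"

    def merged_with(self, other: "LabeledMesh") -> tuple["LabeledMesh", int]:
        """Concatenate two disconnected bodies; returns (mesh, node offset of
        ``other`` in the merged numbering)."""
        off = self.n_nodes
        bnd = dict(self.boundaries)
        for k, v in other.boundaries.items():
            bnd[k] = v + off
        return LabeledMesh(
            points=np.vstack([self.points, other.points]),
            tris=np.vstack([self.tris, other.tris + off]),
            region_id=np.concatenate([self.region_id, other.region_id]),
            boundaries=bnd,
            target_edge_mm=self.target_edge_mm,
        ), off

    def translated(self, dx: float, dy: float) -> "LabeledMesh":
        return LabeledMesh(self.points + np.array([dx, dy]), self.tris,
                           self.region_id, self.boundaries, self.target_edge_mm)


def _subdivide(breaks: list[float], target: float) -> np.ndarray:
    """Grid including every breakpoint, intervals split to <= target."""
    xs = [breaks[0]]
    for a, b in zip(breaks[:-1], breaks[1:]):
        n = max(1, int(np.ceil((b - a) / target - 1e-12)))
        xs.extend(np.linspace(a, b, n + 1)[1:])
    return np.asarray(xs)


def _structured_t6(corner_x: np.ndarray, corner_y: np.ndarray,
                   quad_region: np.ndarray) -> tuple[np.ndarray, np.ndarray,
                                                     np.ndarray]:
    """Mapped structured grid -> T6 triangles.

    corner_x: (nx+1,) craniocaudal grid; corner_y: (nx+1, ny+1) mapped
    ordinates; quad_region: (nx, ny) region id per quad. Each quad is split
    along its (i,j)-(i+1,j+1) diagonal; midside nodes sit at straight-edge
    midpoints so elements are straight-sided (sub-parametric).
    """
    nx = len(corner_x) - 1
    ny = corner_y.shape[1] - 1
    NX, NY = 2 * nx + 1, 2 * ny + 1
    X = np.empty((NX, NY))
    Y = np.empty((NX, NY))
    X[0::2, 0::2] = corner_x[:, None]
    Y[0::2, 0::2] = corner_y
    # edge midpoints and diagonal midpoints from corner averages
    X[1::2, 0::2] = 0.5 * (X[0:-1:2, 0::2] + X[2::2, 0::2])
    Y[1::2, 0::2] = 0.5 * (Y[0:-1:2, 0::2] + Y[2::2, 0::2])
    X[0::2, 1::2] = 0.5 * (X[0::2, 0:-1:2] + X[0::2, 2::2])
    Y[0::2, 1::2] = 0.5 * (Y[0::2, 0:-1:2] + Y[0::2, 2::2])
    X[1::2, 1::2] = 0.5 * (X[0:-1:2, 0:-1:2] + X[2::2, 2::2])
    Y[1::2, 1::2] = 0.5 * (Y[0:-1:2, 0:-1:2] + Y[2::2, 2::2])

    def nid(i, j):
        return i * NY + j

    points = np.column_stack([X.ravel(), Y.ravel()])
    I, J = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    i2, j2 = 2 * I.ravel(), 2 * J.ravel()
    c00, c10 = nid(i2, j2), nid(i2 + 2, j2)
    c11, c01 = nid(i2 + 2, j2 + 2), nid(i2, j2 + 2)
    m_b, m_r = nid(i2 + 1, j2), nid(i2 + 2, j2 + 1)
    m_t, m_l = nid(i2 + 1, j2 + 2), nid(i2, j2 + 1)
    m_d = nid(i2 + 1, j2 + 1)
    t1 = np.column_stack([c00, c10, c11, m_b, m_r, m_d])
    t2 = np.column_stack([c00, c11, c01, m_d, m_t, m_l])
    tris = np.empty((2 * len(c00), 6), dtype=np.int64)
    tris[0::2] = t1
    tris[1::2] = t2
    region = np.repeat(quad_region.ravel(), 2)
    return points, tris, region


def mesh_geometry(geometry: Geometry,
                  target_edge_mm: float | None = None) -> LabeledMesh:
    """Mesh the phantom into a labeled conforming T6 triangulation.

    Band interfaces and vertebra/disc boundaries are mesh lines; each band
    receives ceil(thickness / target) element rows and each craniocaudal
    interval ceil(length / target) columns, so in-plane edge lengths track
    the target except across layers thinner than it (the ~1 mm skin).
    """
    spec = geometry.spec
    target = float(target_edge_mm or spec.mesh_target_edge_mm)
    if target <= 0:
        raise ValueError("target edge must be positive")
    bands = geometry.bands()

    breaks = [0.0, *dict.fromkeys(b for seg in geometry.column_segments
                                  for b in (seg[0], seg[1])),
              spec.body_length_mm]
    breaks = sorted(set(breaks))
    xs = _subdivide(breaks, target)
    nx = len(xs) - 1

    # per-band row counts from the band's mean thickness
    rows: list[tuple[int, dict]] = []
    for band in bands:
        th = band["y_top"](xs) - band["y_bot"](xs)
        n = max(1, int(np.ceil(th.mean() / target - 1e-12)))
        rows.append((n, band))
    ny = sum(n for n, _ in rows)

    corner_y = np.empty((nx + 1, ny + 1))
    quad_region = np.empty((nx, ny), dtype=np.int64)
    band_rows: dict[str, tuple[int, int]] = {}
    j0 = 0
    xmid = 0.5 * (xs[:-1] + xs[1:])
    for n, band in rows:
        yb, yt = band["y_bot"](xs), band["y_top"](xs)
        for k in range(n + 1):
            f = k / n
            corner_y[:, j0 + k] = (1 - f) * yb + f * yt
        labels = np.array([band["resolve"](v).id for v in xmid])
        quad_region[:, j0:j0 + n] = labels[:, None]
        band_rows[band["name"]] = (j0, j0 + n)
        j0 += n

    points, tris, region = _structured_t6(xs, corner_y, quad_region)

    NY = 2 * ny + 1
    NX = 2 * nx + 1
    ii = np.arange(NX)
    jj = np.arange(NY)
    boundaries = {
        "posterior_skin": ii * NY + 0,                  # ordered by x
        "anterior": ii * NY + (NY - 1),
        "cranial_face": jj,                             # i = 0 column
        "caudal_face": (NX - 1) * NY + jj,
    }
    mesh = LabeledMesh(points, tris, region, boundaries, target)
    mesh.validate(min_disc_nodes=0)   # geometric sanity; node counts checked
    return mesh                       # separately where ROI averaging is used


def build_mat_mesh(length_mm: float, thickness_mm: float,
                   target_edge_mm: float, x0: float = 0.0,
                   y_top: float = 0.0) -> LabeledMesh:
    """Rectangular bed-mat strip with its top surface at ``y_top``."""
    xs = _subdivide([x0, x0 + length_mm], target_edge_mm)
    n_rows = max(1, int(np.ceil(thickness_mm / target_edge_mm - 1e-12)))
    yv = np.linspace(y_top - thickness_mm, y_top, n_rows + 1)
    corner_y = np.tile(yv, (len(xs), 1))
    quad_region = np.full((len(xs) - 1, n_rows), MAT.id, dtype=np.int64)
    points, tris, region = _structured_t6(xs, corner_y, quad_region)
    NY = 2 * n_rows + 1
    NX = 2 * (len(xs) - 1) + 1
    ii = np.arange(NX)
    jj = np.arange(NY)
    boundaries = {
        "mat_bottom": ii * NY + 0,
        "mat_top": ii * NY + (NY - 1),
        "mat_ends": np.concatenate([jj, (NX - 1) * NY + jj]),
    }
    return LabeledMesh(points, tris, region, boundaries, target_edge_mm)


# ---------------------------------------------------------------------------
# Measurement helpers (used by tests and reporting)
# ---------------------------------------------------------------------------

def measure_fat_thickness(mesh: LabeledMesh) -> float:
    """Maximum posterior fat-layer thickness measured normal to the skin.

    The posterior skin is flat, so the surface normal is vertical and the
    thickness is the y-extent of the fat region at fixed x.
    """
    nodes = mesh.region_nodes(SUBCUT_FAT)
    pts = mesh.points[nodes]
    best = 0.0
    for x in np.unique(np.round(pts[:, 0], 6)):
        col = pts[np.isclose(pts[:, 0], x, atol=1e-6)]
        best = max(best, float(col[:, 1].max() - col[:, 1].min()))
    return best


def disc_centroids(mesh: LabeledMesh) -> dict[str, np.ndarray]:
    """Area-weighted centroid of each disc region."""
    areas = mesh.signed_areas()
    out = {}
    for lv in DISC_LEVELS:
        els = mesh.region_elements(DISC(lv))
        cent = mesh.points[mesh.tris[els][:, :3]].mean(axis=1)
        w = areas[els]
        out[lv] = (cent * w[:, None]).sum(axis=0) / w.sum()
    return out
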