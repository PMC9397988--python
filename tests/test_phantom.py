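"""Phantom geometry, BMI fat dilation and the labeled structured mesh."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import patraction as pt
from patraction import phantom as ph
from patraction.regions import (DISC, DISC_LEVELS, ID_TO_LABEL, MAT, SKIN,
                                SUBCUT_FAT, VERTEBRA)

from conftest import make_coarse_spec


@pytest.mark.parametrize("name,mm", [
    ("normal", 13.0), ("overweight", 26.0),
    ("moderate_obese", 52.0), ("extreme_obese", 86.0),
])
def test_bmi_class_fat_thickness(name, mm):
    assert ph.bmi_class_fat_thickness(name) == mm


def test_unknown_bmi_class_lists_valid_names():
    with pytest.raises(ValueError, match="overweight"):
        ph.bmi_class_fat_thickness("athletic")


def test_phantom_region_inventory():
    mesh = ph.mesh_geometry(ph.build_phantom(make_coarse_spec()))
    present = {ID_TO_LABEL[int(i)] for i in mesh.region_ids_present()}
    assert sum(1 for r in present if r.kind == "DISC") == 6
    assert sum(1 for r in present if r.kind == "VERTEBRA") == 7
    for lv in DISC_LEVELS:
        assert DISC(lv) in present
    # every non-mat tissue class appears in the default phantom
    kinds = {r.kind for r in present}
    assert kinds >= {"SKIN", "SUBCUT_FAT", "SOFT_TISSUE", "MUSCLE",
                     "EPIDURAL_FAT", "CSF", "CORD"}


def test_fat_thickness_measured_normal_to_skin():
    mesh = ph.mesh_geometry(ph.build_phantom(make_coarse_spec(fat_mm=13.0)))
    assert ph.measure_fat_thickness(mesh) == pytest.approx(13.0, abs=0.5)


def test_straight_spine_when_lordosis_zero():
    spec = make_coarse_spec(lordosis_depth_mm=1e-12)
    mesh = ph.mesh_geometry(ph.build_phantom(spec))
    cents = ph.disc_centroids(mesh)
    ys = np.array([c[1] for c in cents.values()])
    assert np.ptp(ys) <= 1e-9


def test_invalid_spec_names_offending_parameter():
    with pytest.raises(ValueError, match="fat_mm"):
        pt.PhantomSpec(fat_mm=-1.0)
    with pytest.raises(ValueError, match="lordosis_span_mm"):
        pt.PhantomSpec(lordosis_span_mm=1000.0)
    with pytest.raises(ValueError, match="lordosis_depth_mm"):
        pt.PhantomSpec(lordosis_depth_mm=-60.0)


# -- dilation ---------------------------------------------------------------

def _region_points(mesh, exclude_kinds=("SKIN", "SUBCUT_FAT")):
    keep = [i for i in mesh.region_ids_present()
            if ID_TO_LABEL[int(i)].kind not in exclude_kinds]
    nodes = np.unique(mesh.tris[np.isin(mesh.region_id, keep)])
    pts = mesh.points[nodes]
    return pts[np.lexsort((pts[:, 1], pts[:, 0]))]


def test_dilate_identity():
    geo = ph.build_phantom(make_coarse_spec())
    same = ph.dilate_fat(geo, 13.0)
    assert same.spec == geo.spec


def test_dilate_rejects_shrinking():
    geo = ph.build_phantom(make_coarse_spec())
    with pytest.raises(ValueError, match="dilated"):
        ph.dilate_fat(geo, 5.0)


def test_dilation_leaves_inner_tissues_bit_identical():
    geo = ph.build_phantom(make_coarse_spec(fat_mm=13.0))
    fat86 = ph.dilate_fat(geo, 86.0)
    inner_a = _region_points(ph.mesh_geometry(geo))
    inner_b = _region_points(ph.mesh_geometry(fat86))
    assert np.array_equal(inner_a, inner_b)
    assert ph.measure_fat_thickness(ph.mesh_geometry(fat86)) == \
        pytest.approx(86.0, abs=0.5)


def test_dilation_composes_exactly():
    geo = ph.build_phantom(make_coarse_spec(fat_mm=13.0))
    stepped = ph.dilate_fat(ph.dilate_fat(geo, 26.0), 52.0)
    direct = ph.dilate_fat(geo, 52.0)
    ma = ph.mesh_geometry(stepped)
    mb = ph.mesh_geometry(direct)
    assert np.array_equal(ma.points, mb.points)
    assert np.array_equal(ma.region_id, mb.region_id)


# -- meshing ----------------------------------------------------------------

def test_mesh_is_valid_and_conforming_for_all_bmi_classes():
    for name in ph.BMI_FAT_THICKNESS_MM:
        spec = make_coarse_spec(fat_mm=ph.bmi_class_fat_thickness(name))
        mesh = ph.mesh_geometry(ph.build_phantom(spec))
        mesh.validate(min_disc_nodes=50)
        assert np.all(mesh.signed_areas() > 0)


def test_region_areas_conserved_under_meshing():
    geo = ph.build_phantom(make_coarse_spec())
    mesh = ph.mesh_geometry(geo)
    for label in (SUBCUT_FAT, DISC("L2-L3"), VERTEBRA("L3"), SKIN):
        exact = geo.region_area(label)
        meshed = mesh.region_area(label)
        assert meshed == pytest.approx(exact, rel=0.005)


def test_edge_lengths_within_bounds_of_target():
    spec = pt.PhantomSpec()                      # default 4 mm target
    mesh = ph.mesh_geometry(ph.build_phantom(spec))
    t = spec.mesh_target_edge_mm
    p = mesh.points
    for a, b in ((0, 1), (1, 2), (2, 0)):
        L = np.linalg.norm(p[mesh.tris[:, a]] - p[mesh.tris[:, b]], axis=1)
        assert L.min() >= 0.2 * t
        assert L.max() <= 3.0 * t


def test_halving_target_scales_element_count():
    geo = ph.build_phantom(make_coarse_spec())
    n1 = ph.mesh_geometry(geo, target_edge_mm=6.0).n_elems
    n2 = ph.mesh_geometry(geo, target_edge_mm=3.0).n_elems
    assert 3.0 <= n2 / n1 <= 6.0


def test_mesh_generation_is_deterministic():
    spec = make_coarse_spec()
    a = ph.mesh_geometry(ph.build_phantom(spec))
    b = ph.mesh_geometry(ph.build_phantom(spec))
    assert np.array_equal(a.points, b.points)
    assert np.array_equal(a.tris, b.tris)
    assert np.array_equal(a.region_id, b.region_id)


def test_disc_rois_have_enough_nodes_at_default_resolution():
    mesh = ph.mesh_geometry(ph.build_phantom(pt.PhantomSpec()))
    for lv in DISC_LEVELS:
        assert len(mesh.region_nodes(DISC(lv))) >= 50


def test_mat_strip_mesh():
    mesh = ph.build_mat_mesh(200.0, 10.0, 5.0)
    assert set(np.unique(mesh.region_id)) == {MAT.id}
    assert np.all(mesh.signed_areas() > 0)
    assert {"mat_top", "mat_bottom", "mat_ends"} <= set(mesh.boundaries)
    assert mesh.points[mesh.boundaries["mat_top"], 1].max() == 0.0


@settings(max_examples=10, deadline=None, derandomize=True)
@given(fat=st.floats(min_value=13.0, max_value=90.0))
def test_any_fat_thickness_meshes_validly(fat):
    spec = make_coarse_spec(fat_mm=fat)
    mesh = ph.mesh_geometry(ph.build_phantom(spec))
    mesh.validate(min_disc_nodes=50)
    assert ph.measure_fat_thickness(mesh) == pytest.approx(fat, abs=0.5)
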