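"""ROI averaging, sweep summaries, shielding comparisons, safety checks."""

import numpy as np
import pandas as pd
import pytest

import patraction as pt
from patraction import fem
from patraction.analysis import (DiscSummary, disc_average, disc_ordering,
                                 percent_reduction, run_sweep, safety_check)
from patraction.regions import DISC_LEVELS

from conftest import make_coarse_spec


def _constant_state(mesh, stress=1.0, strain=0.01):
    E, Q = mesh.n_elems, 3
    sigma = np.zeros((E, Q, 4))
    sigma[:, :, 0] = stress           # uniaxial: von Mises == stress
    eps = np.zeros((E, Q, 3))
    eps[:, :, 2] = strain * np.sqrt(3.0)   # shear with eq-strain == strain
    return fem.LevelState(tl=9, lift_mm=62.0,
                          u=np.zeros((mesh.n_nodes, 2)),
                          points=mesh.points, sigma=sigma, eps=eps,
                          newton_iters=0, residual=0.0,
                          contact_force=np.zeros(2), contact_active=0,
                          max_penetration=0.0, complementarity=0.0)


@pytest.fixture(scope="module")
def coarse_mesh():
    return pt.mesh_geometry(pt.build_phantom(make_coarse_spec()))


def test_disc_average_of_constant_field(coarse_mesh):
    st = _constant_state(coarse_mesh, stress=0.37, strain=0.004)
    for d in DISC_LEVELS:
        assert disc_average(st, coarse_mesh, d) == pytest.approx(0.37)
        assert disc_average(st, coarse_mesh, d, "equivalent_strain") == \
            pytest.approx(0.004)


def test_disc_average_zero_field(coarse_mesh):
    st = _constant_state(coarse_mesh, stress=0.0, strain=0.0)
    assert disc_average(st, coarse_mesh, "L2-L3") == 0.0


def test_disc_average_rejects_empty_roi():
    from patraction.verify import rectangle_mesh
    mesh = rectangle_mesh(np.linspace(0, 1, 3), np.linspace(0, 1, 3))
    st = _constant_state(mesh)
    with pytest.raises(ValueError, match="empty ROI"):
        disc_average(st, mesh, "L2-L3")
    with pytest.raises(ValueError, match="unknown disc"):
        disc_average(st, mesh, "C1-C2")


# -- reference tables -------------------------------------------------------

def test_reference_table_extremes(table_stress, table_strain):
    s = table_stress.select("normal", 9)
    assert s.set_index("disc").loc["L2-L3", "mean_stress_MPa"] == 1.686
    assert s.set_index("disc").loc["T12-L1", "mean_stress_MPa"] == 0.313
    e = table_strain.select("normal", 9)
    assert e.set_index("disc").loc["L2-L3", "mean_strain"] == \
        pytest.approx(9.232e-2)


def test_disc_ordering_on_reference_table(table_stress):
    order = disc_ordering(table_stress, "normal", 9)
    assert order[0] == "L2-L3"
    assert order[-1] == "T12-L1"


def test_disc_ordering_ties_fall_back_to_anatomy(coarse_mesh):
    rows = [{"bmi_class": "normal", "traction_level": 9, "disc": d,
             "mean_stress_MPa": 1.0, "mean_strain": 0.01, "n_nodes": 100}
            for d in DISC_LEVELS]
    summary = DiscSummary(pd.DataFrame(rows))
    assert disc_ordering(summary, "normal", 9) == list(DISC_LEVELS)


# -- percent reduction ------------------------------------------------------

def test_percent_reduction_identity_and_halving(table_stress):
    assert percent_reduction(table_stress, "normal", "normal") == \
        pytest.approx(0.0)
    halved = DiscSummary(table_stress.table.copy())
    mask = halved.table["bmi_class"] == "overweight"
    halved.table.loc[mask, "mean_stress_MPa"] = \
        0.5 * table_stress.select("normal")["mean_stress_MPa"].to_numpy()
    assert percent_reduction(halved, "normal", "overweight",
                             traction_levels=(5, 7, 9)) == pytest.approx(50.0)


def test_percent_reduction_reference_table_severe_tl9(table_stress):
    # frozen from across-disc arithmetic on the packaged table:
    # normal TL9 mean = 6.478/6, severe TL9 mean = 1.393/6 -> 78.5%
    red = percent_reduction(table_stress, "normal", "extreme_obese",
                            traction_levels=(9,))
    assert red == pytest.approx(78.497, abs=0.05)
    assert round(red) == 78 or round(red) == 79


def test_percent_reduction_invariant_to_uniform_rescaling(table_stress):
    scaled = DiscSummary(table_stress.table.copy())
    scaled.table["mean_stress_MPa"] *= 3.7
    a = percent_reduction(table_stress, "normal", "moderate_obese")
    b = percent_reduction(scaled, "normal", "moderate_obese")
    assert a == pytest.approx(b)


def test_percent_reduction_zero_reference_raises(table_stress):
    zeroed = DiscSummary(table_stress.table.copy())
    zeroed.table["mean_stress_MPa"] = 0.0
    with pytest.raises(ZeroDivisionError):
        percent_reduction(zeroed, "normal", "overweight")


# -- safety -----------------------------------------------------------------

def test_safety_check_reference_tables_pass(table_stress, table_strain):
    rep_s = safety_check(table_stress)
    assert rep_s.all_safe
    assert rep_s.max_stress_MPa == pytest.approx(1.686)
    assert rep_s.stress_margin_MPa > 0
    rep_e = safety_check(table_strain)
    assert rep_e.all_safe
    assert rep_e.max_strain == pytest.approx(9.232e-2)


def test_safety_check_flags_excess(table_stress):
    hot = DiscSummary(table_stress.table.copy())
    hot.table.loc[0, "mean_stress_MPa"] = 3.0
    rep = safety_check(hot)
    assert not rep.all_safe
    assert len(rep.violations) == 1


# -- sweep ------------------------------------------------------------------

def test_sweep_below_onset_is_all_zero():
    s = run_sweep(bmi_classes=("normal",), traction_levels=(0, 3),
                  spec=make_coarse_spec())
    assert len(s.table) == 2 * 6
    assert (s.table["mean_stress_MPa"] == 0.0).all()
    assert (s.table["mean_strain"] == 0.0).all()
    assert not s.failures


def test_sweep_rejects_bad_levels():
    with pytest.raises(ValueError):
        run_sweep(traction_levels=(12,), spec=make_coarse_spec())


def test_default_sweep_counts_and_signs(default_sweep):
    t = default_sweep.table
    assert len(t) == 4 * 9 * 6
    assert (t["mean_stress_MPa"] >= 0).all()
    assert (t["mean_strain"] >= 0).all()
    assert set(t["disc"]) == set(DISC_LEVELS)
    assert not default_sweep.failures
    assert (t["n_nodes"] >= 50).all()


def test_sweep_stress_strain_ratio_consistent(default_sweep):
    """Homogeneous disc material: mean vM / mean eq-strain must lie between
    the Young and constrained moduli implied by E = 17 MPa."""
    t = default_sweep.table
    loaded = t[t["mean_stress_MPa"] > 1e-3]
    ratio = loaded["mean_stress_MPa"] / loaded["mean_strain"]
    E, nu = 17.0, 0.49
    constrained = E * (1 - nu) / ((1 + nu) * (1 - 2 * nu))
    assert (ratio > 0.5 * E).all()
    assert (ratio < constrained).all()


def test_summary_csv_round_trip(tmp_path, table_stress):
    p = tmp_path / "summary.csv"
    table_stress.to_csv(p)
    back = DiscSummary.from_csv(p)
    pd.testing.assert_frame_equal(back.table, table_stress.table)
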