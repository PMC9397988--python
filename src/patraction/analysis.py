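"""Per-disc ROI summaries, BMI x traction-level sweeps and comparisons.

The reported quantity is, per (BMI class, traction level, disc), the
arithmetic mean of the nodal von Mises stress (MPa) and of the nodal
equivalent strain over the disc's region-restricted node set. On top of the
sweep table the module computes the percent load-shielding of each BMI class
relative to the normal phantom, the cranio-caudal ordering of disc stresses,
and a safety assessment against published disc damage thresholds.

Two reference tables from the full-scale MRI-derived 3D simulation of the
same device (mean disc stress and strain at TL5/7/9 for the four BMI models)
ship as packaged CSVs; they validate the analysis arithmetic independently of
the solver and document the values this desk-scale model emulates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import fem
from .fem import (BoundarySpec, FieldSolution, LevelState, SolverSettings,
                  element_nodal_values, equivalent_strain, nodal_average,
                  von_mises)
from .materials import MaterialTable, SafetyThresholds
from .phantom import (LabeledMesh, PhantomSpec, bmi_class_fat_thickness,
                      build_phantom, mesh_geometry)
from .protocol import ContactSpec, TractionProtocol
from .regions import DISC, DISC_LEVELS

__all__ = [
    "DiscSummary", "ComparisonReport", "disc_average", "run_sweep",
    "percent_reduction", "disc_ordering", "safety_check",
    "reference_table", "BMI_CLASSES",
]

BMI_CLASSES: tuple[str, ...] = ("normal", "overweight", "moderate_obese",
                                "extreme_obese")
_SUMMARY_COLUMNS = ["bmi_class", "traction_level", "disc",
                    "mean_stress_MPa", "mean_strain", "n_nodes"]


@dataclass
class DiscSummary:
    """Tidy per-(BMI, TL, disc) summary table with run metadata."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    failures: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in _SUMMARY_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary table missing columns {missing}")
        if (self.table["mean_stress_MPa"] < 0).any() or \
           (self.table["mean_strain"] < 0).any():
            raise ValueError("negative stress/strain in summary")

    def select(self, bmi_class: str | None = None,
               traction_level: int | None = None,
               disc: str | None = None) -> pd.DataFrame:
        t = self.table
        if bmi_class is not None:
            t = t[t["bmi_class"] == bmi_class]
        if traction_level is not None:
            t = t[t["traction_level"] == traction_level]
        if disc is not None:
            t = t[t["disc"] == disc]
        return t

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, metadata: dict | None = None) -> "DiscSummary":
        return cls(pd.read_csv(path), metadata or {})


def reference_table(quantity: str = "stress") -> DiscSummary:
    """Packaged reference DiscSummary from the full-scale 3D study.

    quantity "stress" or "strain"; the other column is filled with zeros
    (the reference publishes the two tables separately).
    """
    names = {"stress": "reference_disc_stress_MPa.csv",
             "strain": "reference_disc_strain.csv"}
    if quantity not in names:
        raise ValueError("quantity must be 'stress' or 'strain'")
    with resources.files("patraction.data").joinpath(names[quantity]).open() as fh:
        wide = pd.read_csv(fh)
    long = wide.melt(id_vars=["bmi_class", "traction_level"],
                     var_name="disc", value_name="value")
    long["value"] = long["value"].astype(float)
    tab = pd.DataFrame({
        "bmi_class": long["bmi_class"],
        "traction_level": long["traction_level"].astype(int),
        "disc": long["disc"],
        "mean_stress_MPa": long["value"] if quantity == "stress" else 0.0,
        "mean_strain": long["value"] if quantity == "strain" else 0.0,
        "n_nodes": 20000,
    })
    return DiscSummary(tab, {"source": "reference 3D MRI-based simulation"})


# ---------------------------------------------------------------------------
# ROI averaging
# ---------------------------------------------------------------------------

def disc_average(state: LevelState | FieldSolution, mesh: LabeledMesh,
                 disc_level: str, quantity: str = "von_mises_stress") -> float:
    """Mean nodal value of a scalar field over one disc's node set.

    quantity: "von_mises_stress" (MPa) or "equivalent_strain". Quadrature
    values are extrapolated to nodes and averaged over the elements of the
    disc region only, so material-interface nodes are not contaminated by
    the much stiffer neighboring vertebrae.
    """
    if isinstance(state, FieldSolution):
        state = state.levels[-1]
    if disc_level not in DISC_LEVELS:
        raise ValueError(f"unknown disc {disc_level!r}; one of {DISC_LEVELS}")
    els = mesh.region_elements(DISC(disc_level))
    if len(els) == 0:
        raise ValueError(f"empty ROI: disc {disc_level} has no elements")
    nodes = mesh.region_nodes(DISC(disc_level))
    if quantity == "von_mises_stress":
        en = element_nodal_values(von_mises(state.sigma))
    elif quantity == "equivalent_strain":
        en = element_nodal_values(equivalent_strain(state.eps))
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    nodal = nodal_average(mesh, en, elements=els)
    return float(np.nanmean(nodal[nodes]))


# ---------------------------------------------------------------------------
# Sweep
# ---------------------------------------------------------------------------

def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_sweep(bmi_classes=BMI_CLASSES, traction_levels=tuple(range(1, 10)),
              spec: PhantomSpec | None = None,
              materials: MaterialTable | None = None,
              protocol: TractionProtocol | None = None,
              contact: ContactSpec | None = None,
              boundary: BoundarySpec | None = None,
              settings: SolverSettings | None = None,
              solution_hook=None) -> DiscSummary:
    """Solve one phantom per BMI class and summarize all requested levels.

    The incremental solver records a snapshot at every integer traction
    level, so a single drive to max(traction_levels) yields the whole
    stress-vs-TL curve per class. A failed solve is recorded in
    ``failures`` and the sweep continues. ``solution_hook(bmi, solution,
    mesh)`` is called per class (export, plotting, ...).
    """
    spec = spec or PhantomSpec()
    materials = materials or MaterialTable()
    protocol = protocol or TractionProtocol()
    settings = settings or SolverSettings()
    levels = sorted(set(int(t) for t in traction_levels))
    if not levels or levels[0] < 0 or levels[-1] > protocol.n_levels:
        raise ValueError(f"traction levels out of range: {traction_levels}")

    rows = []
    failures: list[dict] = []
    for bmi in bmi_classes:
        cls_spec = dataclasses.replace(spec, fat_mm=bmi_class_fat_thickness(bmi))
        mesh = mesh_geometry(build_phantom(cls_spec))
        mesh.validate()
        scene = fem.build_scene(mesh, materials, protocol, contact, boundary,
                                mat_thickness_mm=cls_spec.mat_thickness_mm)
        try:
            sol = fem.solve_traction(mesh, materials, protocol, boundary,
                                     tl=levels[-1], contact=contact,
                                     settings=settings, scene=scene)
        except Exception as exc:   # record and continue with other classes
            failures.append({"bmi_class": bmi, "error": str(exc)})
            continue
        if solution_hook is not None:
            solution_hook(bmi, sol, scene.mesh)
        for tl in levels:
            st = sol.at_level(tl)
            for disc in DISC_LEVELS:
                nodes = scene.mesh.region_nodes(DISC(disc))
                rows.append({
                    "bmi_class": bmi,
                    "traction_level": tl,
                    "disc": disc,
                    "mean_stress_MPa": disc_average(
                        st, scene.mesh, disc, "von_mises_stress"),
                    "mean_strain": disc_average(
                        st, scene.mesh, disc, "equivalent_strain"),
                    "n_nodes": len(nodes),
                })
    meta = {
        "phantom_spec_hash": _config_hash(_dc_asdict(spec)),
        "solver_hash": _config_hash({"settings": _dc_asdict(settings),
                                     "protocol": _dc_asdict(protocol)}),
    }
    return DiscSummary(pd.DataFrame(rows, columns=_SUMMARY_COLUMNS),
                       metadata=meta, failures=failures)


def _dc_asdict(obj) -> dict:
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}


# ---------------------------------------------------------------------------
# Comparisons
# ---------------------------------------------------------------------------

def percent_reduction(summary: DiscSummary, reference_class: str,
                      other_class: str, quantity: str = "stress",
                      traction_levels=tuple(range(5, 10))) -> float:
    """Percent shielding of ``other_class`` relative to ``reference_class``.

    100 * (1 - mean_other / mean_reference), means taken over all six discs
    and the given traction levels (default: the post-onset levels TL5-TL9;
    levels absent from the summary are ignored).
    """
    col = {"stress": "mean_stress_MPa", "strain": "mean_strain"}[quantity]
    vals = {}
    for cls in (reference_class, other_class):
        t = summary.select(bmi_class=cls)
        t = t[t["traction_level"].isin(traction_levels)]
        if t.empty:
            raise ValueError(f"no summary entries for class {cls!r} at "
                             f"levels {traction_levels}")
        vals[cls] = float(t[col].mean())
    if vals[reference_class] == 0:
        raise ZeroDivisionError(
            f"reference class {reference_class!r} has zero mean {quantity}")
    return 100.0 * (1.0 - vals[other_class] / vals[reference_class])


def disc_ordering(summary: DiscSummary, bmi_class: str, tl: int) -> list[str]:
    """Discs ranked by mean stress, highest first.

    Ties are broken by anatomical order, cranial (T12-L1) first.
    """
    t = summary.select(bmi_class=bmi_class, traction_level=tl)
    if len(t) == 0:
        raise ValueError(f"no entries for ({bmi_class}, TL{tl})")
    stress = {r["disc"]: r["mean_stress_MPa"] for _, r in t.iterrows()}
    return sorted(stress, key=lambda d: (-stress[d], DISC_LEVELS.index(d)))


@dataclass
class ComparisonReport:
    """Shielding percentages, disc ordering and safety margins."""

    percent_reduction_stress: dict[str, float]
    percent_reduction_strain: dict[str, float]
    disc_order_reference: list[str]
    max_stress_MPa: float
    max_strain: float
    stress_margin_MPa: float
    strain_margin: float
    violations: pd.DataFrame
    all_safe: bool


def safety_check(summary: DiscSummary,
                 thresholds: SafetyThresholds | None = None) -> ComparisonReport:
    """Flag any (BMI, TL, disc) above the disc damage thresholds.

    Stresses compare against the ultimate stress (MPa); strains against the
    ultimate tensile strain (stored as percent, compared as a fraction).
    """
    th = thresholds or SafetyThresholds()
    t = summary.table
    strain_limit = th.ultimate_strain_pct / 100.0
    bad = t[(t["mean_stress_MPa"] > th.ultimate_stress_MPa)
            | (t["mean_strain"] > strain_limit)]
    ref_cls = ("normal" if (t["bmi_class"] == "normal").any()
               else t["bmi_class"].iloc[0])
    ref_tl = int(t[t["bmi_class"] == ref_cls]["traction_level"].max())
    classes = [c for c in t["bmi_class"].unique() if c != "normal"]
    red_s, red_e = {}, {}
    for c in classes:
        if (t["bmi_class"] == "normal").any():
            try:
                red_s[c] = percent_reduction(summary, "normal", c, "stress")
                red_e[c] = percent_reduction(summary, "normal", c, "strain")
            except (ZeroDivisionError, ValueError):
                pass
    return ComparisonReport(
        percent_reduction_stress=red_s,
        percent_reduction_strain=red_e,
        disc_order_reference=disc_ordering(summary, ref_cls, ref_tl),
        max_stress_MPa=float(t["mean_stress_MPa"].max()),
        max_strain=float(t["mean_strain"].max()),
        stress_margin_MPa=float(th.ultimate_stress_MPa
                                - t["mean_stress_MPa"].max()),
        strain_margin=float(strain_limit - t["mean_strain"].max()),
        violations=bad.reset_index(drop=True),
        all_safe=bool(bad.empty),
    )
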