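"""Actuator model: roller kinematics, mat layer, and the traction schedule.

The massage-bed actuator carries semi-cylindrical rollers beneath a deformable
bed mat. The traction level (TL) setting, 0..9, lifts the rollers vertically
in uniform increments of 62/9 mm, so TL9 corresponds to exactly 62 mm of lift.
The rollers start ``initial_clearance_mm`` below the underside of the mat; the
default clearance equals four traction increments, which places first contact
of the roller-mat-skin chain between TL4 and TL5 and reproduces the observed
near-zero tissue response at TL4 and below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TractionProtocol", "ContactSpec", "tl_to_displacement",
           "roller_profile", "contact_onset_level"]

N_LEVELS_DEFAULT = 9
FULL_RANGE_MM_DEFAULT = 62.0
#: Vertical gap between subject skin and mat top in the assembled scene (mm).
SKIN_MAT_CLEARANCE_MM = 0.1


@dataclass(frozen=True)
class TractionProtocol:
    """Roller geometry, placement and the TL -> vertical displacement map."""

    n_levels: int = N_LEVELS_DEFAULT
    full_range_mm: float = FULL_RANGE_MM_DEFAULT
    roller_radius_mm: float = 25.0
    #: Craniocaudal centers of the active (front) roller pair. Defaults sit
    #: under the L2-L4 vertebral span of the default phantom.
    roller_center_x: tuple[float, ...] = (160.0, 220.0)
    #: Gap between roller apex and mat underside at rest; default is exactly
    #: four traction increments so contact begins between TL4 and TL5.
    initial_clearance_mm: float = 4 * FULL_RANGE_MM_DEFAULT / N_LEVELS_DEFAULT
    include_mat: bool = True

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.full_range_mm <= 0:
            raise ValueError("full_range_mm must be positive")
        if self.roller_radius_mm <= 0:
            raise ValueError("roller_radius_mm must be positive")
        if self.initial_clearance_mm < 0:
            raise ValueError("initial_clearance_mm must be >= 0")
        xs = np.asarray(self.roller_center_x, float)
        if xs.size and np.any(np.diff(np.sort(xs)) < 2 * self.roller_radius_mm):
            raise ValueError("roller centers closer than one diameter: "
                             f"{self.roller_center_x}")

    @property
    def increment_mm(self) -> float:
        return self.full_range_mm / self.n_levels

    def displacement(self, tl: int) -> float:
        return tl_to_displacement(tl, self)

    def schedule(self) -> np.ndarray:
        """Vertical displacement (mm) at every level 0..n_levels."""
        return np.arange(self.n_levels + 1) * self.increment_mm


def tl_to_displacement(tl: int, protocol: TractionProtocol | None = None) -> float:
    """Vertical roller displacement (mm) at integer traction level ``tl``.

    The printed device maximum (62 mm at TL9) is honored exactly: each of the
    nine levels adds 62/9 ~ 6.889 mm.
    """
    protocol = protocol or TractionProtocol()
    if not isinstance(tl, (int, np.integer)):
        raise TypeError(f"traction level must be an integer, got {tl!r}")
    if not 0 <= tl <= protocol.n_levels:
        raise ValueError(
            f"traction level {tl} out of range 0..{protocol.n_levels}")
    # multiply before dividing so the full range is honored exactly at TL9
    return tl * protocol.full_range_mm / protocol.n_levels


def roller_profile(protocol: TractionProtocol, tl: int,
                   mat_underside_y: float = 0.0,
                   n_arc: int = 65) -> list[np.ndarray]:
    """Rigid roller boundary curves (upper semi-circles) at traction level tl.

    Each roller is a semi-cylindrical arc of ``roller_radius_mm`` centered at
    its configured craniocaudal position. At TL0 the apex sits exactly
    ``initial_clearance_mm`` below ``mat_underside_y``; each traction level
    shifts the arcs rigidly upward by ``full_range_mm / n_levels``.

    Returns one (n_arc, 2) polyline per roller.
    """
    lift = tl_to_displacement(tl, protocol)
    R = protocol.roller_radius_mm
    apex_y = mat_underside_y - protocol.initial_clearance_mm + lift
    theta = np.linspace(0.0, np.pi, n_arc)
    arcs = []
    for cx in protocol.roller_center_x:
        arc = np.column_stack([cx + R * np.cos(theta),
                               (apex_y - R) + R * np.sin(theta)])
        arcs.append(arc)
    return arcs


def roller_centers(protocol: TractionProtocol, tl: int,
                   mat_underside_y: float = 0.0) -> np.ndarray:
    """(n_rollers, 2) circle centers at traction level tl."""
    lift = tl_to_displacement(tl, protocol)
    cy = mat_underside_y - protocol.initial_clearance_mm + lift \
        - protocol.roller_radius_mm
    return np.array([[cx, cy] for cx in protocol.roller_center_x])


def contact_onset_level(protocol: TractionProtocol,
                        skin_clearance_mm: float = 0.0) -> int | None:
    """Smallest TL at which the roller-mat-skin chain carries contact force.

    The chain engages once the roller lift strictly exceeds the rest gap
    (roller-to-mat clearance plus any extra skin clearance passed in; the
    assembled-scene skin gap of 0.1 mm is negligible at level granularity).
    Returns None when no level within the protocol range makes contact.
    """
    gap = protocol.initial_clearance_mm + skin_clearance_mm
    for tl in range(protocol.n_levels + 1):
        if tl_to_displacement(tl, protocol) > gap:
            return tl
    return None


@dataclass(frozen=True)
class ContactSpec:
    """Frictionless hard-contact parameters for the two contact pairs.

    Pair 1: roller surfaces (rigid master) vs mat underside (slave nodes).
    Pair 2: mat top (master segments) vs posterior skin (slave nodes).
    Tangential behavior is exactly frictionless; the normal "hard" condition
    is approximated by a stiff penalty with a complementarity post-check.
    """

    friction_coefficient: float = 0.0
    #: Penalty stiffness = penalty_factor * E_softest / element size (MPa/mm^2).
    #: Kept moderate for stable Newton iterations; the augmented-Lagrange
    #: multiplier loop drives the residual penetration below gap_tol_mm.
    penalty_factor: float = 10.0
    #: Admissible residual penetration at convergence (mm).
    gap_tol_mm: float = 0.01
    #: Admissible |gap * pressure| complementarity defect (MPa * mm).
    comp_tol: float = 0.05
    #: Maximum augmented-Lagrange (Uzawa) outer iterations per increment.
    max_augment: int = 30

    def __post_init__(self) -> None:
        if self.friction_coefficient != 0.0:
            raise ValueError("contact is frictionless: friction must be 0")
        if self.penalty_factor <= 0 or self.gap_tol_mm <= 0:
            raise ValueError("penalty_factor and gap_tol_mm must be positive")
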