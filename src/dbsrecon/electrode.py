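"""Quadripolar DBS electrode geometry and trajectory/contact interpolation.

The reconstruction workflow locates two landmarks per electrode — the centre
of the ventral-most contact and a second point further up the (straight)
cranial part of the lead — and derives everything else from the hardware
geometry: the remaining contact centres sit at fixed arc distances along the
trajectory, and the physical tip sits a fixed distance below the
ventral-most contact centre.

For the Medtronic 3389 and PINS L301 leads the contact centres are 2 mm
apart (so contacts 1-3 are 2, 4 and 6 mm from the ventral-most contact) and
the tip-to-contact gap is 1.5 mm; adding half the 1.5 mm contact length puts
the tip 2.25 mm below the ventral-most contact *centre*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acpc import Hemisphere, Point3

__all__ = [
    "BUILTIN_SPECS",
    "ContactSet",
    "DegenerateTrajectoryError",
    "ElectrodeSpec",
    "ElectrodeTrajectory",
    "MEDTRONIC_3389",
    "PINS_L301",
    "average_contacts",
    "fit_trajectory",
    "interpolate_contacts",
    "tip_position",
]

_GEOM_TOL = 1e-9


class DegenerateTrajectoryError(ValueError):
    """The two trajectory landmarks coincide."""


@dataclass(frozen=True)
class ElectrodeSpec:
    """Hardware geometry of a cylindrical multi-contact DBS lead.

    Parameters are manufacturer constants in millimetres:

    tip_to_contact_mm
        Gap between the physical electrode tip and the *lower edge* of the
        ventral-most contact.
    contact_length_mm
        Axial length of one stimulating contact.
    center_spacing_mm
        Centre-to-centre distance of adjacent contacts.
    """

    model_name: str
    tip_to_contact_mm: float = 1.5
    contact_length_mm: float = 1.5
    center_spacing_mm: float = 2.0
    n_contacts: int = 4

    def __post_init__(self) -> None:
        if self.tip_to_contact_mm < 0 or self.contact_length_mm < 0:
            raise ValueError("electrode lengths must be non-negative")
        if self.center_spacing_mm <= 0:
            raise ValueError("center_spacing_mm must be positive")
        if self.n_contacts < 1:
            raise ValueError("n_contacts must be >= 1")
        if self.center_spacing_mm < self.contact_length_mm:
            raise ValueError("contacts overlap: spacing < contact length")

    @property
    def tip_to_center_mm(self) -> float:
        """Distance from the tip to the ventral-most contact *centre*."""
        return self.tip_to_contact_mm + self.contact_length_mm / 2.0


MEDTRONIC_3389 = ElectrodeSpec(model_name="Medtronic 3389")
PINS_L301 = ElectrodeSpec(model_name="PINS L301")

BUILTIN_SPECS = {
    MEDTRONIC_3389.model_name: MEDTRONIC_3389,
    PINS_L301.model_name: PINS_L301,
}


@dataclass(frozen=True)
class ElectrodeTrajectory:
    """Straight-line electrode model anchored at the ventral-most contact.

    ``direction`` is the unit vector from the ventral-most contact centre
    toward the cranial part of the lead (i.e. pointing dorsally along the
    shaft).
    """

    ventral_contact: Point3
    direction: tuple[float, float, float]

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > _GEOM_TOL:
            raise ValueError("direction must be a unit vector")

    def direction_array(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)

    def point_at(self, distance_mm: float) -> Point3:
        """Point ``distance_mm`` dorsal of the ventral contact (negative = ventral)."""
        return Point3.from_array(
            self.ventral_contact.as_array() + distance_mm * self.direction_array()
        )


@dataclass(frozen=True)
class ContactSet:
    """Ordered contact centres of one electrode, ventral-most first."""

    contacts: tuple[Point3, ...]
    side: Hemisphere
    spec: ElectrodeSpec

    def __post_init__(self) -> None:
        if len(self.contacts) < 1:
            raise ValueError("ContactSet requires at least one contact")
        pts = np.array([c.as_array() for c in self.contacts])
        if len(pts) >= 2:
            d0 = pts[1] - pts[0]
            step = np.linalg.norm(d0)
            if abs(step - self.spec.center_spacing_mm) > _GEOM_TOL:
                raise ValueError("contact spacing does not match electrode spec")
            u = d0 / step
            for i in range(1, len(pts)):
                rel = pts[i] - pts[0]
                if abs(np.linalg.norm(rel) - i * step) > 1e-8:
                    raise ValueError("contacts are not equally spaced")
                off_axis = rel - (rel @ u) * u
                if np.linalg.norm(off_axis) > 1e-8:
                    raise ValueError("contacts are not collinear")

    def as_array(self) -> np.ndarray:
        return np.array([c.as_array() for c in self.contacts])


def fit_trajectory(ventral_contact: Point3, cranial_point: Point3) -> ElectrodeTrajectory:
    """Fit the straight electrode line through its two reconstruction landmarks."""
    d = cranial_point.as_array() - ventral_contact.as_array()
    n = float(np.linalg.norm(d))
    if n <= 1e-6:
        raise DegenerateTrajectoryError(
            "ventral contact and cranial point coincide (separation "
            f"{n:.2e} mm)"
        )
    return ElectrodeTrajectory(ventral_contact=ventral_contact, direction=tuple(d / n))


def interpolate_contacts(
    traj: ElectrodeTrajectory,
    spec: ElectrodeSpec,
    side: Hemisphere = Hemisphere.RIGHT,
) -> ContactSet:
    """Place all contact centres along the trajectory.

    Contact ``i`` (0-based, ventral-most first) sits ``i * center_spacing``
    millimetres dorsal of the ventral-most contact, i.e. toward the cranial
    landmark.  This is the parametric-line form of the per-coordinate
    distance equations used in manual planning-station workflows; the
    dorsal-stepping sign is fixed by hardware (all other contacts are above
    the ventral-most one).
    """
    contacts = tuple(
        traj.point_at(i * spec.center_spacing_mm) for i in range(spec.n_contacts)
    )
    return ContactSet(contacts=contacts, side=side, spec=spec)


def tip_position(traj: ElectrodeTrajectory, spec: ElectrodeSpec) -> Point3:
    """Physical electrode tip: below the ventral contact centre along the shaft."""
    return traj.point_at(-spec.tip_to_center_mm)


def average_contacts(cs: ContactSet) -> Point3:
    """Arithmetic per-axis mean of the contact centres.

    Each hemisphere's four contacts are averaged into a single coordinate
    before any between-method comparison.
    """
    return Point3.from_array(cs.as_array().mean(axis=0))
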