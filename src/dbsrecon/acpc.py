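"""Stereotactic AC-PC coordinate frame, hemisphere conventions and pooling.

All electrode geometry in this package lives in a single signed AC-PC frame
with the posterior commissure (PC) at the origin and axes

* ``+X`` lateral toward the patient's right,
* ``+Y`` anterior (toward the anterior commissure),
* ``+Z`` inferior.

Note the inferior-positive Z: together with right-positive X and
anterior-positive Y this is a *left-handed* triple in the usual RAS world
sense; :class:`ACPCFrame` checks handedness after flipping Z back to
superior.

Clinical tables conventionally print left-hemisphere coordinates with all
three axes negated.  That sign flip is a *display* convention only: data are
always stored signed in the canonical frame and the flip is applied at
reporting / pooling time by :func:`display_point` and
:func:`pool_magnitude`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "AXES",
    "ACPCFrame",
    "DegenerateFrameError",
    "Hemisphere",
    "Point3",
    "build_frame",
    "display_point",
    "pool_magnitude",
]

#: Axis names usable wherever an ``axis`` argument is accepted.
AXES = ("x", "y", "z")

_COLLINEAR_SIN_TOL = 1e-6
_UNIT_TOL = 1e-9


class DegenerateFrameError(ValueError):
    """AC, PC and midsagittal landmarks do not define a frame."""


class Hemisphere(str, Enum):
    """Side of an electrode or anatomical structure."""

    LEFT = "left"
    RIGHT = "right"

    @property
    def sign_x(self) -> float:
        """Sign of the lateral (X) direction for this side: +1 right, -1 left."""
        return 1.0 if self is Hemisphere.RIGHT else -1.0


@dataclass(frozen=True)
class Point3:
    """A point in millimetres; AC-PC frame unless documented otherwise."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"Point3.{name} must be finite, got {v!r}")

    @classmethod
    def from_array(cls, a: np.ndarray | Sequence[float]) -> "Point3":
        a = np.asarray(a, dtype=float)
        if a.shape != (3,):
            raise ValueError(f"expected shape (3,), got {a.shape}")
        return cls(float(a[0]), float(a[1]), float(a[2]))

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    def distance_to(self, other: "Point3") -> float:
        return float(np.linalg.norm(self.as_array() - other.as_array()))


def display_point(p: Point3, side: Hemisphere) -> Point3:
    """Apply the reporting sign convention: negate all axes for the left side.

    Stored data are signed in the canonical frame; clinical tables print
    left-hemisphere rows with flipped signs.  Only reporting and pooling code
    should call this.
    """
    if side is Hemisphere.LEFT:
        return Point3(-p.x, -p.y, -p.z)
    return p


def pool_magnitude(
    coords: Sequence[tuple[Point3, Hemisphere]], axis: str
) -> list[float]:
    """Pool one axis across hemispheres as per-electrode magnitudes.

    Left-hemisphere points are first taken through the display sign flip,
    then the absolute value on the requested axis is returned for every
    electrode, preserving input order.  This is how "all electrodes" rows of
    per-axis summary tables are formed when the two sides carry opposite
    signs.
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
    if len(coords) == 0:
        raise ValueError("cannot pool an empty coordinate list")
    out = []
    for p, side in coords:
        disp = display_point(p, side)
        out.append(abs(getattr(disp, axis)))
    return out


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateFrameError("zero-length axis vector")
    return v / n


@dataclass(frozen=True)
class ACPCFrame:
    """Rigid frame with PC origin; axes expressed in world (scanner) mm.

    ``axis_x/axis_y/axis_z`` are the canonical lateral-right / anterior /
    inferior directions.  The triple ``(axis_x, axis_y, -axis_z)`` must be
    right-handed.
    """

    origin: Point3
    axis_x: tuple[float, float, float]
    axis_y: tuple[float, float, float]
    axis_z: tuple[float, float, float]

    def __post_init__(self) -> None:
        R = self.rotation()
        for i, name in enumerate(("axis_x", "axis_y", "axis_z")):
            n = np.linalg.norm(R[i])
            if abs(n - 1.0) > _UNIT_TOL:
                raise DegenerateFrameError(f"{name} is not unit length (|v|={n})")
        for i in range(3):
            for j in range(i + 1, 3):
                if abs(float(R[i] @ R[j])) > _UNIT_TOL:
                    raise DegenerateFrameError("axes are not mutually orthogonal")
        # right-handed once Z is flipped back to superior
        det = float(np.linalg.det(np.stack([R[0], R[1], -R[2]])))
        if det < 0:
            raise DegenerateFrameError("frame is not right-handed (with Z superior)")

    def rotation(self) -> np.ndarray:
        """World->ACPC rotation with the axes as rows."""
        return np.array([self.axis_x, self.axis_y, self.axis_z], dtype=float)

    def to_acpc(self, p: Point3) -> Point3:
        """Map a world-mm point into the AC-PC frame (rigid transform)."""
        rel = p.as_array() - self.origin.as_array()
        return Point3.from_array(self.rotation() @ rel)

    def from_acpc(self, p: Point3) -> Point3:
        """Inverse of :meth:`to_acpc`."""
        return Point3.from_array(
            self.origin.as_array() + self.rotation().T @ p.as_array()
        )


def build_frame(ac: Point3, pc: Point3, midsagittal: Point3) -> ACPCFrame:
    """Construct the AC-PC frame from three world-space landmarks.

    Parameters
    ----------
    ac, pc
        Anterior and posterior commissure in world mm.  The PC becomes the
        origin and ``+Y`` points from PC to AC.
    midsagittal
        Any additional midsagittal-plane point *superior* to the AC-PC line
        (e.g. a vertex-ward interhemispheric point).  It fixes the roll of
        the frame: ``+Z`` is the inferior direction perpendicular to Y
        within the midsagittal plane.

    Raises
    ------
    DegenerateFrameError
        If AC and PC coincide or the midsagittal point is collinear with
        the AC-PC line (sin of the angle below 1e-6).
    """
    a = ac.as_array()
    p = pc.as_array()
    m = midsagittal.as_array()
    y_vec = a - p
    if np.linalg.norm(y_vec) < 1e-9:
        raise DegenerateFrameError("AC and PC coincide")
    y = _unit(y_vec)
    w = m - p
    nw = np.linalg.norm(w)
    if nw < 1e-9 or np.linalg.norm(np.cross(y, w)) < _COLLINEAR_SIN_TOL * nw:
        raise DegenerateFrameError(
            "midsagittal point is collinear with the AC-PC line"
        )
    superior = _unit(w - (w @ y) * y)
    z = -superior  # +Z inferior
    x = np.cross(y, superior)  # completes right-handed (x, y, superior)
    return ACPCFrame(
        origin=pc,
        axis_x=tuple(x),
        axis_y=tuple(y),
        axis_z=tuple(z),
    )
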