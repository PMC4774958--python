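"""Landmark-based measurement of leading-edge serration shape.

A serration is the free-standing, bent-away tip of a barb on the outer vane
of an owl flight feather.  Its planform shape is summarised by three
parameters measured on a two-dimensional ventral projection of the feather
(the x-y plane of the feather frame):

* the inclination angle ``alpha`` — the angle between the rachis axis and
  the straight base of the barb (degrees, unsigned, in [0, 90]);
* the tip-displacement angle ``beta`` — the angle between the base direction
  and the straight segment from the point of separation to the serration
  tip (degrees, signed: positive when the tip deviates away from the
  rachis, negative when it bends toward it);
* the serration length — the arc length of the curved barb-shaft path from
  the point of separation to the tip (mm).

All measurements are taken in a canonical feather frame in which the y-axis
runs from the beginning of the calamus to the tip of the rachis and the
x-axis points toward the outer vane.  Left-wing data are mirrored into this
frame on the fly, so "away from the rachis" is always +x and the sign of
``beta`` is handedness-independent.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "EdgeCategory",
    "FeatherFrame",
    "SerrationLandmarks",
    "VanePosition",
    "inclination_angle",
    "tip_displacement_angle",
    "serration_length",
    "classify_edge_element",
    "normalized_vane_position",
    "DEFAULT_AWAY_THRESHOLD_DEG",
]

#: Minimum tip-displacement (degrees) that counts as "bent away from the
#: rachis" when classifying an edge element.  Guards against digitisation
#: noise; there is no biological threshold, a detached tip with any clearly
#: positive bend is a serration.
DEFAULT_AWAY_THRESHOLD_DEG = 2.0

_EPS = 1e-12


class EdgeCategory(enum.Enum):
    """Classification of a leading-edge element.

    ``SMOOTH``: barb tip attached to the adjoining barb (closed vane).
    ``DENTICULATION``: detached, spear-head-like tip that is straight or
    bent toward the rachis.
    ``SERRATION``: detached tip bent away from the rachis — the functional
    comb tooth of the owl leading edge.
    """

    SMOOTH = "smooth"
    DENTICULATION = "denticulation"
    SERRATION = "serration"


@dataclass(frozen=True)
class FeatherFrame:
    """Feather coordinate frame.

    The y-axis is the line from the beginning of the calamus to the tip of
    the rachis; the x-axis is perpendicular, toward the outer vane.  For a
    right wing the outer vane lies at +x of the raw coordinates; for a left
    wing the raw coordinates are mirror-imaged and are re-expressed in the
    canonical (right-wing) frame by all measurement routines.
    """

    calamus_start: tuple[float, float] = (0.0, 0.0)
    rachis_tip: tuple[float, float] = (0.0, 1.0)
    wing_side: str = "right"

    def __post_init__(self) -> None:
        if self.wing_side not in ("left", "right"):
            raise ValueError(f"wing_side must be 'left' or 'right', got {self.wing_side!r}")
        d = np.subtract(self.rachis_tip, self.calamus_start, dtype=float)
        if float(np.hypot(*d)) <= _EPS:
            raise ValueError("degenerate frame: calamus_start equals rachis_tip")

    @property
    def y_axis(self) -> np.ndarray:
        d = np.subtract(self.rachis_tip, self.calamus_start, dtype=float)
        return d / np.linalg.norm(d)

    @property
    def x_axis(self) -> np.ndarray:
        """Unit vector toward the outer vane in the canonical frame."""
        yx, yy = self.y_axis
        x = np.array([yy, -yx])
        return -x if self.wing_side == "left" else x

    def to_canonical(self, points: np.ndarray) -> np.ndarray:
        """Express raw (n, 2) points in canonical (x=away, y=rachis) coords."""
        p = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(
            self.calamus_start, dtype=float
        )
        return np.column_stack([p @ self.x_axis, p @ self.y_axis])


@dataclass(frozen=True)
class SerrationLandmarks:
    """Labelled 2D landmarks (mm) of one barb / edge element.

    ``path`` is the digitised curved barb-shaft path from the point of
    separation to the tip (ordered, first point = separation point, last
    point = tip).  ``detached`` records whether the barb tip is free
    standing (True) or knitted to the adjoining barb (False).
    """

    frame: FeatherFrame
    barb_origin: tuple[float, float]
    separation_point: tuple[float, float]
    tip: tuple[float, float]
    path: np.ndarray = field(repr=False)
    detached: bool = True

    def __post_init__(self) -> None:
        path = np.asarray(self.path, dtype=float)
        if path.ndim != 2 or path.shape[1] != 2 or path.shape[0] < 2:
            raise ValueError("path must be an (n>=2, 2) array of points")
        object.__setattr__(self, "path", path)
        if not np.allclose(path[0], self.separation_point, atol=1e-9):
            raise ValueError("path must start at the separation point")
        if not np.allclose(path[-1], self.tip, atol=1e-9):
            raise ValueError("path must end at the tip")
        if np.any(np.linalg.norm(np.diff(path, axis=0), axis=1) <= _EPS):
            raise ValueError("consecutive path points must be distinct")
        base = np.subtract(self.separation_point, self.barb_origin, dtype=float)
        if float(np.hypot(*base)) <= _EPS:
            raise ValueError("degenerate base segment: barb_origin equals separation_point")


def _direction_angle_deg(v: np.ndarray) -> float:
    """Signed angle (degrees) of a canonical-frame vector from the rachis
    axis (+y), measured toward the outer vane (+x)."""
    return math.degrees(math.atan2(v[0], v[1]))


def _canonical_vector(landmarks: SerrationLandmarks, start, end) -> np.ndarray:
    pts = landmarks.frame.to_canonical(np.array([start, end], dtype=float))
    return pts[1] - pts[0]


def inclination_angle(landmarks: SerrationLandmarks) -> float:
    """Angle alpha between the rachis axis and the barb base (degrees).

    Unsigned angle between the two lines, in [0, 90].
    """
    base = _canonical_vector(landmarks, landmarks.barb_origin, landmarks.separation_point)
    n = np.linalg.norm(base)
    if n <= _EPS:
        raise ValueError("degenerate base segment")
    cosang = abs(base[1]) / n
    return math.degrees(math.acos(min(1.0, cosang)))


def tip_displacement_angle(landmarks: SerrationLandmarks) -> float:
    """Signed angle beta between barb base and the separation-to-tip chord.

    Positive when the tip is displaced away from the rachis (toward the
    outer vane), negative when it bends toward the rachis; degrees.
    """
    base = _canonical_vector(landmarks, landmarks.barb_origin, landmarks.separation_point)
    chord = _canonical_vector(landmarks, landmarks.separation_point, landmarks.tip)
    if np.linalg.norm(chord) <= _EPS:
        raise ValueError("tip coincides with the separation point")
    if np.linalg.norm(base) <= _EPS:
        raise ValueError("degenerate base segment")
    ang = _direction_angle_deg(chord) - _direction_angle_deg(base)
    # wrap to (-180, 180]
    ang = (ang + 180.0) % 360.0 - 180.0
    return ang


def serration_length(landmarks: SerrationLandmarks) -> float:
    """In-plane curved length (mm): arc length of the path polyline."""
    seg = np.diff(landmarks.path, axis=0)
    return float(np.linalg.norm(seg, axis=1).sum())


def classify_edge_element(
    landmarks: SerrationLandmarks,
    away_threshold_deg: float = DEFAULT_AWAY_THRESHOLD_DEG,
) -> EdgeCategory:
    """Classify an edge element as smooth, denticulation, or serration.

    A serration requires both a detached barb tip and a bending of the tip
    away from the rachis; a detached tip that is straight or bent toward
    the rachis is only a denticulation.
    """
    if away_threshold_deg < 0:
        raise ValueError("away_threshold_deg must be >= 0")
    if not landmarks.detached:
        return EdgeCategory.SMOOTH
    if tip_displacement_angle(landmarks) > away_threshold_deg:
        return EdgeCategory.SERRATION
    return EdgeCategory.DENTICULATION


class VanePosition(NamedTuple):
    fraction: float
    clamped: bool


def normalized_vane_position(
    y_coord: float, vane_start_y: float, vane_tip_y: float
) -> VanePosition:
    """Map a rachis-axis coordinate to the normalized vane position.

    The beginning of the outer vane maps to 0 and its tip to 1.  Values
    outside the vane are clamped into [0, 1] and flagged.
    """
    span = vane_tip_y - vane_start_y
    if abs(span) <= _EPS:
        raise ValueError("zero-length vane: vane_start_y equals vane_tip_y")
    f = (y_coord - vane_start_y) / span
    clamped = f < 0.0 or f > 1.0
    return VanePosition(min(1.0, max(0.0, f)), clamped)
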