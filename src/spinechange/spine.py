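"""Sagittal spine-curve reconstruction from five forward-tilt angles.

The five wearable sensors report forward tilts ``tau_1..tau_5`` (degrees,
sensor 1 lowest).  The curve model turns these into six ordered 2D points
``P0..P5`` in the sagittal plane (x anterior, y cranial): ``P1`` is pinned
to the origin, consecutive sensor positions are joined by constant-curvature
arcs of fixed arc length ``L`` whose tangent angle interpolates linearly
between the two sensors' tilts, and ``P0`` extends straight down from
``P1`` along sensor 1's tangent.

The tangent direction at tilt ``tau`` is ``(sin tau, cos tau)``: zero tilt
points straight up, positive tilt leans anteriorly.  The chord of an arc
from tilt ``a`` to tilt ``b`` has the closed form

    chord = L * sinc((b - a) / 2) * (sin m, cos m),   m = (a + b) / 2,

with ``sinc(h) = sin(h) / h`` (``= 1`` at ``h = 0``), which is exact for
all ``a, b`` and numerically stable through the straight-segment limit
``b -> a``.

An *offset spine shape* is the same reconstruction applied to the per-sensor
angle differences of a posture pair (guided minus unguided); it renders the
postural change as horizontal offsets from a vertical line.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .io import N_SENSORS, PosturePair

Sign = str  # one of "+", "o", "-"


@dataclasses.dataclass(frozen=True)
class SpineCurve:
    """Six ordered sagittal-plane points with their source angles.

    ``points`` is a (6, 2) array ``P0..P5`` in model units; ``P1 == (0, 0)``
    exactly.  ``source_angles`` are the five input tilts in degrees and
    ``segment_length`` the per-segment arc length ``L``.
    """

    points: np.ndarray
    source_angles: tuple[float, ...]
    segment_length: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (6, 2):
            raise ValueError(f"expected 6 2D points, got shape {pts.shape}")
        object.__setattr__(self, "points", pts)


@dataclasses.dataclass(frozen=True)
class OffsetShape:
    """Offset spine shape of one posture pair, with per-point x-sign annotations.

    ``signs[i]`` is '+' if ``points[i, 0] > zero_tol``, '-' if below
    ``-zero_tol`` and 'o' otherwise.  Points keep the curve order ``P0..P5``,
    which coincides with increasing y whenever every angle difference stays
    within (-90, 90) degrees — always the case for realistic posture change.
    """

    points: np.ndarray
    signs: tuple[Sign, ...]
    pair_id: str

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (6, 2):
            raise ValueError(f"expected 6 2D points, got shape {pts.shape}")
        if len(self.signs) != 6 or any(s not in "+o-" for s in self.signs):
            raise ValueError("signs must be six symbols from {+, o, -}")
        object.__setattr__(self, "points", pts)


def arc_chord(tau_start: float, tau_end: float, length: float) -> np.ndarray:
    """Chord displacement of one constant-curvature arc (angles in radians)."""
    half = 0.5 * (tau_end - tau_start)
    mid = 0.5 * (tau_start + tau_end)
    # np.sinc is sin(pi x)/(pi x); rescale to plain sin(h)/h
    return length * np.sinc(half / np.pi) * np.array([math.sin(mid), math.cos(mid)])


def reconstruct_curve(angles_deg: Sequence[float], length: float = 1.0) -> SpineCurve:
    """Reconstruct the six-point sagittal spine curve from five tilt angles.

    Parameters
    ----------
    angles_deg
        Forward tilts ``tau_1..tau_5`` in degrees, sensor 1 first.
    length
        Arc length ``L`` of each of the four inter-sensor arcs and of the
        straight basal extension ``P1 -> P0``; must be positive.
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.shape != (N_SENSORS,):
        raise ValueError(f"expected {N_SENSORS} angles, got shape {angles.shape}")
    if not np.all(np.isfinite(angles)):
        raise ValueError("angles must be finite")
    if not (math.isfinite(length) and length > 0):
        raise ValueError(f"segment length must be positive, got {length!r}")

    tau = np.radians(angles)
    points = np.zeros((6, 2))
    # P1 at the origin; P2..P5 accumulate arc chords
    for i in range(1, N_SENSORS):
        points[i + 1] = points[i] + arc_chord(tau[i - 1], tau[i], length)
    points[0] = -length * np.array([math.sin(tau[0]), math.cos(tau[0])])
    return SpineCurve(points=points, source_angles=tuple(angles), segment_length=length)


def classify_sign(x: float, zero_tol: float) -> Sign:
    if x > zero_tol:
        return "+"
    if x < -zero_tol:
        return "-"
    return "o"


def offset_shape(
    pair: PosturePair, length: float = 1.0, zero_tol: float = 1e-9
) -> OffsetShape:
    """Reconstruct the offset spine shape of a posture pair.

    The guided-minus-unguided angle differences are fed through
    :func:`reconstruct_curve`; each resulting point's x-coordinate is
    annotated with its sign ('o' within ``zero_tol`` of zero).
    """
    curve = reconstruct_curve(pair.angle_deltas, length)
    signs = tuple(classify_sign(x, zero_tol) for x in curve.points[:, 0])
    return OffsetShape(points=curve.points, signs=signs, pair_id=pair.pair_id)


def curve_to_frame(curve: SpineCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {"point": range(6), "x": curve.points[:, 0], "y": curve.points[:, 1]}
    )


def offsets_to_frame(shapes: Sequence[OffsetShape]) -> pd.DataFrame:
    rows = []
    for s in shapes:
        for level in range(6):
            rows.append(
                {
                    "pair_id": s.pair_id,
                    "point": level,
                    "x": s.points[level, 0],
                    "y": s.points[level, 1],
                    "sign": s.signs[level],
                }
            )
    return pd.DataFrame(rows)
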