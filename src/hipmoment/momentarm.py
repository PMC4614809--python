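"""Muscle-tendon length and moment arms.

Two routes to the same quantity:

* :func:`excursion_moment_arm` — the tendon-excursion method: perturb the
  femur by a small pure-hinge rotation about the instantaneous joint axis
  and centrally difference the muscle-tendon length,
  r = -dL/dtheta (virtual-work sign: a muscle with a positive moment arm
  shortens as the anatomical angle increases).
* :func:`geometric_moment_arm` — the exact lever: for every path segment
  joining a pelvis-owned point to a femur-owned point, the projection of
  the segment's moment about the joint center onto the hinge axis.

The geometric route is the engine's reference; the excursion route is the
classical experimental procedure and must agree with it to discretization
error.  Both accept either axis convention ("corrected" or "legacy") so
that the error of pelvis-fixed axes can be measured, not just fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kinematics import axis_set, femur_orientation, rotation_about
from .model import DOFS, LimbModel, MusclePath, Posture

__all__ = [
    "ExcursionSettings",
    "DegenerateGeometryError",
    "muscle_length",
    "excursion_moment_arm",
    "geometric_moment_arm",
]

_MIN_SEGMENT = 1e-12


class DegenerateGeometryError(ValueError):
    """A muscle path segment collapsed to zero length at some posture."""


@dataclass(frozen=True)
class ExcursionSettings:
    """Central-difference settings for the tendon-excursion method.

    ``h_deg`` is the half-step of the hinge perturbation in degrees;
    0 < h <= 2.  The default 0.25 deg keeps the second-order truncation
    error far below any anatomically meaningful moment arm while staying
    well clear of floating-point cancellation.
    """

    h_deg: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 < self.h_deg <= 2.0):
            raise ValueError(f"h_deg must satisfy 0 < h <= 2, got {self.h_deg!r}")


DEFAULT_SETTINGS = ExcursionSettings()


def _path_arrays(muscle: MusclePath) -> tuple[np.ndarray, np.ndarray]:
    """Stack path points into an (n, 3) array plus a femur-ownership mask."""
    pts = np.array([p.xyz for p in muscle.points], dtype=float)
    femur = np.array([p.segment == "femur" for p in muscle.points])
    return pts, femur


def _world_points(
    pts: np.ndarray, femur: np.ndarray, rot: np.ndarray, center: np.ndarray
) -> np.ndarray:
    world = pts.copy()
    world[femur] = center + pts[femur] @ rot.T
    return world


def _polyline_length(world: np.ndarray, muscle_name: str) -> float:
    deltas = np.diff(world, axis=0)
    seg = np.sqrt((deltas * deltas).sum(axis=1))
    if (seg < _MIN_SEGMENT).any():
        raise DegenerateGeometryError(
            f"muscle {muscle_name!r} has a zero-length path segment at this posture"
        )
    return float(seg.sum())


def muscle_length(model: LimbModel, muscle: str, posture: Posture) -> float:
    """Total polyline length of the muscle path at a posture (model units)."""
    mus = model.muscle(muscle)
    pts, femur = _path_arrays(mus)
    rot = femur_orientation(posture, model.joint)
    world = _world_points(pts, femur, rot, np.asarray(model.joint.center))
    return _polyline_length(world, muscle)


def excursion_moment_arm(
    model: LimbModel,
    muscle: str,
    dof: str,
    posture: Posture,
    mode: str = "corrected",
    settings: ExcursionSettings = DEFAULT_SETTINGS,
) -> float:
    """Tendon-excursion moment arm about one dof's instantaneous axis.

    Replicates the pure-hinge protocol: the femur (with its attached path
    points) is rotated by +/- h about the axis from
    :func:`~hipmoment.kinematics.axis_set` through the joint center while
    the other two angles are held fixed, and
    r = -(L(+h) - L(-h)) / (2 h)  with h in radians.
    """
    if dof not in DOFS:
        raise ValueError(f"dof must be one of {DOFS}, got {dof!r}")
    mus = model.muscle(muscle)
    pts, femur = _path_arrays(mus)
    center = np.asarray(model.joint.center, dtype=float)
    rot0 = femur_orientation(posture, model.joint)
    axes = axis_set(posture, model.joint, mode)
    u = axes.axis(dof)
    sense = model.joint.sense(dof)
    h_rad = math.radians(settings.h_deg)
    lengths = []
    for step in (h_rad, -h_rad):
        rot = rotation_about(u, sense * step) @ rot0
        world = _world_points(pts, femur, rot, center)
        lengths.append(_polyline_length(world, muscle))
    return -(lengths[0] - lengths[1]) / (2.0 * h_rad)


def geometric_moment_arm(
    model: LimbModel,
    muscle: str,
    dof: str,
    posture: Posture,
    mode: str = "corrected",
) -> float:
    """Exact moment arm about one dof's instantaneous axis (no differencing).

    Only mixed-ownership path segments contribute: pelvis-pelvis and
    femur-femur segments are posture-invariant in length.  For a segment
    with femur-owned endpoint b (global), other endpoint a and unit
    direction e = (b - a)/|b - a|, the contribution is
    -s * u . ((b - c) x e), with c the joint center, u the hinge axis and
    s the dof's sense.
    """
    if dof not in DOFS:
        raise ValueError(f"dof must be one of {DOFS}, got {dof!r}")
    mus = model.muscle(muscle)
    pts, femur = _path_arrays(mus)
    center = np.asarray(model.joint.center, dtype=float)
    rot = femur_orientation(posture, model.joint)
    world = _world_points(pts, femur, rot, center)
    u = axis_set(posture, model.joint, mode).axis(dof)
    sense = model.joint.sense(dof)
    total = 0.0
    for i in range(len(world) - 1):
        fa, fb = femur[i], femur[i + 1]
        if fa == fb:
            continue
        b, a = (world[i + 1], world[i]) if fb else (world[i], world[i + 1])
        d = b - a
        norm = math.sqrt(float(d @ d))
        if norm < _MIN_SEGMENT:
            raise DegenerateGeometryError(
                f"muscle {muscle!r} has a zero-length path segment at this posture"
            )
        e = d / norm
        total += -sense * float(u @ np.cross(b - center, e))
    return total
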