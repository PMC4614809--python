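"""Hip joint-axis conventions and rigid femur transforms.

The hip is a pure three-degree-of-freedom rotational joint.  Femur
orientation is the intrinsic cascade FE -> ABD -> LAR:

* flexion-extension about the pelvis-fixed mediolateral axis (global z);
* abduction-adduction about the FE-rotated x axis;
* long-axis rotation about the FE- and ABD-rotated y axis.

Under the *corrected* convention the instantaneous joint axes follow that
cascade: the FE axis never moves; flexing the hip rotates the ABD and LAR
axes with the femur; abducting rotates the LAR axis but not the FE axis;
long-axis rotation moves no axis (the femur spins about the LAR axis
itself).  The *legacy* convention keeps all three axes pelvis-fixed at
their neutral directions for every posture — the error this engine exists
to quantify.

Global frame: x = craniocaudal, y = proximodistal (the femur's long axis
points along -y at neutral), z = mediolateral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import DOFS, MODES, HipJoint, Posture

__all__ = [
    "AxisSet",
    "femur_orientation",
    "axis_set",
    "transform_femur_point",
    "rotation_about",
    "is_rotation",
    "X_HAT",
    "Y_HAT",
    "Z_HAT",
]

X_HAT = np.array([1.0, 0.0, 0.0])
Y_HAT = np.array([0.0, 1.0, 0.0])
Z_HAT = np.array([0.0, 0.0, 1.0])

#: Neutral direction of each dof's rotation axis.
NEUTRAL_AXES = {"FE": Z_HAT, "ABD": X_HAT, "LAR": Y_HAT}


def _rx(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _ry(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rz(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Right-handed rotation matrix about a unit axis (Rodrigues form)."""
    x, y, z = axis
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    one_c = 1.0 - c
    return np.array(
        [
            [c + x * x * one_c, x * y * one_c - z * s, x * z * one_c + y * s],
            [y * x * one_c + z * s, c + y * y * one_c, y * z * one_c - x * s],
            [z * x * one_c - y * s, z * y * one_c + x * s, c + z * z * one_c],
        ]
    )


def is_rotation(matrix: np.ndarray, tol: float = 1e-12) -> bool:
    """True if the matrix is orthonormal with determinant +1 within tol."""
    if matrix.shape != (3, 3):
        return False
    return (
        np.abs(matrix @ matrix.T - np.eye(3)).max() <= tol
        and abs(np.linalg.det(matrix) - 1.0) <= tol
    )


@dataclass(frozen=True)
class AxisSet:
    """The three instantaneous unit rotation axes at a posture, global frame."""

    u_fe: np.ndarray
    u_abd: np.ndarray
    u_lar: np.ndarray
    mode: str

    def axis(self, dof: str) -> np.ndarray:
        return {"FE": self.u_fe, "ABD": self.u_abd, "LAR": self.u_lar}[dof]


def femur_orientation(posture: Posture, joint: HipJoint) -> np.ndarray:
    """Rotation taking femur-local (neutral) coordinates to the global frame.

    Intrinsic composition R = Rz(s_fe*fe) @ Rx(s_abd*abd) @ Ry(s_lar*lar),
    angles converted from anatomical degrees via the joint's dof senses.
    """
    fe = math.radians(joint.sense("FE") * posture.fe_deg)
    abd = math.radians(joint.sense("ABD") * posture.abd_deg)
    lar = math.radians(joint.sense("LAR") * posture.lar_deg)
    return _rz(fe) @ _rx(abd) @ _ry(lar)


def axis_set(posture: Posture, joint: HipJoint, mode: str = "corrected") -> AxisSet:
    """Instantaneous rotation axes at a posture under the given convention.

    Corrected: u_fe = z always; u_abd = Rz(s_fe*fe) @ x (rotates with
    flexion-extension only); u_lar = Rz(s_fe*fe) @ Rx(s_abd*abd) @ y
    (rotates with flexion-extension and abduction-adduction, never with
    long-axis rotation).  Legacy: all three axes stay at their neutral,
    pelvis-fixed directions.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if mode == "legacy":
        return AxisSet(Z_HAT.copy(), X_HAT.copy(), Y_HAT.copy(), mode)
    fe = math.radians(joint.sense("FE") * posture.fe_deg)
    abd = math.radians(joint.sense("ABD") * posture.abd_deg)
    r_fe = _rz(fe)
    u_abd = r_fe @ X_HAT
    u_lar = r_fe @ _rx(abd) @ Y_HAT
    return AxisSet(Z_HAT.copy(), u_abd, u_lar, mode)


def transform_femur_point(
    p: np.ndarray | tuple[float, float, float], posture: Posture, joint: HipJoint
) -> np.ndarray:
    """Global position of a femur-local point (relative to the joint center)."""
    rot = femur_orientation(posture, joint)
    return np.asarray(joint.center, dtype=float) + rot @ np.asarray(p, dtype=float)
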