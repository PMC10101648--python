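"""Forward kinematics of the 4-DOF arm and endpoint geometry.

The arm is the serial chain shoulder pitch -> shoulder yaw -> shoulder roll ->
elbow, with link translations 0.05, 0.22 and 0.16 (dimensionless link-length
units).  The wrist position is obtained by chaining four homogeneous
transforms ``G01 G12 G23 G34`` and reading off the image of the origin; three
of the transforms carry a fixed pi/2 joint offset.  The workspace is therefore
contained in a ball of radius 0.16 + 0.22 + 0.05 = 0.43 around the shoulder.

The module also provides the cursor-rotation used in visuomotor-rotation
experiments (a rigid rotation of the displayed endpoint about an axis through
the origin) and the projected angular-error metric: initial and final hand
positions are projected onto a common plane and the angle at the initial
position between the movement direction and the goal direction is returned,
signed by the right-hand rule about the plane normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "JointAngles",
    "forward_kinematics",
    "rotate_endpoint",
    "angular_error",
    "MAX_REACH",
]

#: Upper bound on the wrist distance from the shoulder (sum of link offsets).
MAX_REACH = 0.16 + 0.22 + 0.05

_HALF_PI = np.pi / 2.0


@dataclass(frozen=True)
class JointAngles:
    """Joint configuration of the arm, all angles in radians."""

    pitch: float
    yaw: float
    roll: float
    elbow: float

    def __post_init__(self) -> None:
        values = (self.pitch, self.yaw, self.roll, self.elbow)
        if not np.all(np.isfinite(values)):
            raise ValueError(f"joint angles must be finite, got {values}")

    def as_array(self) -> np.ndarray:
        return np.array([self.pitch, self.yaw, self.roll, self.elbow])


def _g01(pitch: float) -> np.ndarray:
    c, s = np.cos(pitch), np.sin(pitch)
    return np.array(
        [
            [c, 0.0, -s, 0.0],
            [s, 0.0, c, 0.0],
            [0.0, -1.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def _g12(yaw: float) -> np.ndarray:
    c, s = np.cos(_HALF_PI + yaw), np.sin(_HALF_PI + yaw)
    return np.array(
        [
            [c, 0.0, -s, 0.05 * c],
            [s, 0.0, c, 0.05 * s],
            [0.0, -1.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def _g23(roll: float) -> np.ndarray:
    c, s = np.cos(_HALF_PI + roll), np.sin(_HALF_PI + roll)
    return np.array(
        [
            [c, 0.0, s, 0.0],
            [s, 0.0, -c, 0.0],
            [0.0, 1.0, 0.0, 0.22],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def _g34(elbow: float) -> np.ndarray:
    c, s = np.cos(_HALF_PI + elbow), np.sin(_HALF_PI + elbow)
    return np.array(
        [
            [c, -s, 0.0, 0.16 * c],
            [s, c, 0.0, 0.16 * s],
            [0.0, 0.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def forward_kinematics(angles: JointAngles | np.ndarray) -> np.ndarray:
    """Wrist position for a joint configuration.

    Parameters
    ----------
    angles
        A :class:`JointAngles` or an array-like ``(pitch, yaw, roll, elbow)``
        in radians.

    Returns
    -------
    ndarray of shape (3,)
        Wrist position in workspace units, origin at the shoulder.
    """
    if isinstance(angles, JointAngles):
        pitch, yaw, roll, elbow = angles.as_array()
    else:
        arr = np.asarray(angles, dtype=float)
        if arr.shape != (4,):
            raise ValueError(f"expected 4 joint angles, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"joint angles must be finite, got {arr}")
        pitch, yaw, roll, elbow = arr
    g04 = _g01(pitch) @ _g12(yaw) @ _g23(roll) @ _g34(elbow)
    return g04[:3, 3].copy()


def rotate_endpoint(position: np.ndarray, axis: np.ndarray, angle_deg: float,
                    center: np.ndarray | None = None) -> np.ndarray:
    """Rigidly rotate ``position`` about an ``axis`` through ``center``.

    Used to implement the cursor perturbation: the displayed endpoint is the
    physical endpoint rotated by ``angle_deg`` degrees (right-hand rule about
    ``axis``) around the movement start point; the arm itself is untouched.
    ``center`` defaults to the origin.
    """
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0.0 or not np.isfinite(norm):
        raise ValueError("rotation axis must be non-zero and finite")
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / norm)
    p = np.asarray(position, dtype=float)
    if center is None:
        return rot.apply(p)
    c = np.asarray(center, dtype=float)
    return c + rot.apply(p - c)


def _project(v: np.ndarray, unit_normal: np.ndarray) -> np.ndarray:
    return v - np.dot(v, unit_normal) * unit_normal


def angular_error(
    initial: np.ndarray,
    final: np.ndarray,
    goal: np.ndarray,
    plane_normal: np.ndarray,
    degenerate_tol: float = 1e-12,
) -> float:
    """Signed projected angular error of a movement, in degrees.

    The movement vector ``final - initial`` and the goal vector
    ``goal - initial`` are projected onto the plane orthogonal to
    ``plane_normal``; the returned value is the angle between the projections.
    Zero means the movement went straight at the goal.  The sign is positive
    when the movement is rotated counterclockwise from the goal direction
    about ``plane_normal`` (right-hand rule), which makes the aftereffect of a
    removed cursor rotation show up as a sign flip.
    """
    normal = np.asarray(plane_normal, dtype=float)
    n_norm = np.linalg.norm(normal)
    if n_norm == 0.0 or not np.isfinite(n_norm):
        raise ValueError("plane normal must be non-zero and finite")
    normal = normal / n_norm

    move = _project(np.asarray(final, float) - np.asarray(initial, float), normal)
    aim = _project(np.asarray(goal, float) - np.asarray(initial, float), normal)
    if np.linalg.norm(move) <= degenerate_tol or np.linalg.norm(aim) <= degenerate_tol:
        raise ValueError("projected movement or goal vector is degenerate")
    # atan2 of the out-of-plane cross component against the dot product gives
    # the signed angle from the goal direction to the movement direction.
    return float(
        np.degrees(np.arctan2(np.dot(normal, np.cross(aim, move)), np.dot(aim, move)))
    )
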