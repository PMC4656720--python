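"""Kinematics of the 22-DOF arm/hand.

The arm has a 3-DOF ball shoulder (angles th1 about x, th2 about y, th3
about z), a 1-DOF elbow hinge (th4) and a 3-DOF wrist; each of the four
fingers has three flexion hinges and the thumb a 2-DOF base plus one hinge,
for 3 + 1 + 3 + 15 = 22 controlled degrees of freedom.

The wrist position admits the closed form

    w = A(th1, th2, th3) * (l1 + sin(th4) * l2) + B(th1, th2, th3) * cos(th4) * l2

with orthonormal frame vectors

    A = ( s3 c1 - c3 s2 s1,  -(c3 c1 + s3 s2 s1),  -c2 s1 )
    B = ( -(s3 s1 + c3 s2 c1),  c3 s1 - s3 s2 c1,  -c2 c1 )

so the upper arm points along A and the forearm rotates in the A-B plane by
the elbow angle (th4 = 0 is a 90-degree bend, th4 = pi/2 a straight arm, a
kinematic singularity).  At the zero pose the upper arm hangs along -y and
the forearm points along -z.  The analytic 3x4 Jacobian below is the exact
derivative of this chain.

Hand frame: +z_h distal (along the forearm at zero wrist angles), +y_h the
palmar normal, +x_h across the palm; wrist rotations are intrinsic x-y-z.
Finger flexion rotates about local x, curling the digit toward +y_h.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .config import ArmConfig, HandConfig


class JointLimitError(ValueError):
    """An angle lies outside its configured joint limit interval."""


class SingularJacobianError(RuntimeError):
    """JJ^T is numerically singular (e.g., fully outstretched arm)."""


# ---------------------------------------------------------------------------
# state
# ---------------------------------------------------------------------------

@dataclass
class ArmHandState:
    """Joint angles and velocities of the limb (radians, rad/s)."""

    shoulder_angles: np.ndarray = field(default_factory=lambda: np.zeros(3))
    elbow_angle: float = 0.0
    wrist_angles: np.ndarray = field(default_factory=lambda: np.zeros(3))
    finger_joints: np.ndarray = field(default_factory=lambda: np.zeros(15))
    joint_velocities: np.ndarray = field(default_factory=lambda: np.zeros(22))
    l1: float = 0.17
    l2: float = 0.17

    def __post_init__(self):
        self.shoulder_angles = np.asarray(self.shoulder_angles, dtype=float)
        self.wrist_angles = np.asarray(self.wrist_angles, dtype=float)
        self.finger_joints = np.asarray(self.finger_joints, dtype=float)
        self.joint_velocities = np.asarray(self.joint_velocities, dtype=float)
        if self.finger_joints.shape != (15,):
            raise ValueError("finger_joints must hold 15 angles")
        if self.joint_velocities.shape != (22,):
            raise ValueError("22 degrees of freedom expected")

    @property
    def angles(self) -> np.ndarray:
        """All 22 angles in canonical order: shoulder, elbow, wrist, fingers."""
        return np.concatenate([self.shoulder_angles, [self.elbow_angle],
                               self.wrist_angles, self.finger_joints])

    @classmethod
    def from_angles(cls, angles: np.ndarray, l1: float = 0.17, l2: float = 0.17,
                    velocities: np.ndarray | None = None) -> "ArmHandState":
        angles = np.asarray(angles, dtype=float)
        if angles.shape != (22,):
            raise ValueError("expected 22 angles")
        vel = np.zeros(22) if velocities is None else np.asarray(velocities, float)
        return cls(shoulder_angles=angles[:3], elbow_angle=float(angles[3]),
                   wrist_angles=angles[4:7], finger_joints=angles[7:22],
                   joint_velocities=vel, l1=l1, l2=l2)

    @property
    def arm_angles(self) -> np.ndarray:
        return np.concatenate([self.shoulder_angles, [self.elbow_angle]])


def joint_limit_bounds(arm: ArmConfig) -> Tuple[np.ndarray, np.ndarray]:
    """(lower, upper) limits for all 22 DOFs in canonical order."""
    lo = ([lim[0] for lim in arm.shoulder_limits] + [arm.elbow_limits[0]]
          + [lim[0] for lim in arm.wrist_limits] + [arm.finger_limits[0]] * 15)
    hi = ([lim[1] for lim in arm.shoulder_limits] + [arm.elbow_limits[1]]
          + [lim[1] for lim in arm.wrist_limits] + [arm.finger_limits[1]] * 15)
    return np.array(lo), np.array(hi)


def check_limits(state: ArmHandState, arm: ArmConfig) -> None:
    lo, hi = joint_limit_bounds(arm)
    a = state.angles
    bad = np.where((a < lo - 1e-12) | (a > hi + 1e-12))[0]
    if bad.size:
        raise JointLimitError(f"angles at DOF indices {bad.tolist()} outside limits")


# ---------------------------------------------------------------------------
# arm forward kinematics and Jacobian
# ---------------------------------------------------------------------------

def _arm_frame(theta: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    s1, c1 = np.sin(theta[0]), np.cos(theta[0])
    s2, c2 = np.sin(theta[1]), np.cos(theta[1])
    s3, c3 = np.sin(theta[2]), np.cos(theta[2])
    A = np.array([s3 * c1 - c3 * s2 * s1,
                  -(c3 * c1 + s3 * s2 * s1),
                  -c2 * s1])
    B = np.array([-(s3 * s1 + c3 * s2 * c1),
                  c3 * s1 - s3 * s2 * c1,
                  -c2 * c1])
    return A, B


def wrist_position(theta: np.ndarray, l1: float, l2: float) -> np.ndarray:
    """Wrist position from shoulder/elbow angles (th1..th4)."""
    A, B = _arm_frame(theta)
    s4, c4 = np.sin(theta[3]), np.cos(theta[3])
    return A * (l1 + s4 * l2) + B * (c4 * l2)


def elbow_position(theta: np.ndarray, l1: float) -> np.ndarray:
    A, _ = _arm_frame(theta)
    return A * l1


def forearm_rotation(theta: np.ndarray) -> np.ndarray:
    """World rotation of the forearm/hand base frame (columns x_h, y_h, z_h).

    z_h points from the elbow to the wrist; y_h (palmar at zero wrist
    angles) lies in the arm plane; x_h completes a right-handed frame.
    """
    A, B = _arm_frame(theta)
    s4, c4 = np.sin(theta[3]), np.cos(theta[3])
    z_h = s4 * A + c4 * B
    y_h = c4 * A - s4 * B
    x_h = np.cross(y_h, z_h)
    return np.column_stack([x_h, y_h, z_h])


def jacobian(theta: np.ndarray, l1: float, l2: float) -> np.ndarray:
    """Analytic 3x4 wrist Jacobian d(wrist)/d(th1..th4) in m/rad."""
    t1, t2, t3, t4 = theta
    s1, c1 = np.sin(t1), np.cos(t1)
    s2, c2 = np.sin(t2), np.cos(t2)
    s3, c3 = np.sin(t3), np.cos(t3)
    s4, c4 = np.sin(t4), np.cos(t4)
    r = l1 + s4 * l2
    # dA/dth_i and dB/dth_i of the closed-form chain
    dA = np.array([
        [-s3 * s1 - c3 * s2 * c1, c3 * s1 - s3 * s2 * c1, -c2 * c1],
        [-c3 * c2 * s1, -s3 * c2 * s1, s2 * s1],
        [c3 * c1 + s3 * s2 * s1, s3 * c1 - c3 * s2 * s1, 0.0],
    ])  # rows: d/dth1, d/dth2, d/dth3
    dB = np.array([
        [-s3 * c1 + c3 * s2 * s1, c3 * c1 + s3 * s2 * s1, c2 * s1],
        [-c3 * c2 * c1, -s3 * c2 * c1, s2 * c1],
        [-c3 * s1 + s3 * s2 * c1, -s3 * s1 - c3 * s2 * c1, 0.0],
    ])
    A, B = _arm_frame(theta)
    J = np.empty((3, 4))
    for i in range(3):
        J[:, i] = dA[i] * r + dB[i] * (c4 * l2)
    J[:, 3] = A * (c4 * l2) - B * (s4 * l2)
    return J


def jacobian_pseudoinverse(J: np.ndarray, condition_cap: float = 1e6) -> np.ndarray:
    """Right pseudo-inverse J^T (J J^T)^-1 with a singularity guard."""
    JJt = J @ J.T
    if np.linalg.cond(JJt) > condition_cap:
        raise SingularJacobianError("Jacobian is rank deficient (singular pose)")
    return J.T @ np.linalg.inv(JJt)


def ik_step(state: ArmHandState, displacement: np.ndarray, arm: ArmConfig,
            ) -> Tuple[np.ndarray, bool]:
    """One resolved-rate IK step: target arm angles for a wrist displacement.

    Returns ``(theta_hat, clamped)`` where *theta_hat* are the four target
    shoulder/elbow angles clamped to the joint limits and *clamped* flags
    whether any limit was hit.  The displacement is capped at the configured
    per-step magnitude.
    """
    d = np.asarray(displacement, dtype=float)
    norm = np.linalg.norm(d)
    if norm > arm.ik_step_cap:
        d = d * (arm.ik_step_cap / norm)
    theta = state.arm_angles
    J = jacobian(theta, state.l1, state.l2)
    Jp = jacobian_pseudoinverse(J, arm.ik_condition_cap)
    theta_hat = theta + Jp @ d
    lo, hi = joint_limit_bounds(arm)
    clipped = np.clip(theta_hat, lo[:4], hi[:4])
    return clipped, bool(np.any(clipped != theta_hat))


def pd_torque(theta: np.ndarray, theta_hat: np.ndarray, theta_dot: np.ndarray,
              p: float | np.ndarray, d: float | np.ndarray) -> np.ndarray:
    """PD control torque tau = p (theta_hat - theta) - d theta_dot.

    Damping opposes velocity (dissipative sign).
    """
    return p * (np.asarray(theta_hat) - np.asarray(theta)) - d * np.asarray(theta_dot)


# ---------------------------------------------------------------------------
# hand landmarks
# ---------------------------------------------------------------------------

def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


FINGER_NAMES = ("index", "middle", "ring", "pinky")

#: landmark identifiers produced by :func:`hand_landmarks`
LANDMARKS = ("palm",
             "finger_pad_0", "finger_pad_1", "finger_pad_2", "finger_pad_3",
             "inner_finger_0", "inner_finger_1", "inner_finger_2", "inner_finger_3",
             "finger_side_0", "thumb_pad", "thumb_side")


def hand_rotation(state: ArmHandState) -> np.ndarray:
    """World rotation of the hand frame after the wrist angles."""
    R_fore = forearm_rotation(state.arm_angles)
    wx, wy, wz = state.wrist_angles
    return R_fore @ _rot_x(wx) @ _rot_y(wy) @ _rot_z(wz)


def hand_landmarks(state: ArmHandState, hand: HandConfig) -> Dict[str, np.ndarray]:
    """World positions of the contact landmarks on palm, fingers and thumb.

    Finger flexion bends each phalanx about the hand-local x axis toward the
    palmar (+y_h) side; the thumb base abducts about z_h and flexes about an
    oblique axis so its pad opposes the finger pads.
    """
    w = wrist_position(state.arm_angles, state.l1, state.l2)
    Rh = hand_rotation(state)
    out: Dict[str, np.ndarray] = {}
    out["palm"] = w + Rh @ np.array([0.0, 0.0, hand.palm_center_offset])

    fj = state.finger_joints
    segs = hand.finger_segments
    for fi, bx in enumerate(hand.finger_base_x):
        base = w + Rh @ np.array([bx, 0.0, hand.finger_base_z])
        ang = fj[3 * fi: 3 * fi + 3]
        R = Rh.copy()
        pos = base
        joints: List[np.ndarray] = [pos]
        for a, seg in zip(ang, segs):
            # positive flexion curls the phalanx toward the palmar (+y_h) side
            R = R @ _rot_x(-a)
            pos = pos + R @ np.array([0.0, 0.0, seg])
            joints.append(pos)
        tip_pad = pos + R @ np.array([0.0, hand.pad_offset, 0.0])
        out[f"finger_pad_{fi}"] = tip_pad
        out[f"inner_finger_{fi}"] = 0.5 * (joints[0] + joints[1]) \
            + R @ np.array([0.0, hand.pad_offset, 0.0])
        if fi == 0:
            # radial side of the index distal phalanx (side-grasp surface)
            out["finger_side_0"] = 0.5 * (joints[2] + joints[3]) \
                + R @ np.array([-hand.pad_offset, 0.0, 0.0])

    # thumb: base abduction about z_h, flexion about x_h, one hinge
    t_ab, t_fl, t_ip = fj[12], fj[13], fj[14]
    tb = w + Rh @ np.asarray(hand.thumb_base)
    Rt = Rh @ _rot_z(t_ab) @ _rot_x(t_fl)
    # thumb points across the palm toward +x_h at zero angles
    d1 = Rt @ np.array([np.cos(0.9), np.sin(0.9) * 0.3, np.sin(0.9)])
    d1 = d1 / np.linalg.norm(d1)
    p1 = tb + hand.thumb_segments[0] * d1
    Rt2 = Rt @ _rot_x(t_ip)
    d2 = Rt2 @ np.array([np.cos(0.9), np.sin(0.9) * 0.3, np.sin(0.9)])
    d2 = d2 / np.linalg.norm(d2)
    p2 = p1 + hand.thumb_segments[1] * d2
    pad_dir = Rt2 @ np.array([0.3, 1.0, 0.0])
    pad_dir = pad_dir / np.linalg.norm(pad_dir)
    out["thumb_pad"] = p2 + hand.pad_offset * pad_dir
    out["thumb_side"] = p2 + hand.pad_offset * (Rt2 @ np.array([1.0, 0.0, 0.0]))
    return out


def landmark_array(state: ArmHandState, hand: HandConfig) -> np.ndarray:
    """Landmark positions stacked in :data:`LANDMARKS` order, shape (12, 3)."""
    lm = hand_landmarks(state, hand)
    return np.array([lm[name] for name in LANDMARKS])
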