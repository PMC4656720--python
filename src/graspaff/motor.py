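"""Primary motor module: decode premotor fields and drive the movement.

This module is deliberately non-neural: it decodes the settled premotor
fields into a :class:`GraspPlan` (center-of-mass decoding with an activity
threshold), then runs three coupled controllers —

* the *reach controller*: a 3-D wrist DMP toward the offset target, fed
  through resolved-rate inverse kinematics; after the offset point is
  reached the wrist retargets the object center, and palm or thumb contact
  halts the reach permanently;
* the *wrist-rotation controller*: decoded wrist angles passed straight to
  the wrist PD controllers;
* the *grasp-phase controller*: preshape begins when a reach target is
  set; enclose begins when the wrist comes within the trigger distance
  kappa of the object or on palm contact, whichever happens first.  A
  normalized timing DMP (0 to 1) interpolates the finger joints from their
  current angles to the virtual-finger posture, and digits freeze on
  contact.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .config import ArmConfig, MotorConfig
from .dmp import DmpState, dmp_step, make_dmp, retarget
from .dnf import DnfField
from .objects import cartesian_from_spherical
from .premotor import VF_COMBINATIONS

# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------


def decode_center_of_mass(activity: np.ndarray, preferred: np.ndarray,
                          xi: float = 0.01) -> Optional[np.ndarray]:
    """Activity-weighted mean of preferred values over units with f >= xi.

    *preferred* has shape ``activity.shape + (dims,)``.  Returns None when
    every unit is below threshold (no-decode: treated as no movement).
    """
    f = np.asarray(activity, dtype=float)
    mask = f >= xi
    if not mask.any():
        return None
    w = np.where(mask, f, 0.0)
    dims = preferred.shape[-1]
    return (w[..., None] * preferred).reshape(-1, dims).sum(0) / w.sum()


def select_vf(f5e_fields: Dict[str, DnfField], xi: float = 0.01,
              ) -> Optional[Tuple[str, float]]:
    """Inter-field competition picks the combination; intra-field the aperture.

    The winning virtual-finger combination is the field with the highest
    peak firing (ties go to the lowest enum order: precision, tripod,
    power, side); the aperture is the 1-D center-of-mass decode of that
    field.  Returns None when no field has a super-threshold unit.
    """
    best_vf, best_peak = None, -np.inf
    for vf in VF_COMBINATIONS:
        peak = float(f5e_fields[vf].f.max())
        if peak >= xi and peak > best_peak:
            best_vf, best_peak = vf, peak
    if best_vf is None:
        return None
    fld = f5e_fields[best_vf]
    ap = decode_center_of_mass(fld.f, fld.preferred_grid(), xi)
    return best_vf, float(np.clip(ap[0], 0.0, 1.0))


@dataclass
class GraspPlan:
    """Decoded motor parameters for one reach-to-grasp movement."""

    object_center: Tuple[float, float, float]     # (phi_s, theta_s, rho_s)
    reach_offset: Tuple[float, float, float]      # (phi_o, theta_o, rho_o)
    wrist_orientation: Tuple[float, float, float]
    vf_combination: str
    max_aperture: float

    def __post_init__(self):
        if self.vf_combination not in VF_COMBINATIONS:
            raise ValueError(f"unknown VF combination {self.vf_combination!r}")
        if not 0.0 <= self.max_aperture <= 1.0:
            raise ValueError("aperture must lie in [0, 1]")

    def to_json(self) -> str:
        return json.dumps({
            "object_center": list(self.object_center),
            "reach_offset": list(self.reach_offset),
            "wrist_orientation": list(self.wrist_orientation),
            "vf_combination": self.vf_combination,
            "max_aperture": self.max_aperture})

    @classmethod
    def from_json(cls, text: str) -> "GraspPlan":
        d = json.loads(text)
        return cls(object_center=tuple(d["object_center"]),
                   reach_offset=tuple(d["reach_offset"]),
                   wrist_orientation=tuple(d["wrist_orientation"]),
                   vf_combination=d["vf_combination"],
                   max_aperture=float(d["max_aperture"]))


def compose_reach_target(object_center: Sequence[float],
                         reach_offset: Sequence[float],
                         workspace_radius: float) -> Tuple[np.ndarray, bool]:
    """Cartesian wrist target: object center plus world-aligned offset.

    The object-centered spherical offset is expressed in the world-aligned
    frame at the object center.  Targets outside the reachable workspace
    are clamped to the boundary sphere and flagged.
    """
    c = cartesian_from_spherical(*object_center)
    o = cartesian_from_spherical(*reach_offset)
    target = c + o
    norm = np.linalg.norm(target)
    if norm > workspace_radius:
        return target * (workspace_radius / norm), True
    return target, False


# ---------------------------------------------------------------------------
# virtual-finger posture table
# ---------------------------------------------------------------------------

# finger-joint layout: index(3), middle(3), ring(3), pinky(3), thumb(ab, fl, ip)
_CURLED = (1.5, 1.3, 1.0)

#: preshape postures at aperture 0 / aperture 1 and the enclose posture.
#: Aperture linearly scales the thumb-finger opening of the involved digits;
#: uninvolved digits keep the combination's stated default.
DEFAULT_POSTURES: Dict[str, Dict[str, tuple]] = {
    "precision": {
        "open": (0.20, 0.10, 0.05) + _CURLED * 3 + (0.15, 0.05, 0.05),
        "closed": (0.70, 0.50, 0.30) + _CURLED * 3 + (0.55, 0.25, 0.20),
        "enclose": (1.05, 0.90, 0.70) + _CURLED * 3 + (1.15, 0.45, 0.40),
        "involved": ("index", "thumb"),
    },
    "tripod": {
        "open": (0.20, 0.10, 0.05) * 2 + _CURLED * 2 + (0.15, 0.05, 0.05),
        "closed": (0.70, 0.50, 0.30) * 2 + _CURLED * 2 + (0.55, 0.25, 0.20),
        "enclose": (1.05, 0.90, 0.70) * 2 + _CURLED * 2 + (1.15, 0.45, 0.40),
        "involved": ("index", "middle", "thumb"),
    },
    "power": {
        "open": (0.40, 0.25, 0.10) * 4 + (0.15, 0.05, 0.05),
        "closed": (0.95, 0.65, 0.45) * 4 + (0.45, 0.20, 0.15),
        "enclose": (1.60, 1.30, 1.00) * 4 + (0.95, 0.55, 0.45),
        "involved": ("index", "middle", "ring", "pinky", "thumb"),
    },
    "side": {
        "open": _CURLED * 4 + (0.00, 0.00, 0.00),
        "closed": _CURLED * 4 + (0.25, 0.10, 0.05),
        "enclose": _CURLED * 4 + (1.00, 0.40, 0.30),
        "involved": ("thumb",),
    },
}

_DIGIT_SLICES = {"index": slice(0, 3), "middle": slice(3, 6), "ring": slice(6, 9),
                 "pinky": slice(9, 12), "thumb": slice(12, 15)}


def vf_to_fingers(vf_combination: str, max_aperture: float, phase: str,
                  postures: Dict[str, Dict[str, tuple]] | None = None,
                  ) -> np.ndarray:
    """Target finger angles (15) for a combination, aperture and phase.

    ``phase`` is "preshape" or "enclose".  During preshape the opening of
    the involved digits interpolates linearly between the closed
    (aperture 0) and open (aperture 1) posture; uninvolved digits sit at
    the combination's default regardless of aperture.
    """
    table = (postures or DEFAULT_POSTURES).get(vf_combination)
    if table is None:
        raise ValueError(f"unknown VF combination {vf_combination!r}")
    if not 0.0 <= max_aperture <= 1.0:
        raise ValueError("aperture must lie in [0, 1]")
    if phase == "enclose":
        return np.asarray(table["enclose"], dtype=float)
    if phase != "preshape":
        raise ValueError(f"unknown grasp phase {phase!r}")
    open_p = np.asarray(table["open"], dtype=float)
    closed_p = np.asarray(table["closed"], dtype=float)
    target = closed_p + max_aperture * (open_p - closed_p)
    for digit, sl in _DIGIT_SLICES.items():
        if digit not in table["involved"]:
            target[sl] = closed_p[sl]
    return target


# ---------------------------------------------------------------------------
# controllers
# ---------------------------------------------------------------------------

def _timing_dmp(duration: float, alpha_u: float) -> DmpState:
    # critically damped step response reaches ~0.95 at omega * t = 4.74
    omega = 4.74 / duration
    return make_dmp(0.0, 1.0, K=omega ** 2, D=2 * omega, alpha_u=alpha_u)


@dataclass
class ReachController:
    """Wrist trajectory generation + inverse kinematics, with stop-on-contact."""

    target: np.ndarray
    final_center: np.ndarray
    dmp: DmpState
    retarget_tolerance: float
    halted: bool = False
    retargeted: bool = False
    singular: bool = False
    frozen_targets: Optional[np.ndarray] = None

    @classmethod
    def create(cls, wrist_pos: np.ndarray, plan_target: np.ndarray,
               object_center: np.ndarray, cfg: MotorConfig) -> "ReachController":
        dmp = make_dmp(wrist_pos, plan_target, K=cfg.dmp_K, D=cfg.dmp_D,
                       alpha_u=cfg.dmp_alpha_u, n_basis=cfg.n_basis,
                       v_cap=cfg.reach_speed_cap)
        return cls(target=np.asarray(plan_target, float),
                   final_center=np.asarray(object_center, float),
                   dmp=dmp, retarget_tolerance=cfg.retarget_tolerance)

    def step(self, state, arm_cfg: ArmConfig, dt: float,
             stop_contact: bool) -> Tuple[np.ndarray, bool]:
        """Next shoulder/elbow targets. Returns (theta_hat[4], clamped)."""
        from .kinematics import ik_step, wrist_position, SingularJacobianError
        if stop_contact:
            self.halted = True
        wrist = wrist_position(state.arm_angles, state.l1, state.l2)
        if self.halted:
            # reach halts at the current wrist position, permanently
            if self.frozen_targets is None:
                self.frozen_targets = state.arm_angles.copy()
            return self.frozen_targets, False
        if (not self.retargeted
                and np.linalg.norm(wrist - self.target) < self.retarget_tolerance):
            retarget(self.dmp, self.final_center)
            self.retargeted = True
        dmp_step(self.dmp, dt)
        displacement = self.dmp.x - wrist
        try:
            theta_hat, clamped = ik_step(state, displacement, arm_cfg)
        except SingularJacobianError:
            self.singular = True
            return state.arm_angles.copy(), False
        return theta_hat, clamped


@dataclass
class GraspPhaseController:
    """Preshape/enclose phase sequencing and finger-target interpolation."""

    plan: GraspPlan
    kappa: float
    preshape_dmp: DmpState
    enclose_dmp: DmpState
    postures: Optional[Dict[str, Dict[str, tuple]]] = None
    phase: str = "preshape"
    _start_angles: Optional[np.ndarray] = None
    _frozen: np.ndarray = field(default_factory=lambda: np.zeros(15, dtype=bool))
    _frozen_targets: np.ndarray = field(default_factory=lambda: np.zeros(15))

    @classmethod
    def create(cls, plan: GraspPlan, cfg: MotorConfig,
               postures=None) -> "GraspPhaseController":
        return cls(plan=plan, kappa=cfg.kappa,
                   preshape_dmp=_timing_dmp(cfg.preshape_duration, cfg.dmp_alpha_u),
                   enclose_dmp=_timing_dmp(cfg.enclose_duration, cfg.dmp_alpha_u),
                   postures=postures)

    def step(self, finger_angles: np.ndarray, wrist_object_distance: float,
             palm_contact: bool, digit_contacts: Sequence[str],
             dt: float) -> np.ndarray:
        """Advance the phase machine one control step; return 15 finger targets."""
        if self.phase == "preshape" and (wrist_object_distance < self.kappa
                                         or palm_contact):
            self.phase = "enclose"
            self._start_angles = None
        if self._start_angles is None:
            self._start_angles = np.asarray(finger_angles, dtype=float).copy()
        dmp = self.preshape_dmp if self.phase == "preshape" else self.enclose_dmp
        dmp_step(dmp, dt)
        timing = float(np.clip(dmp.x[0], 0.0, 1.0))
        final = vf_to_fingers(self.plan.vf_combination, self.plan.max_aperture,
                              self.phase, self.postures)
        targets = self._start_angles + timing * (final - self._start_angles)
        if self.phase == "enclose":
            # digits freeze where they touch the object (no further closing)
            for digit in digit_contacts:
                sl = _DIGIT_SLICES.get(digit)
                if sl is None:
                    continue
                idx = np.arange(15)[sl]
                newly = idx[~self._frozen[idx]]
                if newly.size:
                    self._frozen[newly] = True
                    self._frozen_targets[newly] = finger_angles[newly]
            targets = np.where(self._frozen, self._frozen_targets, targets)
        return targets
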