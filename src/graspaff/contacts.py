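"""Geometric contact detection and the grasp-stability surrogate.

Rigid-body dynamics are replaced by the only physics outputs the learning
loop consumes: contact events and an opposition-axis stability verdict.
A hand landmark within the contact tolerance of the object surface (or
penetrating it) while not retracting yields a `Contact`.  A grasp is stable
iff two contacts from opposing body parts define a segment that passes
through the object interior, and such a pair persists continuously for the
hold duration (2 s of simulation time).  A fast, non-grasping collision
displaces the object along the push direction proportionally to the
penetration depth — the surrogate for knocking the object out of reach.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .config import ContactConfig
from .objects import ObjectPrimitive

#: pairs of body-part classes whose contacts can form an opposition axis
_OPPOSING = (
    ("thumb", "finger"),
    ("thumb", "inner"),
    ("palm", "finger"),
    ("palm", "inner"),
)


def body_part_class(name: str) -> str:
    if name.startswith("thumb"):
        return "thumb"
    if name.startswith("finger"):
        return "finger"
    if name.startswith("inner"):
        return "inner"
    return "palm"


@dataclass(frozen=True)
class Contact:
    body_part: str
    point: Tuple[float, float, float]
    time: float

    @property
    def part_class(self) -> str:
        return body_part_class(self.body_part)


def detect_contacts(landmarks: Dict[str, np.ndarray], obj: ObjectPrimitive,
                    cfg: ContactConfig, t: float = 0.0,
                    velocities: Dict[str, np.ndarray] | None = None,
                    ) -> List[Contact]:
    """Contacts between hand landmarks and the object surface.

    A landmark makes contact when its signed distance to the surface is at
    most the tolerance.  When a velocity is supplied, landmarks that move
    away from the object faster than the configured floor are excluded
    (no "contact" while retracting).
    """
    names = list(landmarks.keys())
    pts = np.array([landmarks[n] for n in names])
    sd = obj.signed_distance(pts)
    out: List[Contact] = []
    for i, name in enumerate(names):
        if sd[i] > cfg.tolerance:
            continue
        if velocities is not None and name in velocities:
            to_surface = obj.center - pts[i]
            norm = np.linalg.norm(to_surface)
            if norm > 1e-12:
                approach = float(velocities[name] @ (to_surface / norm))
                if approach < cfg.approach_speed_floor:
                    continue
        out.append(Contact(body_part=name, point=tuple(pts[i]), time=t))
    return out


def has_opposition(contacts: Sequence[Contact], obj: ObjectPrimitive,
                   margin: float = 1e-4, n_samples: int = 33) -> bool:
    """Whether any pair of contacts from opposing parts crosses the interior.

    All candidate pair segments are sampled and tested against the signed
    distance field in one batch.
    """
    by_class: Dict[str, List[Contact]] = {}
    for c in contacts:
        by_class.setdefault(c.part_class, []).append(c)
    pairs = [(ca.point, cb.point)
             for cls_a, cls_b in _OPPOSING
             for ca in by_class.get(cls_a, ())
             for cb in by_class.get(cls_b, ())]
    if not pairs:
        return False
    a = np.array([p[0] for p in pairs])
    b = np.array([p[1] for p in pairs])
    t = np.linspace(0.0, 1.0, n_samples)[1:-1]
    pts = a[:, None, :] * (1 - t)[None, :, None] + b[:, None, :] * t[None, :, None]
    sd = obj.signed_distance(pts.reshape(-1, 3))
    return bool(np.any(sd < -margin))


def evaluate_grasp_stability(contact_history: Sequence[Sequence[Contact]],
                             obj: ObjectPrimitive, dt: float,
                             hold_duration: float = 2.0) -> bool:
    """Stable iff an opposition axis persists continuously for *hold_duration*.

    *contact_history* is the per-control-step list of contacts over the
    post-enclose interval; *dt* is the control step.  The criterion counts
    the longest uninterrupted run of steps with an interior-crossing
    opposing pair.
    """
    needed = int(round(hold_duration / dt))
    run = 0
    best = 0
    for step_contacts in contact_history:
        if has_opposition(step_contacts, obj):
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best >= needed


def opposition_flags(contact_history: Sequence[Sequence[Contact]],
                     obj: ObjectPrimitive) -> np.ndarray:
    return np.array([has_opposition(c, obj) for c in contact_history], dtype=bool)


def perturb_object_on_collision(obj: ObjectPrimitive,
                                landmarks: Dict[str, np.ndarray],
                                velocities: Dict[str, np.ndarray],
                                contacts: Sequence[Contact],
                                cfg: ContactConfig) -> ObjectPrimitive:
    """Displace the object after a fast, non-grasping collision.

    If a landmark penetrates deeper than the threshold while the hand moves
    faster than the configured speed, and the current contacts do *not*
    satisfy the opposition test, the object is pushed along the landmark's
    velocity direction by ``gain * penetration`` (capped per step).
    Grasping (opposed) contact configurations never displace the object.
    """
    if not contacts:
        return obj
    if has_opposition(contacts, obj):
        return obj
    names = list(landmarks.keys())
    pts = np.array([landmarks[n] for n in names])
    sd = obj.signed_distance(pts)
    best_push = None
    best_pen = cfg.perturb_penetration
    for i, name in enumerate(names):
        pen = -float(sd[i])
        if pen <= best_pen:
            continue
        vel = velocities.get(name)
        if vel is None:
            continue
        speed = float(np.linalg.norm(vel))
        if speed < cfg.perturb_speed:
            continue
        best_pen = pen
        best_push = (vel / speed) * min(cfg.perturb_gain * pen, cfg.perturb_cap)
    if best_push is None:
        return obj
    return obj.displaced(best_push)


def contacts_to_rows(trial: int, contact_history: Sequence[Sequence[Contact]],
                     dt: float, t0: float = 0.0) -> List[dict]:
    """Flatten a contact history into tidy rows (trial, time, body_part, x, y, z)."""
    rows = []
    for k, step_contacts in enumerate(contact_history):
        for c in step_contacts:
            rows.append({"trial": trial, "time": t0 + k * dt,
                         "body_part": c.body_part,
                         "x": c.point[0], "y": c.point[1], "z": c.point[2]})
    return rows
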