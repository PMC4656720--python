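"""Graspable object primitives.

An :class:`ObjectPrimitive` is a cube, rectangular prism, cylinder, sphere or
flat plate with a size triple, a shoulder-centered Cartesian position and an
intrinsic x-y-z Euler orientation.  Derived quantities — the main-axis unit
vector, outward face normals (rectangular shapes), the shoulder-centered
spherical pose, and signed distances to the surface — feed the parietal
encoders and the contact surrogate.

Spherical convention: ``theta_s`` is the polar angle from the +y axis in
[0, pi]; ``phi_s = atan2(z, x)`` is the azimuth in the x-z plane, restricted
to [-pi, 0] (objects are presented in the -z hemisphere); ``rho_s`` is the
distance from the shoulder.  Gravity is absent: an object keeps its pose
unless displaced by a collision.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np
from scipy.spatial.transform import Rotation

SHAPES = ("cube", "rectangular_prism", "cylinder", "sphere", "plate")
RECTANGULAR = ("cube", "rectangular_prism", "plate")


def spherical_from_cartesian(p: np.ndarray) -> Tuple[float, float, float]:
    """Return (phi_s, theta_s, rho_s) for a shoulder-centered point."""
    p = np.asarray(p, dtype=float)
    rho = float(np.linalg.norm(p))
    if rho == 0.0:
        return 0.0, 0.0, 0.0
    theta = float(np.arccos(np.clip(p[1] / rho, -1.0, 1.0)))
    phi = float(np.arctan2(p[2], p[0]))
    return phi, theta, rho


def cartesian_from_spherical(phi: float, theta: float, rho: float) -> np.ndarray:
    return rho * np.array([np.sin(theta) * np.cos(phi),
                           np.cos(theta),
                           np.sin(theta) * np.sin(phi)])


@dataclass(frozen=True)
class ObjectPrimitive:
    shape: str
    size: Tuple[float, float, float]
    position: Tuple[float, float, float]
    orientation: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if any(s <= 0 for s in self.size):
            raise ValueError("all sizes must be strictly positive")

    # -- derived geometry -------------------------------------------------
    @property
    def rotation(self) -> Rotation:
        return Rotation.from_euler("xyz", self.orientation)

    @property
    def _R(self) -> np.ndarray:
        """Rotation matrix, cached (SDF queries run every control step)."""
        R = self.__dict__.get("_R_cache")
        if R is None:
            R = self.rotation.as_matrix()
            object.__setattr__(self, "_R_cache", R)
        return R

    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)

    @property
    def main_axis(self) -> np.ndarray:
        """Unit vector of the longest body axis in world coordinates."""
        local = np.zeros(3)
        if self.shape == "cylinder":
            local[2] = 1.0
        else:
            local[int(np.argmax(self.size))] = 1.0
        axis = self.rotation.apply(local)
        return axis / np.linalg.norm(axis)

    @property
    def face_normals(self) -> np.ndarray:
        """Outward unit normals of the six faces (rectangular shapes only)."""
        if self.shape not in RECTANGULAR:
            return np.zeros((0, 3))
        local = np.vstack([np.eye(3), -np.eye(3)])
        return self.rotation.apply(local)

    def visible_normals(self, view_direction: np.ndarray) -> np.ndarray:
        """Faces whose outward normal points against the view direction."""
        normals = self.face_normals
        if len(normals) == 0:
            return normals
        v = np.asarray(view_direction, dtype=float)
        n = np.linalg.norm(v)
        if n == 0:
            return np.zeros((0, 3))
        return normals[normals @ (v / n) < 0.0]

    @property
    def spherical(self) -> Tuple[float, float, float]:
        return spherical_from_cartesian(self.center)

    @property
    def half_extent(self) -> float:
        return 0.5 * float(max(self.size))

    # -- geometry queries -------------------------------------------------
    def _to_local(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.center) @ self._R

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance from world points to the surface (negative inside)."""
        single = np.asarray(points).ndim == 1
        q = self._to_local(points)
        s = np.asarray(self.size, dtype=float)
        if self.shape == "sphere":
            d = np.linalg.norm(q, axis=1) - 0.5 * s[0]
        elif self.shape == "cylinder":
            # local z is the cylinder axis; s[0] is the diameter, s[2] the length
            radial = np.linalg.norm(q[:, :2], axis=1) - 0.5 * s[0]
            axial = np.abs(q[:, 2]) - 0.5 * s[2]
            outside = np.maximum(radial, 0.0) ** 2 + np.maximum(axial, 0.0) ** 2
            inside = np.minimum(np.maximum(radial, axial), 0.0)
            d = np.sqrt(outside) + inside
        else:  # box family
            h = 0.5 * s
            excess = np.abs(q) - h
            outside = np.linalg.norm(np.maximum(excess, 0.0), axis=1)
            inside = np.minimum(excess.max(axis=1), 0.0)
            d = outside + inside
        return float(d[0]) if single else d

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """True for points strictly inside the body (shrunk by *margin*)."""
        return self.signed_distance(points) < -margin

    def segment_crosses_interior(self, a: np.ndarray, b: np.ndarray,
                                 margin: float = 1e-4, n_samples: int = 33) -> bool:
        """Whether the open segment a-b passes through the object interior."""
        t = np.linspace(0.0, 1.0, n_samples)[1:-1]
        pts = np.outer(1 - t, np.asarray(a)) + np.outer(t, np.asarray(b))
        return bool(np.any(self.contains(pts, margin=margin)))

    def displaced(self, delta: np.ndarray) -> "ObjectPrimitive":
        return replace(self, position=tuple(self.center + np.asarray(delta)))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {"shape": self.shape, "size": list(self.size),
                "position": list(self.position),
                "orientation": list(self.orientation)}

    @classmethod
    def from_dict(cls, d: dict) -> "ObjectPrimitive":
        return cls(shape=d["shape"], size=tuple(d["size"]),
                   position=tuple(d["position"]),
                   orientation=tuple(d.get("orientation", (0.0, 0.0, 0.0))))
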