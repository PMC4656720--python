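"""Parietal feature-extraction populations (V6A/MIP and cIPS).

Each population is a 1-, 2- or 3-D grid of units with Gaussian tuning
curves over object features:

* ``DIST`` — shoulder-centered distance, 1-D over [0, 1] m;
* ``DIR``  — shoulder-centered direction, 2-D over azimuth [0, pi] and
  elevation [-pi, 0];
* ``CYL`` / ``RECT`` — main-axis orientation (Euler components), 3-D,
  gated by object shape: cylinders drive only CYL, box-like shapes only
  RECT, and the non-matching population carries pure noise;
* ``SOS`` — outward normals of the visible faces of box-like shapes,
  3-D over [-1, 1] per component;
* ``S``   — size triple, 3-D.

Unit activity sums the Gaussian responses over all presented object
components and adds i.i.d. Gaussian noise, clipped at zero.  The affordance
map input ``I`` concatenates DIR, CYL, RECT, SOS and S (distance is encoded
but deliberately excluded) and is scaled to unit Euclidean norm.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .config import ParietalConfig, PopulationConfig
from .objects import ObjectPrimitive, RECTANGULAR


@dataclass(frozen=True)
class PopulationSpec:
    """Preferred-value grid and tuning parameters of one population."""

    grid_shape: Tuple[int, ...]
    ranges: Tuple[Tuple[float, float], ...]
    sigma: float
    noise_sd: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @classmethod
    def from_config(cls, cfg: PopulationConfig) -> "PopulationSpec":
        return cls(tuple(cfg.grid_shape), tuple(tuple(r) for r in cfg.ranges),
                   cfg.sigma, cfg.noise_sd)

    @property
    def dims(self) -> int:
        return len(self.grid_shape)

    @property
    def n_units(self) -> int:
        return int(np.prod(self.grid_shape))

    def axes(self) -> List[np.ndarray]:
        """Uniformly spaced preferred values per dimension."""
        return [np.linspace(lo, hi, n)
                for (lo, hi), n in zip(self.ranges, self.grid_shape)]

    def preferred_grid(self) -> np.ndarray:
        """Preferred value tuples on the full grid, shape grid_shape + (dims,)."""
        mesh = np.meshgrid(*self.axes(), indexing="ij")
        return np.stack(mesh, axis=-1)

    def grid_spacing(self) -> np.ndarray:
        return np.array([(hi - lo) / (n - 1)
                         for (lo, hi), n in zip(self.ranges, self.grid_shape)])


@dataclass
class PopulationActivity:
    spec: PopulationSpec
    values: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.grid_shape:
            raise ValueError("activity shape does not match the population grid")

    def decode(self, threshold: float = 0.0) -> np.ndarray:
        """Center-of-mass decode of the encoded stimulus value(s)."""
        f = self.values
        mask = f >= threshold if threshold > 0 else np.ones_like(f, bool)
        w = np.where(mask, f, 0.0)
        total = w.sum()
        if total <= 0:
            raise ValueError("no super-threshold activity to decode")
        grid = self.spec.preferred_grid()
        return (w[..., None] * grid).reshape(-1, self.spec.dims).sum(0) / total


def _gaussian_sum(spec: PopulationSpec, stimuli: np.ndarray) -> np.ndarray:
    """Sum of unit-height Gaussians over stimulus rows, on the preferred grid."""
    grid = spec.preferred_grid()           # shape grid + (d,)
    acts = np.zeros(spec.grid_shape)
    for stim in np.atleast_2d(stimuli):
        sq = ((grid - stim) ** 2).sum(axis=-1)
        acts += np.exp(-sq / (2.0 * spec.sigma ** 2))
    return acts


def _noise(spec: PopulationSpec, rng: np.random.Generator | None) -> np.ndarray:
    if rng is None or spec.noise_sd == 0:
        return np.zeros(spec.grid_shape)
    return rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)


def _finish(spec: PopulationSpec, acts: np.ndarray,
            rng: np.random.Generator | None, t: float) -> PopulationActivity:
    values = np.clip(acts + _noise(spec, rng), 0.0, None)
    return PopulationActivity(spec=spec, values=values, timestamp=t)


def encode_distance(objects: Sequence[ObjectPrimitive], spec: PopulationSpec,
                    rng: np.random.Generator | None = None,
                    t: float = 0.0) -> PopulationActivity:
    """DIST: 1-D Gaussian code over shoulder-centered distance per component."""
    if spec.dims != 1:
        raise ValueError("distance population must be 1-D")
    d = np.array([[obj.spherical[2]] for obj in objects])
    return _finish(spec, _gaussian_sum(spec, d) if len(d) else np.zeros(spec.grid_shape),
                   rng, t)


def encode_direction(objects: Sequence[ObjectPrimitive], spec: PopulationSpec,
                     rng: np.random.Generator | None = None,
                     t: float = 0.0) -> PopulationActivity:
    """DIR: 2-D Gaussian code over (azimuth theta_s, elevation phi_s).

    Preferred ranges are bounded intervals; no angular wraparound is applied
    (objects are sampled inside the represented ranges).
    """
    if spec.dims != 2:
        raise ValueError("direction population must be 2-D")
    stims = np.array([[obj.spherical[1], obj.spherical[0]] for obj in objects])
    acts = _gaussian_sum(spec, stims) if len(stims) else np.zeros(spec.grid_shape)
    return _finish(spec, acts, rng, t)


def encode_axis_orientation(objects: Sequence[ObjectPrimitive],
                            cyl_spec: PopulationSpec, rect_spec: PopulationSpec,
                            rng: np.random.Generator | None = None,
                            t: float = 0.0,
                            ) -> Tuple[PopulationActivity, PopulationActivity]:
    """CYL and RECT: shape-gated 3-D codes over the Euler orientation.

    Cylinders drive only CYL; box-like shapes only RECT; spheres neither —
    the non-matching population carries pure noise.
    """
    cyl_stims = [list(o.orientation) for o in objects if o.shape == "cylinder"]
    rect_stims = [list(o.orientation) for o in objects if o.shape in RECTANGULAR]
    cyl_acts = (_gaussian_sum(cyl_spec, np.array(cyl_stims))
                if cyl_stims else np.zeros(cyl_spec.grid_shape))
    rect_acts = (_gaussian_sum(rect_spec, np.array(rect_stims))
                 if rect_stims else np.zeros(rect_spec.grid_shape))
    return (_finish(cyl_spec, cyl_acts, rng, t),
            _finish(rect_spec, rect_acts, rng, t))


def encode_surface_normals(objects: Sequence[ObjectPrimitive],
                           spec: PopulationSpec, cfg: ParietalConfig,
                           rng: np.random.Generator | None = None,
                           t: float = 0.0) -> PopulationActivity:
    """SOS: 3-D code summing over the visible face normals of box-like shapes.

    A face is visible iff its outward normal has negative dot product with
    the view direction (from the origin toward the object, or a fixed
    configured direction).
    """
    stims: List[List[float]] = []
    for obj in objects:
        if obj.shape not in RECTANGULAR:
            continue
        if cfg.view_mode == "fixed":
            view = np.asarray(cfg.view_direction, dtype=float)
        else:
            view = obj.center
        for n in obj.visible_normals(view):
            stims.append(list(n))
    acts = (_gaussian_sum(spec, np.array(stims))
            if stims else np.zeros(spec.grid_shape))
    return _finish(spec, acts, rng, t)


def encode_size(objects: Sequence[ObjectPrimitive], spec: PopulationSpec,
                rng: np.random.Generator | None = None,
                t: float = 0.0) -> PopulationActivity:
    """S: 3-D Gaussian code over the size triple (s_x, s_y, s_z)."""
    stims = np.array([list(o.size) for o in objects])
    acts = _gaussian_sum(spec, stims) if len(stims) else np.zeros(spec.grid_shape)
    return _finish(spec, acts, rng, t)


def build_aip_input(direction: PopulationActivity, cyl: PopulationActivity,
                    rect: PopulationActivity, sos: PopulationActivity,
                    size: PopulationActivity) -> Tuple[np.ndarray, bool]:
    """Concatenate DIR, CYL, RECT, SOS, S and normalize to unit Euclidean norm.

    Distance (DIST) never enters the affordance-map input.  Returns
    ``(I, degenerate)``; an all-zero concatenation is returned as the zero
    vector with the degenerate flag set.
    """
    parts = [p.values.ravel() for p in (direction, cyl, rect, sos, size)]
    vec = np.concatenate(parts)
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite population activity")
    norm = np.linalg.norm(vec)
    if norm == 0.0:
        return vec, True
    return vec / norm, False


class ParietalEncoder:
    """Bundle of all population specs with a one-call trial encoding."""

    def __init__(self, cfg: ParietalConfig):
        self.cfg = cfg
        self.dist = PopulationSpec.from_config(cfg.dist)
        self.direction = PopulationSpec.from_config(cfg.direction)
        self.cyl = PopulationSpec.from_config(cfg.cyl)
        self.rect = PopulationSpec.from_config(cfg.rect)
        self.sos = PopulationSpec.from_config(cfg.sos)
        self.size = PopulationSpec.from_config(cfg.size)

    @property
    def aip_input_dim(self) -> int:
        return (self.direction.n_units + self.cyl.n_units + self.rect.n_units
                + self.sos.n_units + self.size.n_units)

    def encode(self, objects: Sequence[ObjectPrimitive],
               rng: np.random.Generator | None = None, t: float = 0.0) -> dict:
        dist = encode_distance(objects, self.dist, rng, t)
        direction = encode_direction(objects, self.direction, rng, t)
        cyl, rect = encode_axis_orientation(objects, self.cyl, self.rect, rng, t)
        sos = encode_surface_normals(objects, self.sos, self.cfg, rng, t)
        size = encode_size(objects, self.size, rng, t)
        I, degenerate = build_aip_input(direction, cyl, rect, sos, size)
        return {"DIST": dist, "DIR": direction, "CYL": cyl, "RECT": rect,
                "SOS": sos, "S": size, "I": I, "degenerate": degenerate}
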