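"""Reinforcement-modulated self-organizing affordance map.

A toroidal grid (default 40 x 40) of weight vectors over the parietal input
vector I.  Unit activity is the plain dot product W(i,j) . I plus noise.
Competitive learning moves the best-matching unit (BMU, Euclidean metric)
and its toroidal neighborhood toward I:

    W <- W + Theta(beta; r) * alpha * (I - W)
    Theta = exp(-beta^2 / (2 r^2))   for beta < r, else 0
    r(T)     = r0 * exp(-T / lambda) + rs
    alpha(T) = a0 * exp(-T / lambda) + rs

where beta is the toroidal Euclidean index distance to the BMU, T the
training epoch (incremented once per trial) and rs the global reinforcement
signal.  A positive rs transiently widens the neighborhood and raises the
learning rate, so inputs that lead to rewarded grasps recruit more map
units; the rs contribution is floored at zero (a failed grasp does not
invert the update).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .config import SomConfig


@dataclass
class SomState:
    """Weight grid and epoch bookkeeping of the affordance map."""

    weights: np.ndarray          # (grid, grid, input_dim)
    epoch: int = 0
    r0: float = 20.0
    alpha0: float = 0.1
    lam: float = 150.0
    noise_sd: float = 0.01

    def __post_init__(self):
        # float32: the map is memory-bandwidth bound (40 x 40 x ~3000 weights)
        self.weights = np.asarray(self.weights, dtype=np.float32)
        if self.weights.ndim != 3 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("weights must have shape (grid, grid, input_dim)")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    @property
    def grid(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def initialize(cls, input_dim: int, cfg: SomConfig,
                   rng: np.random.Generator) -> "SomState":
        w = rng.uniform(0.0, cfg.weight_init,
                        size=(cfg.grid, cfg.grid, input_dim)).astype(np.float32)
        return cls(weights=w, epoch=0, r0=cfg.r0, alpha0=cfg.alpha0,
                   lam=cfg.lam, noise_sd=cfg.noise_sd)


def aip_activity(state: SomState, I: np.ndarray,
                 rng: np.random.Generator | None = None,
                 noise_sd: float | None = None) -> np.ndarray:
    """Activity grid W . I + noise (linear in I; no clipping)."""
    acts = state.weights @ np.asarray(I, dtype=np.float32)
    sd = state.noise_sd if noise_sd is None else noise_sd
    if rng is not None and sd > 0:
        acts = acts + rng.normal(0.0, sd, size=acts.shape)
    return acts


def find_bmu(state: SomState, I: np.ndarray) -> Tuple[int, int]:
    """Best matching unit: argmin of ||I - W(i,j)||; ties -> lowest flat index."""
    I = np.asarray(I, dtype=np.float32)
    if np.linalg.norm(I) == 0.0:
        raise ValueError("degenerate (zero) input vector: no BMU")
    diff = state.weights - I
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    flat = int(np.argmin(d2))          # argmin returns the lowest flat index on ties
    return flat // state.grid, flat % state.grid


def toroidal_index_distance(grid: int, bmu: Tuple[int, int]) -> np.ndarray:
    """Toroidal Euclidean distance of every unit's index pair to the BMU."""
    idx = np.arange(grid)
    di = np.abs(idx - bmu[0])
    di = np.minimum(di, grid - di)
    dj = np.abs(idx - bmu[1])
    dj = np.minimum(dj, grid - dj)
    return np.sqrt(di[:, None] ** 2 + dj[None, :] ** 2)


def neighborhood(beta: np.ndarray | float, r: float) -> np.ndarray:
    """Truncated Gaussian neighborhood Theta(beta; r) in [0, 1].

    For r = 0 the limit convention applies: 1 at the BMU, 0 elsewhere.
    """
    beta = np.asarray(beta, dtype=float)
    if r < 0:
        raise ValueError("radius must be non-negative")
    if r == 0.0:
        return (beta == 0.0).astype(float)
    theta = np.exp(-(beta ** 2) / (2.0 * r ** 2))
    return np.where(beta < r, theta, 0.0)


def radius(state: SomState, rs: float = 0.0) -> float:
    """Neighborhood radius r(T) = r0 e^(-T/lambda) + max(rs, 0)."""
    return state.r0 * np.exp(-state.epoch / state.lam) + max(rs, 0.0)


def learning_rate(state: SomState, rs: float = 0.0) -> float:
    """Learning rate alpha(T) = alpha0 e^(-T/lambda) + max(rs, 0)."""
    return state.alpha0 * np.exp(-state.epoch / state.lam) + max(rs, 0.0)


def som_update(state: SomState, I: np.ndarray, rs: float = 0.0,
               advance_epoch: bool = True) -> SomState:
    """One competitive-learning step toward I (in place; returns *state*).

    The epoch counter advances once per call (one call per trial).
    """
    I = np.asarray(I, dtype=np.float32)
    bmu = find_bmu(state, I)
    r = radius(state, rs)
    alpha = learning_rate(state, rs)
    beta = toroidal_index_distance(state.grid, bmu)
    gain = (neighborhood(beta, r) * alpha).astype(np.float32)
    rows, cols = np.nonzero(gain)        # only units inside the truncation radius
    if rows.size:
        w = state.weights[rows, cols]
        state.weights[rows, cols] = w + gain[rows, cols, None] * (I - w)
    if advance_epoch:
        state.epoch += 1
    return state
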