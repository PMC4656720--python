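"""Dynamic movement primitives (point-attractor form with phase-gated forcing).

    v' = u K ( sum_i psi_i(u) (c_i + x0) / sum_i psi_i(u) - x )
         + (1 - u) K (g - x) - D v
    x' = v
    u' = -alpha_u u        (canonical phase, u(0) = 1, decaying to 0)

With the default straight-line equilibrium points c_i = g - x0 the forcing
term collapses onto the goal and the DMP reduces to a critically damped
point attractor; non-default c_i shape the transient path.  The same
primitive with scalar x0 = 0, g = 1 serves as the normalized timing signal
of the grasp phases.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class DmpState:
    x: np.ndarray            # controlled value (scalar or vector)
    v: np.ndarray            # velocity
    u: float                 # phase in (0, 1]
    x0: np.ndarray
    g: np.ndarray
    K: float = 100.0
    D: float = 20.0
    alpha_u: float = 3.07
    centers: Optional[np.ndarray] = None     # (n_basis, dim) equilibrium points
    basis_centers: np.ndarray = field(default_factory=lambda: np.linspace(1.0, 0.01, 10))
    basis_width: float = 0.055
    v_cap: Optional[float] = None

    def __post_init__(self):
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.v = np.atleast_1d(np.asarray(self.v, dtype=float))
        self.x0 = np.atleast_1d(np.asarray(self.x0, dtype=float))
        self.g = np.atleast_1d(np.asarray(self.g, dtype=float))
        if self.centers is None:
            # straight-line settings: every equilibrium point at the goal
            self.centers = np.tile(self.g - self.x0, (len(self.basis_centers), 1))
        else:
            self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))

    def psi(self, u: float) -> np.ndarray:
        """Gaussian basis activations over the phase variable."""
        return np.exp(-(u - self.basis_centers) ** 2 / (2.0 * self.basis_width ** 2))


def make_dmp(x0, g, K: float, D: float, alpha_u: float, n_basis: int = 10,
             v_cap: float | None = None) -> DmpState:
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    bc = np.linspace(1.0, 1.0 / (2 * n_basis), n_basis)
    width = 0.5 * (bc[0] - bc[1]) / np.sqrt(2 * np.log(2)) if n_basis > 1 else 0.1
    return DmpState(x=x0.copy(), v=np.zeros_like(x0), u=1.0, x0=x0, g=g,
                    K=K, D=D, alpha_u=alpha_u,
                    basis_centers=bc, basis_width=width, v_cap=v_cap)


def dmp_step(state: DmpState, dt: float) -> DmpState:
    """Advance the DMP by one explicit-Euler step (in place; returns *state*)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    u = state.u
    psi = state.psi(u)
    total = psi.sum()
    if total > 1e-12:
        attractor = (psi @ (state.centers + state.x0)) / total
    else:
        attractor = state.g
    vdot = (u * state.K * (attractor - state.x)
            + (1.0 - u) * state.K * (state.g - state.x)
            - state.D * state.v)
    state.v = state.v + dt * vdot
    if state.v_cap is not None:
        speed = np.linalg.norm(state.v)
        if speed > state.v_cap:
            state.v *= state.v_cap / speed
    state.x = state.x + dt * state.v
    state.u = u * np.exp(-state.alpha_u * dt)
    return state


def retarget(state: DmpState, g) -> None:
    """Move the goal (and straight-line equilibria) to a new target."""
    state.g = np.atleast_1d(np.asarray(g, dtype=float))
    state.centers = np.tile(state.g - state.x0, (len(state.basis_centers), 1))
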