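"""Dynamic neural fields: leaky-integrator grids with winner-take-all kernels.

Membrane dynamics (explicit Euler):

    tau du/dt = -u + h + IN + f * W + eps,     f = 1 / (1 + exp(-beta (u - u0)))

The interaction kernel is a Gaussian center peak on a uniform inhibitory
floor, evaluated on a grid twice the field size so every unit competes with
every other:

    W(i[,j,k]) = w_excite exp(-sum((idx - N/2)^2) / (2 sigma^2)) - w_inhibit

Because the kernel covers the whole field, the recurrent term splits into a
separable Gaussian convolution plus global inhibition proportional to the
total firing; `dnf_step` uses that decomposition (it is exact, see
`tests/test_dnf.py`).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy.ndimage import convolve1d

from .config import DnfConfig


def sigmoid(u: np.ndarray, beta: float, u0: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-beta * (u - u0)))


def dnf_kernel(dims: int, N: int, cfg: DnfConfig) -> np.ndarray:
    """Full interaction kernel on the doubled grid (size 2N per dimension)."""
    if N < 2:
        raise ValueError("field size must be at least 2")
    idx = np.arange(2 * N, dtype=float)
    sq1 = (idx - N / 2.0) ** 2
    if dims == 1:
        sq = sq1
    elif dims == 2:
        sq = sq1[:, None] + sq1[None, :]
    elif dims == 3:
        sq = sq1[:, None, None] + sq1[None, :, None] + sq1[None, None, :]
    else:
        raise ValueError("1-, 2- or 3-D fields only")
    return cfg.w_excite * np.exp(-sq / (2.0 * cfg.sigma ** 2)) - cfg.w_inhibit


@dataclass
class DnfField:
    """One field: preferred-value grid, membrane potentials and firing rates."""

    shape: Tuple[int, ...]
    axes: List[np.ndarray]               # preferred values per dimension
    cfg: DnfConfig
    u: np.ndarray = field(init=False)
    f: np.ndarray = field(init=False)

    def __post_init__(self):
        if len(self.axes) != len(self.shape):
            raise ValueError("axes/shape dimensionality mismatch")
        self.reset()
        # 1-D excitatory profile reused per dimension (separable Gaussian)
        n = max(self.shape)
        offsets = np.arange(-(n - 1), n, dtype=float)
        self._exc1d = np.exp(-offsets ** 2 / (2.0 * self.cfg.sigma ** 2))
        # boundary correction: border units see less of the kernel than
        # interior ones; rescale by full/local kernel mass so every grid
        # location competes on equal footing
        ones = np.ones(self.shape)
        local = ones
        for axis in range(self.dims):
            k = self._kernel_1d(self.shape[axis])
            local = convolve1d(local, k, axis=axis, mode="constant", cval=0.0)
        self._boundary_gain = local.max() / local

    def reset(self) -> None:
        self.u = np.full(self.shape, self.cfg.h, dtype=float)
        self.f = sigmoid(self.u, self.cfg.beta, self.cfg.u0)

    @property
    def dims(self) -> int:
        return len(self.shape)

    def preferred_grid(self) -> np.ndarray:
        mesh = np.meshgrid(*self.axes, indexing="ij")
        return np.stack(mesh, axis=-1)

    def _kernel_1d(self, n: int) -> np.ndarray:
        c = len(self._exc1d) // 2
        return self._exc1d[c - (n - 1): c + n]

    # -- dynamics ---------------------------------------------------------
    def recurrent_input(self, boundary_corrected: bool = True) -> np.ndarray:
        """f * W computed as separable excitation minus global inhibition."""
        exc = self.f
        for axis in range(self.dims):
            exc = convolve1d(exc, self._kernel_1d(self.shape[axis]),
                             axis=axis, mode="constant", cval=0.0)
        if boundary_corrected:
            exc = exc * self._boundary_gain
        return self.cfg.w_excite * exc - self.cfg.w_inhibit * self.f.sum()

    def step(self, IN: np.ndarray, rng: np.random.Generator | None = None,
             dt: float | None = None) -> None:
        """One explicit-Euler update of u, then recompute f."""
        dt = self.cfg.dt if dt is None else dt
        if dt > self.cfg.tau / 2:
            raise ValueError("dt must be <= tau/2")
        eps = (rng.normal(0.0, self.cfg.noise_sd, self.shape)
               if rng is not None and self.cfg.noise_sd > 0 else 0.0)
        du = -self.u + self.cfg.h + IN + self.recurrent_input() + eps
        self.u = self.u + (dt / self.cfg.tau) * du
        if not np.all(np.isfinite(self.u)):
            raise FloatingPointError("non-finite membrane potential")
        self.f = sigmoid(self.u, self.cfg.beta, self.cfg.u0)

    def settle(self, IN: np.ndarray, steps: int,
               rng: np.random.Generator | None = None) -> None:
        for _ in range(steps):
            self.step(IN, rng)

    # -- read-outs --------------------------------------------------------
    def peak(self) -> Tuple[float, Tuple[int, ...]]:
        flat = int(np.argmax(self.f))
        return float(self.f.max()), np.unravel_index(flat, self.shape)

    def decode(self, xi: float) -> np.ndarray | None:
        """Center-of-mass decode over units with f >= xi; None if all below."""
        mask = self.f >= xi
        if not mask.any():
            return None
        w = np.where(mask, self.f, 0.0)
        grid = self.preferred_grid()
        return ((w[..., None] * grid).reshape(-1, self.dims).sum(0)
                / w.sum())


def make_field(axes: List[np.ndarray], cfg: DnfConfig) -> DnfField:
    return DnfField(shape=tuple(len(a) for a in axes), axes=list(axes), cfg=cfg)
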