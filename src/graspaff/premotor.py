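"""Premotor reach/grasp planning network.

Each premotor region holds a preparation-related and an execution-related
dynamic neural field:

* F2  — object center: direction (2-D) and distance (1-D) fields, driven by
  the parietal DIR/DIST codes through fixed 3I relays;
* F7  — object-centered reach offset: direction (2-D) and radius (1-D)
  fields, driven by the affordance map and (direction only) by F2;
* F5  — four 1-D fields over maximum aperture, one per virtual-finger
  combination (precision, tripod, power, side), mutually inhibiting;
* WR  — wrist rotation, one 3-D field over the wrist joint angles, driven
  by the affordance map, the F7 offset direction and the F5 fields.

Preparation fields relay to execution fields through fixed 2I weights;
every execution field receives tonic inhibition GP (10 before the go
signal, 0 after).  All afferents of the preparation fields from the
affordance map (and F2->F7, F7->WR, F5->WR) learn with a reward-modulated
Hebbian rule, using the execution-field firing as the eligibility trace:

    dW = alpha * rs * outer(pre, exec)

which is Hebbian for rs > 0 and anti-Hebbian for rs < 0.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .config import ArmConfig, DnfConfig, PremotorConfig
from .dnf import DnfField, make_field

VF_COMBINATIONS = ("precision", "tripod", "power", "side")


def _linspace(rng: Tuple[float, float], n: int) -> np.ndarray:
    return np.linspace(rng[0], rng[1], n)


@dataclass
class LearnedWeights:
    """All reinforcement-learned connection matrices (flattened field axes)."""

    aip_f7dir: np.ndarray
    aip_f7rad: np.ndarray
    f2_f7: np.ndarray
    aip_f5: Dict[str, np.ndarray]
    aip_wr: np.ndarray
    f7_wr: np.ndarray
    f5_wr: Dict[str, np.ndarray]

    def items(self):
        yield "aip_f7dir", self.aip_f7dir
        yield "aip_f7rad", self.aip_f7rad
        yield "f2_f7", self.f2_f7
        for vf in VF_COMBINATIONS:
            yield f"aip_f5_{vf}", self.aip_f5[vf]
        yield "aip_wr", self.aip_wr
        yield "f7_wr", self.f7_wr
        for vf in VF_COMBINATIONS:
            yield f"f5_wr_{vf}", self.f5_wr[vf]

    def checksums(self) -> Dict[str, float]:
        return {name: float(w.sum()) for name, w in self.items()}


class PremotorNetwork:
    """The full set of premotor fields, fixed relays and learned weights."""

    def __init__(self, cfg: PremotorConfig, dnf_cfg: DnfConfig, arm: ArmConfig,
                 aip_units: int, rng: np.random.Generator):
        self.cfg = cfg
        self.dnf_cfg = dnf_cfg
        self.aip_units = aip_units
        self.go = False

        dir_axes = [
            _linspace((0.0, np.pi), cfg.dir_shape[0]),
            _linspace((-np.pi, 0.0), cfg.dir_shape[1]),
        ]
        off_axes = [
            _linspace(tuple(cfg.offset_dir_ranges[0]), cfg.dir_shape[0]),
            _linspace(tuple(cfg.offset_dir_ranges[1]), cfg.dir_shape[1]),
        ]
        rad_axis = [_linspace(tuple(cfg.rad_range), cfg.rad_size)]
        off_rad_axis = [_linspace(tuple(cfg.offset_rad_range), cfg.rad_size)]
        ap_axis = [_linspace((0.0, 1.0), cfg.aperture_size)]
        wr_axes = [_linspace(tuple(lim), n)
                   for lim, n in zip(arm.wrist_limits, cfg.wr_shape)]

        f = lambda axes: make_field(axes, dnf_cfg)
        self.fields: Dict[str, DnfField] = {
            "F2vrDIR": f(dir_axes), "F2dDIR": f(dir_axes),
            "F2vrRAD": f(rad_axis), "F2dRAD": f(rad_axis),
            "F7sDIR": f(off_axes), "F7eDIR": f(off_axes),
            "F7sRAD": f(off_rad_axis), "F7eRAD": f(off_rad_axis),
            "WRs": f(wr_axes), "WRe": f(wr_axes),
        }
        for vf in VF_COMBINATIONS:
            self.fields[f"F5s_{vf}"] = f(ap_axis)
            self.fields[f"F5e_{vf}"] = f(ap_axis)

        n_dir = int(np.prod(cfg.dir_shape))
        n_wr = int(np.prod(cfg.wr_shape))
        w0 = cfg.learned_init
        u = lambda *shape: rng.uniform(0.0, w0, size=shape)
        self.learned = LearnedWeights(
            aip_f7dir=u(aip_units, n_dir),
            aip_f7rad=u(aip_units, cfg.rad_size),
            f2_f7=u(n_dir, n_dir),
            aip_f5={vf: u(aip_units, cfg.aperture_size) for vf in VF_COMBINATIONS},
            aip_wr=u(aip_units, n_wr),
            f7_wr=u(n_dir, n_wr),
            f5_wr={vf: u(cfg.aperture_size, n_wr) for vf in VF_COMBINATIONS},
        )
        # fixed relays, never modified by learning
        self.W_input = cfg.fixed_gain_input   # parietal -> F2 (3I)
        self.W_relay = cfg.fixed_gain_relay   # preparation -> execution (2I)
        self._cached_aip: np.ndarray | None = None
        self._aip_proj: Dict[str, np.ndarray] = {}

    # -- go signal --------------------------------------------------------
    def set_go_signal(self, go: bool) -> None:
        self.go = bool(go)

    @property
    def gp(self) -> float:
        """Tonic inhibition applied to every execution field's input."""
        return 0.0 if self.go else self.cfg.gp_level

    # -- input computation ------------------------------------------------
    def compute_inputs(self, aip: np.ndarray, parietal: dict,
                       ) -> Dict[str, np.ndarray]:
        """Per-field weighted input grids from the current firing rates.

        *aip* is the flattened affordance-map activity; *parietal* must
        contain the DIR and DIST activity grids.  Recurrent terms inside
        each field are handled by the field itself; this assembles the
        between-field feedforward sums.
        """
        cfg = self.cfg
        F = self.fields
        gp = self.gp
        proj = self._aip_projections(aip)
        IN: Dict[str, np.ndarray] = {}
        IN["F2vrDIR"] = self.W_input * parietal["DIR"]
        IN["F2vrRAD"] = self.W_input * parietal["DIST"]
        IN["F2dDIR"] = self.W_relay * F["F2vrDIR"].f - gp
        IN["F2dRAD"] = self.W_relay * F["F2vrRAD"].f - gp

        dir_shape = F["F7sDIR"].shape
        IN["F7sDIR"] = (proj["f7dir"]
                        + (F["F2vrDIR"].f.ravel() @ self.learned.f2_f7
                           ).reshape(dir_shape))
        IN["F7sRAD"] = proj["f7rad"]
        IN["F7eDIR"] = self.W_relay * F["F7sDIR"].f - gp
        IN["F7eRAD"] = self.W_relay * F["F7sRAD"].f - gp

        f5_sums = {vf: float(F[f"F5s_{vf}"].f.sum()) for vf in VF_COMBINATIONS}
        for vf in VF_COMBINATIONS:
            others = sum(s for v, s in f5_sums.items() if v != vf)
            IN[f"F5s_{vf}"] = (proj[f"f5_{vf}"]
                               - cfg.f5_cross_inhibition * others)
            IN[f"F5e_{vf}"] = self.W_relay * F[f"F5s_{vf}"].f - gp

        wr_shape = F["WRs"].shape
        wr_in = proj["wr"] + F["F7sDIR"].f.ravel() @ self.learned.f7_wr
        for vf in VF_COMBINATIONS:
            wr_in = wr_in + F[f"F5s_{vf}"].f @ self.learned.f5_wr[vf]
        IN["WRs"] = wr_in.reshape(wr_shape)
        IN["WRe"] = self.W_relay * F["WRs"].f - gp
        return IN

    def _aip_projections(self, aip: np.ndarray) -> Dict[str, np.ndarray]:
        """AIP-driven input terms, cached per activity vector (static within
        a trial's settling loop).

        The affordance drive is divisively normalized (L1) before the gain:
        premotor input scale then stays constant while the affordance map
        sparsifies over training, so field ignition does not depend on the
        map's training epoch.
        """
        if self._cached_aip is aip and self._aip_proj:
            return self._aip_proj
        a = np.asarray(aip, dtype=float).ravel()
        total = np.abs(a).sum()
        a = a * (self.cfg.aip_gain / total) if total > 0 else a
        L = self.learned
        proj = {
            "f7dir": (a @ L.aip_f7dir).reshape(self.fields["F7sDIR"].shape),
            "f7rad": a @ L.aip_f7rad,
            "wr": a @ L.aip_wr,
        }
        for vf in VF_COMBINATIONS:
            proj[f"f5_{vf}"] = a @ L.aip_f5[vf]
        self._cached_aip = aip
        self._aip_proj = proj
        return proj

    def invalidate_cache(self) -> None:
        self._cached_aip = None
        self._aip_proj = {}

    def step(self, aip: np.ndarray, parietal: dict,
             rng: np.random.Generator | None = None,
             subset: Tuple[str, ...] | None = None) -> None:
        """Advance fields by one Euler step with freshly assembled inputs."""
        IN = self.compute_inputs(aip, parietal)
        for name, fld in self.fields.items():
            if subset is None or name in subset:
                fld.step(IN[name], rng)

    #: the network is feedforward between fields, so before the go signal
    #: only preparation fields evolve, and after it only execution fields do
    PREP_FIELDS = ("F2vrDIR", "F2vrRAD", "F7sDIR", "F7sRAD", "WRs",
                   "F5s_precision", "F5s_tripod", "F5s_power", "F5s_side")
    EXEC_FIELDS = ("F2dDIR", "F2dRAD", "F7eDIR", "F7eRAD", "WRe",
                   "F5e_precision", "F5e_tripod", "F5e_power", "F5e_side")

    def settle(self, aip: np.ndarray, parietal: dict, steps: int,
               rng: np.random.Generator | None = None,
               subset: Tuple[str, ...] | None = None) -> None:
        for _ in range(steps):
            self.step(aip, parietal, rng, subset)

    def reset(self) -> None:
        for fld in self.fields.values():
            fld.reset()
        self.go = False
        self.invalidate_cache()

    # -- learning ---------------------------------------------------------
    def reinforce(self, aip: np.ndarray, rs: float, n_steps: int = 1) -> None:
        """Reward-modulated Hebbian update of every learned matrix.

        Applied once per reward step (*n_steps* collapses identical steps).
        Weights are floored at zero after anti-Hebbian updates.
        """
        if rs == 0.0:
            return
        cfg = self.cfg
        F = self.fields
        aip = np.asarray(aip, dtype=float).ravel()
        scale = rs * n_steps

        def upd(W: np.ndarray, alpha: float, pre: np.ndarray, post: np.ndarray):
            W += alpha * scale * np.outer(pre, post.ravel())
            np.clip(W, 0.0, cfg.learned_max, out=W)

        L = self.learned
        upd(L.aip_f7dir, cfg.alpha_f7, aip, F["F7eDIR"].f)
        upd(L.aip_f7rad, cfg.alpha_f7, aip, F["F7eRAD"].f)
        upd(L.f2_f7, cfg.alpha_f7, F["F2dDIR"].f.ravel(), F["F7eDIR"].f)
        for vf in VF_COMBINATIONS:
            upd(L.aip_f5[vf], cfg.alpha_f5, aip, F[f"F5e_{vf}"].f)
        upd(L.aip_wr, cfg.alpha_wr, aip, F["WRe"].f)
        upd(L.f7_wr, cfg.alpha_wr, F["F7eDIR"].f.ravel(), F["WRe"].f)
        for vf in VF_COMBINATIONS:
            upd(L.f5_wr[vf], cfg.alpha_wr, F[f"F5e_{vf}"].f.ravel(), F["WRe"].f)

    def reinforce_wrist_only(self, rs: float, n_steps: int = 1) -> None:
        """Wrist-pretraining scope: only the F7 -> wrist-rotation weights learn."""
        if rs == 0.0:
            return
        W = self.learned.f7_wr
        W += (self.cfg.alpha_wr * rs * n_steps
              * np.outer(self.fields["F7eDIR"].f.ravel(),
                         self.fields["WRe"].f.ravel()))
        np.clip(W, 0.0, self.cfg.learned_max, out=W)
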