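"""Model configuration: every free parameter of the simulator in one place.

The configuration round-trips losslessly through YAML, rejects unknown keys,
and validates ranges on load.  All angles are radians, lengths are meters,
the coordinate frame is right-handed with the shoulder at the origin.
"""
from __future__ import annotations

from pathlib import Path
from typing import Literal, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Cfg(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ArmConfig(_Cfg):
    """Geometry, joint limits and PD gains of the 22-DOF arm/hand.

    Limb proportions are scaled from published macaque data for a ~7.5 kg
    animal; upper-arm and forearm lengths default to 0.17 m each.
    """

    l1: float = Field(0.17, gt=0, description="upper arm length (m)")
    l2: float = Field(0.17, gt=0, description="forearm length (m)")
    # joint limits, radians: shoulder x/y/z, elbow, wrist x/y/z
    shoulder_limits: Tuple[Tuple[float, float], ...] = (
        (-1.6, 1.6), (-1.6, 1.6), (-1.6, 1.6))
    elbow_limits: Tuple[float, float] = (-1.2, 1.45)
    wrist_limits: Tuple[Tuple[float, float], ...] = (
        (-1.0, 1.0), (-1.0, 1.0), (-1.5, 1.5))
    finger_limits: Tuple[float, float] = (-0.35, 1.9)
    p_arm: float = Field(400.0, gt=0, description="PD gain, arm joints")
    d_arm: float = Field(40.0, ge=0, description="PD damping, arm joints")
    p_finger: float = Field(900.0, gt=0)
    d_finger: float = Field(60.0, ge=0)
    ik_step_cap: float = Field(0.02, gt=0, description="per-step IK displacement cap (m)")
    ik_condition_cap: float = Field(1e6, gt=0, description="singularity threshold on cond(JJ^T)")


class HandConfig(_Cfg):
    """Hand segment geometry (meters, hand-local frame; +z distal, +y palmar)."""

    palm_center_offset: float = 0.040     # wrist -> palm patch along +z
    palm_width: float = 0.055
    finger_base_z: float = 0.070          # wrist -> finger MCP row
    finger_base_x: Tuple[float, ...] = (-0.0255, -0.0085, 0.0085, 0.0255)
    finger_segments: Tuple[float, ...] = (0.030, 0.020, 0.015)
    thumb_base: Tuple[float, float, float] = (-0.033, 0.004, 0.030)
    thumb_segments: Tuple[float, float] = (0.028, 0.022)
    pad_offset: float = 0.004             # fingertip pad sits palmar of the tip


class ContactConfig(_Cfg):
    tolerance: float = Field(0.005, gt=0, description="surface distance for contact (m)")
    approach_speed_floor: float = Field(-0.05,
                                        description="min landmark speed toward surface (m/s)")
    hold_duration: float = Field(2.0, gt=0, description="opposition persistence for stability (s)")
    # collision-perturbation surrogate
    perturb_penetration: float = Field(0.004, gt=0)
    perturb_speed: float = Field(0.10, ge=0)
    perturb_gain: float = Field(5.0, ge=0)
    perturb_cap: float = Field(0.02, gt=0, description="max displacement per step (m)")


class PopulationConfig(_Cfg):
    """One Gaussian population code: grid shape, value ranges, width, noise."""

    grid_shape: Tuple[int, ...]
    ranges: Tuple[Tuple[float, float], ...]
    sigma: float = Field(..., gt=0)
    noise_sd: float = Field(0.01, ge=0)

    @model_validator(mode="after")
    def _dims_match(self):
        if len(self.grid_shape) != len(self.ranges):
            raise ValueError("grid_shape and ranges must have equal length")
        return self


class ParietalConfig(_Cfg):
    """V6A/MIP and cIPS population codes feeding the affordance map."""

    dist: PopulationConfig = PopulationConfig(
        grid_shape=(31,), ranges=((0.0, 1.0),), sigma=0.05)
    direction: PopulationConfig = PopulationConfig(
        grid_shape=(21, 21),
        ranges=((0.0, 3.141592653589793), (-3.141592653589793, 0.0)),
        sigma=0.10)
    cyl: PopulationConfig = PopulationConfig(
        grid_shape=(9, 9, 9),
        ranges=((-1.5707963267948966, 1.5707963267948966),) * 3, sigma=0.25)
    rect: PopulationConfig = PopulationConfig(
        grid_shape=(9, 9, 9),
        ranges=((-1.5707963267948966, 1.5707963267948966),) * 3, sigma=0.25)
    sos: PopulationConfig = PopulationConfig(
        grid_shape=(9, 9, 9), ranges=((-1.0, 1.0),) * 3, sigma=0.12)
    size: PopulationConfig = PopulationConfig(
        grid_shape=(11, 11, 11), ranges=((0.0, 0.18),) * 3, sigma=0.016)
    view_mode: Literal["from_origin", "fixed"] = "from_origin"
    view_direction: Tuple[float, float, float] = (0.0, 0.0, -1.0)


class SomConfig(_Cfg):
    """Reinforcement-modulated self-organizing affordance map (toroidal grid)."""

    grid: int = Field(40, ge=2)
    r0: float = Field(28.0, gt=0, description="initial neighborhood radius (grid units)")
    alpha0: float = Field(0.6, gt=0, description="initial learning rate")
    lam: float = Field(350.0, gt=0, description="decay constant (trials)")
    weight_init: float = Field(0.01, gt=0, description="weights ~ U(0, weight_init)")
    noise_sd: float = Field(0.01, ge=0, description="activity noise sd")


class DnfConfig(_Cfg):
    """Shared dynamic-neural-field parameters (all fields use the same set)."""

    tau: float = Field(0.010, gt=0, description="membrane time constant (s)")
    h: float = -1.0
    beta: float = Field(4.0, gt=0, description="sigmoid slope")
    u0: float = 0.5
    w_excite: float = Field(1.2, gt=0)
    w_inhibit: float = Field(0.5, ge=0)
    sigma: float = Field(2.0, gt=0, description="kernel width (grid cells)")
    noise_sd: float = Field(0.05, ge=0)
    dt: float = Field(0.001, gt=0, description="integration step (s)")
    settle_steps: int = Field(120, ge=1)
    decode_steps: int = Field(50, ge=1, description="settling window after go (steps)")

    @model_validator(mode="after")
    def _stable(self):
        if self.dt > self.tau / 2:
            raise ValueError("dt must be <= tau/2 for stable Euler integration")
        return self


class PremotorConfig(_Cfg):
    """Grid sizes, fixed gains and learned-weight settings of the premotor fields."""

    dir_shape: Tuple[int, int] = (21, 21)
    rad_size: int = 31
    rad_range: Tuple[float, float] = (0.0, 1.0)
    offset_dir_ranges: Tuple[Tuple[float, float], ...] = (
        (0.0, 3.141592653589793), (-3.141592653589793, 3.141592653589793))
    offset_rad_range: Tuple[float, float] = (0.0, 0.10)
    aperture_size: int = 11
    wr_shape: Tuple[int, int, int] = (9, 9, 9)
    fixed_gain_input: float = Field(3.0, description="parietal->F2 relay weight (3I)")
    fixed_gain_relay: float = Field(2.0, description="preparation->execution weight (2I)")
    f5_cross_inhibition: float = Field(0.25, ge=0)
    gp_level: float = Field(10.0, ge=0, description="tonic inhibition before the go signal")
    learned_init: float = Field(0.05, gt=0, description="learned weights ~ U(0, learned_init)")
    learned_max: float = Field(0.3, gt=0, description="cap on learned weight entries")
    aip_gain: float = Field(72.0, gt=0,
                            description="scale on AIP drive to premotor fields")
    alpha_f7: float = Field(0.05, gt=0)
    alpha_f5: float = Field(0.05, gt=0)
    alpha_wr: float = Field(0.05, gt=0)
    xi: float = Field(0.01, gt=0, description="decode threshold on firing rates")


class MotorConfig(_Cfg):
    """Reach/grasp controller parameters (DMPs, triggers, postures)."""

    dmp_K: float = Field(100.0, gt=0)
    dmp_D: float = Field(20.0, gt=0)
    dmp_alpha_u: float = Field(3.07, gt=0, description="canonical phase decay (1/s)")
    n_basis: int = Field(10, ge=1)
    kappa: float = Field(0.06, gt=0, description="enclose trigger distance (m)")
    reach_speed_cap: float = Field(0.8, gt=0, description="DMP velocity cap (m/s)")
    preshape_duration: float = Field(0.7, gt=0)
    enclose_duration: float = Field(0.5, gt=0)
    retarget_tolerance: float = Field(0.01, gt=0)
    workspace_fraction: float = Field(0.9, gt=0, le=1.0)


class RewardConfig(_Cfg):
    da_success: float = Field(1.0, gt=0)
    da_fail: float = Field(-0.05, lt=0)
    reward_steps: int = Field(5, ge=1, description="reward window, last N control steps")


class TrainingConfig(_Cfg):
    """Trial protocol and staged curriculum lengths."""

    duration: float = Field(5.0, gt=0, description="trial length (s)")
    dt: float = Field(0.001, gt=0, description="control time step (s)")
    object_onset: float = Field(0.5, ge=0)
    go_time: float = Field(1.0, gt=0)
    object_refresh: int = Field(6, ge=1, description="trials per object pose")
    n_aip_trials: int = Field(1000, ge=0)
    n_wrist_trials: int = Field(2000, ge=0)
    n_grasp_trials: int = Field(10000, ge=0)
    wrist_stop_rate: float = Field(0.6, ge=0, le=1,
                                   description="early-stop palm-contact rate")
    wrist_stop_window: int = Field(200, ge=1)
    # object sampling
    shapes: Tuple[str, ...] = ("cube", "rectangular_prism", "cylinder", "sphere", "plate")
    rho_range: Tuple[float, float] = (0.15, 0.28)
    theta_range: Tuple[float, float] = (1.1, 2.0)
    phi_range: Tuple[float, float] = (-2.4, -0.8)
    orient_range: Tuple[float, float] = (-1.2, 1.2)
    # novel-object probe: disjoint pose/size ranges, same shapes
    novel_rho_range: Tuple[float, float] = (0.29, 0.305)
    novel_size_scale: float = Field(1.35, gt=0,
                                    description="size multiplier for novel probes")
    novel_fraction: float = Field(0.5, ge=0, le=1,
                                  description="probe onset as fraction of grasp stage")


class ModelConfig(_Cfg):
    """Top-level configuration aggregating every module's parameters."""

    seed: int = 0
    scale: int = Field(1, ge=1,
                       description="divides stage lengths and multiplies control dt")
    arm: ArmConfig = ArmConfig()
    hand: HandConfig = HandConfig()
    contact: ContactConfig = ContactConfig()
    parietal: ParietalConfig = ParietalConfig()
    som: SomConfig = SomConfig()
    dnf: DnfConfig = DnfConfig()
    premotor: PremotorConfig = PremotorConfig()
    motor: MotorConfig = MotorConfig()
    reward: RewardConfig = RewardConfig()
    training: TrainingConfig = TrainingConfig()

    # -- scaled views -----------------------------------------------------
    def scaled_trials(self, n: int) -> int:
        return max(1, n // self.scale)

    @property
    def control_dt(self) -> float:
        """Control step after applying the global scale factor."""
        return self.training.dt * self.scale

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return self.model_dump(mode="json")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ModelConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.model_validate(data)


def load_config(path: str | Path | None = None, **overrides) -> ModelConfig:
    """Load a YAML config (defaults when *path* is None) with keyword overrides."""
    cfg = ModelConfig.load(path) if path is not None else ModelConfig()
    if overrides:
        data = cfg.to_dict()
        data.update(overrides)
        cfg = ModelConfig.model_validate(data)
    return cfg
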