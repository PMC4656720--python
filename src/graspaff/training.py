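"""Trial protocol, staged curriculum and the full closed-loop model.

A trial runs for 5 s at a 1 ms base control step (multiplied by the global
scale factor).  The object appears at 0.5 s and is encoded by the parietal
populations; the premotor preparation fields settle on that input.  At 1 s
the go signal releases the tonic inhibition of the execution fields, the
grasp plan is decoded after a short settling window, and the motor
controllers execute the reach and grasp until the trial ends.  In the last
five control steps the reinforcement signal rs is applied:

* AIP pretraining   — no movements, rs = 0, only the affordance map learns;
* wrist pretraining — rs = DA_success / 4 if palm contact was achieved at
  all; only the F7 -> wrist-rotation weights learn;
* grasp training    — rs = DA_success for a stable grasp, DA_fail
  otherwise; the affordance map and all learned premotor weights update.

Objects are resampled every 6 trials.  From the configured point of the
grasp stage onward, probe trials draw objects with the same shapes but
pose/size ranges disjoint from the training ranges (novel-object probe).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .config import ModelConfig
from .contacts import (detect_contacts, has_opposition,
                       perturb_object_on_collision)
from .kinematics import (ArmHandState, hand_landmarks, joint_limit_bounds,
                         wrist_position)
from .motor import (GraspPhaseController, GraspPlan, ReachController,
                    compose_reach_target, select_vf)
from .objects import ObjectPrimitive, cartesian_from_spherical
from .populations import ParietalEncoder
from .premotor import PremotorNetwork, VF_COMBINATIONS
from .rng import RngStreams
from .som import SomState, aip_activity, som_update

STAGES = ("aip", "wrist", "grasp")

#: canonical training sizes per shape: the training set is a fixed set of
#: objects presented at random orientations and locations; sizes change
#: only in the novel-object probe
CANONICAL_SIZES: Dict[str, Tuple[float, float, float]] = {
    "cube": (0.03, 0.03, 0.03),
    "rectangular_prism": (0.025, 0.025, 0.10),
    "cylinder": (0.045, 0.045, 0.16),              # (diameter, diameter, length)
    "sphere": (0.06, 0.06, 0.06),
    "plate": (0.12, 0.12, 0.008),
}


def sample_object(rng: np.random.Generator, cfg: ModelConfig,
                  novel: bool = False) -> ObjectPrimitive:
    """Sample a training (or novel-probe) object.

    Training objects use the canonical per-shape sizes with uniformly random
    position and orientation.  Novel probes keep the shapes but scale each
    size dimension by a uniform factor in [0.70, 0.95] (sizes outside the
    training set by construction) and draw distances beyond the training
    range.
    """
    tr = cfg.training
    if not tr.shapes:
        raise ValueError("empty shape set")
    shape = tr.shapes[rng.integers(len(tr.shapes))]

    base = np.array(CANONICAL_SIZES[shape])
    if novel:
        size = tuple(base * rng.uniform(0.70, 0.95))
    else:
        size = tuple(base)

    rho_rng = tr.novel_rho_range if novel else tr.rho_range
    rho = float(rng.uniform(*rho_rng))
    theta = float(rng.uniform(*tr.theta_range))
    phi = float(rng.uniform(*tr.phi_range))
    pos = cartesian_from_spherical(phi, theta, rho)
    orient = tuple(rng.uniform(*tr.orient_range, size=3))
    return ObjectPrimitive(shape=shape, size=size, position=tuple(pos),
                           orientation=orient)


@dataclass
class TrialRecord:
    """Per-trial log entry (compact aggregates, not per-step traces)."""

    trial: int
    stage: str
    object: dict
    novel: bool
    aip: np.ndarray                       # flattened activity at decode time
    plan: Optional[GraspPlan]
    palm_contact: bool
    success: bool
    rs: float
    rs_sum: float
    decoded: bool


class ProtocolError(RuntimeError):
    """Stages executed out of order."""


class GraspModel:
    """The complete simulator: parietal codes, affordance map, premotor
    fields, motor controllers and the kinematic environment."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.rng = RngStreams(self.config.seed)
        self.encoder = ParietalEncoder(self.config.parietal)
        self.som = SomState.initialize(self.encoder.aip_input_dim,
                                       self.config.som, self.rng.som_init)
        # the decay constant is denominated in trials: desk-scale runs
        # shrink stage lengths, so the annealing shrinks with them
        self.som.lam = self.config.som.lam / self.config.scale
        self.premotor = PremotorNetwork(self.config.premotor, self.config.dnf,
                                        self.config.arm,
                                        self.som.grid * self.som.grid,
                                        self.rng.premotor_init)
        self.log: List[TrialRecord] = []
        self.stages_done: List[str] = []
        self.trial_count = 0

    # -- plumbing ---------------------------------------------------------
    @property
    def workspace_radius(self) -> float:
        arm = self.config.arm
        return self.config.motor.workspace_fraction * (arm.l1 + arm.l2)

    def _rest_state(self) -> ArmHandState:
        arm = self.config.arm
        return ArmHandState(l1=arm.l1, l2=arm.l2)

    def _decode_plan(self) -> Optional[GraspPlan]:
        xi = self.config.premotor.xi
        F = self.premotor.fields
        center_dir = F["F2dDIR"].decode(xi)
        center_rad = F["F2dRAD"].decode(xi)
        off_dir = F["F7eDIR"].decode(xi)
        off_rad = F["F7eRAD"].decode(xi)
        wrist = F["WRe"].decode(xi)
        vf = select_vf({v: F[f"F5e_{v}"] for v in VF_COMBINATIONS}, xi)
        if any(v is None for v in (center_dir, center_rad, off_dir, off_rad,
                                   wrist, vf)):
            return None
        return GraspPlan(
            object_center=(float(center_dir[1]), float(center_dir[0]),
                           float(center_rad[0])),
            reach_offset=(float(off_dir[1]), float(off_dir[0]),
                          float(off_rad[0])),
            wrist_orientation=tuple(float(a) for a in wrist),
            vf_combination=vf[0], max_aperture=vf[1])

    # -- movement ---------------------------------------------------------
    def _run_movement(self, plan: GraspPlan, obj: ObjectPrimitive,
                      ) -> Tuple[bool, bool, ObjectPrimitive]:
        """Execute the reach/grasp; returns (stable, palm_contact, object)."""
        cfg = self.config
        dt = cfg.control_dt
        arm_cfg = cfg.arm
        tr = cfg.training

        state = self._rest_state()
        lo, hi = joint_limit_bounds(arm_cfg)
        angles = state.angles.copy()
        vel = np.zeros(22)

        target, _ = compose_reach_target(plan.object_center, plan.reach_offset,
                                         self.workspace_radius)
        reach = ReachController.create(
            wrist_position(angles[:4], arm_cfg.l1, arm_cfg.l2), target,
            cartesian_from_spherical(*plan.object_center), cfg.motor)
        grasp = GraspPhaseController.create(plan, cfg.motor)
        wrist_target = np.clip(np.asarray(plan.wrist_orientation),
                               lo[4:7], hi[4:7])

        n_steps = int(round((tr.duration - tr.go_time) / dt))
        gains_p = np.concatenate([np.full(7, arm_cfg.p_arm),
                                  np.full(15, arm_cfg.p_finger)])
        gains_d = np.concatenate([np.full(7, arm_cfg.d_arm),
                                  np.full(15, arm_cfg.d_finger)])

        prev_lm: Dict[str, np.ndarray] | None = None
        palm_contact_ever = False
        stop_reach = False
        opposition_history: List[bool] = []

        for _ in range(n_steps):
            state = ArmHandState.from_angles(angles, arm_cfg.l1, arm_cfg.l2,
                                             velocities=vel)
            lm = hand_landmarks(state, cfg.hand)
            lm_vel = ({k: (lm[k] - prev_lm[k]) / dt for k in lm}
                      if prev_lm is not None else None)
            contacts = detect_contacts(lm, obj, cfg.contact, velocities=lm_vel)
            palm_now = any(c.part_class == "palm" for c in contacts)
            thumb_now = any(c.part_class == "thumb" for c in contacts)
            palm_contact_ever = palm_contact_ever or palm_now
            if palm_now or thumb_now:
                stop_reach = True
            if len(contacts) >= 2:
                opposition_history.append(has_opposition(contacts, obj))
            else:
                opposition_history.append(False)
            if contacts and lm_vel is not None:
                obj = perturb_object_on_collision(obj, lm, lm_vel, contacts,
                                                  cfg.contact)

            arm_targets, _ = reach.step(state, arm_cfg, dt, stop_reach)
            wrist_obj_dist = float(np.linalg.norm(
                wrist_position(angles[:4], arm_cfg.l1, arm_cfg.l2) - obj.center))
            digit_contacts = sorted({_digit_of(c.body_part) for c in contacts}
                                    - {None})
            finger_targets = grasp.step(angles[7:], wrist_obj_dist, palm_now,
                                        digit_contacts, dt)
            targets = np.concatenate([arm_targets, wrist_target, finger_targets])
            targets = np.clip(targets, lo, hi)
            tau = gains_p * (targets - angles) - gains_d * vel
            vel = vel + dt * tau
            angles = np.clip(angles + dt * vel, lo, hi)
            prev_lm = lm

        stable = _longest_run(opposition_history) * dt >= cfg.contact.hold_duration
        return stable, palm_contact_ever, obj

    # -- the trial --------------------------------------------------------
    def run_trial(self, obj: ObjectPrimitive, stage: str,
                  novel: bool = False) -> TrialRecord:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        cfg = self.config
        enc = self.encoder.encode([obj], self.rng.parietal_noise)
        aip = aip_activity(self.som, enc["I"], self.rng.som_noise)
        aip_flat = aip.ravel()

        rs = 0.0
        plan = None
        palm = False
        success = False
        decoded = False

        if stage != "aip" and not enc["degenerate"]:
            net = self.premotor
            net.reset()
            net.set_go_signal(False)
            parietal = {"DIR": enc["DIR"].values, "DIST": enc["DIST"].values}
            net.settle(aip_flat, parietal, cfg.dnf.settle_steps,
                       self.rng.premotor_noise, subset=net.PREP_FIELDS)
            net.set_go_signal(True)
            net.settle(aip_flat, parietal, cfg.dnf.decode_steps,
                       self.rng.premotor_noise, subset=net.EXEC_FIELDS)
            plan = self._decode_plan()
            decoded = plan is not None
            if decoded:
                stable, palm, _ = self._run_movement(plan, obj)
                success = stable

            if stage == "wrist":
                rs = cfg.reward.da_success / 4.0 if palm else 0.0
                self.premotor.reinforce_wrist_only(rs, cfg.reward.reward_steps)
            else:  # grasp
                rs = cfg.reward.da_success if success else cfg.reward.da_fail
                self.premotor.reinforce(aip_flat, rs, cfg.reward.reward_steps)

        if stage in ("aip", "grasp") and not enc["degenerate"]:
            som_update(self.som, enc["I"], rs=rs)
        else:
            self.som.epoch += 1

        rec = TrialRecord(trial=self.trial_count, stage=stage,
                          object=obj.to_dict(), novel=novel,
                          aip=aip_flat.astype(np.float32), plan=plan,
                          palm_contact=palm, success=success, rs=rs,
                          rs_sum=rs * cfg.reward.reward_steps, decoded=decoded)
        self.log.append(rec)
        self.trial_count += 1
        return rec

    # -- stages -----------------------------------------------------------
    def _check_order(self, stage: str) -> None:
        order = {"aip": [], "wrist": ["aip"], "grasp": ["aip", "wrist"]}
        for prereq in order[stage]:
            if prereq not in self.stages_done:
                raise ProtocolError(f"stage {stage!r} requires {prereq!r} first")

    def run_stage(self, stage: str, n_trials: int,
                  probe_onset: Optional[int] = None) -> List[TrialRecord]:
        """Run one curriculum stage with the 6-trial object refresh.

        For the grasp stage, *probe_onset* (trial index within the stage)
        switches object sampling to the novel probe ranges.
        """
        self._check_order(stage)
        records: List[TrialRecord] = []
        obj: ObjectPrimitive | None = None
        novel = False
        tr = self.config.training
        palm_window: List[bool] = []
        for k in range(n_trials):
            if k % tr.object_refresh == 0 or obj is None:
                novel = (stage == "grasp" and probe_onset is not None
                         and k >= probe_onset)
                obj = sample_object(self.rng.objects, self.config, novel=novel)
            records.append(self.run_trial(obj, stage, novel=novel))
            if stage == "wrist":
                palm_window.append(records[-1].palm_contact)
                window = max(50, tr.wrist_stop_window // self.config.scale)
                if (len(palm_window) >= window
                        and np.mean(palm_window[-window:]) > tr.wrist_stop_rate):
                    break
        if stage not in self.stages_done:
            self.stages_done.append(stage)
        return records

    def pretrain_aip(self, n_trials: Optional[int] = None) -> List[TrialRecord]:
        n = self.config.scaled_trials(self.config.training.n_aip_trials) \
            if n_trials is None else n_trials
        return self.run_stage("aip", n)

    def pretrain_wrist(self, n_trials: Optional[int] = None) -> List[TrialRecord]:
        n = self.config.scaled_trials(self.config.training.n_wrist_trials) \
            if n_trials is None else n_trials
        return self.run_stage("wrist", n)

    def train_grasp(self, n_trials: Optional[int] = None,
                    probe: bool = True) -> List[TrialRecord]:
        n = self.config.scaled_trials(self.config.training.n_grasp_trials) \
            if n_trials is None else n_trials
        onset = int(self.config.training.novel_fraction * n) if probe else None
        return self.run_stage("grasp", n, probe_onset=onset)


def _digit_of(body_part: str) -> Optional[str]:
    if body_part.startswith("thumb"):
        return "thumb"
    for prefix in ("finger_pad_", "inner_finger_", "finger_side_"):
        if body_part.startswith(prefix):
            return ("index", "middle", "ring", "pinky")[int(body_part[-1])]
    return None


def _longest_run(flags: List[bool]) -> int:
    best = run = 0
    for fl in flags:
        run = run + 1 if fl else 0
        best = max(best, run)
    return best
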