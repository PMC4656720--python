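"""Decoding, grasp planning and the reach/grasp controllers."""
import numpy as np
import pytest

from graspaff.config import ModelConfig
from graspaff.dnf import make_field
from graspaff.motor import (DEFAULT_POSTURES, GraspPhaseController, GraspPlan,
                            compose_reach_target, decode_center_of_mass,
                            select_vf, vf_to_fingers)
from graspaff.objects import ObjectPrimitive, cartesian_from_spherical
from graspaff.training import GraspModel

#: a frozen plan/object pair known to produce a stable precision pinch
#: (movement execution is deterministic given plan and object)
GOLDEN_PLAN = GraspPlan(
    object_center=(-1.8, 1.45, 0.22),
    reach_offset=(0.811952503519767, 1.6151482216379063, 0.03974987483148034),
    wrist_orientation=(-0.5049701559453383, -0.9764119489149883,
                       -0.9227935680440681),
    vf_combination="precision",
    max_aperture=0.7844224846172874)

GOLDEN_OBJECT = ObjectPrimitive(
    "cube", (0.03, 0.03, 0.03),
    tuple(cartesian_from_spherical(-1.8, 1.45, 0.22)))


class TestDecoding:
    def test_single_super_threshold_unit_decodes_its_preferred_value(self):
        f = np.zeros(9)
        f[3] = 0.5
        pref = np.linspace(0, 1, 9)[:, None]
        out = decode_center_of_mass(f, pref)
        assert np.isclose(out[0], pref[3, 0])

    def test_equal_pair_decodes_the_midpoint(self):
        f = np.zeros(5)
        f[1] = f[3] = 0.4
        pref = np.array([0.1, 0.2, 0.3, 0.4, 0.5])[:, None]
        out = decode_center_of_mass(f, pref)
        assert np.isclose(out[0], 0.3)

    def test_matches_brute_force_resummation(self, rng):
        f = rng.uniform(0, 0.3, size=(7, 6))
        pref = np.stack(np.meshgrid(np.linspace(0, 1, 7),
                                    np.linspace(-1, 0, 6),
                                    indexing="ij"), axis=-1)
        out = decode_center_of_mass(f, pref, xi=0.01)
        mask = f >= 0.01
        expected = ((f * mask)[..., None] * pref).sum((0, 1)) / (f * mask).sum()
        assert np.allclose(out, expected)

    def test_all_below_threshold_is_no_decode(self):
        f = np.full(9, 0.001)
        assert decode_center_of_mass(f, np.zeros((9, 1)), xi=0.01) is None


class TestVfSelection:
    def _fields(self, cfg, peaks):
        axes = [np.linspace(0, 1, 11)]
        d = cfg.to_dict()["dnf"]
        d["noise_sd"] = 0.0
        from graspaff.config import DnfConfig
        dnf = DnfConfig(**d)
        out = {}
        for vf, peak in peaks.items():
            fld = make_field(axes, dnf)
            fld.f = np.zeros(11)
            if peak:
                fld.f[peak[0]] = peak[1]
            out[vf] = fld
        return out

    def test_only_active_field_wins(self, cfg):
        fields = self._fields(cfg, {"precision": None, "tripod": None,
                                    "power": (5, 0.9), "side": None})
        vf, ap = select_vf(fields)
        assert vf == "power"
        assert np.isclose(ap, np.linspace(0, 1, 11)[5])

    def test_higher_peak_beats_lower(self, cfg):
        fields = self._fields(cfg, {"precision": (2, 0.9), "tripod": (8, 0.8),
                                    "power": None, "side": None})
        assert select_vf(fields)[0] == "precision"

    def test_exact_tie_goes_to_lowest_enum_order(self, cfg):
        fields = self._fields(cfg, {"precision": (2, 0.7), "tripod": (8, 0.7),
                                    "power": (5, 0.7), "side": None})
        assert select_vf(fields)[0] == "precision"

    def test_nothing_super_threshold_is_no_grasp(self, cfg):
        fields = self._fields(cfg, {v: None for v in
                                    ("precision", "tripod", "power", "side")})
        assert select_vf(fields) is None


class TestReachTarget:
    def test_zero_offset_targets_the_center(self):
        target, clamped = compose_reach_target((-1.8, 1.5, 0.2),
                                               (0.0, 0.0, 0.0), 0.31)
        assert np.allclose(target, cartesian_from_spherical(-1.8, 1.5, 0.2))
        assert not clamped

    def test_offset_along_reference_axis(self):
        """theta_o = 0 points along +y of the world-aligned offset frame."""
        target, _ = compose_reach_target((-1.8, 1.5, 0.2), (0.0, 0.0, 0.1),
                                         0.5)
        center = cartesian_from_spherical(-1.8, 1.5, 0.2)
        assert np.allclose(target - center, [0, 0.1, 0], atol=1e-12)

    def test_opposite_offsets_are_symmetric(self):
        c = (-1.8, 1.5, 0.2)
        t1, _ = compose_reach_target(c, (0.5, 1.0, 0.08), 0.5)
        t2, _ = compose_reach_target(c, (0.5 - np.pi, np.pi - 1.0, 0.08), 0.5)
        center = cartesian_from_spherical(*c)
        assert np.allclose(t1 - center, -(t2 - center), atol=1e-12)

    def test_unreachable_target_clamped_and_flagged(self):
        # offset pointing radially away from the shoulder
        target, clamped = compose_reach_target((-1.8, 1.5, 0.3),
                                               (-1.8, 1.5, 0.1), 0.31)
        assert clamped
        assert np.isclose(np.linalg.norm(target), 0.31)


class TestPostures:
    def test_zero_aperture_is_the_minimal_opening(self):
        t = vf_to_fingers("precision", 0.0, "preshape")
        closed = np.asarray(DEFAULT_POSTURES["precision"]["closed"])
        assert np.allclose(t, closed)

    def test_aperture_midpoint_is_linear(self):
        lo = vf_to_fingers("precision", 0.0, "preshape")
        hi = vf_to_fingers("precision", 1.0, "preshape")
        mid = vf_to_fingers("precision", 0.5, "preshape")
        assert np.allclose(mid, 0.5 * (lo + hi))

    def test_power_enclose_flexes_all_fingers(self):
        t = vf_to_fingers("power", 0.5, "enclose")
        for base in (0, 3, 6, 9):            # each finger's MCP joint
            assert t[base] > 1.0

    def test_side_grasp_keeps_fingers_enclosed_thumb_extended(self):
        t = vf_to_fingers("side", 1.0, "preshape")
        assert np.all(t[[0, 3, 6, 9]] >= 1.0)   # fingers curled
        assert t[12] <= 0.1                     # thumb extended

    def test_uninvolved_digits_ignore_aperture(self):
        lo = vf_to_fingers("precision", 0.0, "preshape")
        hi = vf_to_fingers("precision", 1.0, "preshape")
        assert np.allclose(lo[3:12], hi[3:12])  # middle/ring/pinky fixed

    def test_unknown_combination_rejected(self):
        with pytest.raises(ValueError):
            vf_to_fingers("hook", 0.5, "preshape")


class TestGraspPhases:
    def _controller(self, cfg):
        return GraspPhaseController.create(GOLDEN_PLAN, cfg.motor)

    def test_timing_endpoints_interpolate_current_to_final(self, cfg):
        ctl = self._controller(cfg)
        start = np.zeros(15)
        t0 = ctl.step(start, 1.0, False, [], 1e-9)   # timing ~ 0
        assert np.allclose(t0, start, atol=1e-4)
        for _ in range(3000):
            t = ctl.step(start, 1.0, False, [], 0.001)
        final = vf_to_fingers(GOLDEN_PLAN.vf_combination,
                              GOLDEN_PLAN.max_aperture, "preshape")
        assert np.allclose(t, final, atol=0.01)

    def test_enclose_triggers_just_inside_kappa(self, cfg):
        ctl = self._controller(cfg)
        ctl.step(np.zeros(15), cfg.motor.kappa + 0.01, False, [], 0.001)
        assert ctl.phase == "preshape"
        ctl.step(np.zeros(15), cfg.motor.kappa - 1e-6, False, [], 0.001)
        assert ctl.phase == "enclose"

    def test_palm_contact_triggers_enclose_before_kappa(self, cfg):
        ctl = self._controller(cfg)
        ctl.step(np.zeros(15), 1.0, True, [], 0.001)
        assert ctl.phase == "enclose"

    def test_contacted_digit_freezes(self, cfg):
        ctl = self._controller(cfg)
        ctl.step(np.zeros(15), 0.0, True, [], 0.001)     # enclose starts
        angles = np.full(15, 0.3)
        t1 = ctl.step(angles, 0.0, True, ["index"], 0.001)
        assert np.allclose(t1[0:3], 0.3)                 # frozen at contact
        t2 = ctl.step(np.full(15, 0.5), 0.0, True, [], 0.001)
        assert np.allclose(t2[0:3], 0.3)                 # stays frozen

    def test_phase_never_reverts(self, cfg):
        ctl = self._controller(cfg)
        ctl.step(np.zeros(15), 0.0, True, [], 0.001)
        assert ctl.phase == "enclose"
        ctl.step(np.zeros(15), 1.0, False, [], 0.001)
        assert ctl.phase == "enclose"


class TestGoldenTrial:
    def test_hand_specified_pinch_is_stable(self):
        """End-to-end open-loop check: the frozen precision-pinch plan on a
        small cube produces a stable grasp verdict."""
        model = GraspModel(ModelConfig(seed=0, scale=10))
        stable, palm, obj = model._run_movement(GOLDEN_PLAN, GOLDEN_OBJECT)
        assert stable

    def test_plan_serialization_round_trip(self):
        assert GraspPlan.from_json(GOLDEN_PLAN.to_json()) == GOLDEN_PLAN

    def test_invalid_plans_rejected(self):
        with pytest.raises(ValueError):
            GraspPlan((-1.8, 1.45, 0.22), (0, 0, 0), (0, 0, 0), "fist", 0.5)
        with pytest.raises(ValueError):
            GraspPlan((-1.8, 1.45, 0.22), (0, 0, 0), (0, 0, 0), "power", 1.5)
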