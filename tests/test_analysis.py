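"""Preference index, selectivity reports, feature fits, success curves."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from graspaff.analysis import (classify_selectivity, feature_pi_panel,
                               linear_feature_fit, preference_index,
                               selectivity_timecourse, success_rate_curve)
from graspaff.objects import cartesian_from_spherical
from graspaff.training import TrialRecord


def make_record(i, shape="cube", aip=None, success=False, novel=False,
                pos=None, orient=(0.1, 0.2, 0.3), size=(0.03, 0.03, 0.03),
                stage="grasp"):
    pos = pos if pos is not None else tuple(
        cartesian_from_spherical(-1.7, 1.4, 0.2))
    obj = {"shape": shape, "size": list(size), "position": list(pos),
           "orientation": list(orient)}
    return TrialRecord(trial=i, stage=stage, object=obj, novel=novel,
                       aip=aip if aip is not None else np.zeros(4,
                                                                np.float32),
                       plan=None, palm_contact=False, success=success,
                       rs=0.0, rs_sum=0.0, decoded=False)


class TestPreferenceIndex:
    def test_single_category_responder_scores_one(self):
        assert preference_index([1, 0, 0, 0, 0]) == 1.0

    def test_uniform_responder_scores_zero(self):
        assert preference_index([1, 1, 1, 1, 1]) == 0.0

    def test_worked_example_half(self):
        assert preference_index([2, 1, 1, 1, 1]) == 0.5

    def test_undefined_for_non_positive_peak(self):
        with pytest.raises(ValueError):
            preference_index([0.0, 0.0, 0.0])

    @given(st.lists(st.floats(0.0, 10.0, allow_subnormal=False),
                    min_size=2, max_size=8),
           st.floats(0.1, 100.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_scale_invariant(self, r, c):
        if max(r) < 1e-6:        # degenerate: PI undefined either way
            return
        assert np.isclose(preference_index(r),
                          preference_index([c * x for x in r]), atol=1e-9)

    @given(st.lists(st.floats(0.01, 5.0), min_size=3, max_size=6),
           st.floats(0.01, 5.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_dominance(self, r, boost):
        """Raising the preferred response with others fixed never lowers PI."""
        r = list(r)
        i = int(np.argmax(r))
        r2 = list(r)
        r2[i] += boost
        assert preference_index(r2) >= preference_index(r) - 1e-12


class TestClassification:
    @pytest.mark.parametrize("pi,expected", [
        (0.8, "high"), (0.1, "non"), (0.75, "moderate"), (0.25, "moderate"),
        (0.5, "moderate"), (1.0, "high"), (0.0, "non")])
    def test_thresholds(self, pi, expected):
        assert classify_selectivity(pi) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_selectivity(1.5)


class TestTimecourse:
    def _synthetic_log(self, n=1000, units=8, rng=None):
        rng = rng or np.random.default_rng(0)
        shapes = ["cube", "sphere", "plate", "cylinder"]
        recs = []
        for i in range(n):
            s = shapes[rng.integers(4)]
            aip = np.full(units, 0.1, np.float32)
            aip[shapes.index(s) % units] = 1.0   # each unit owns one shape
            recs.append(make_record(i, shape=s, aip=aip))
        return recs

    def test_one_shape_per_unit_reports_all_owned_units_high(self):
        recs = self._synthetic_log()
        reps = selectivity_timecourse(recs, block=500)
        for rep in reps:
            assert rep.counts["high"] == 4      # the four shape-owning units
            assert rep.counts["high"] + rep.counts["moderate"] \
                + rep.counts["non"] + rep.counts["excluded"] == 8

    def test_constant_activity_gives_flat_zero_pi(self):
        recs = [make_record(i, shape=("cube", "sphere")[i % 2],
                            aip=np.full(6, 0.5, np.float32))
                for i in range(1000)]
        reps = selectivity_timecourse(recs, block=500)
        assert len(reps) == 2
        for rep in reps:
            assert rep.counts["non"] == 6
            assert np.isclose(rep.mean_pi, 0.0, atol=1e-6)

    def test_unit_count_conserved_per_block(self):
        recs = self._synthetic_log(n=1500, units=16)
        for rep in selectivity_timecourse(recs, block=500):
            assert sum(rep.counts.values()) == 16


class TestFeaturePanel:
    def test_size_tuned_unit_scores_high_on_size_only(self):
        rng = np.random.default_rng(1)
        recs = []
        for i in range(600):
            s = float(rng.uniform(0.02, 0.06))
            shape = ("cube", "sphere", "plate")[rng.integers(3)]
            aip = np.array([1.0 if s > 0.052 else 0.01, 0.5], np.float32)
            recs.append(make_record(i, shape=shape, size=(s, s, s), aip=aip))
        panel = feature_pi_panel(recs, n_bins=5)
        assert panel.shape == (2, 9)
        assert panel.loc[0, "s_x"] > 0.6
        assert panel.loc[0, "shape"] < 0.25
        assert panel.loc[1, "s_x"] < 0.1     # untuned unit

    def test_shuffled_labels_concentrate_near_null(self):
        rng = np.random.default_rng(2)
        base = [make_record(i, shape=("cube", "sphere")[i % 2],
                            aip=rng.uniform(0.4, 0.6, 3).astype(np.float32),
                            orient=tuple(rng.uniform(-1, 1, 3)),
                            size=tuple(rng.uniform(0.02, 0.06, 3)),
                            pos=tuple(cartesian_from_spherical(
                                float(rng.uniform(-2, -1)),
                                float(rng.uniform(1, 2)), 0.2)))
                for i in range(800)]
        panel = feature_pi_panel(base)
        # activity independent of all features: PI near 0 everywhere
        assert (panel.to_numpy() < 0.2).all()


class TestLinearFit:
    def test_exact_linear_unit_recovered_with_r2_one(self):
        rng = np.random.default_rng(3)
        recs = []
        for i in range(400):
            o = tuple(rng.uniform(-1, 1, 3))
            aip = np.array([2.0 + 3.0 * o[0], 1.0], np.float32)
            recs.append(make_record(i, orient=o, aip=aip,
                                    shape=("cube", "sphere")[i % 2],
                                    pos=tuple(cartesian_from_spherical(
                                        float(rng.uniform(-2, -1)),
                                        float(rng.uniform(1, 2)), 0.2))))
        out = linear_feature_fit(recs)
        i_ox = out["features"].index("o_x")
        sd = np.std([r.object["orientation"][0] for r in recs])
        assert np.isclose(out["coefficients"][0, i_ox], 3.0 * sd, rtol=1e-3)
        assert out["r_squared"][0] > 0.999

    def test_pure_noise_unit_has_small_coefficients(self):
        rng = np.random.default_rng(4)
        recs = []
        for i in range(600):
            o = tuple(rng.uniform(-1, 1, 3))
            aip = rng.normal(1.0, 0.1, 2).astype(np.float32)
            recs.append(make_record(i, orient=o, aip=aip,
                                    shape=("cube", "sphere", "plate")[i % 3],
                                    pos=tuple(cartesian_from_spherical(
                                        float(rng.uniform(-2, -1)),
                                        float(rng.uniform(1, 2)), 0.2))))
        out = linear_feature_fit(recs)
        # permutation null scale: coefficients ~ sd/sqrt(n)
        assert np.abs(out["coefficients"]).max() < 3 * 0.1 / np.sqrt(600) * 10

    def test_too_few_trials_rejected(self):
        rng = np.random.default_rng(6)
        recs = [make_record(i, aip=np.zeros(2, np.float32),
                            orient=tuple(rng.uniform(-1, 1, 3)),
                            size=tuple(rng.uniform(0.02, 0.06, 3)),
                            pos=tuple(cartesian_from_spherical(
                                float(rng.uniform(-2, -1)),
                                float(rng.uniform(1, 2)), 0.2)))
                for i in range(20)]
        with pytest.raises(ValueError):
            linear_feature_fit(recs)


class TestSuccessCurve:
    def test_all_fail_log_is_all_zeros(self):
        recs = [make_record(i, success=False) for i in range(300)]
        curve = success_rate_curve(recs, window=100)
        assert (curve["success_rate"] == 0).all()

    def test_alternating_success_is_half_everywhere(self):
        recs = [make_record(i, success=(i % 2 == 0)) for i in range(400)]
        curve = success_rate_curve(recs, window=100)
        assert np.allclose(curve["success_rate"], 0.5)

    def test_concatenation_invariance(self):
        rng = np.random.default_rng(5)
        a = [make_record(i, success=bool(rng.integers(2))) for i in range(200)]
        b = [make_record(200 + i, success=bool(rng.integers(2)))
             for i in range(200)]
        whole = success_rate_curve(a + b, window=100)
        pa = success_rate_curve(a, window=100)
        pb = success_rate_curve(b, window=100)
        assert np.allclose(whole["success_rate"],
                           np.concatenate([pa["success_rate"],
                                           pb["success_rate"]]))

    def test_novel_trials_reported_separately(self):
        recs = ([make_record(i, success=True) for i in range(100)]
                + [make_record(100 + i, success=False, novel=True)
                   for i in range(100)])
        curve = success_rate_curve(recs, window=100)
        fam = curve[~curve["novel"]]
        nov = curve[curve["novel"]]
        assert (fam["success_rate"] == 1.0).all()
        assert (nov["success_rate"] == 0.0).all()


class TestPurity:
    def test_analyses_are_pure_functions_of_the_log(self):
        rng = np.random.default_rng(7)
        recs = [make_record(i, shape=("cube", "sphere", "plate")[i % 3],
                            aip=rng.uniform(0, 1, 5).astype(np.float32),
                            success=bool(rng.integers(2)))
                for i in range(600)]
        a = selectivity_timecourse(recs, block=200)
        b = selectivity_timecourse(recs, block=200)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.pi, rb.pi, equal_nan=True)
            assert ra.counts == rb.counts
        ca = success_rate_curve(recs, window=200)
        cb = success_rate_curve(recs, window=200)
        assert ca.equals(cb)
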