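"""Parietal Gaussian population codes and the affordance-map input vector."""
import numpy as np
import pytest

from graspaff.config import ParietalConfig
from graspaff.objects import ObjectPrimitive, cartesian_from_spherical
from graspaff.populations import (ParietalEncoder, PopulationSpec,
                                  build_aip_input, encode_axis_orientation,
                                  encode_direction, encode_distance,
                                  encode_size, encode_surface_normals)


def spec1d(n=15, lo=0.0, hi=1.0, sigma=0.1):
    return PopulationSpec((n,), ((lo, hi),), sigma, 0.0)


def obj_at(rho, theta=1.5, phi=-1.5, shape="sphere", size=(0.04,) * 3,
           orientation=(0.0, 0.0, 0.0)):
    return ObjectPrimitive(shape, size,
                           tuple(cartesian_from_spherical(phi, theta, rho)),
                           orientation)


class TestDistance:
    def test_peak_activity_is_one_at_preferred_distance(self):
        spec = spec1d()
        d = spec.axes()[0][7]
        act = encode_distance([obj_at(d)], spec)
        assert np.isclose(act.values[7], 1.0)

    def test_one_sigma_offset_gives_exp_minus_half(self):
        spec = spec1d(sigma=0.05)
        d = spec.axes()[0][7]
        act = encode_distance([obj_at(d + 0.05)], spec)
        assert np.isclose(act.values[7], np.exp(-0.5), atol=1e-12)

    def test_two_components_at_same_distance_double_the_peak(self):
        spec = spec1d()
        d = spec.axes()[0][7]
        act = encode_distance([obj_at(d), obj_at(d)], spec)
        assert np.isclose(act.values[7], 2.0)


class TestDirection:
    def test_exact_preferred_direction_peaks_at_one(self):
        cfg = ParietalConfig()
        spec = PopulationSpec.from_config(cfg.direction)
        th = spec.axes()[0][8]
        ph = spec.axes()[1][4]
        act = encode_direction([obj_at(0.2, theta=th, phi=ph)], spec)
        assert np.isclose(act.values[8, 4], 1.0)

    def test_azimuth_offset_by_sigma_gives_exp_minus_half(self):
        cfg = ParietalConfig()
        spec = PopulationSpec.from_config(cfg.direction)
        th = spec.axes()[0][8]
        ph = spec.axes()[1][4]
        act = encode_direction([obj_at(0.2, theta=th + spec.sigma, phi=ph)], spec)
        assert np.isclose(act.values[8, 4], np.exp(-0.5), atol=1e-9)

    def test_translation_shifts_the_peak(self):
        """Noise-free encoders are deterministic and equivariant: moving the
        stimulus by one grid step moves the activity peak by one cell."""
        cfg = ParietalConfig()
        spec = PopulationSpec.from_config(cfg.direction)
        th = spec.axes()[0]
        ph = spec.axes()[1][4]
        a1 = encode_direction([obj_at(0.2, theta=th[6], phi=ph)], spec)
        a2 = encode_direction([obj_at(0.2, theta=th[9], phi=ph)], spec)
        assert np.unravel_index(a1.values.argmax(), spec.grid_shape) == (6, 4)
        assert np.unravel_index(a2.values.argmax(), spec.grid_shape) == (9, 4)


class TestShapeGating:
    def setup_method(self):
        cfg = ParietalConfig()
        self.cfg = cfg
        self.cyl = PopulationSpec.from_config(cfg.cyl)
        self.rect = PopulationSpec.from_config(cfg.rect)
        self.sos = PopulationSpec.from_config(cfg.sos)

    def test_sphere_drives_neither_axis_population(self):
        c, r = encode_axis_orientation([obj_at(0.2, shape="sphere")],
                                       self.cyl, self.rect)
        assert np.all(c.values == 0) and np.all(r.values == 0)

    def test_cylinder_drives_only_cyl(self):
        o = obj_at(0.2, shape="cylinder", size=(0.04, 0.04, 0.12),
                   orientation=tuple(self.cyl.axes()[0][4] for _ in range(3)))
        c, r = encode_axis_orientation([o], self.cyl, self.rect)
        assert np.isclose(c.values[4, 4, 4], 1.0)
        assert np.all(r.values == 0)

    def test_cube_drives_only_rect(self):
        o = obj_at(0.2, shape="cube", size=(0.04,) * 3,
                   orientation=tuple(self.rect.axes()[0][4] for _ in range(3)))
        c, r = encode_axis_orientation([o], self.cyl, self.rect)
        assert np.isclose(r.values[4, 4, 4], 1.0)
        assert np.all(c.values == 0)

    def test_sos_sphere_all_zero(self):
        act = encode_surface_normals([obj_at(0.2, shape="sphere")],
                                     self.sos, self.cfg)
        assert np.all(act.values == 0)

    def test_sos_counts_visible_faces_against_oracle(self):
        """An axis-aligned cube seen from an oblique view direction exposes
        exactly the faces whose normal . view < 0."""
        d = self.cfg.model_dump(mode="json")
        d["view_mode"] = "fixed"
        d["view_direction"] = (-1.0, -1.0, -1.0)
        cfg = ParietalConfig.model_validate(d)
        o = obj_at(0.2, shape="cube")
        visible = o.visible_normals(np.array([-1.0, -1.0, -1.0]))
        assert len(visible) == 3
        act = encode_surface_normals([o], self.sos, cfg)
        # one unit-height peak per visible normal: activity sums over faces
        grid = self.sos.preferred_grid()
        for n in visible:
            idx = np.unravel_index(
                np.argmin(((grid - n) ** 2).sum(-1)), self.sos.grid_shape)
            assert act.values[idx] > 0.8

    def test_sos_equivariant_under_object_rotation(self):
        d = self.cfg.model_dump(mode="json")
        d["view_mode"] = "fixed"
        d["view_direction"] = (-1.0, -1.0, -1.0)
        cfg = ParietalConfig.model_validate(d)
        a0 = encode_surface_normals([obj_at(0.2, shape="cube")], self.sos, cfg)
        a1 = encode_surface_normals(
            [obj_at(0.2, shape="cube", orientation=(0, 0, np.pi / 2))],
            self.sos, cfg)
        # quarter turn about z maps the visible-face set onto itself
        assert np.allclose(np.sort(a0.values.ravel()),
                           np.sort(a1.values.ravel()), atol=1e-6)


class TestSize:
    def test_preferred_size_triple_peaks_at_one(self):
        cfg = ParietalConfig()
        spec = PopulationSpec.from_config(cfg.size)
        s = tuple(spec.axes()[i][3] for i in range(3))
        act = encode_size([obj_at(0.2, shape="cube", size=s)], spec)
        assert np.isclose(act.values[3, 3, 3], 1.0)

    def test_decoded_size_stable_under_grid_doubling(self):
        cfg = ParietalConfig()
        spec = PopulationSpec.from_config(cfg.size)
        fine = PopulationSpec(tuple(2 * n - 1 for n in spec.grid_shape),
                              spec.ranges, spec.sigma, 0.0)
        size = (0.045, 0.045, 0.045)
        a = encode_size([obj_at(0.2, shape="cube", size=size)], spec)
        b = encode_size([obj_at(0.2, shape="cube", size=size)], fine)
        da, db = a.decode(), b.decode()
        assert np.all(np.abs(da - db) <= 0.02 * np.asarray(size))


class TestAipInput:
    def test_unit_norm_and_scale_invariance(self, cfg, rng):
        enc = ParietalEncoder(cfg.parietal)
        out = enc.encode([obj_at(0.2, shape="cube")])
        I = out["I"]
        assert np.isclose(np.linalg.norm(I), 1.0)
        # scaling all population activities by 10 leaves I unchanged
        scaled = [out[k] for k in ("DIR", "CYL", "RECT", "SOS", "S")]
        for p in scaled:
            p.values = 10 * p.values
        I2, _ = build_aip_input(*scaled)
        assert np.allclose(I, I2)

    def test_all_zero_populations_flagged_degenerate(self, cfg):
        enc = ParietalEncoder(cfg.parietal)
        out = enc.encode([])
        assert out["degenerate"]
        assert np.all(out["I"] == 0)

    def test_distance_population_never_enters_input(self, cfg):
        enc = ParietalEncoder(cfg.parietal)
        assert enc.aip_input_dim == (enc.direction.n_units + enc.cyl.n_units
                                     + enc.rect.n_units + enc.sos.n_units
                                     + enc.size.n_units)
        out = enc.encode([obj_at(0.2)])
        assert len(out["I"]) == enc.aip_input_dim  # DIST excluded

    def test_non_finite_activity_rejected(self, cfg):
        enc = ParietalEncoder(cfg.parietal)
        out = enc.encode([obj_at(0.2, shape="cube")])
        out["DIR"].values[0, 0] = np.nan
        with pytest.raises(ValueError):
            build_aip_input(out["DIR"], out["CYL"], out["RECT"], out["SOS"],
                            out["S"])

    def test_center_of_mass_decode_recovers_stimulus(self):
        """Decoding a noise-free single-component code recovers the stimulus
        within one grid spacing."""
        spec = spec1d(n=15, sigma=0.08)
        d = 0.437
        act = encode_distance([obj_at(d)], spec)
        decoded = act.decode(threshold=0.05)
        assert abs(decoded[0] - d) <= spec.grid_spacing()[0]
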