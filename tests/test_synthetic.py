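import math

import numpy as np
import pytest

from hearttube import SyntheticConfig, make_centerline, synthesize_heart
from hearttube.synthetic import COMPARTMENTS, GeometryError, PlacementError

from conftest import plain_tube_config


class TestConfigValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticConfig(compartment_fractions=(0.2, 0.2, 0.2, 0.2, 0.1))

    def test_fractions_must_be_positive(self):
        with pytest.raises(ValueError, match="positive"):
            SyntheticConfig(compartment_fractions=(-0.1, 0.3, 0.3, 0.3, 0.2))

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError, match="radii"):
            SyntheticConfig(tube_radius_by_compartment=(10, 10, -1, 10, 10))

    def test_zero_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            SyntheticConfig(spacing=(0.0, 1.0, 1.0))

    def test_volume_scale_scales_avc_volume_linearly(self):
        cfg = SyntheticConfig()
        scaled = cfg.with_volume_scale(1.25, "AVC")
        i = COMPARTMENTS.index("AVC")
        v0 = np.prod(cfg.nucleus_axes_mean[i])
        v1 = np.prod(scaled.nucleus_axes_mean[i])
        assert v1 / v0 == pytest.approx(1.25, rel=1e-9)
        # other compartments untouched
        assert scaled.nucleus_axes_mean[0] == cfg.nucleus_axes_mean[0]


class TestMakeCenterline:
    def test_straight_line_arc_length(self):
        cfg = plain_tube_config("straight", {"length": 100.0})
        cl = make_centerline(cfg)
        assert cl.length == pytest.approx(100.0, rel=1e-6)
        chord = np.linalg.norm(cl.outflow_point - cl.inflow_point)
        assert cl.length / chord == pytest.approx(1.0, rel=1e-9)

    def test_semicircular_arc_geometry(self):
        cfg = plain_tube_config(
            "arc", {"radius": 50.0, "turn_fraction": 0.5}, grid=(40, 90, 140)
        )
        cl = make_centerline(cfg)
        assert cl.length == pytest.approx(math.pi * 50.0, rel=1e-4)
        sep = np.linalg.norm(cl.outflow_point - cl.inflow_point)
        assert sep == pytest.approx(100.0, rel=1e-4)

    def test_helix_arc_length_matches_closed_form(self):
        # x = R cos t, y = R sin t, z = c t: length = T sqrt(R² + c²)
        radius, pitch, turns = 25.0, 40.0, 1.0
        cfg = plain_tube_config(
            "helix",
            {"radius": radius, "pitch": pitch, "turns": turns},
            grid=(60, 90, 90),
            spacing=(1.5, 1.0, 1.0),
        )
        cl = make_centerline(cfg)
        c = pitch / (2 * math.pi)
        expected = 2 * math.pi * turns * math.sqrt(radius ** 2 + c ** 2)
        assert cl.length == pytest.approx(expected, rel=0.005)

    def test_arclength_monotonic_and_dense(self):
        cfg = plain_tube_config("arc", {"radius": 40.0, "turn_fraction": 0.4})
        cl = make_centerline(cfg)
        seg = np.diff(cl.arclength)
        assert np.all(seg > 0)
        assert seg.max() <= min(cfg.spacing)

    def test_curve_exiting_grid_raises(self):
        with pytest.raises(GeometryError, match="margin"):
            make_centerline(
                plain_tube_config("straight", {"length": 500.0}, grid=(30, 40, 60))
            )

    def test_unknown_kind_raises(self):
        with pytest.raises(GeometryError, match="supported"):
            make_centerline(plain_tube_config("zigzag", {}))

    def test_spline_passes_near_control_points(self):
        pts = [[30, 30, 20], [32, 60, 60], [30, 30, 100]]
        cfg = plain_tube_config(
            "spline", {"control_points": pts}, grid=(42, 70, 130),
            spacing=(1.5, 1.0, 1.0), radius=6.0,
        )
        cl = make_centerline(cfg)
        assert cl.length > np.linalg.norm(
            cl.outflow_point - cl.inflow_point
        ) - 1e-6


class TestSynthesizeHeart:
    def test_cylinder_lumen_volume(self):
        # straight tube radius 20 µm, length 100 µm, isotropic 1 µm
        cfg = plain_tube_config(
            "straight", {"length": 100.0},
            grid=(60, 60, 170), spacing=(1.0, 1.0, 1.0), radius=20.0,
        )
        heart = synthesize_heart(cfg)
        count = int((heart.compartments.data > 0).sum())
        analytic = math.pi * 20.0 ** 2 * 100.0
        assert count == pytest.approx(analytic, rel=0.03)

    def test_single_spherical_nucleus_voxel_volume(self):
        # zero noise / PSF; one spherical nucleus of r = 5 µm
        cfg = plain_tube_config(
            "straight", {"length": 80.0},
            grid=(50, 50, 120), spacing=(1.0, 1.0, 1.0), radius=12.0,
        )
        cfg = SyntheticConfig(
            **{
                **cfg.__dict__,
                "n_nuclei_by_compartment": (0, 0, 1, 0, 0),
                "nucleus_axes_mean": ((5.0, 5.0, 5.0),) * 5,
                "nucleus_axes_sd": 0.0,
            }
        )
        heart = synthesize_heart(cfg)
        count = int((heart.nuclei_labels.data > 0).sum())
        assert count == pytest.approx(4.0 / 3.0 * math.pi * 125.0, rel=0.05)

    def test_seeding_contract(self):
        cfg7a = SyntheticConfig(seed=7)
        cfg7b = SyntheticConfig(seed=7)
        cfg8 = SyntheticConfig(seed=8)
        h7a = synthesize_heart(cfg7a)
        h7b = synthesize_heart(cfg7b)
        h8 = synthesize_heart(cfg8)
        assert np.array_equal(h7a.nuclear.data, h7b.nuclear.data)
        assert np.array_equal(h7a.membrane.data, h7b.membrane.data)
        assert not np.array_equal(h7a.nuclear.data, h8.nuclear.data)

    def test_overcrowding_raises_placement_error(self):
        cfg = plain_tube_config("straight", {"length": 80.0})
        with pytest.raises(PlacementError, match="AVC"):
            synthesize_heart(
                SyntheticConfig(
                    **{**cfg.__dict__, "n_nuclei_by_compartment": (0, 0, 500, 0, 0)}
                )
            )

    def test_nuclei_labels_disjoint_from_construction(self, clean_heart):
        labels = clean_heart.nuclei_labels.data
        n = len(clean_heart.truth.nuclei)
        present = np.unique(labels)
        assert present[0] == 0 and len(present) == n + 1

    def test_compartments_partition_lumen(self, clean_heart):
        comp = clean_heart.compartments.data
        assert set(np.unique(comp)) == {0, 1, 2, 3, 4, 5}

    def test_nucleus_centers_inside_their_interval(self, clean_heart):
        intervals = clean_heart.truth.compartment_intervals
        for nuc in clean_heart.truth.nuclei:
            lo, hi = intervals[nuc.compartment]
            assert lo <= nuc.arclength <= hi

    def test_analytic_convolutedness_at_least_one(self, clean_heart):
        assert clean_heart.truth.analytic_convolutedness >= 1.0

    def test_arc_convolutedness_matches_closed_form(self):
        # semicircle: arc/chord = πR / 2R = π/2
        cfg = plain_tube_config(
            "arc", {"radius": 50.0, "turn_fraction": 0.5}, grid=(40, 90, 140)
        )
        heart = synthesize_heart(cfg)
        assert heart.truth.analytic_convolutedness == pytest.approx(
            math.pi / 2.0, rel=0.005
        )

    def test_noise_free_ellipsoid_intensity_integral(self):
        # PSF preserves the integral; sum(I) = amplitude × voxelized volume
        cfg = plain_tube_config(
            "straight", {"length": 80.0},
            grid=(50, 50, 120), spacing=(1.0, 1.0, 1.0), radius=12.0,
        )
        cfg = SyntheticConfig(
            **{
                **cfg.__dict__,
                "n_nuclei_by_compartment": (0, 0, 1, 0, 0),
                "psf_sigma": (1.0, 1.0, 1.0),
            }
        )
        heart = synthesize_heart(cfg)
        voxels = int((heart.nuclei_labels.data > 0).sum())
        total = heart.nuclear.data.sum()
        assert total == pytest.approx(cfg.nucleus_intensity * voxels, rel=0.01)

    def test_golgi_offsets_shape_and_magnitude(self, clean_heart):
        offs = clean_heart.truth.golgi_offsets
        assert offs.shape == (len(clean_heart.truth.nuclei), 3)
        np.testing.assert_allclose(
            np.linalg.norm(offs, axis=1), clean_heart.config.golgi_distance,
            rtol=1e-9,
        )

    def test_write_round_trip(self, clean_heart, tmp_path):
        from hearttube import read_labels, read_stack

        clean_heart.write(tmp_path)
        nuc = read_stack(tmp_path / "nuclear.tif")
        comp = read_labels(tmp_path / "compartments.tif")
        assert nuc.spacing == clean_heart.nuclear.spacing
        np.testing.assert_allclose(nuc.data, clean_heart.nuclear.data.astype(np.float32))
        assert np.array_equal(comp.data, clean_heart.compartments.data)
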