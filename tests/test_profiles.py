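import numpy as np
import pytest

from hearttube import (
    ImageStack,
    LabelVolume,
    SyntheticConfig,
    estimate_normals,
    max_projection_intensity,
    normalize_to_reference,
    place_anchors,
    sample_line_profiles,
    synthesize_heart,
)


@pytest.fixture(scope="module")
def contrast_heart():
    """Nucleus-free heart with AVC membrane programmed at 2× atrial intensity."""
    cfg = SyntheticConfig(
        membrane_intensity_by_compartment=(80, 100, 200, 100, 80),
        n_nuclei_by_compartment=(0,) * 5,
        seed=5,
    )
    return synthesize_heart(cfg)


def _lumen(heart):
    return LabelVolume(
        (heart.compartments.data > 0).astype(np.int32), heart.compartments.spacing
    )


class TestEstimateNormals:
    def test_plane_membrane_normals_along_z(self):
        mask = np.zeros((40, 21, 21), dtype=np.int32)
        mask[:20] = 1  # half-space boundary at z = 20 (spacing 1 µm)
        vol = LabelVolume(mask, (1, 1, 1))
        anchors = [(19.5, 10.0, 10.0), (19.5, 5.0, 15.0)]
        normals, valid = estimate_normals(vol, anchors)
        assert valid.all()
        for n in normals:
            angle = np.degrees(np.arccos(abs(n[0])))
            assert angle < 2.0

    def test_spherical_shell_normals_radial(self):
        center = np.array([17.5, 17.5, 17.5])
        zz, yy, xx = np.indices((71, 71, 71)).astype(float) * 0.5
        r = np.sqrt((zz - 17.5) ** 2 + (yy - 17.5) ** 2 + (xx - 17.5) ** 2)
        ball = LabelVolume((r <= 12).astype(np.int32), (0.5, 0.5, 0.5))
        rng = np.random.default_rng(0)
        dirs = rng.normal(size=(20, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        anchors = center + 12.0 * dirs
        normals, valid = estimate_normals(ball, anchors)
        for d, n, ok in zip(dirs, normals, valid):
            if not ok:
                continue
            angle = np.degrees(np.arccos(np.clip(abs(np.dot(d, n)), -1, 1)))
            assert angle < 5.0

    def test_far_anchor_rejected(self):
        mask = np.zeros((30, 30, 30), dtype=np.int32)
        mask[10:20, 10:20, 10:20] = 1
        with pytest.warns(UserWarning, match="rejected"):
            _, valid = estimate_normals(
                LabelVolume(mask, (1, 1, 1)), [(1.0, 1.0, 1.0)]
            )
        assert not valid[0]


class TestSampleLineProfiles:
    def test_constant_image_max_is_constant(self):
        img = ImageStack(np.full((20, 20, 20), 3.5), (1, 1, 1))
        pset = sample_line_profiles(
            img, [(10, 10, 10)], [(0, 0, 1)], half_length=3.0, step=0.5
        )
        assert pset.lines[0].max_intensity == pytest.approx(3.5)

    def test_max_equals_sample_max_exactly(self):
        rng = np.random.default_rng(0)
        img = ImageStack(rng.uniform(0, 10, (20, 20, 20)), (1, 1, 1))
        pset = sample_line_profiles(
            img, [(10, 10, 10), (5, 5, 5)], [(0, 0, 1), (0, 1, 0)]
        )
        for ln in pset.lines:
            assert ln.max_intensity == ln.samples.max()

    def test_gaussian_ridge_peak_recovered(self):
        # membrane plane at z = 15 blurred along z: peak read along the normal
        z = np.arange(30, dtype=float)
        profile = 50.0 * np.exp(-((z - 15.0) ** 2) / (2 * 1.5 ** 2))
        img = ImageStack(np.tile(profile[:, None, None], (1, 21, 21)), (1, 1, 1))
        pset = sample_line_profiles(
            img, [(15.0, 10.0, 10.0)], [(1.0, 0.0, 0.0)],
            half_length=3.0, step=0.25,
        )
        assert pset.lines[0].max_intensity == pytest.approx(50.0, rel=0.05)

    def test_normal_flip_invariance(self):
        rng = np.random.default_rng(1)
        img = ImageStack(rng.uniform(0, 10, (25, 25, 25)), (1, 1, 1))
        fwd = sample_line_profiles(img, [(12, 12, 12)], [(0, 0, 1)])
        rev = sample_line_profiles(img, [(12, 12, 12)], [(0, 0, -1)])
        assert fwd.lines[0].max_intensity == pytest.approx(
            rev.lines[0].max_intensity
        )

    def test_out_of_bounds_truncated_with_warning(self):
        img = ImageStack(np.ones((10, 10, 10)), (1, 1, 1))
        with pytest.warns(UserWarning, match="truncated"):
            pset = sample_line_profiles(
                img, [(0.5, 5.0, 5.0)], [(1.0, 0.0, 0.0)], half_length=4.0
            )
        assert len(pset.lines) == 1

    def test_bad_step_raises(self):
        img = ImageStack(np.ones((5, 5, 5)), (1, 1, 1))
        with pytest.raises(ValueError):
            sample_line_profiles(img, [(2, 2, 2)], [(0, 0, 1)], half_length=1.0, step=2.0)

    def test_membrane_contrast_recovery(self, contrast_heart):
        heart = contrast_heart
        rng = np.random.default_rng(0)
        lumen = _lumen(heart)
        means = {}
        for region, label in (("atrium", 2), ("AVC", 3)):
            anchors = place_anchors(heart.membrane_labels, label, 30, rng)
            normals, valid = estimate_normals(lumen, anchors)
            pset = sample_line_profiles(
                heart.membrane, anchors[valid], normals[valid], region=region
            )
            means[region] = pset.maxima.mean()
        assert 1.8 <= means["AVC"] / means["atrium"] <= 2.2

    def test_noise_free_peak_near_membrane_surface(self):
        cfg = SyntheticConfig(
            n_nuclei_by_compartment=(0,) * 5,
            psf_sigma=(0, 0, 0), gaussian_sd=0.0, poisson_scale=0.0, seed=2,
        )
        heart = synthesize_heart(cfg)
        rng = np.random.default_rng(0)
        anchors = place_anchors(heart.membrane_labels, 2, 10, rng)
        normals, valid = estimate_normals(_lumen(heart), anchors)
        step = 0.25
        pset = sample_line_profiles(
            heart.membrane, anchors[valid], normals[valid], step=step
        )
        for ln in pset.lines:
            peak_offset = (np.argmax(ln.samples) - (len(ln.samples) - 1) / 2) * step
            # anchor sits on a membrane voxel; peak within one step + voxel
            assert abs(peak_offset) <= 1.0 + step


class TestSingleZPlaneMode:
    def test_anchor_plane_constrained(self, contrast_heart):
        heart = contrast_heart
        rng = np.random.default_rng(0)
        zs = np.unique(np.argwhere(heart.membrane_labels.data == 3)[:, 0])
        z = int(zs[len(zs) // 2])
        anchors = place_anchors(heart.membrane_labels, 3, 6, rng, z_plane=z)
        assert np.allclose(anchors[:, 0], z * heart.membrane_labels.spacing[0])


class TestMaxProjection:
    def test_single_hot_voxel(self):
        data = np.zeros((4, 5, 5))
        data[2, 3, 1] = 9.0
        roi = np.zeros((5, 5), dtype=bool)
        roi[3, 1] = True
        assert max_projection_intensity(ImageStack(data, (1, 1, 1)), roi) == 9.0

    def test_all_zero_stack(self):
        roi = np.ones((5, 5), dtype=bool)
        assert max_projection_intensity(
            ImageStack(np.zeros((3, 5, 5)), (1, 1, 1)), roi
        ) == 0.0

    def test_projection_takes_max_over_z(self):
        data = np.zeros((2, 4, 4))
        data[0, 2, 2] = 3.0
        data[1, 2, 2] = 7.0
        roi = np.zeros((4, 4), dtype=bool)
        roi[2, 2] = True
        assert max_projection_intensity(ImageStack(data, (1, 1, 1)), roi) == 7.0

    def test_empty_roi_raises(self):
        with pytest.raises(ValueError, match="ROI"):
            max_projection_intensity(
                ImageStack(np.zeros((3, 4, 4)), (1, 1, 1)),
                np.zeros((4, 4), dtype=bool),
            )


class TestNormalizeToReference:
    def test_basic_arithmetic(self):
        out = normalize_to_reference([2.0, 6.0], [4.0])
        np.testing.assert_allclose(out, [0.5, 1.5])

    def test_self_reference_mean_one(self):
        vals = [3.0, 5.0, 7.0]
        out = normalize_to_reference(vals, vals)
        assert out.mean() == pytest.approx(1.0)

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            normalize_to_reference([1.0], [])

    def test_nonpositive_reference_raises(self):
        with pytest.raises(ValueError, match="positive"):
            normalize_to_reference([1.0], [0.0, 0.0])

    def test_halved_contrast_recovery(self):
        # flow-off mimic: AVC membrane at 0.5× atrial intensity
        cfg = SyntheticConfig(
            membrane_intensity_by_compartment=(80, 100, 50, 100, 80),
            n_nuclei_by_compartment=(0,) * 5,
            seed=9,
        )
        heart = synthesize_heart(cfg)
        rng = np.random.default_rng(0)
        lumen = _lumen(heart)
        maxima = {}
        for region, label in (("atrium", 2), ("AVC", 3)):
            anchors = place_anchors(heart.membrane_labels, label, 25, rng)
            normals, valid = estimate_normals(lumen, anchors)
            maxima[region] = sample_line_profiles(
                heart.membrane, anchors[valid], normals[valid]
            ).maxima
        normalized = normalize_to_reference(maxima["AVC"], maxima["atrium"])
        assert 0.4 <= normalized.mean() <= 0.6
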