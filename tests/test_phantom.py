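"""Phantom generator: rasterization fidelity, truth consistency, sectioner."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.spatial import cKDTree

import lumenprof as lp
from lumenprof.phantom import _segment_truth

from conftest import make_curved_scene


class TestVesselSpec:
    def test_stenosis_narrows_diameter_to_one_minus_severity(self):
        v = lp.VesselSpec(
            [[0, 0, 0], [0, 0, 4.2]], base_diameter=0.328,
            stenoses=[(0.5, 0.4, 0.1)], length=4.2,
        )
        assert float(v.diameter_at(0.5)) == pytest.approx(0.1968, abs=1e-12)
        assert float(v.diameter_at(0.2)) == pytest.approx(0.328)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(base_diameter=-1.0),
            dict(base_diameter=0.3, stenoses=[(0.5, 1.0, 0.1)]),
            dict(base_diameter=0.3, stenoses=[(0.0, 0.5, 0.1)]),
            dict(base_diameter=0.3, stenoses=[(0.5, 0.5, 0.0)]),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            lp.VesselSpec([[0, 0, 0], [0, 0, 1]], **kwargs)

    def test_duplicate_control_points_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            lp.VesselSpec([[0, 0, 0], [0, 0, 0], [0, 0, 1]], base_diameter=0.3)

    def test_arc_length_matches_requested_length(self):
        v = lp.VesselSpec(
            [[0, 0, 0], [0.1, -0.1, 1.4], [0, 0.1, 2.8], [0, 0, 4.2]],
            base_diameter=0.3, length=4.2,
        )
        _, arc = v.sample_centerline(0.009)
        assert arc[-1] == pytest.approx(4.2, rel=1e-9)
        assert np.all(np.diff(arc) > 0)


class TestBuildPhantom:
    def test_deep_interior_voxels_equal_blood_exactly(self):
        """No blur, no noise: voxels deeper than one voxel inside the wall
        carry the pure blood intensity."""
        v = lp.VesselSpec([[0, 0, 0], [0, 0, 1.8]], base_diameter=0.18, length=1.8)
        scene = lp.SceneSpec(
            [v], intensity_blood=148.3, intensity_muscle=100.0,
            intensity_background=50.0, psf_sigma=0.0, noise_sd=0.0,
        )
        ph = lp.build_phantom(scene)
        vol = ph.volume
        truth = ph.truths[0]
        grids = [
            np.arange(n) * s + o
            for n, s, o in zip(vol.shape, vol.spacing, vol.origin)
        ]
        gx, gy, gz = np.meshgrid(*grids, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        tree = cKDTree(truth.sampled_centerline)
        d, i = tree.query(pts, workers=1)
        signed = (d - truth.true_diameter[i] / 2).reshape(vol.shape)
        deep = signed < -0.018
        assert deep.sum() > 500
        assert np.all(vol.intensities[deep] == 148.3)

    def test_blood_roi_recovers_configured_intensity(self):
        """The default in vivo blood level (148.3 +/- 2.0 units) is recovered
        from the generated blood ROI within 3 SEM."""
        v = lp.VesselSpec([[0, 0, 0], [0, 0, 2.4]], base_diameter=0.328, length=2.4)
        scene = lp.SceneSpec(
            [v], intensity_blood=148.3, intensity_muscle=100.0,
            intensity_background=50.0, noise_sd=2.0, psf_sigma=0.009, rng_seed=5,
        )
        ph = lp.build_phantom(scene)
        sl = ph.volume.roi_slices(ph.blood_roi)
        roi = ph.volume.intensities[sl]
        sem = 2.0 / np.sqrt(roi.size)
        assert abs(roi.mean() - 148.3) < 3 * sem

    def test_bit_identical_for_same_spec(self):
        v = lp.VesselSpec([[0, 0, 0], [0.05, 0, 1.2]], base_diameter=0.2)
        a = lp.build_phantom(lp.SceneSpec([v], rng_seed=11))
        b = lp.build_phantom(lp.SceneSpec([v], rng_seed=11))
        assert np.array_equal(a.volume.intensities, b.volume.intensities)
        assert np.array_equal(a.truths[0].true_diameter, b.truths[0].true_diameter)

    def test_different_seed_changes_noise(self):
        v = lp.VesselSpec([[0, 0, 0], [0.05, 0, 1.2]], base_diameter=0.2)
        a = lp.build_phantom(lp.SceneSpec([v], rng_seed=11))
        b = lp.build_phantom(lp.SceneSpec([v], rng_seed=12))
        assert not np.array_equal(a.volume.intensities, b.volume.intensities)

    @pytest.mark.parametrize("diameter_vox", [8, 12, 18])
    def test_thresholded_volume_conserves_tube_volume(self, diameter_vox):
        """With no blur/noise and the threshold at half occupancy, the
        above-threshold volume matches the analytic cylinder within 5%."""
        d = diameter_vox * 0.018
        v = lp.VesselSpec([[0, 0, 0], [0, 0, 2.4]], base_diameter=d, length=2.4)
        scene = lp.SceneSpec(
            [v], intensity_blood=150.0, intensity_muscle=51.0,
            intensity_background=50.0, psf_sigma=0.0, noise_sd=0.0,
        )
        ph = lp.build_phantom(scene)
        thr = (150.0 + 51.0) / 2
        measured = (ph.volume.intensities >= thr).sum() * 0.018**3
        # the tube terminates in hemispherical caps: a capsule
        r = d / 2
        analytic = np.pi * r**2 * 2.4 + 4.0 / 3.0 * np.pi * r**3
        assert measured == pytest.approx(analytic, rel=0.05)

    def test_truth_profile_matches_bruteforce_binning(self):
        rng = np.random.default_rng(3)
        scene = make_curved_scene(rng, 14, stenosis=(0.4, 0.3, 0.2))
        truth = lp.build_phantom(scene).truths[0]
        t = truth.arc_length / truth.arc_length[-1]
        expected = np.array(
            [
                truth.true_diameter[(t >= i / 9) & ((t < (i + 1) / 9) | (i == 8))].mean()
                for i in range(9)
            ]
        )
        np.testing.assert_array_equal(truth.true_segment_diameter, expected)
        np.testing.assert_allclose(
            truth.true_segment_area, np.pi * expected**2 / 4, rtol=1e-12
        )

    def test_truth_sampled_at_half_voxel_steps(self):
        v = lp.VesselSpec([[0, 0, 0], [0, 0, 1.2]], base_diameter=0.2, length=1.2)
        truth = lp.build_phantom(lp.SceneSpec([v], noise_sd=0.0)).truths[0]
        assert np.max(np.diff(truth.arc_length)) <= 0.5 * 0.018 + 1e-12

    def test_vessel_outside_explicit_bounds_rejected(self):
        v = lp.VesselSpec([[0, 0, 0], [0, 0, 2.4]], base_diameter=0.3, length=2.4)
        scene = lp.SceneSpec([v], shape=(20, 20, 20), origin=(0, 0, 0))
        with pytest.raises(ValueError, match="does not fit"):
            lp.build_phantom(scene)

    def test_intensity_ordering_enforced(self):
        v = lp.VesselSpec([[0, 0, 0], [0, 0, 1]], base_diameter=0.2)
        with pytest.raises(ValueError, match="ordering"):
            lp.SceneSpec([v], intensity_blood=100, intensity_muscle=120)


class TestVirtualHistology:
    def test_nine_sections_span_arch_to_bifurcation(self):
        """A 4.2 mm vessel sectioned every 0.5 mm yields nine sections."""
        v = lp.VesselSpec([[0, 0, 0], [0, 0, 4.2]], base_diameter=0.328, length=4.2)
        scene = lp.SceneSpec([v], noise_sd=0.0)
        sections = lp.virtual_histology(scene, lp.HistologyArtefactSpec(section_spacing=0.5))
        assert len(sections) == 9
        np.testing.assert_allclose(
            [s.position_mm for s in sections], np.arange(9) * 0.5
        )

    def test_shrink_scales_perimeter_linearly_and_area_quadratically(self):
        v = lp.VesselSpec([[0, 0, 0], [0, 0, 4.2]], base_diameter=0.4, length=4.2)
        scene = lp.SceneSpec([v], noise_sd=0.0)
        f = 0.8
        full = lp.virtual_histology(scene, lp.HistologyArtefactSpec(shrink_factor=1.0))
        shrunk = lp.virtual_histology(scene, lp.HistologyArtefactSpec(shrink_factor=f))
        for s_full, s_shr in zip(full, shrunk):
            p1, a1 = lp.polygon_metrics(s_full.contour)
            p2, a2 = lp.polygon_metrics(s_shr.contour)
            assert p2 == pytest.approx(f * p1, rel=1e-9)
            assert a2 == pytest.approx(f**2 * a1, rel=1e-9)

    def test_compression_preserves_perimeter_and_shrinks_area(self):
        """Equal-perimeter ellipse at axis ratio 2: perimeter within 0.5% of
        the circle's (quadrature oracle), planimetric area strictly below."""
        v = lp.VesselSpec([[0, 0, 0], [0, 0, 1.0]], base_diameter=0.4, length=1.0)
        scene = lp.SceneSpec([v], noise_sd=0.0)
        art = lp.HistologyArtefactSpec(shrink_factor=1.0, compression_ratio=2.0,
                                       section_spacing=0.5)
        sections = lp.virtual_histology(scene, art)
        r = 0.2
        a, b = lp.phantom.ellipse_semi_axes(2 * np.pi * r, 2.0)
        oracle, _ = quad(
            lambda th: np.sqrt(a**2 * np.sin(th) ** 2 + b**2 * np.cos(th) ** 2),
            0.0, 2 * np.pi, limit=200,
        )
        assert oracle == pytest.approx(2 * np.pi * r, rel=1e-6)
        for s in sections:
            p, area = lp.polygon_metrics(s.contour)
            assert p == pytest.approx(2 * np.pi * r, rel=0.005)
            assert area < np.pi * r**2

    def test_plaque_area_is_fraction_of_shrunken_media_circle(self):
        v = lp.VesselSpec([[0, 0, 0], [0, 0, 1.0]], base_diameter=0.4, length=1.0)
        scene = lp.SceneSpec([v], noise_sd=0.0)
        art = lp.HistologyArtefactSpec(shrink_factor=0.8, plaque_fraction=0.25,
                                       section_spacing=0.5)
        sections = lp.virtual_histology(scene, art)
        r = 0.8 * 0.2
        for s in sections:
            assert s.role == "inner_media"
            assert s.plaque_area_mm2 == pytest.approx(0.25 * np.pi * r**2, rel=1e-9)

    def test_spacing_beyond_length_gives_single_section_with_warning(self):
        v = lp.VesselSpec([[0, 0, 0], [0, 0, 1.0]], base_diameter=0.3, length=1.0)
        scene = lp.SceneSpec([v], noise_sd=0.0)
        with pytest.warns(UserWarning, match="single section"):
            sections = lp.virtual_histology(scene, lp.HistologyArtefactSpec(section_spacing=2.0))
        assert len(sections) == 1
        assert sections[0].position_mm == 0.0

    def test_sectioner_deterministic_for_fixed_seed(self):
        v = lp.VesselSpec([[0, 0, 0], [0, 0, 4.2]], base_diameter=0.3, length=4.2)
        scene = lp.SceneSpec([v], noise_sd=0.0)
        art = lp.HistologyArtefactSpec(compression_ratio=1.5, rng_seed=4)
        s1 = lp.virtual_histology(scene, art)
        s2 = lp.virtual_histology(scene, art)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.contour, b.contour)

    @pytest.mark.parametrize(
        "kwargs", [dict(shrink_factor=0.0), dict(shrink_factor=1.2),
                   dict(compression_ratio=0.5), dict(plaque_fraction=1.0),
                   dict(section_spacing=0.0)],
    )
    def test_invalid_artefacts_rejected(self, kwargs):
        with pytest.raises(ValueError):
            lp.HistologyArtefactSpec(**kwargs)
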