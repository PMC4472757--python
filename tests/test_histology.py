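"""Polygon morphometry, perimeter-based lumen rule, plaque subtraction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import lumenprof as lp
from lumenprof.histology import contour_from_wkt, contour_to_wkt, sections_from_frame, sections_to_frame

SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


class TestPolygonMetrics:
    def test_unit_square(self):
        p, a = lp.polygon_metrics(SQUARE)
        assert p == pytest.approx(4.0, rel=1e-12)
        assert a == pytest.approx(1.0, rel=1e-12)

    def test_256gon_approximates_circle(self):
        theta = np.linspace(0, 2 * np.pi, 257)[:-1]
        poly = 0.5 * np.column_stack([np.cos(theta), np.sin(theta)])
        p, a = lp.polygon_metrics(poly)
        assert p == pytest.approx(np.pi, rel=1e-3)
        assert a == pytest.approx(np.pi / 4, rel=1e-3)

    def test_orientation_invariance(self):
        p1, a1 = lp.polygon_metrics(SQUARE)
        p2, a2 = lp.polygon_metrics(SQUARE[::-1])
        assert (p1, a1) == (p2, a2)

    def test_self_intersection_rejected(self):
        bowtie = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 0.0], [0.0, 1.5]])
        with pytest.raises(ValueError, match="self-intersecting"):
            lp.polygon_metrics(bowtie)

    def test_degenerate_zero_area_warns(self):
        collinear = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        with pytest.warns(UserWarning, match="degenerate"):
            p, a = lp.polygon_metrics(collinear)
        assert a == 0.0

    def test_micron_contours_converted_to_mm(self):
        c = lp.SectionContour(SQUARE * 1000.0, position_mm=0.0, units="um")
        p, a = lp.polygon_metrics(c)
        assert p == pytest.approx(4.0, rel=1e-12)
        assert a == pytest.approx(1.0, rel=1e-12)


class TestLumenFromPerimeter:
    def test_perimeter_pi_gives_unit_diameter(self):
        d, a = lp.lumen_from_perimeter(np.pi)
        assert d == pytest.approx(1.0, rel=1e-12)
        assert a == pytest.approx(np.pi / 4, rel=1e-12)

    def test_square_perimeter_quantifies_convexification_bias(self):
        """P = 4 (unit square): the circular rule gives d = A = 4/pi, strictly
        above the square's planimetric area 1."""
        d, a = lp.lumen_from_perimeter(4.0)
        assert d == pytest.approx(4 / np.pi, rel=1e-12)
        assert a == pytest.approx(4 / np.pi, rel=1e-12)
        assert a > 1.0

    def test_nonpositive_perimeter_rejected(self):
        with pytest.raises(ValueError):
            lp.lumen_from_perimeter(0.0)

    def test_compressed_section_recovers_uncompressed_circle_area(self):
        """Perimeter-preserving compression (axis ratio 2) leaves the
        perimeter-rule lumen area within 1% of the true circle area."""
        v = lp.VesselSpec([[0, 0, 0], [0, 0, 1.0]], base_diameter=0.4, length=1.0)
        scene = lp.SceneSpec([v], noise_sd=0.0)
        art = lp.HistologyArtefactSpec(shrink_factor=1.0, compression_ratio=2.0,
                                       section_spacing=0.5)
        for s in lp.virtual_histology(scene, art):
            perim, plan = lp.polygon_metrics(s.contour)
            _, lumen = lp.lumen_from_perimeter(perim)
            assert lumen == pytest.approx(np.pi * 0.2**2, rel=0.01)
            assert plan < lumen  # compression destroyed planimetric area

    @given(st.lists(st.floats(0.2, 2.0), min_size=3, max_size=40))
    def test_isoperimetric_bound_on_star_polygons(self, radii):
        """P^2/(4 pi) >= planimetric area for every simple closed contour."""
        r = np.asarray(radii)
        theta = np.linspace(0, 2 * np.pi, len(r), endpoint=False)
        poly = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        p, a = lp.polygon_metrics(poly)
        _, circ_area = lp.lumen_from_perimeter(p)
        assert circ_area >= a - 1e-12


class TestLumenWithPlaque:
    def test_subtraction(self):
        # media circle of area 0.10 mm^2 -> P = 2 sqrt(pi * 0.10)
        p_media = 2 * np.sqrt(np.pi * 0.10)
        assert p_media == pytest.approx(1.12100, abs=5e-6)
        assert lp.lumen_with_plaque(p_media, 0.03) == pytest.approx(0.07, rel=1e-9)

    def test_zero_plaque_reduces_to_perimeter_rule(self):
        _, circle = lp.lumen_from_perimeter(1.5)
        assert lp.lumen_with_plaque(1.5, 0.0) == pytest.approx(circle, rel=1e-12)

    def test_excess_plaque_clamps_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="near-occlusion"):
            lumen = lp.lumen_with_plaque(1.0, 1.0)
        assert lumen == 0.0

    def test_measure_section_dispatches_on_role(self):
        theta = np.linspace(0, 2 * np.pi, 65)[:-1]
        circle = 0.2 * np.column_stack([np.cos(theta), np.sin(theta)])
        healthy = lp.measure_section(lp.SectionContour(circle, 0.0, role="lumen"))
        assert not healthy.used_plaque_rule
        diseased = lp.measure_section(
            lp.SectionContour(circle, 0.0, role="inner_media", plaque_area_mm2=0.05)
        )
        assert diseased.used_plaque_rule
        assert diseased.lumen_area == pytest.approx(healthy.lumen_area - 0.05, rel=1e-9)


class TestHistologyProfile:
    def _measurement(self, pos, area, vid="v0"):
        perim = 2 * np.sqrt(np.pi * area)
        return lp.SectionMeasurement(
            perimeter=perim, planimetric_area=area, circ_diameter=perim / np.pi,
            lumen_area=area, used_plaque_rule=False, position_mm=pos, vessel_id=vid,
        )

    def test_nine_equal_sections_give_constant_profile(self):
        ms = [self._measurement(0.5 * k, 0.08) for k in range(9)]
        prof = lp.histology_profile(ms)
        assert prof.n_segments == 9
        np.testing.assert_allclose(prof.area, 0.08)

    def test_nine_sections_are_index_matched(self):
        areas = 0.05 + 0.01 * np.arange(9)
        ms = [self._measurement(0.5 * k, areas[k]) for k in range(9)]
        prof = lp.histology_profile(ms)
        np.testing.assert_allclose(prof.area, areas, rtol=1e-12)

    def test_eight_sections_use_nearest_bin_assignment(self):
        """With one lost section, positions map to the nearest of nine bin
        centres; verified against a brute-force assignment."""
        keep = [0, 1, 2, 3, 5, 6, 7, 8]
        areas = 0.05 + 0.01 * np.arange(9)
        ms = [self._measurement(0.5 * k, areas[k]) for k in keep]
        with pytest.warns(UserWarning, match="no section"):
            prof = lp.histology_profile(ms)
        pos = np.array([0.5 * k for k in keep])
        t = (pos - pos[0]) / (pos[-1] - pos[0])
        centers = (np.arange(9) + 0.5) / 9
        expected = np.full(9, np.nan)
        for tk, a in zip(t, areas[keep]):
            expected[np.abs(centers - tk).argmin()] = a
        np.testing.assert_allclose(prof.area, expected, rtol=1e-12)

    def test_duplicate_positions_rejected(self):
        ms = [self._measurement(0.0, 0.08), self._measurement(0.0, 0.09)]
        with pytest.raises(ValueError, match="duplicate"):
            lp.histology_profile(ms)

    def test_shrink_free_sections_match_phantom_truth_profile(self):
        """Virtual histology at shrink 1, no compression, no plaque recovers
        the phantom's true segment areas within 5%."""
        v = lp.VesselSpec(
            [[0, 0, 0], [0.05, -0.03, 2.1], [0, 0, 4.2]],
            base_diameter=0.35, stenoses=[(0.5, 0.15, 0.9)], length=4.2,
        )
        scene = lp.SceneSpec([v], noise_sd=0.0)
        truth = lp.build_phantom(scene).truths[0]
        art = lp.HistologyArtefactSpec(shrink_factor=1.0, section_spacing=0.5)
        ms = [
            lp.measure_section(
                lp.SectionContour(s.contour, s.position_mm, role=s.role,
                                  plaque_area_mm2=s.plaque_area_mm2)
            )
            for s in lp.virtual_histology(scene, art)
        ]
        prof = lp.histology_profile(ms)
        np.testing.assert_allclose(prof.area, truth.true_segment_area, rtol=0.05)

    def test_linear_shrink_scales_lumen_area_by_square(self):
        theta = np.linspace(0, 2 * np.pi, 101)[:-1]
        poly = np.column_stack([0.3 * np.cos(theta), 0.2 * np.sin(theta)])
        f = 0.77
        m1 = lp.measure_section(lp.SectionContour(poly, 0.0))
        m2 = lp.measure_section(lp.SectionContour(f * poly, 0.0))
        assert m2.lumen_area == pytest.approx(f**2 * m1.lumen_area, rel=1e-12)
        assert m2.perimeter == pytest.approx(f * m1.perimeter, rel=1e-12)


class TestSectionSerialization:
    def test_wkt_round_trip(self):
        np.testing.assert_allclose(contour_from_wkt(contour_to_wkt(SQUARE)), SQUARE)

    def test_sections_frame_round_trip(self):
        contours = [
            lp.SectionContour(SQUARE * 0.1, position_mm=0.5, role="inner_media",
                              plaque_area_mm2=0.01, vessel_id="m1"),
        ]
        frame = sections_to_frame(contours)
        back = sections_from_frame(frame)
        np.testing.assert_allclose(back[0].vertices, contours[0].vertices)
        assert back[0].role == "inner_media"
        assert back[0].plaque_area_mm2 == pytest.approx(0.01)
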