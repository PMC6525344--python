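import numpy as np
import pytest

from conftest import make_ellipse, make_rippled
from onlshape.errors import GeometryError, NoContourError, ParameterError
from onlshape.height_map import HeightImage, reference_level
from onlshape.onlb import (
    Contour,
    convex_hull_deficit,
    efd_fit,
    efd_reconstruct,
    evaluate_criteria,
    extract_level_contour,
    resample_contour,
    restore_ratio,
    select_onlb,
)
from onlshape.synthetic_data import BumpModel, generate_surfaces
from onlshape.height_map import build_height_image


def gaussian_bump_image(base=10.0, peak=100.0, sigma=60.0, size=512, center=None):
    c = (size - 1) / 2.0 if center is None else center
    y, x = np.mgrid[0:size, 0:size].astype(float)
    r2 = (x - c) ** 2 + (y - c) ** 2
    return HeightImage(base + peak * np.exp(-r2 / (2 * sigma**2)))


class TestContour:
    def test_area_and_perimeter_of_square(self):
        v = np.array([[0, 0], [10, 0], [10, 10], [5, 10], [2.5, 10],
                      [0, 10], [0, 5], [0, 2.5]], dtype=float)
        c = Contour(v)
        assert c.area_S == pytest.approx(100.0)
        assert c.perimeter_L == pytest.approx(40.0)

    def test_orientation_normalized(self):
        c1 = make_ellipse(50, 30)
        c2 = Contour(c1.vertices[::-1])  # reversed input
        assert np.allclose(abs(c1.area_S), abs(c2.area_S))
        # both stored with positive shoelace orientation
        from onlshape.onlb import _shoelace
        assert _shoelace(c1.vertices) > 0 and _shoelace(c2.vertices) > 0

    def test_too_few_vertices_rejected(self):
        with pytest.raises(GeometryError):
            Contour(np.array([[0, 0], [1, 0], [0, 1]], dtype=float))

    def test_isoperimetric_bound(self):
        for c in (make_ellipse(80, 80), make_ellipse(90, 30, theta_deg=40),
                  make_rippled(amp=0.3, lobes=5)):
            assert 4 * np.pi * c.area_S / c.perimeter_L**2 <= 1 + 1e-6


class TestEfd:
    def test_circle_first_harmonic_energy(self, circle):
        # closed form: a1^2 + b1^2 + c1^2 + d1^2 = 2 r^2 for a circle of radius r
        co = efd_fit(circle, 5)
        assert (co.harmonics[0] ** 2).sum() == pytest.approx(2 * 100.0**2, rel=1e-3)

    def test_ellipse_first_harmonic_dominates(self, ellipse_2to1):
        # constant-speed (arc-length) traversal of an ellipse is not a pure
        # sinusoid, so a small fraction of energy (~0.6% for 2:1) leaks into
        # odd harmonics; the first harmonic still carries essentially all of it
        co = efd_fit(ellipse_2to1, 5)
        total = (co.harmonics**2).sum()
        assert (co.harmonics[1:] ** 2).sum() / total < 1e-2

    def test_translation_changes_only_dc(self, ellipse_2to1):
        co = efd_fit(ellipse_2to1, 5)
        shifted = Contour(ellipse_2to1.vertices + [17.0, -9.0])
        co2 = efd_fit(shifted, 5)
        np.testing.assert_allclose(co2.harmonics, co.harmonics, atol=1e-9)
        assert co2.dc[0] - co.dc[0] == pytest.approx(17.0, abs=1e-9)
        assert co2.dc[1] - co.dc[1] == pytest.approx(-9.0, abs=1e-9)

    def test_circle_reconstruction_area(self, circle):
        rec = efd_reconstruct(efd_fit(circle, 5), 100)
        assert rec.area_S == pytest.approx(np.pi * 100.0**2, rel=5e-3)

    def test_octagon_from_first_harmonic_inscribed(self, ellipse_2to1):
        co = efd_fit(ellipse_2to1, 1)
        octagon = efd_reconstruct(co, 8)
        assert octagon.area_S < ellipse_2to1.area_S

    def test_reconstruction_converges_with_harmonics(self):
        # ellipse plus a small 6-lobe ripple: the mismatched region between
        # the reconstruction and the original shrinks as harmonics grow
        from shapely.geometry import Polygon

        t = np.linspace(0, 2 * np.pi, 2048, endpoint=False)
        r = 100 * (1 + 0.05 * np.cos(6 * t))
        c = Contour(np.column_stack([1.5 * r * np.cos(t) + 256, r * np.sin(t) + 256]))
        orig = Polygon(c.vertices)
        errs = []
        for h in (1, 3, 5, 7, 9):
            rec = efd_reconstruct(efd_fit(c, h), 2048)
            errs.append(orig.symmetric_difference(Polygon(rec.vertices)).area)
        assert errs == sorted(errs, reverse=True)
        assert errs[-1] < 0.01 * c.area_S

    def test_too_few_vertices_for_harmonics(self):
        c = resample_contour(make_ellipse(50, 30), 9)
        with pytest.raises(ParameterError):
            efd_fit(c, 5)


class TestHullDeficit:
    def test_convex_contour_has_no_deficit(self, ellipse_2to1):
        deficit, ratio = convex_hull_deficit(ellipse_2to1)
        assert deficit == pytest.approx(0.0, abs=ellipse_2to1.area_S * 1e-3)
        assert ratio == pytest.approx(1.0, abs=1e-3)

    def test_notched_square_exact(self):
        # 100x100 square with a 20x20 notch: deficit 400, hull ratio 10000/9600
        v = np.array([
            [0, 0], [100, 0], [100, 100], [60, 100], [60, 80],
            [40, 80], [40, 100], [0, 100],
        ], dtype=float)
        deficit, ratio = convex_hull_deficit(Contour(v))
        assert deficit == pytest.approx(400.0)
        assert ratio == pytest.approx(10000.0 / 9600.0)

    def test_deep_star_fails_solidity(self):
        star = make_rippled(amp=0.45, lobes=7)
        _, ratio = convex_hull_deficit(star)
        assert ratio > 1.2


class TestRestoreRatio:
    def test_ellipse_is_restorable(self, ellipse_2to1):
        assert restore_ratio(ellipse_2to1) > 0.95

    def test_crenellated_contour_is_not_restorable(self):
        assert restore_ratio(make_rippled(amp=0.2, lobes=12)) < 0.95

    def test_scale_invariance(self):
        c = make_rippled(amp=0.15, lobes=5)
        c2 = Contour(c.vertices * 2.0)
        assert restore_ratio(c2) == pytest.approx(restore_ratio(c), abs=1e-3)

    def test_rotation_invariance(self):
        r1 = restore_ratio(make_ellipse(90, 45, theta_deg=0))
        r2 = restore_ratio(make_ellipse(90, 45, theta_deg=37))
        assert r2 == pytest.approx(r1, abs=1e-3)

    def test_monotone_in_ripple_amplitude(self):
        ratios = [restore_ratio(make_rippled(amp=a, lobes=9)) for a in (0.0, 0.1, 0.2, 0.3)]
        assert ratios == sorted(ratios, reverse=True)


class TestExtractLevelContour:
    def test_gaussian_bump_level_set_radius(self):
        # closed form: h = base + peak*exp(-r^2/2s^2) crosses base+peak/2
        # at r = s*sqrt(2 ln 2)
        sigma, base, peak = 60.0, 0.0, 100.0
        hi = gaussian_bump_image(base=base, peak=peak, sigma=sigma)
        level = base + peak / 2.0
        c = extract_level_contour(hi, level)
        expected_r = sigma * np.sqrt(2 * np.log(2))
        assert c.area_S == pytest.approx(np.pi * expected_r**2, rel=0.01)

    def test_level_above_maximum_rejected(self):
        hi = gaussian_bump_image(peak=50.0)
        with pytest.raises(NoContourError):
            extract_level_contour(hi, 1000.0)

    def test_two_bumps_keeps_peak_component(self):
        y, x = np.mgrid[0:512, 0:512].astype(float)
        tall = 100 * np.exp(-((x - 150) ** 2 + (y - 256) ** 2) / (2 * 40**2))
        short = 60 * np.exp(-((x - 400) ** 2 + (y - 256) ** 2) / (2 * 40**2))
        hi = HeightImage(tall + short)
        c = extract_level_contour(hi, 30.0)
        cx = c.vertices[:, 0].mean()
        assert abs(cx - 150) < 15  # encloses only the taller bump

    def test_area_monotone_in_level(self):
        hi = gaussian_bump_image()
        areas = [extract_level_contour(hi, lv).area_S for lv in (20, 40, 60, 80)]
        assert areas == sorted(areas, reverse=True)


class TestCriteriaAndSelection:
    def test_smooth_bump_passes_all(self):
        hi = gaussian_bump_image()
        c = extract_level_contour(hi, 50.0)
        report = evaluate_criteria(hi, c)
        assert report.passed and report.failing() == []

    def test_border_clipped_contour_fails_criterion_one(self):
        hi = gaussian_bump_image(sigma=200.0, center=50.0)  # bump spills off-image
        c = extract_level_contour(hi, 15.0)
        report = evaluate_criteria(hi, c)
        assert not report.inside_hi and not report.passed

    def test_selection_returns_lowest_passing_level(self):
        model = BumpModel(sigma_major_px=60, sigma_minor_px=45, theta_true_deg=20, seed=0)
        stack, _ = generate_surfaces(model)
        hi = build_height_image(stack)
        ref = reference_level(hi)
        res = select_onlb(hi, ref)
        assert res.level_px >= ref.level_px
        assert res.criteria.passed
        # idempotence: re-evaluating the returned contour still passes
        assert evaluate_criteria(hi, res.contour).passed
        # no lower scanned level passes
        lower = res.level_px - 1.0
        if lower > 0:
            try:
                c = extract_level_contour(hi, lower)
                assert not evaluate_criteria(hi, c).passed
            except NoContourError:
                pass

    def test_selection_failure_lists_diagnostics(self):
        from onlshape.errors import SelectionFailureError

        # peak sits on the image corner: every level contour is clipped
        hi = gaussian_bump_image(sigma=80.0, base=5.0, center=2.0)
        ref = reference_level(hi)
        with pytest.raises(SelectionFailureError) as exc:
            select_onlb(hi, ref)
        assert len(exc.value.diagnostics) > 0

    def test_level_um_is_rpe_distance(self):
        model = BumpModel(seed=1)
        stack, _ = generate_surfaces(model)
        hi = build_height_image(stack)
        res = select_onlb(hi, reference_level(hi))
        assert res.distance_rpe_um == pytest.approx(res.level_px * 3.87)
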