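"""Tests of curve rasterization, the Harris detector and point screening."""

import numpy as np
import pytest
from scipy import ndimage

from ricekey import (DominantPointSet, InputError, detect_dominant_points,
                     find_dominant_points, fit_dominant_points,
                     gaussian_kernel, growth_rate, harris_response,
                     rasterize_curve, ratio_curve, screen_points,
                     select_images, smooth)
from ricekey.keyperiod import auto_y_step
from ricekey.synthetic import generate_breakpoint_curve

from conftest import SEASON_START


def brute_force_local_maxima(resp, window):
    """Independent oracle: double-loop strict window-maximum scan."""
    r = window // 2
    nr, nc = resp.shape
    out = []
    for i in range(nr):
        for j in range(nc):
            patch = resp[max(0, i - r):i + r + 1, max(0, j - r):j + r + 1]
            if resp[i, j] >= patch.max():
                out.append((i, j))
    return out


class TestRasterize:
    def test_constant_series_single_row(self):
        img = rasterize_curve(np.full(30, 2.0), y_step=0.01)
        rows = np.nonzero(img.pixels)[0]
        assert len(set(rows)) == 1
        assert img.pixels.sum() == 30  # one pixel per column

    def test_unit_slope_staircase(self):
        # slope equal to y_step advances exactly one row per column
        img = rasterize_curve(0.001 * np.arange(40), y_step=0.001)
        rows = np.array([np.nonzero(img.pixels[:, j])[0] for j in range(40)],
                        dtype=object)
        first = [r.min() for r in rows]
        assert np.all(np.diff(first) == 1)

    def test_two_day_series_two_columns(self):
        img = rasterize_curve([0.0, 0.5], y_step=0.01)
        assert img.pixels.shape[1] == 2

    def test_non_finite_rejected(self):
        with pytest.raises(InputError):
            rasterize_curve([0.0, np.nan, 1.0], 0.01)

    def test_polyline_is_connected(self):
        img = rasterize_curve([0.0, 0.3, 0.35, 0.1], y_step=0.01)
        labeled, n = ndimage.label(img.pixels > 0,
                                   structure=np.ones((3, 3), dtype=int))
        assert n == 1


class TestGaussianKernel:
    def test_normalized_and_symmetric(self):
        g = gaussian_kernel(2.0, 9)
        assert g.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(g, g[::-1, :])
        np.testing.assert_allclose(g, g[:, ::-1])
        np.testing.assert_allclose(g, g.T)

    def test_large_sigma_approaches_uniform(self):
        g = gaussian_kernel(1e4, 3)
        np.testing.assert_allclose(g, np.full((3, 3), 1.0 / 9.0), atol=1e-6)

    def test_even_size_rejected(self):
        with pytest.raises(InputError):
            gaussian_kernel(1.0, 4)


class TestSmooth:
    def test_constant_image_unchanged(self):
        img = rasterize_curve(np.full(30, 1.0), 0.01)
        img.pixels[:] = 0.5
        out = smooth(img, gaussian_kernel(1.5, 5))
        np.testing.assert_allclose(out.pixels, 0.5)

    def test_successive_smooths_compose(self):
        rng = np.random.default_rng(0)
        img = rasterize_curve(np.cumsum(rng.uniform(0, 0.02, 60)), 0.01)
        from scipy.signal import convolve2d
        g3 = gaussian_kernel(1.0, 3)
        twice = smooth(smooth(img, g3), g3)
        composed = convolve2d(g3, g3)  # full 5x5 composition
        once = ndimage.convolve(img.pixels, composed, mode="reflect")
        # interior only: border handling differs between one and two passes
        np.testing.assert_allclose(twice.pixels[3:-3, 3:-3],
                                   once[3:-3, 3:-3], atol=1e-10)

    def test_oversized_kernel_rejected(self):
        img = rasterize_curve([0.0, 0.01, 0.02], 0.01)
        with pytest.raises(InputError):
            smooth(img, gaussian_kernel(3.0, 35))


class TestHarrisResponse:
    def test_flat_image_zero_response(self):
        img = rasterize_curve(np.full(40, 1.0), 0.01)
        img.pixels[:] = 0.0
        resp = harris_response(img)
        np.testing.assert_allclose(resp.response, 0.0, atol=1e-15)

    def test_corner_measure_formula(self):
        # lambda1 = lambda2 = 1 gives R = 1 - k * 4; an ideal edge
        # (lambda2 = 0) gives R = -k * lambda1^2 < 0
        k = 0.04
        det, trace = 1.0 * 1.0, 1.0 + 1.0
        assert det - k * trace ** 2 == pytest.approx(0.84)
        lam1 = 2.5
        assert 0.0 * lam1 - k * lam1 ** 2 < 0

    def test_straight_edge_negative_interior(self):
        # vertical step edge: no positive interior corner response
        img = rasterize_curve(np.full(60, 1.0), 0.01)
        img.pixels[:] = 0.0
        img.pixels[:, 30:] = 1.0
        resp = harris_response(img).response
        assert resp[8:-8, 8:-8].max() <= 1e-12

    def test_k_range_enforced(self):
        img = rasterize_curve([0.0, 0.01, 0.03], 0.01)
        with pytest.raises(Exception):
            harris_response(img, k=0.1)

    def test_matches_skimage_harris_ranking(self):
        # independent cross-check: an L-shaped thick region's strongest
        # skimage Harris corner coincides with ours within a pixel or two
        from skimage.feature import corner_harris, corner_peaks
        img = rasterize_curve(np.full(80, 1.0), 0.01)
        px = np.zeros((60, 80))
        px[10:50, 10:20] = 1.0
        px[40:50, 10:70] = 1.0
        img.pixels = px
        ours = harris_response(img).response
        ours_peak = np.unravel_index(np.argmax(ours), ours.shape)
        theirs = corner_peaks(corner_harris(px, k=0.04), min_distance=5)
        d = np.min(np.abs(theirs - np.array(ours_peak)).sum(axis=1))
        assert d <= 3


class TestDetect:
    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        img = rasterize_curve(np.cumsum(rng.uniform(-0.01, 0.03, 80)), 0.01)
        sm = smooth(img, gaussian_kernel(1.0, 9))
        resp = harris_response(sm)
        pts = detect_dominant_points(resp, window=9)
        oracle = brute_force_local_maxima(resp.response, 9)
        oracle_cols = {j for i, j in oracle}
        for doy in pts.doys:
            assert doy in oracle_cols

    def test_oracle_equivalence_on_large_response(self):
        # full-size check: window-maximum mask equals the double-loop scan
        rng = np.random.default_rng(12)
        resp = ndimage.gaussian_filter(rng.normal(size=(200, 500)), 3.0)
        fast = resp >= ndimage.maximum_filter(resp, size=9, mode="reflect")
        brute = brute_force_local_maxima(resp, 9)
        brute_mask = np.zeros(resp.shape, dtype=bool)
        for i, j in brute:
            brute_mask[i, j] = True
        np.testing.assert_array_equal(fast[4:-4, 4:-4], brute_mask[4:-4, 4:-4])

    def test_straight_line_has_no_interior_points(self):
        pts = find_dominant_points(0.01 * np.arange(100), SEASON_START)
        assert len(pts) == 0

    def test_single_break_localized(self):
        series, corners = generate_breakpoint_curve(
            [(0, 0.02), (50, 0.002)], n_days=100)
        pts = find_dominant_points(series, 0)
        assert len(pts) == 1
        assert abs(pts.doys[0] - corners[0]) <= 3

    def test_two_breaks_ordered(self):
        series, corners = generate_breakpoint_curve(
            [(0, 0.002), (30, 0.02), (70, 0.001)], n_days=100)
        pts = find_dominant_points(series, 0)
        assert len(pts) == 2
        assert list(pts.doys) == sorted(pts.doys)
        for p, c in zip(pts.doys, corners):
            assert abs(p - c) <= 3

    def test_double_logistic_points_near_curvature_extrema(self):
        # ground truth: curvature extrema of the analytic curve in the
        # raster geometry (value axis scaled by 1/y_step)
        def dlog(t, A, k1, t1, k2, t2):
            return 0.1 + A * (1 / (1 + np.exp(-k1 * (t - t1)))
                              - 1 / (1 + np.exp(-k2 * (t - t2))))

        rng = np.random.default_rng(1)
        days = np.arange(100.0)
        for _ in range(10):
            args = (rng.uniform(3, 5), rng.uniform(0.2, 0.4),
                    rng.uniform(22, 40), rng.uniform(0.15, 0.3),
                    rng.uniform(65, 82))
            series = dlog(days, *args)
            y_step = auto_y_step(series)
            t = np.linspace(0, 99, 9901)
            y = dlog(t, *args) / y_step
            d1 = np.gradient(y, t)
            d2 = np.gradient(d1, t)
            kappa = np.abs(d2) / (1 + d1 ** 2) ** 1.5
            is_max = (kappa[1:-1] > kappa[:-2]) & (kappa[1:-1] > kappa[2:])
            extrema = t[1:-1][is_max]
            pts = find_dominant_points(series, 0)
            assert len(pts) >= 1
            for p in pts.doys:
                assert min(abs(p - e) for e in extrema) <= 3

    def test_scale_robustness_on_season_curve(self, sim_stressed):
        base = find_dominant_points(sim_stressed.lai, SEASON_START)
        coarse = find_dominant_points(
            sim_stressed.lai, SEASON_START,
            y_step=2 * auto_y_step(sim_stressed.lai))
        assert len(coarse) >= 1
        for p in coarse.doys:
            assert min(abs(p - b) for b in base.doys) <= 3


class TestPngDump:
    def test_curve_and_response_written(self, tmp_path):
        from ricekey.keyperiod import save_image_png
        img = rasterize_curve(0.01 * np.arange(40) ** 1.5, y_step=0.05)
        resp = harris_response(smooth(img, gaussian_kernel(1.0, 9)))
        save_image_png(img, tmp_path / "curve.png")
        save_image_png(resp, tmp_path / "response.png")
        assert (tmp_path / "curve.png").stat().st_size > 0
        assert (tmp_path / "response.png").stat().st_size > 0


class TestRatioAndGrowthRate:
    def test_identical_curves_give_unit_ratio(self, sim_stressed):
        ratio, off = ratio_curve(sim_stressed.lai, sim_stressed.lai)
        np.testing.assert_allclose(ratio, 1.0)

    def test_constant_scaling(self):
        ref = np.linspace(1.0, 5.0, 50)
        ratio, off = ratio_curve(0.8 * ref, ref)
        np.testing.assert_allclose(ratio, 0.8)
        assert off == 0

    def test_low_reference_trimmed(self):
        ref = np.concatenate([[0.01, 0.02], np.linspace(1, 4, 30)])
        ratio, off = ratio_curve(ref * 0.9, ref)
        assert off == 2 and len(ratio) == 30

    def test_all_low_reference_rejected(self):
        with pytest.raises(InputError):
            ratio_curve(np.full(30, 0.01), np.full(30, 0.01))

    def test_growth_rate_telescopes(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(0, 5, 40)
        gr = growth_rate(v)
        assert len(gr) == 39
        assert gr.sum() == pytest.approx(v[-1] - v[0])
        np.testing.assert_allclose(growth_rate(np.full(10, 3.0)), 0.0)
        np.testing.assert_allclose(growth_rate(2.0 * np.arange(5)), 2.0)


class TestScreenAndSelect:
    @staticmethod
    def _points(doys, source="LAI"):
        return DominantPointSet(np.asarray(doys), source,
                                np.full(len(doys), np.nan))

    def test_identical_sets_pass_through(self, sim_stressed):
        gr = growth_rate(sim_stressed.lai)
        pts = self._points([184, 217, 243])
        merged = screen_points(pts, self._points([184, 217, 243], "RATIO"),
                               gr, SEASON_START + 1)
        assert list(merged.doys) == [184, 217, 243]
        assert merged.source == "MERGED"

    def test_equal_rate_change_tie_keeps_lai_point(self):
        gr = np.zeros(99)  # flat growth rate: every change is zero
        merged = screen_points(self._points([200]), self._points([190], "RATIO"),
                               gr, SEASON_START + 1)
        assert list(merged.doys) == [200]

    def test_larger_rate_change_wins(self):
        gr = np.zeros(99)
        gr[35:] = 1.0  # sharp growth-rate step at DOY ~206
        merged = screen_points(self._points([206]), self._points([190], "RATIO"),
                               gr, SEASON_START + 1)
        assert list(merged.doys) == [206]

    def test_distant_points_both_kept(self):
        gr = np.zeros(99)
        merged = screen_points(self._points([180]), self._points([250], "RATIO"),
                               gr, SEASON_START + 1)
        assert list(merged.doys) == [180, 250]

    def test_select_images_prefers_nearest_then_earlier(self):
        assert select_images([195, 204], [199]) == [195]
        assert select_images([194, 204], [199]) == [194]
        assert select_images([184, 211, 241, 260], [184, 211]) == [184, 211]

    def test_select_images_collapses_duplicates(self):
        assert select_images([200], [199, 201]) == [200]


class TestFit:
    def test_points_at_every_day_fit_exactly(self, sim_stressed):
        pts = np.arange(SEASON_START, SEASON_START + 100)
        fitted, r2 = fit_dominant_points(sim_stressed.lai, SEASON_START, pts)
        assert r2 == pytest.approx(1.0)

    def test_linear_series_any_points(self):
        series = 0.05 * np.arange(60) + 1.0
        fitted, r2 = fit_dominant_points(series, 0, [20, 40])
        assert r2 == pytest.approx(1.0)

    def test_single_break_curve_fits_through_break(self):
        series, corners = generate_breakpoint_curve(
            [(0, 0.02), (50, 0.002)], n_days=100)
        _, r2 = fit_dominant_points(series, 0, corners)
        assert r2 > 0.99
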