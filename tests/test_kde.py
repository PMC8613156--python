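"""Kernel density estimation and LSCV bandwidth selection."""

import math

import numpy as np
import pandas as pd
import pytest

from gazeri.exceptions import NoDataError, ParameterError
from gazeri.grid import GridSpec
from gazeri.kde import (
    BandwidthSearch,
    LscvKDE,
    density_for_group,
    gaussian_kde,
    lscv_criterion,
    select_bandwidth,
)


def naive_kde(points, H, xc, yc):
    """Per-pixel, per-point double loop."""
    Hinv = np.linalg.inv(H)
    norm = 1.0 / (2 * math.pi * math.sqrt(np.linalg.det(H)))
    out = np.zeros((len(yc), len(xc)))
    for i, y in enumerate(yc):
        for j, x in enumerate(xc):
            for px, py in points:
                d = np.array([x - px, y - py])
                out[i, j] += math.exp(-0.5 * d @ Hinv @ d)
    return out * norm / len(points)


def naive_lscv(points, H, grid):
    """Brute-force criterion: Riemann sum on the 3-sigma-extended grid plus
    an explicit leave-one-out double loop."""
    pad = int(math.ceil(3.0 * math.sqrt(max(H[0, 0], H[1, 1]))))
    xc = np.arange(-pad, grid.w + pad) + 0.5
    yc = np.arange(-pad, grid.h + pad) + 0.5
    f = naive_kde(points, H, xc, yc)
    riemann = float((f**2).sum())
    N = len(points)
    Hinv = np.linalg.inv(H)
    norm = 1.0 / (2 * math.pi * math.sqrt(np.linalg.det(H)))
    loo_sum = 0.0
    for i in range(N):
        s = 0.0
        for j in range(N):
            if j == i:
                continue
            d = points[i] - points[j]
            s += norm * math.exp(-0.5 * d @ Hinv @ d)
        loo_sum += s / (N - 1)
    return riemann - 2.0 / N * loo_sum


class TestGaussianKde:
    def test_matches_naive_double_loop(self, rng):
        """Fast separable/diagonal path vs the naive triple loop, <= 1e-10."""
        for trial in range(5):
            w, h = int(rng.integers(8, 33)), int(rng.integers(8, 33))
            grid = GridSpec(w, h)
            n = int(rng.integers(2, 21))
            pts = np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])
            if trial % 2 == 0:
                H = np.diag(rng.uniform(1.0, 9.0, 2))
            else:
                a, b = rng.uniform(2.0, 9.0, 2)
                c = rng.uniform(-0.5, 0.5) * math.sqrt(a * b)
                H = np.array([[a, c], [c, b]])
            fast = gaussian_kde(pts, H, grid)
            slow = naive_kde(pts, H, np.arange(w) + 0.5, np.arange(h) + 0.5)
            np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_single_center_point_isotropic(self):
        grid = GridSpec(21, 21)
        v = gaussian_kde(np.array([[10.5, 10.5]]), np.diag([4.0, 4.0]), grid)
        assert np.unravel_index(v.argmax(), v.shape) == (10, 10)
        # proportional to an isotropic Gaussian: log-density is quadratic in r^2
        np.testing.assert_allclose(v, v.T, atol=1e-15)

    def test_symmetric_points_symmetric_map(self):
        grid = GridSpec(20, 20)
        pts = np.array([[5.0, 10.0], [15.0, 10.0]])
        v = gaussian_kde(pts, np.diag([3.0, 3.0]), grid)
        np.testing.assert_allclose(v, v[:, ::-1], atol=1e-12)

    def test_interior_point_mass_close_to_one(self):
        # grid is ~10 sigma wide around the point: Riemann mass ~ 1
        grid = GridSpec(41, 41)
        v = gaussian_kde(np.array([[20.5, 20.5]]), np.diag([4.0, 4.0]), grid)
        assert v.sum() == pytest.approx(1.0, abs=1e-3)

    def test_no_points_rejected(self):
        with pytest.raises(NoDataError):
            gaussian_kde(np.empty((0, 2)), np.eye(2), GridSpec(5, 5))

    @pytest.mark.parametrize(
        "H", [np.array([[1.0, 0.5], [0.4, 1.0]]), np.array([[1.0, 2.0], [2.0, 1.0]])]
    )
    def test_invalid_bandwidth_rejected(self, H):
        with pytest.raises(ParameterError):
            gaussian_kde(np.array([[1.0, 1.0]]), H, GridSpec(5, 5))


class TestLscvCriterion:
    def test_matches_brute_force(self, rng):
        """50 random configurations vs the double-loop oracle, <= 1e-10."""
        for _ in range(50):
            w, h = int(rng.integers(6, 16)), int(rng.integers(6, 16))
            grid = GridSpec(w, h)
            n = int(rng.integers(2, 11))
            pts = np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])
            H = np.diag(rng.uniform(0.5, 6.0, 2))
            assert lscv_criterion(pts, H, grid) == pytest.approx(
                naive_lscv(pts, H, grid), abs=1e-10
            )

    def test_density_estimate_invariant_under_duplication(self):
        grid = GridSpec(16, 16)
        pts = np.array([[4.0, 5.0], [10.0, 11.0], [7.0, 3.0]])
        H = np.diag([2.0, 2.0])
        np.testing.assert_allclose(
            gaussian_kde(pts, H, grid),
            gaussian_kde(np.vstack([pts, pts]), H, grid),
            atol=1e-14,
        )

    def test_undersmoothing_penalized_on_two_clusters(self, rng):
        grid = GridSpec(40, 40)
        c1 = rng.normal([10, 20], 1.5, (15, 2))
        c2 = rng.normal([30, 20], 1.5, (15, 2))
        pts = np.vstack([c1, c2])
        tiny = lscv_criterion(pts, np.diag([0.01, 0.01]), grid)
        moderate = lscv_criterion(pts, np.diag([2.0, 2.0]), grid)
        assert tiny > moderate

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(NoDataError):
            lscv_criterion(np.array([[1.0, 1.0]]), np.eye(2), GridSpec(5, 5))


class TestSelectBandwidth:
    def test_gaussian_data_near_reference_rate(self, rng):
        """N = 200 Gaussian draws: selected stds within a factor 3 of the
        plug-in reference sigma * N**(-1/6)."""
        grid = GridSpec(60, 60)
        sigma = 6.0
        pts = rng.normal(30.0, sigma, (200, 2))
        H = select_bandwidth(pts, grid, BandwidthSearch(n_per_axis=9))
        ref = sigma * 200 ** (-1 / 6)
        for hii in (H[0, 0], H[1, 1]):
            assert ref / 3 <= math.sqrt(hii) <= ref * 3

    def test_matches_exhaustive_grid_minimum(self, rng):
        grid = GridSpec(24, 24)
        pts = rng.uniform(2, 22, (25, 2))
        search = BandwidthSearch(n_per_axis=10, refine=False)
        H = select_bandwidth(pts, grid, search)
        # independent exhaustive scan over the same candidate family
        sx_pilot = pts[:, 0].std(ddof=1) * 25 ** (-1 / 6)
        sy_pilot = pts[:, 1].std(ddof=1) * 25 ** (-1 / 6)
        mult = np.geomspace(0.25, 4.0, 10)
        best, best_val = None, np.inf
        for sx in sx_pilot * mult:
            for sy in sy_pilot * mult:
                v = lscv_criterion(pts, np.diag([sx**2, sy**2]), grid)
                if v < best_val:
                    best, best_val = np.diag([sx**2, sy**2]), v
        np.testing.assert_allclose(H, best, rtol=1e-12)

    def test_affine_equivariance_under_scaling(self, rng):
        c = 2
        grid = GridSpec(20, 20)
        pts = rng.uniform(3, 17, (30, 2))
        search = BandwidthSearch(n_per_axis=8, refine=False)
        H1 = select_bandwidth(pts, grid, search)
        H2 = select_bandwidth(pts * c, GridSpec(20 * c, 20 * c), search)
        np.testing.assert_allclose(H2, H1 * c**2, rtol=0.05)

    def test_degenerate_points_guidance(self):
        pts = np.tile([[5.0, 5.0]], (10, 1))
        with pytest.raises(NoDataError, match="fixed-bandwidth"):
            select_bandwidth(pts, GridSpec(10, 10))

    def test_deterministic(self, rng):
        grid = GridSpec(18, 18)
        pts = rng.uniform(2, 16, (20, 2))
        search = BandwidthSearch(n_per_axis=6)
        np.testing.assert_array_equal(
            select_bandwidth(pts, grid, search), select_bandwidth(pts, grid, search)
        )


def _gaze_table(points_by_group, frame_index=0):
    rows = []
    for g, pts in points_by_group.items():
        for i, (x, y) in enumerate(pts):
            rows.append(
                {"participant": f"{g}{i}", "group": g, "frame_index": frame_index,
                 "x_stim": x, "y_stim": y}
            )
    return pd.DataFrame(rows)


class TestDensityForGroup:
    def test_density_sums_to_one(self, rng):
        grid = GridSpec(30, 24)
        pts = np.column_stack([rng.uniform(4, 26, 30), rng.uniform(4, 20, 30)])
        gaze = _gaze_table({"g": pts})
        d = density_for_group(gaze, 0, "g", grid, search=BandwidthSearch(6, refine=False))
        assert d.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert d.n_points == 30
        assert d.mass <= 1.0 + 1e-6

    def test_groups_get_independent_bandwidths(self, rng):
        grid = GridSpec(30, 24)
        a = np.column_stack([rng.uniform(2, 28, 25), rng.uniform(2, 22, 25)])
        b = np.column_stack([rng.normal(15, 1.0, 25), rng.normal(12, 1.0, 25)])
        gaze = _gaze_table({"a": a, "b": b})
        search = BandwidthSearch(8, refine=False)
        da = density_for_group(gaze, 0, "a", grid, search=search)
        db = density_for_group(gaze, 0, "b", grid, search=search)
        assert not np.allclose(da.bandwidth, db.bandwidth)

    def test_too_few_points_skips_or_falls_back(self):
        grid = GridSpec(10, 10)
        gaze = _gaze_table({"g": [(5.0, 5.0)]})
        assert density_for_group(gaze, 0, "g", grid) is None
        d = density_for_group(
            gaze, 0, "g", grid, policy="fixed", fixed_bandwidth=np.diag([2.0, 2.0])
        )
        assert d is not None
        np.testing.assert_array_equal(d.bandwidth, np.diag([2.0, 2.0]))

    def test_concentrated_fixations_concentrate_mass(self, rng):
        """All fixations inside a box -> nearly all mass within the box
        dilated by 3 bandwidth standard deviations."""
        grid = GridSpec(40, 32)
        pts = np.column_stack([rng.uniform(10, 18, 40), rng.uniform(8, 14, 40)])
        gaze = _gaze_table({"g": pts})
        d = density_for_group(gaze, 0, "g", grid, search=BandwidthSearch(8, refine=False))
        r = 3 * math.sqrt(max(d.bandwidth[0, 0], d.bandwidth[1, 1]))
        x0, x1 = int(max(0, 10 - r)), int(min(40, 18 + r))
        y0, y1 = int(max(0, 8 - r)), int(min(32, 14 + r))
        assert d.values[y0:y1, x0:x1].sum() >= 0.95


class TestSmoothingMonotonicity:
    def test_pixel_variance_decreases_with_bandwidth(self, rng):
        """The smoother the estimate, the flatter the map."""
        grid = GridSpec(32, 32)
        pts = np.column_stack([rng.uniform(4, 28, 20), rng.uniform(4, 28, 20)])
        variances = [
            gaussian_kde(pts, np.diag([s**2, s**2]), grid).var()
            for s in (0.5, 1.0, 2.0, 4.0, 8.0)
        ]
        assert all(a > b for a, b in zip(variances, variances[1:]))


class TestLscvKdeEstimator:
    def test_sklearn_protocol(self, rng):
        grid = GridSpec(20, 20)
        est = LscvKDE(grid, search=BandwidthSearch(5, refine=False))
        pts = rng.uniform(2, 18, (15, 2))
        assert est.fit(pts) is est
        assert est.bandwidth_.shape == (2, 2)
        assert est.n_points_ == 15
        params = est.get_params()
        assert params["grid"] is grid
        m = est.density_map(frame_index=3, group="t")
        assert m.frame_index == 3 and m.group == "t"
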