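"""Design stacking, standardization, LASSO path, BIC selection, RI curves."""

import math

import numpy as np
import pytest

from gazeri.exceptions import InputError
from gazeri.features import AoiPolygon, FeatureMap, aoi_map, center_bias_map, uniform_map
from gazeri.grid import GridSpec
from gazeri.model import (
    LassoBIC,
    FrameFit,
    bic_score,
    count_nonzero,
    default_lambda_grid,
    fit_frame,
    lasso_path,
    ri_curves,
    select_by_bic,
    stack_maps,
    stack_multigroup,
    standardize,
)

GRID = GridSpec(20, 16)


def box(label, x0, y0, x1, y1, grid=GRID, frame=0):
    m = aoi_map(AoiPolygon(label, frame, ((x0, y0), (x1, y0), (x1, y1), (x0, y1))), grid)
    return FeatureMap(m.name, frame, m.values)


def feature_set(grid=GRID):
    return [
        uniform_map(grid),
        center_bias_map(grid),
        box("A", 1, 1, 6, 6, grid),
        box("B", 13, 9, 19, 15, grid),
    ]


class TestStacking:
    def test_shapes_and_order(self):
        grid = GridSpec(2, 2)
        maps = [uniform_map(grid)] * 3
        d = stack_maps(maps, np.full((2, 2), 0.25))
        assert d.X.shape == (4, 3)
        assert d.y.shape == (4,)

    def test_row_major_unstack_roundtrip(self, rng):
        vals = rng.uniform(0, 1, GRID.shape)
        vals /= vals.sum()
        d = stack_maps([FeatureMap("custom:x", 0, vals)], vals)
        np.testing.assert_array_equal(d.X[:, 0].reshape(GRID.shape), vals)
        np.testing.assert_array_equal(d.y.reshape(GRID.shape), vals)

    def test_two_group_block_structure(self, rng):
        maps = feature_set()
        yT = rng.dirichlet(np.ones(GRID.n_pixels)).reshape(GRID.shape)
        yC = rng.dirichlet(np.ones(GRID.n_pixels)).reshape(GRID.shape)
        d = stack_multigroup(maps, maps, yT, yC)
        n = GRID.n_pixels
        assert d.X.shape == (2 * n, 8)
        # treatment block first: dummy 1 there, 0 on the control block
        np.testing.assert_array_equal(d.group_dummy[:n], 1.0)
        np.testing.assert_array_equal(d.group_dummy[n:], 0.0)
        # interaction columns are elementwise products with the dummy
        for k in range(4):
            np.testing.assert_array_equal(d.X[:, 4 + k], d.X[:, k] * d.group_dummy)
        assert d.labels[4:] == [m.name + ":G" for m in maps]

    def test_label_mismatch_rejected(self, rng):
        y = rng.uniform(0.1, 1, GRID.shape)
        with pytest.raises(InputError):
            stack_multigroup(feature_set(), feature_set()[::-1], y, y)


class TestStandardize:
    def _design(self, rng):
        maps = feature_set()
        yT = 0.5 * maps[2].values + 0.5 * maps[1].values
        yC = 0.3 * maps[3].values + 0.7 * maps[1].values
        return stack_multigroup(maps, maps, yT, yC)

    def test_zero_mean_unit_sd_per_block(self, rng):
        d = self._design(rng)
        std, record = standardize(d)
        for g, sl in std.blocks:
            assert abs(std.y[sl].mean()) < 1e-12
            assert abs(std.y[sl].std() - 1) < 1e-12
            for j, lab in enumerate(std.labels):
                if ":G" in lab:
                    continue
                col = std.X[sl, j]
                assert abs(col.mean()) < 1e-12, (g, lab)
                assert abs(col.std() - 1) < 1e-12, (g, lab)

    def test_uniform_column_absorbed(self, rng):
        d = self._design(rng)
        std, record = standardize(d)
        assert "uniform" in record.dropped
        assert "uniform" not in std.labels
        assert "uniform:G" not in std.labels

    def test_interactions_built_after_standardization(self, rng):
        d = self._design(rng)
        std, _ = standardize(d)
        dummy = d.group_dummy
        for j, lab in enumerate(std.labels):
            if lab.endswith(":G"):
                base = std.labels.index(lab[:-2])
                np.testing.assert_array_equal(std.X[:, j], std.X[:, base] * dummy)

    def test_destandardized_betas_reproduce_predictions(self, rng):
        """Raw-scale betas from the scaling record give the same predictions
        as the standardized fit, block by block."""
        d = self._design(rng)
        std, record = standardize(d)
        beta, *_ = np.linalg.lstsq(std.X, std.y, rcond=None)
        fit = FrameFit(
            frame_index=0, groups=[g for g, _ in d.blocks],
            base_labels=[m.name for m in feature_set()], labels=std.labels,
            beta=beta, lambda_=0.0, bic=0.0, r2_adj=1.0,
            n_nonzero=count_nonzero(beta), record=record,
        )
        raw = fit.raw_weights()
        pred_std = std.X @ beta
        labels_main = [m.name for m in feature_set()]
        cols = {lab: d.X[:, i] for i, lab in enumerate(d.labels) if ":G" not in lab}
        for g, sl in d.blocks:
            y_mu, y_sd = record.y_stats[g]
            pred_raw = np.zeros(sl.stop - sl.start)
            for lab in labels_main:
                pred_raw += raw[g][lab] * cols[lab][sl]
            np.testing.assert_allclose(pred_raw, y_mu + y_sd * pred_std[sl], atol=1e-8)


def random_orthonormal(rng, n, p):
    q, _ = np.linalg.qr(rng.standard_normal((n, p)))
    return q[:, :p]


class TestLassoPath:
    def test_orthonormal_design_soft_thresholds(self, rng):
        """Closed-form soft-threshold oracle across 100 random instances."""
        for _ in range(100):
            n, p = 40, 5
            X = random_orthonormal(rng, n, p)
            y = rng.standard_normal(n)
            b_ols = X.T @ y
            lambdas = np.array([2.0, 0.8, 0.2, 0.05])
            path = lasso_path(X, y, lambdas)
            for lam, beta in zip(lambdas, path):
                oracle = np.sign(b_ols) * np.maximum(np.abs(b_ols) - lam / 2, 0.0)
                np.testing.assert_allclose(beta, oracle, atol=1e-8)

    def test_zero_lambda_is_least_squares(self, rng):
        X = rng.standard_normal((60, 4))
        y = rng.standard_normal(60)
        beta = lasso_path(X, y, np.array([0.0]))[0]
        expected, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(beta, expected, atol=1e-8)

    def test_kkt_threshold_zeroes_everything(self, rng):
        X = rng.standard_normal((50, 4))
        y = rng.standard_normal(50)
        lam_max = 2.0 * np.abs(X.T @ y).max()
        beta = lasso_path(X, y, np.array([lam_max]))[0]
        np.testing.assert_allclose(beta, 0.0, atol=1e-10)

    def test_non_descending_grid_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(InputError):
            lasso_path(X, rng.standard_normal(10), np.array([0.1, 1.0]))


class TestBicSelection:
    def test_independent_formula(self, rng):
        X = rng.standard_normal((80, 3))
        y = rng.standard_normal(80)
        lambdas = default_lambda_grid(X, y, n_lambdas=10)
        path = lasso_path(X, y, lambdas)
        idx, bics = select_by_bic(path, lambdas, X, y)
        for i, beta in enumerate(path):
            rss = float(((y - X @ beta) ** 2).sum())
            k = count_nonzero(beta)
            sigma2 = rss / 80
            oracle = 80 * math.log(2 * math.pi * sigma2) + 80 + k * math.log(80)
            assert bics[i] == pytest.approx(oracle, abs=1e-8)
        assert bics[idx] == bics.min()

    def test_prefers_true_sparse_model(self, rng):
        """With n >> K the BIC picks the true support over the overfit OLS."""
        wins = 0
        for _ in range(20):
            n = 500
            X = rng.standard_normal((n, 6))
            y = X[:, 1] * 2.0 - X[:, 3] * 1.5 + rng.normal(0, 0.5, n)
            sparse = np.zeros(6)
            sub, *_ = np.linalg.lstsq(X[:, [1, 3]], y, rcond=None)
            sparse[[1, 3]] = sub
            full, *_ = np.linalg.lstsq(X, y, rcond=None)
            idx, _ = select_by_bic(
                np.vstack([sparse, full]), np.array([1.0, 0.0]), X, y
            )
            wins += idx == 0
        assert wins >= 18

    def test_single_element_path(self, rng):
        X = rng.standard_normal((30, 2))
        y = rng.standard_normal(30)
        idx, bics = select_by_bic(np.zeros((1, 2)), np.array([5.0]), X, y)
        assert idx == 0 and len(bics) == 1

    def test_ties_break_toward_larger_lambda(self):
        X = np.eye(4)
        y = np.zeros(4)
        path = np.zeros((3, 4))  # identical fits
        idx, _ = select_by_bic(path, np.array([3.0, 1.0, 0.0]), X, y)
        assert idx == 0


class TestFitFrame:
    def test_noiseless_mixture_recovered_exactly(self):
        maps = feature_set()
        Y = 0.7 * maps[2].values + 0.3 * maps[1].values  # aoi:A and center_bias
        fit = fit_frame(Y, maps, frame_index=0)
        assert fit.r2_adj == pytest.approx(1.0, abs=1e-6)
        raw = fit.raw_weights()
        g = fit.groups[0]
        assert raw[g]["aoi:A"] == pytest.approx(0.7, abs=1e-6)
        assert raw[g]["center_bias"] == pytest.approx(0.3, abs=1e-6)
        assert abs(raw[g]["aoi:B"]) < 1e-6
        betas = fit.beta_dict()
        assert abs(betas["aoi:B"]) <= 1e-10
        assert betas["uniform"] == 0.0

    def test_uninformative_response_selects_nothing(self, rng):
        maps = feature_set()
        Y = uniform_map(GRID).values * (1 + 1e-3 * rng.standard_normal(GRID.shape))
        fit = fit_frame(Y, maps, frame_index=0)
        assert fit.n_nonzero == 0
        assert abs(fit.r2_adj) < 0.05

    def test_block_equivalence_two_group_ols(self, rng):
        """At lambda = 0 with per-group standardization the stacked fit
        reproduces both separate single-group OLS fits."""
        maps = feature_set()
        yT = 0.55 * maps[2].values + 0.25 * maps[1].values + 0.20 * maps[3].values
        yC = 0.20 * maps[2].values + 0.40 * maps[1].values + 0.40 * maps[3].values
        both = fit_frame((yT, yC), (maps, maps), frame_index=0, lambdas=[0.0])
        w = both.group_weights()
        for y_one, group in ((yT, "treatment"), (yC, "control")):
            solo = fit_frame(y_one, maps, frame_index=0, lambdas=[0.0])
            w_solo = solo.group_weights()[solo.groups[0]]
            for lab in solo.base_labels:
                assert w[group][lab] == pytest.approx(w_solo[lab], abs=1e-8)

    def test_irrelevant_features_shrunk_to_zero(self, rng):
        """Simulate N = 2000 fixations from 2 of 6 maps; the selected support
        should equal the true pair in most replicates.  The response is the
        empirical fixation histogram, so deviations from the true mixture are
        pure multinomial noise."""
        grid = GridSpec(30, 24)
        maps = [
            uniform_map(grid),
            center_bias_map(grid),
            box("A", 1, 1, 8, 8, grid),
            box("B", 22, 16, 29, 23, grid),
            box("C", 22, 1, 29, 8, grid),
            box("D", 1, 16, 8, 23, grid),
        ]
        true_density = 0.6 * maps[2].values + 0.4 * maps[1].values
        flat = true_density.ravel()
        hits = 0
        reps = 25
        for _ in range(reps):
            counts = rng.multinomial(2000, flat)
            Y = (counts / 2000.0).reshape(grid.shape)
            fit = fit_frame(Y, maps, frame_index=0)
            support = {
                lab for lab, val in fit.beta_dict().items() if abs(val) > 1e-10
            }
            hits += support == {"aoi:A", "center_bias"}
        assert hits >= 0.8 * reps

    def test_sparsistency_trend_along_path(self, rng):
        """Averaged over replicates, the share of correctly-zeroed irrelevant
        features does not decrease with lambda."""
        maps = feature_set()
        true_density = 0.6 * maps[2].values + 0.4 * maps[1].values
        flat = true_density.ravel()
        irrelevant = ["aoi:B"]
        probes = [0, 30, 60, 90, 100]  # descending-lambda path indices
        freq = np.zeros(len(probes))
        reps = 20
        from gazeri.kde import LscvKDE
        from gazeri.model import DesignMatrix, default_lambda_grid, stack_maps

        for _ in range(reps):
            idx = rng.choice(flat.size, size=800, p=flat)
            iy, ix = np.divmod(idx, GRID.w)
            pts = np.column_stack([ix + rng.random(800), iy + rng.random(800)])
            Y = LscvKDE(GRID, bandwidth=np.diag([3.0, 3.0])).fit(pts).density_map()
            std, record = standardize(stack_maps(maps, Y))
            lambdas = default_lambda_grid(std.X, std.y)
            path = lasso_path(std.X, std.y, lambdas)
            for pi, probe in enumerate(probes):
                beta = dict(zip(std.labels, path[probe]))
                freq[pi] += all(abs(beta[lab]) <= 1e-10 for lab in irrelevant)
        freq /= reps
        assert all(a >= b - 0.1 for a, b in zip(freq, freq[1:]))


class TestRICurves:
    def test_normalization_and_control_identity(self):
        maps = feature_set()
        yT = 0.5 * maps[2].values + 0.5 * maps[1].values
        yC = 0.25 * maps[2].values + 0.75 * maps[1].values
        fits = [
            fit_frame((yT, yC), (maps, maps), frame_index=f, lambdas=[0.0])
            for f in (0, 1)
        ]
        ri = ri_curves(fits)
        betas = fits[0].beta_dict()
        for lab in fits[0].base_labels:
            assert ri.curves["control"].loc[0, lab] == betas[lab]
        ri_norm = ri_curves(fits, normalize=True)
        for g, df in ri_norm.curves.items():
            assert abs(df.loc[0].abs().sum() - 1.0) < 1e-9

    def test_skipped_frames_flagged(self):
        maps = feature_set()
        Y = 0.5 * maps[2].values + 0.5 * maps[1].values
        fits = [fit_frame(Y, maps, frame_index=0), FrameFit.skip(1, "no data")]
        ri = ri_curves(fits)
        assert ri.skipped == [1]
        assert list(ri.curves[fits[0].groups[0]].index) == [0]
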