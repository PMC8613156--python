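"""Eye-position density maps by bivariate kernel density estimation.

For each frame and each group, the fixation coordinates of all participants
are pooled and smoothed with a scaled bivariate Gaussian kernel

    K_H(x) = (2 pi)^-1 |H|^(-1/2) exp(-x' H^-1 x / 2),

where ``H`` is a symmetric positive-definite 2x2 bandwidth matrix in squared
pixels.  The bandwidth is selected per frame and per group by minimizing the
least-squares cross-validation criterion

    LSCV(H) = int f_hat(x; H)^2 dx  -  (2/N) sum_i f_hat_{-i}(X_i; H),

whose second term uses the exact leave-one-out estimator.  The squared-density
integral is taken as a Riemann sum over the pixel grid extended by three
standard deviations beyond the stimulus box, so boundary mass is not lost; for
diagonal ``H`` the sum is evaluated through a separable Gram-matrix identity
that is algebraically equal to the naive per-pixel sum.

The search family is restricted to diagonal ``H`` (a log-spaced candidate grid
around a plug-in pilot bandwidth, optionally refined by Nelder-Mead); full
unconstrained LSCV is ill-conditioned at the few dozen points available per
frame.  No boundary correction is applied to the estimate itself; for the
regression stage the map is renormalized to sum 1 over the stimulus grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import NoDataError, ParameterError
from .grid import GridSpec

__all__ = [
    "BandwidthSearch",
    "EyePositionDensityMap",
    "LscvKDE",
    "gaussian_kde",
    "lscv_criterion",
    "select_bandwidth",
    "density_for_group",
]


def validate_bandwidth(H: np.ndarray) -> np.ndarray:
    """Check symmetry (1e-12) and positive definiteness of a 2x2 bandwidth."""
    H = np.asarray(H, dtype=float)
    if H.shape != (2, 2):
        raise ParameterError(f"bandwidth must be 2x2, got {H.shape}")
    if abs(H[0, 1] - H[1, 0]) > 1e-12:
        raise ParameterError("bandwidth matrix must be symmetric")
    ev = np.linalg.eigvalsh(H)
    if ev.min() <= 0:
        raise ParameterError(f"bandwidth matrix must be positive definite (eigenvalues {ev})")
    return H


@dataclass(frozen=True)
class EyePositionDensityMap:
    """KDE-derived density grid for one frame and one group.

    ``values`` sums to 1 over the grid (renormalized for modeling); ``mass``
    is the pre-renormalization Riemann mass on the stimulus box, at most 1 up
    to discretization (the remainder fell off-grid).
    """

    frame_index: int
    group: str
    values: np.ndarray
    n_points: int
    bandwidth: np.ndarray
    mass: float


def _centers(n: int, pad: int) -> np.ndarray:
    return np.arange(-pad, n + pad, dtype=float) + 0.5


def _kde_on_centers(points: np.ndarray, H: np.ndarray, xc: np.ndarray, yc: np.ndarray) -> np.ndarray:
    """Average of N scaled Gaussian kernels at grid center cross product."""
    N = len(points)
    if abs(H[0, 1]) <= 1e-300:  # diagonal: separable product of 1-D normals
        hx, hy = H[0, 0], H[1, 1]
        kx = np.exp(-0.5 * (xc[None, :] - points[:, 0, None]) ** 2 / hx) / math.sqrt(
            2 * math.pi * hx
        )
        ky = np.exp(-0.5 * (yc[None, :] - points[:, 1, None]) ** 2 / hy) / math.sqrt(
            2 * math.pi * hy
        )
        return (ky.T @ kx) / N
    Hinv = np.linalg.inv(H)
    norm = 1.0 / (2 * math.pi * math.sqrt(np.linalg.det(H)))
    out = np.zeros((len(yc), len(xc)))
    dxg, dyg = np.meshgrid(xc, yc)
    for px, py in points:
        dx, dy = dxg - px, dyg - py
        q = Hinv[0, 0] * dx * dx + 2 * Hinv[0, 1] * dx * dy + Hinv[1, 1] * dy * dy
        out += np.exp(-0.5 * q)
    return out * (norm / N)


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError(f"points must be (N, 2), got shape {pts.shape}")
    return pts


def gaussian_kde(points, H, grid: GridSpec) -> np.ndarray:
    """Evaluate the kernel density estimate at the grid's pixel centers.

    Returns the raw density (h, w); the Riemann mass ``values.sum() * 1`` may
    be below 1 when kernels overlap the grid boundary.
    """
    pts = _as_points(points)
    if len(pts) == 0:
        raise NoDataError("kernel density estimation needs at least one point")
    H = validate_bandwidth(H)
    return _kde_on_centers(pts, H, _centers(grid.w, 0), _centers(grid.h, 0))


def _pad_for(H: np.ndarray) -> int:
    return int(math.ceil(3.0 * math.sqrt(max(H[0, 0], H[1, 1]))))


def lscv_criterion(points, H, grid: GridSpec) -> float:
    """Least-squares cross-validation score of a candidate bandwidth.

    The integral term is a Riemann sum (pixel area 1) over the grid extended
    by three marginal standard deviations; the leave-one-out term is exact.
    """
    pts = _as_points(points)
    N = len(pts)
    if N < 2:
        raise NoDataError("LSCV needs at least two points (leave-one-out undefined)")
    H = validate_bandwidth(H)
    pad = _pad_for(H)
    f = _kde_on_centers(pts, H, _centers(grid.w, pad), _centers(grid.h, pad))
    riemann = float(np.sum(f * f))  # pixel area = 1

    dx = pts[:, 0, None] - pts[None, :, 0]
    dy = pts[:, 1, None] - pts[None, :, 1]
    if abs(H[0, 1]) <= 1e-300:
        q = dx * dx / H[0, 0] + dy * dy / H[1, 1]
    else:
        Hinv = np.linalg.inv(H)
        q = Hinv[0, 0] * dx * dx + 2 * Hinv[0, 1] * dx * dy + Hinv[1, 1] * dy * dy
    K = np.exp(-0.5 * q) / (2 * math.pi * math.sqrt(np.linalg.det(H)))
    np.fill_diagonal(K, 0.0)
    loo = K.sum(axis=1) / (N - 1)
    return riemann - 2.0 / N * float(loo.sum())


@dataclass(frozen=True)
class BandwidthSearch:
    """Candidate family for the diagonal LSCV bandwidth search.

    ``span`` multiplies the per-axis plug-in pilot standard deviation
    (``sigma_hat * N**(-1/6)``); ``n_per_axis`` log-spaced candidates per axis
    form the grid; ``refine`` runs a Nelder-Mead polish from the grid argmin.
    Deterministic throughout (no randomness).
    """

    n_per_axis: int = 15
    span: tuple[float, float] = (0.25, 4.0)
    refine: bool = True
    refine_maxiter: int = 60

    def __post_init__(self) -> None:
        if self.n_per_axis < 2:
            raise ParameterError("need at least 2 candidates per axis")
        if not (0 < self.span[0] < self.span[1]):
            raise ParameterError(f"bad span {self.span}")


def _pilot_stds(pts: np.ndarray) -> tuple[float, float]:
    N = len(pts)
    sx, sy = pts[:, 0].std(ddof=1 if N > 1 else 0), pts[:, 1].std(ddof=1 if N > 1 else 0)
    if sx <= 0 or sy <= 0:
        raise NoDataError(
            "points are degenerate along an axis; LSCV bandwidth selection is "
            "impossible — use the fixed-bandwidth fallback policy"
        )
    factor = N ** (-1.0 / 6.0)  # bivariate plug-in rate
    return sx * factor, sy * factor


def select_bandwidth(points, grid: GridSpec, search: BandwidthSearch | None = None) -> np.ndarray:
    """Diagonal bandwidth minimizing the LSCV criterion over the search family."""
    pts = _as_points(points)
    if len(pts) < 2:
        raise NoDataError("bandwidth selection needs at least two points")
    if search is None:
        search = BandwidthSearch()
    px, py = _pilot_stds(pts)
    mult = np.geomspace(search.span[0], search.span[1], search.n_per_axis)
    cand_x = px * mult
    cand_y = py * mult
    best, best_val = None, math.inf
    for sx in cand_x:
        for sy in cand_y:
            val = lscv_criterion(pts, np.diag([sx * sx, sy * sy]), grid)
            if val < best_val:
                best, best_val = (sx, sy), val
    assert best is not None
    if search.refine:
        from scipy.optimize import minimize

        def objective(u):
            sx, sy = math.exp(u[0]), math.exp(u[1])
            return lscv_criterion(pts, np.diag([sx * sx, sy * sy]), grid)

        res = minimize(
            objective,
            x0=[math.log(best[0]), math.log(best[1])],
            method="Nelder-Mead",
            options={"maxiter": search.refine_maxiter, "xatol": 1e-3, "fatol": 0.0},
        )
        if res.fun < best_val:
            best = (math.exp(res.x[0]), math.exp(res.x[1]))
    return np.diag([best[0] ** 2, best[1] ** 2])


class LscvKDE(BaseEstimator):
    """Bivariate kernel density estimator with LSCV-selected diagonal bandwidth.

    Parameters
    ----------
    grid : GridSpec
        Stimulus pixel grid the density is evaluated on.
    search : BandwidthSearch, optional
        Candidate family for the bandwidth search; defaults documented there.
    bandwidth : array-like (2, 2), optional
        Fixed bandwidth; when given, no selection is performed (the
        fixed-bandwidth fallback).

    Attributes
    ----------
    bandwidth_ : ndarray (2, 2)
        Selected (or fixed) bandwidth matrix, squared pixels.
    n_points_ : int
        Number of fixation points used.
    """

    def __init__(self, grid: GridSpec, search: BandwidthSearch | None = None, bandwidth=None):
        self.grid = grid
        self.search = search
        self.bandwidth = bandwidth

    def fit(self, X, y=None) -> "LscvKDE":
        pts = _as_points(X)
        if self.bandwidth is not None:
            if len(pts) < 1:
                raise NoDataError("kernel density estimation needs at least one point")
            self.bandwidth_ = validate_bandwidth(self.bandwidth)
        else:
            self.bandwidth_ = select_bandwidth(pts, self.grid, self.search)
        self.points_ = pts
        self.n_points_ = len(pts)
        return self

    def evaluate(self) -> np.ndarray:
        """Raw density at pixel centers (may sum to < 1 near boundaries)."""
        return gaussian_kde(self.points_, self.bandwidth_, self.grid)

    def density_map(self, frame_index: int = 0, group: str = "") -> EyePositionDensityMap:
        """Density renormalized to sum 1 over the grid, for the regression."""
        raw = self.evaluate()
        mass = float(raw.sum())
        if mass <= 0:
            raise NoDataError("density map has zero mass on the grid")
        return EyePositionDensityMap(
            frame_index=frame_index,
            group=group,
            values=raw / mass,
            n_points=self.n_points_,
            bandwidth=self.bandwidth_,
            mass=mass,
        )


def density_for_group(
    gaze: pd.DataFrame,
    frame_index: int,
    group: str,
    grid: GridSpec,
    policy: str = "skip",
    fixed_bandwidth=None,
    search: BandwidthSearch | None = None,
) -> EyePositionDensityMap | None:
    """Per-frame, per-group density map with independently selected bandwidth.

    ``policy="skip"`` (default) runs LSCV selection and returns None for
    cells with fewer than two usable points, so the caller records a skipped
    frame.  ``policy="fixed"`` with a ``fixed_bandwidth`` disables selection
    entirely and smooths with the given matrix (the fixed-bandwidth mode,
    also used as the fallback for degenerate cells).
    """
    if policy not in ("skip", "fixed"):
        raise ParameterError(f"unknown policy {policy!r}")
    sel = gaze[(gaze["frame_index"] == frame_index) & (gaze["group"] == group)]
    pts = sel[["x_stim", "y_stim"]].to_numpy(dtype=float)
    if policy == "fixed" and fixed_bandwidth is not None:
        # fixed-bandwidth mode: no per-cell selection at all
        if len(pts) == 0:
            return None
        return LscvKDE(grid, bandwidth=fixed_bandwidth).fit(pts).density_map(
            frame_index, group
        )
    if len(pts) < 2:
        if policy == "skip" or len(pts) == 0:
            return None
        if fixed_bandwidth is None:
            raise ParameterError("policy 'fixed' requires fixed_bandwidth")
        est = LscvKDE(grid, bandwidth=fixed_bandwidth).fit(pts)
        return est.density_map(frame_index, group)
    try:
        est = LscvKDE(grid, search=search).fit(pts)
    except NoDataError:  # degenerate spread along an axis

        if policy == "fixed" and fixed_bandwidth is not None:
            est = LscvKDE(grid, bandwidth=fixed_bandwidth).fit(pts)
        else:
            return None
    return est.density_map(frame_index, group)
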