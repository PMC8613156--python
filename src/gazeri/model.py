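"""Master-saliency decomposition of eye-position density maps.

Per frame, the group-level eye-position density map ``Y`` is modeled as a
linear combination of feature maps,

    Y = sum_k beta_k M_k + eps,

with all maps flattened to vectors of length ``n = w*h`` in row-major pixel
order.  The weights are estimated by the LASSO,

    beta(lambda) = argmin ||Y - sum_k beta_k M_k||^2 + lambda sum_k |beta_k|,

along a descending lambda path, and the reported fit is the one minimizing
the Bayesian Information Criterion

    BIC = -2 log L + K log n,

with Gaussian likelihood (variance RSS/n) and K the number of nonzero
weights (the unbiased LASSO degrees of freedom).  At ``lambda = 0`` the fit
is ordinary least squares; above ``2 * max|X'y|`` all weights are zero.

Two or more groups share one design: the response stacks the per-group
density maps (treatment block first), a group dummy is interacted with every
feature column, and the interaction weights ``beta_{k,G}`` measure how much a
feature's importance differs between groups.  Maps and response are centered
and standardized separately within each group block, so a group with an
overall stronger density peak cannot masquerade as a feature effect.

The uniform map deserves a note: after centering, a constant column is
identically zero and unidentifiable, so in standardized fits it is absorbed
by the (zero) intercept of the centered model and reported with weight 0 —
matching its diagnostic role as the catch-all that *should* carry no weight.
Raw-scale weights, including a raw uniform weight, can be recovered from the
standardization record.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import GeometryError, InputError, ParameterError
from .features import FeatureMap
from .kde import EyePositionDensityMap

INTERACTION_SUFFIX = ":G"


def _is_interaction(label: str) -> bool:
    return label.endswith(INTERACTION_SUFFIX) or ":G[" in label


def _flatten(values: np.ndarray) -> np.ndarray:
    return np.asarray(values, dtype=float).ravel(order="C")


def _map_values(obj) -> np.ndarray:
    if isinstance(obj, (FeatureMap, EyePositionDensityMap)):
        return obj.values
    return np.asarray(obj, dtype=float)


@dataclass
class DesignMatrix:
    """Stacked regression design for one frame.

    ``blocks`` lists ``(group_label, row_slice)`` in stacking order (treatment
    block(s) first, reference group last).  ``labels`` orders the columns:
    main effects first, then interaction columns suffixed ``":G"`` (two
    groups) or ``":G[<group>]"`` (more).  ``group_dummy`` is the 0/1 indicator
    of the first non-reference block (the M_G dummy in the two-group model).
    """

    X: np.ndarray
    y: np.ndarray
    labels: list[str]
    blocks: list[tuple[str, slice]]
    interaction_groups: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def group_dummy(self) -> np.ndarray:
        d = np.zeros(self.n)
        if self.interaction_groups:
            g = self.interaction_groups[0]
            for label, sl in self.blocks:
                if label == g:
                    d[sl] = 1.0
        return d


def _check_same_grid(vectors: list[np.ndarray]) -> int:
    shapes = {v.shape for v in vectors}
    if len(shapes) != 1:
        raise GeometryError(f"maps/response have mismatched shapes: {shapes}")
    return vectors[0].size


def stack_maps(maps: list[FeatureMap], Y) -> DesignMatrix:
    """Single-group design: one column per map, rows in row-major pixel order."""
    if not maps:
        raise InputError("need at least one feature map")
    arrays = [_map_values(m) for m in maps] + [_map_values(Y)]
    _check_same_grid(arrays)
    X = np.column_stack([_flatten(a) for a in arrays[:-1]])
    y = _flatten(arrays[-1])
    group = Y.group if isinstance(Y, EyePositionDensityMap) and Y.group else "group"
    return DesignMatrix(
        X=X,
        y=y,
        labels=[m.name for m in maps],
        blocks=[(group, slice(0, len(y)))],
    )


def stack_groups(
    maps_by_group: dict[str, list[FeatureMap]],
    y_by_group: dict[str, object],
    order: list[str],
) -> DesignMatrix:
    """General multi-group design; the last group in ``order`` is the reference.

    Columns: K main effects (each map stacked across all blocks), then K
    interaction columns per non-reference group (elementwise product of the
    main column with that group's dummy).
    """
    if set(maps_by_group) != set(order) or set(y_by_group) != set(order):
        raise InputError("maps/response groups do not match the group order")
    label_sets = {g: [m.name for m in maps_by_group[g]] for g in order}
    first = label_sets[order[0]]
    for g, labels in label_sets.items():
        if labels != first:
            raise InputError(
                f"feature labels differ between groups: {g} has {labels}, expected {first}"
            )
    arrays = []
    for g in order:
        arrays.extend(_map_values(m) for m in maps_by_group[g])
        arrays.append(_map_values(y_by_group[g]))
    _check_same_grid(arrays)

    n_block = arrays[0].size
    blocks = [(g, slice(i * n_block, (i + 1) * n_block)) for i, g in enumerate(order)]
    K = len(first)
    main_cols = [
        np.concatenate([_flatten(_map_values(maps_by_group[g][k])) for g in order])
        for k in range(K)
    ]
    y = np.concatenate([_flatten(_map_values(y_by_group[g])) for g in order])
    non_ref = order[:-1]
    labels = list(first)
    cols = list(main_cols)
    for g in non_ref:
        dummy = np.zeros(len(y))
        dummy[[sl for lbl, sl in blocks if lbl == g][0]] = 1.0
        suffix = INTERACTION_SUFFIX if len(order) == 2 else f":G[{g}]"
        for k in range(K):
            cols.append(main_cols[k] * dummy)
            labels.append(first[k] + suffix)
    return DesignMatrix(
        X=np.column_stack(cols), y=y, labels=labels, blocks=blocks,
        interaction_groups=non_ref,
    )


def stack_multigroup(
    maps_treatment: list[FeatureMap],
    maps_control: list[FeatureMap],
    Y_treatment,
    Y_control,
    treatment: str = "treatment",
    control: str = "control",
) -> DesignMatrix:
    """Two-group design: response [Y_T; Y_C], dummy 1 on the treatment block."""
    return stack_groups(
        {treatment: maps_treatment, control: maps_control},
        {treatment: Y_treatment, control: Y_control},
        [treatment, control],
    )


# ---------------------------------------------------------------------------
# standardization


@dataclass
class StandardizationRecord:
    """Per-block means/SDs sufficient to map standardized betas to raw scale."""

    mode: str
    groups: list[str]
    col_stats: dict[tuple[str, str], tuple[float, float]]  # (group, label) -> (mean, sd)
    y_stats: dict[str, tuple[float, float]]
    dropped: list[str]
    labels: list[str]  # surviving column labels, in design order

    def raw_betas(self, beta: np.ndarray, base_labels: list[str]) -> dict[str, dict[str, float]]:
        """Raw-scale per-group weights from standardized coefficients.

        For each group the effective standardized weight of feature k (main
        plus that group's interaction) is rescaled by ``sd(y) / sd(M_k)``
        within the group's block.  The uniform map's raw weight is the
        implied intercept divided by the constant map value; it is reported
        under ``"uniform"`` when the uniform map was absorbed.
        """
        out: dict[str, dict[str, float]] = {}
        idx = {lab: i for i, lab in enumerate(self.labels)}
        for gi, g in enumerate(self.groups):
            is_ref = gi == len(self.groups) - 1
            eff: dict[str, float] = {}
            for lab in base_labels:
                if lab in self.dropped:
                    continue
                b = beta[idx[lab]] if lab in idx else 0.0
                if not is_ref:
                    suffix = INTERACTION_SUFFIX if len(self.groups) == 2 else f":G[{g}]"
                    inter = lab + suffix
                    if inter in idx:
                        b = b + beta[idx[inter]]
                eff[lab] = b
            y_mu, y_sd = self.y_stats[g]
            raw = {}
            intercept = y_mu
            for lab, b in eff.items():
                mu, sd = self.col_stats[(g, lab)]
                raw[lab] = b * y_sd / sd
                intercept -= raw[lab] * mu
            for lab in self.dropped:
                mu, _ = self.col_stats[(g, lab)]
                raw[lab] = intercept / mu if mu != 0 else 0.0
            out[g] = raw
        return out


def standardize(
    design: DesignMatrix, mode: str = "per_group"
) -> tuple[DesignMatrix, StandardizationRecord]:
    """Center and scale main-effect columns and the response within each group.

    ``mode="per_group"`` (default) standardizes within each group block;
    ``mode="pooled"`` uses one block spanning all rows.  Interaction columns
    are rebuilt from the standardized main columns, so the block-equivalence
    of the stacked model with separate per-group fits is preserved exactly.
    Zero-variance columns are dropped: silently for the uniform map (absorbed
    by the centered model's intercept), with a warning otherwise.
    """
    if mode not in ("per_group", "pooled"):
        raise ParameterError(f"unknown standardization mode {mode!r}")
    blocks = design.blocks if mode == "per_group" else [("pooled", slice(0, design.n))]
    main = [lab for lab in design.labels if not _is_interaction(lab)]
    col_of = {lab: i for i, lab in enumerate(design.labels)}

    col_stats: dict[tuple[str, str], tuple[float, float]] = {}
    y_stats: dict[str, tuple[float, float]] = {}
    dropped: list[str] = []
    std_main: dict[str, np.ndarray] = {}

    y_std = np.empty_like(design.y)
    for g, sl in blocks:
        mu, sd = design.y[sl].mean(), design.y[sl].std()
        if sd <= 0:
            raise InputError(f"response has zero variance in block {g!r}")
        y_std[sl] = (design.y[sl] - mu) / sd
        y_stats[g] = (float(mu), float(sd))

    for lab in main:
        col = design.X[:, col_of[lab]]
        out = np.empty_like(col)
        degenerate = False
        for g, sl in blocks:
            mu, sd = col[sl].mean(), col[sl].std()
            col_stats[(g, lab)] = (float(mu), float(sd))
            if sd <= 1e-15 * max(1.0, abs(mu)):
                degenerate = True
            else:
                out[sl] = (col[sl] - mu) / sd
        if degenerate:
            if lab != "uniform":
                warnings.warn(
                    f"column {lab!r} has zero variance within a group block; dropped",
                    stacklevel=2,
                )
            dropped.append(lab)
        else:
            std_main[lab] = out

    kept_main = [lab for lab in main if lab not in dropped]
    cols = [std_main[lab] for lab in kept_main]
    labels = list(kept_main)
    for g in design.interaction_groups:
        dummy = np.zeros(design.n)
        dummy[[sl for lbl, sl in design.blocks if lbl == g][0]] = 1.0
        suffix = (
            INTERACTION_SUFFIX if len(design.interaction_groups) == 1 else f":G[{g}]"
        )
        for lab in kept_main:
            cols.append(std_main[lab] * dummy)
            labels.append(lab + suffix)
    record = StandardizationRecord(
        mode=mode,
        groups=[g for g, _ in design.blocks],
        col_stats=col_stats,
        y_stats=y_stats,
        dropped=dropped,
        labels=labels,
    )
    std_design = DesignMatrix(
        X=np.column_stack(cols) if cols else np.empty((design.n, 0)),
        y=y_std,
        labels=labels,
        blocks=design.blocks,
        interaction_groups=design.interaction_groups,
    )
    return std_design, record


# ---------------------------------------------------------------------------
# LASSO path and BIC selection


def default_lambda_grid(
    X: np.ndarray, y: np.ndarray, n_lambdas: int = 100, min_ratio: float = 1e-4,
    include_zero: bool = True,
) -> np.ndarray:
    """Descending log-spaced grid from the KKT all-zero threshold downwards.

    ``lambda_max = 2 * max|X'y|`` is the smallest penalty at which every
    weight is exactly zero; the grid spans down to ``lambda_max * min_ratio``
    with ``lambda = 0`` (the least-squares endpoint) appended.
    """
    lam_max = 2.0 * float(np.abs(X.T @ y).max()) if X.size else 1.0
    if lam_max <= 0:
        lam_max = 1.0
    grid = np.geomspace(lam_max, lam_max * min_ratio, n_lambdas)
    if include_zero:
        grid = np.append(grid, 0.0)
    return grid


def lasso_path(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Coefficients along a descending lambda path (no intercept).

    The penalty convention is ``||y - X b||^2 + lambda * ||b||_1``; positive
    lambdas are solved by coordinate descent, ``lambda = 0`` by least squares.
    Returns an array of shape ``(len(lambdas), n_features)``.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) > 0):
        raise InputError("lambda grid must be non-increasing")
    if np.any(lambdas < 0):
        raise InputError("lambdas must be nonnegative")
    n, p = X.shape
    out = np.zeros((len(lambdas), p))
    pos = lambdas > 0
    if pos.any():
        from sklearn.linear_model import lasso_path as _sk_path

        alphas = lambdas[pos] / (2.0 * n)
        _, coefs, _ = _sk_path(X, y, alphas=alphas, max_iter=100_000, tol=1e-10)
        # sklearn returns coefs ordered by its (descending) alpha ordering
        order = np.argsort(-alphas, kind="stable")
        inv = np.empty_like(order)
        inv[order] = np.arange(len(order))
        out[np.flatnonzero(pos)] = coefs.T[inv]
    if (~pos).any():
        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
        out[~pos] = beta0
    return out


#: weights with magnitude at or below this are treated as exact zeros
ZERO_TOL = 1e-10


def count_nonzero(beta: np.ndarray) -> int:
    return int(np.sum(np.abs(beta) > ZERO_TOL))


def bic_score(rss: float, n: int, k: int) -> float:
    """Gaussian BIC with variance RSS/n and k nonzero weights."""
    sigma2 = max(rss / n, 1e-300)
    return n * math.log(2 * math.pi * sigma2) + n + k * math.log(n)


def select_by_bic(
    path: np.ndarray, lambdas: np.ndarray, X: np.ndarray, y: np.ndarray
) -> tuple[int, np.ndarray]:
    """Index of the BIC-minimizing path entry; ties break toward larger lambda."""
    if len(path) == 0:
        raise InputError("empty path")
    bics = np.empty(len(path))
    for i, beta in enumerate(path):
        resid = y - X @ beta
        bics[i] = bic_score(float(resid @ resid), len(y), count_nonzero(beta))
    best = 0
    for i in range(1, len(path)):
        if bics[i] < bics[best]:  # strict: earlier (sparser, larger lambda) wins ties
            best = i
    return best, bics


class LassoBIC(BaseEstimator, RegressorMixin):
    """L1-penalized linear regression with BIC-selected penalty.

    A scikit-learn style regressor: :meth:`fit` solves the LASSO along a
    descending lambda grid (``||y - Xb||^2 + lambda ||b||_1``, no intercept —
    inputs are expected centered) and keeps the solution minimizing the
    Gaussian BIC with the nonzero count as degrees of freedom.

    Parameters
    ----------
    lambdas : array-like, optional
        Descending penalty grid; by default 100 log-spaced values from the
        all-zero threshold down to 1e-4 of it, plus 0.
    n_lambdas, lambda_min_ratio, include_zero :
        Shape of the default grid.

    Attributes
    ----------
    coef_ : selected weights; ``lambda_``, ``bic_``, ``r2_``, ``r2_adj_``,
    ``n_nonzero_`` describe the selected fit; ``lambdas_``, ``path_coefs_``,
    ``bic_path_`` expose the whole path.
    """

    def __init__(
        self,
        lambdas=None,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 1e-4,
        include_zero: bool = True,
    ):
        self.lambdas = lambdas
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.include_zero = include_zero

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise InputError(f"bad shapes X {X.shape}, y {y.shape}")
        lambdas = (
            np.asarray(self.lambdas, dtype=float)
            if self.lambdas is not None
            else default_lambda_grid(
                X, y, self.n_lambdas, self.lambda_min_ratio, self.include_zero
            )
        )
        path = lasso_path(X, y, lambdas)
        best, bics = select_by_bic(path, lambdas, X, y)
        n = len(y)
        beta = path[best]
        resid = y - X @ beta
        rss = float(resid @ resid)
        tss = float(((y - y.mean()) ** 2).sum())
        p = count_nonzero(beta)
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        denom = n - p - 1
        self.coef_ = beta
        self.lambda_ = float(lambdas[best])
        self.bic_ = float(bics[best])
        self.r2_ = r2
        self.r2_adj_ = 1.0 - (1.0 - r2) * (n - 1) / denom if denom > 0 else -math.inf
        self.n_nonzero_ = p
        self.lambdas_ = lambdas
        self.path_coefs_ = path
        self.bic_path_ = bics
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.coef_


# ---------------------------------------------------------------------------
# per-frame fits and RI curves


@dataclass
class FrameFit:
    """Selected decomposition of one frame (or an explicit skip record)."""

    frame_index: int
    groups: list[str]
    base_labels: list[str]  # all requested features, including absorbed ones
    labels: list[str]  # surviving standardized design columns
    beta: np.ndarray  # aligned with ``labels``
    lambda_: float
    bic: float
    r2_adj: float
    n_nonzero: int
    record: StandardizationRecord | None
    skipped: bool = False
    reason: str | None = None

    @classmethod
    def skip(cls, frame_index: int, reason: str) -> "FrameFit":
        return cls(
            frame_index=frame_index, groups=[], base_labels=[], labels=[],
            beta=np.empty(0), lambda_=math.nan, bic=math.nan, r2_adj=math.nan,
            n_nonzero=0, record=None, skipped=True, reason=reason,
        )

    def beta_dict(self) -> dict[str, float]:
        """Standardized weights for every requested label (absorbed ones 0)."""
        d = dict.fromkeys(self.base_labels, 0.0)
        for g in self.groups[:-1]:
            suffix = INTERACTION_SUFFIX if len(self.groups) == 2 else f":G[{g}]"
            d.update(dict.fromkeys([lab + suffix for lab in self.base_labels], 0.0))
        d.update(zip(self.labels, self.beta))
        return d

    def group_weights(self, normalize: bool = False) -> dict[str, dict[str, float]]:
        """Per-group effective standardized weight of every base feature.

        Reference-group weight is the main effect; other groups add their
        interaction term.  ``normalize`` divides each group's weight vector by
        the sum of absolute weights.
        """
        betas = self.beta_dict()
        out: dict[str, dict[str, float]] = {}
        for gi, g in enumerate(self.groups):
            is_ref = gi == len(self.groups) - 1
            suffix = INTERACTION_SUFFIX if len(self.groups) == 2 else f":G[{g}]"
            w = {}
            for lab in self.base_labels:
                b = betas[lab]
                if not is_ref:
                    b += betas.get(lab + suffix, 0.0)
                w[lab] = b
            if normalize:
                total = sum(abs(v) for v in w.values())
                if total > 0:
                    w = {k: v / total for k, v in w.items()}
            out[g] = w
        return out

    def raw_weights(self) -> dict[str, dict[str, float]]:
        """Per-group weights mapped back to the raw (unstandardized) scale."""
        if self.record is None:
            raise InputError("skipped frame has no fit to de-standardize")
        return self.record.raw_betas(self.beta_dict_as_array(), self.base_labels)

    def beta_dict_as_array(self) -> np.ndarray:
        d = self.beta_dict()
        return np.array([d[lab] for lab in self.record.labels])


def _fit_design(
    design: DesignMatrix,
    frame_index: int,
    lambdas=None,
    standardize_mode: str = "per_group",
    do_standardize: bool = True,
    n_lambdas: int = 100,
) -> FrameFit:
    base_labels = [lab for lab in design.labels if not _is_interaction(lab)]
    if do_standardize:
        std, record = standardize(design, standardize_mode)
    else:
        std, record = design, None
    est = LassoBIC(lambdas=lambdas, n_lambdas=n_lambdas).fit(std.X, std.y)
    return FrameFit(
        frame_index=frame_index,
        groups=[g for g, _ in design.blocks],
        base_labels=base_labels,
        labels=std.labels,
        beta=est.coef_,
        lambda_=est.lambda_,
        bic=est.bic_,
        r2_adj=est.r2_adj_,
        n_nonzero=est.n_nonzero_,
        record=record,
    )


def fit_frame(
    Y,
    maps,
    *,
    frame_index: int | None = None,
    lambdas=None,
    standardize_mode: str = "per_group",
    do_standardize: bool = True,
    treatment: str = "treatment",
    control: str = "control",
) -> FrameFit:
    """Fit one frame, single-group (``Y``, ``maps``) or two-group
    (``Y=(Y_T, Y_C)``, ``maps=(maps_T, maps_C)``).

    Returns the BIC-selected weights with the penalty, BIC and adjusted R^2
    (using the nonzero count as the parameter count).
    """
    if isinstance(Y, tuple):
        maps_T, maps_C = maps
        design = stack_multigroup(maps_T, maps_C, Y[0], Y[1], treatment, control)
        some_map = maps_T[0]
    else:
        design = stack_maps(list(maps), Y)
        some_map = maps[0]
    if frame_index is None:
        frame_index = getattr(some_map, "frame_index", 0)
    return _fit_design(design, frame_index, lambdas, standardize_mode, do_standardize)


@dataclass
class RICurveSet:
    """Relative-importance curves: per group, feature weight against frame."""

    curves: dict[str, pd.DataFrame]  # group -> (frames x features)
    skipped: list[int]
    normalized: bool

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for g, df in self.curves.items():
            for frame, row in df.iterrows():
                for feat, val in row.items():
                    rows.append(
                        {"frame_index": frame, "group": g, "feature": feat, "beta": val}
                    )
        return pd.DataFrame(rows)


def ri_curves(fits: list[FrameFit], normalize: bool = False) -> RICurveSet:
    """Assemble per-feature weight-versus-frame curves from frame fits.

    The reference (control) curve carries the main-effect weights verbatim;
    each other group's curve is main effect plus that group's interaction.
    With ``normalize=True`` each frame's weight vector is divided by its sum
    of absolute weights.
    """
    if not fits:
        raise InputError("need at least one frame fit")
    done = [f for f in fits if not f.skipped]
    skipped = [f.frame_index for f in fits if f.skipped]
    if not done:
        return RICurveSet(curves={}, skipped=skipped, normalized=normalize)
    groups = done[0].groups
    features = done[0].base_labels
    per_group: dict[str, dict[int, dict[str, float]]] = {g: {} for g in groups}
    for f in done:
        if f.groups != groups or f.base_labels != features:
            raise InputError("inconsistent groups/features across frame fits")
        w = f.group_weights(normalize=normalize)
        for g in groups:
            per_group[g][f.frame_index] = w[g]
    curves = {
        g: pd.DataFrame.from_dict(d, orient="index").sort_index()[features]
        for g, d in per_group.items()
    }
    return RICurveSet(curves=curves, skipped=skipped, normalized=normalize)


class MasterSaliencyModel(BaseEstimator):
    """Full per-frame decomposition pipeline over a cleaned gaze table.

    For every frame with feature maps available, the per-group eye-position
    density maps are estimated (KDE with per-frame, per-group LSCV
    bandwidths), stacked into a single- or multi-group design, standardized
    within group blocks, and decomposed by LASSO with BIC selection.  The
    fitted object exposes per-frame weights, adjusted R^2, and the
    relative-importance curves.

    Parameters
    ----------
    grid : GridSpec
        Stimulus pixel grid.
    lambdas : array-like, optional
        Penalty grid passed to :class:`LassoBIC` (default: automatic).
    standardize_mode : {"per_group", "pooled"}
        How maps and response are centered/scaled; per-group is the default
        so a group with a stronger density peak cannot mimic a feature
        effect.
    kde_search : BandwidthSearch, optional
        Bandwidth search family; ``kde_policy`` ("skip" or "fixed") and
        ``fixed_bandwidth`` govern frames with too few gaze points.
    group_order : list of str, optional
        Stacking order; the last group is the reference (control).  Default:
        sorted group labels.

    Attributes
    ----------
    frame_fits_ : list of FrameFit (including explicit skip records)
    ri_ : RICurveSet
    r2_adj_ : pandas.Series of adjusted R^2 by frame
    bandwidths_ : pandas.DataFrame of per-frame, per-group bandwidths
    groups_ : group stacking order used
    """

    def __init__(
        self,
        grid,
        lambdas=None,
        standardize_mode: str = "per_group",
        do_standardize: bool = True,
        kde_search=None,
        kde_policy: str = "skip",
        fixed_bandwidth=None,
        group_order=None,
        normalize_ri: bool = False,
        n_lambdas: int = 100,
    ):
        self.grid = grid
        self.lambdas = lambdas
        self.n_lambdas = n_lambdas
        self.standardize_mode = standardize_mode
        self.do_standardize = do_standardize
        self.kde_search = kde_search
        self.kde_policy = kde_policy
        self.fixed_bandwidth = fixed_bandwidth
        self.group_order = group_order
        self.normalize_ri = normalize_ri

    def fit(self, gaze: pd.DataFrame, maps_by_frame: dict[int, list[FeatureMap]]):
        """Fit every frame present in ``maps_by_frame``.

        ``gaze`` is a cleaned gaze table (columns participant, group,
        frame_index, x_stim, y_stim); ``maps_by_frame`` maps 0-based frame
        indices to that frame's feature maps (shared across groups — the
        groups watched the same stimulus).  A frame for which the first
        stimulus frame has no dynamic map is simply absent from the dict.
        """
        from .kde import density_for_group

        groups = (
            list(self.group_order)
            if self.group_order is not None
            else sorted(map(str, gaze["group"].unique()))
        )
        fits: list[FrameFit] = []
        bw_rows = []
        for f in sorted(maps_by_frame):
            maps = maps_by_frame[f]
            ys = {}
            skip_reason = None
            fb = (
                self.fixed_bandwidth.get(f)
                if isinstance(self.fixed_bandwidth, dict)
                else self.fixed_bandwidth
            )
            for g in groups:
                d = density_for_group(
                    gaze, f, g, self.grid,
                    policy=self.kde_policy,
                    fixed_bandwidth=fb,
                    search=self.kde_search,
                )
                if d is None:
                    skip_reason = f"too few gaze points for group {g!r} on frame {f}"
                    break
                ys[g] = d
                bw_rows.append(
                    {
                        "frame_index": f, "group": g, "n_points": d.n_points,
                        "h_xx": d.bandwidth[0, 0], "h_yy": d.bandwidth[1, 1],
                    }
                )
            if skip_reason is not None:
                fits.append(FrameFit.skip(f, skip_reason))
                continue
            if len(groups) == 1:
                design = stack_maps(maps, ys[groups[0]])
            else:
                design = stack_groups({g: maps for g in groups}, ys, groups)
            fits.append(
                _fit_design(
                    design, f, self.lambdas, self.standardize_mode,
                    self.do_standardize, self.n_lambdas,
                )
            )
        self.groups_ = groups
        self.frame_fits_ = fits
        self.skipped_ = [f.frame_index for f in fits if f.skipped]
        self.ri_ = ri_curves(fits, normalize=self.normalize_ri)
        self.r2_adj_ = pd.Series(
            {f.frame_index: f.r2_adj for f in fits if not f.skipped}, dtype=float
        ).sort_index()
        self.bandwidths_ = pd.DataFrame(
            bw_rows, columns=["frame_index", "group", "n_points", "h_xx", "h_yy"]
        )
        return self

    def results_table(self) -> pd.DataFrame:
        """Tidy per-frame results: one row per (frame, coefficient)."""
        rows = []
        for f in self.frame_fits_:
            if f.skipped:
                rows.append(
                    {"frame_index": f.frame_index, "feature": None, "beta": math.nan,
                     "lambda": math.nan, "bic": math.nan, "r2_adj": math.nan,
                     "n_nonzero": 0, "skipped": True}
                )
                continue
            for lab, val in f.beta_dict().items():
                rows.append(
                    {"frame_index": f.frame_index, "feature": lab, "beta": val,
                     "lambda": f.lambda_, "bic": f.bic, "r2_adj": f.r2_adj,
                     "n_nonzero": f.n_nonzero, "skipped": False}
                )
        return pd.DataFrame(rows)
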