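"""Permutation tests for group differences in feature-map weights.

Under the null hypothesis of no group difference, participant group labels
are exchangeable.  The test re-assigns participants to groups at random
(preserving group sizes, leaving each participant's data intact), re-runs the
complete two-group estimation pipeline — per-group kernel density estimation,
per-block standardization, LASSO with BIC selection — and records the
interaction coefficients beta_{k,G}.  The two-sided p-value for feature k is

    p = (1 + #{ |beta*_{k,G}| >= |beta_{k,G}| }) / (P + 1),

with the +1 smoothing that keeps p-values in (0, 1].  Frames are usually a
small equidistant subset of the stimulus, for runtime reasons.  No correction
for multiple frames/features is applied; the reported p-values are raw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InputError, ParameterError
from .grid import GridSpec
from .model import FrameFit, MasterSaliencyModel, _is_interaction

__all__ = [
    "PermutationResult",
    "permute_groups",
    "equidistant_frames",
    "permutation_test",
]


@dataclass
class PermutationResult:
    """Observed group-difference coefficients and their null distribution."""

    frame_index: int
    observed: dict[str, float]  # interaction label -> observed beta
    permuted: dict[str, np.ndarray]  # interaction label -> P permuted betas
    p_values: dict[str, float]
    skipped: bool = False
    reason: str | None = None


def permute_groups(gaze: pd.DataFrame, rng: np.random.Generator | int) -> pd.DataFrame:
    """Randomly re-assign participant-level group labels, preserving sizes.

    The unit of permutation is the participant: within-participant data are
    untouched, only the participant -> group map is shuffled.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    pg = gaze[["participant", "group"]].drop_duplicates("participant")
    if pg["group"].nunique() < 2:
        raise InputError("permutation requires at least two groups")
    labels = pg["group"].to_numpy().copy()
    rng.shuffle(labels)
    mapping = dict(zip(pg["participant"], labels))
    out = gaze.copy()
    out["group"] = out["participant"].map(mapping)
    return out


def equidistant_frames(n_frames: int, count: int, first: int = 1) -> list[int]:
    """Evenly spaced 0-based frame indices over the modelable range.

    The range starts at ``first`` (default 1: the first stimulus frame has no
    dynamic map) and ends at ``n_frames - 1``.  ``count = 1`` returns the
    middle frame.
    """
    last = n_frames - 1
    if count < 1:
        raise ParameterError("count must be >= 1")
    n_avail = last - first + 1
    if count > n_avail:
        raise ParameterError(
            f"requested {count} frames but only {n_avail} are modelable"
        )
    if count == 1:
        return [(first + last) // 2]
    idx = np.round(np.linspace(first, last, count)).astype(int)
    return sorted(set(idx.tolist()))


def _interaction_betas(fit: FrameFit) -> dict[str, float]:
    d = fit.beta_dict()
    return {lab: val for lab, val in d.items() if _is_interaction(lab)}


def permutation_test(
    gaze: pd.DataFrame,
    maps_by_frame: dict,
    frames: list[int],
    P: int,
    seed: int,
    grid: GridSpec,
    *,
    model: MasterSaliencyModel | None = None,
    reuse_bandwidths: bool = False,
    reuse_lambda: bool = False,
) -> list[PermutationResult]:
    """Permutation distribution of the group-difference coefficients.

    For each frame in ``frames`` the observed two-group fit is computed, then
    ``P`` permutations of the participant group labels are drawn (duplicates
    allowed — standard Monte Carlo practice) and the full pipeline is re-run
    on each.  ``reuse_bandwidths`` replaces per-group LSCV selection with one
    bandwidth per frame selected from the *pooled* points (label-invariant,
    so permutation exactness is preserved), applied to the observed fit and
    every permutation alike; ``reuse_lambda`` freezes the observed penalty
    instead of re-selecting by BIC.  Both are off by default (full pipeline
    symmetry).  Deterministic for a fixed seed.
    """
    if P < 1:
        raise ParameterError("P must be >= 1")
    if not frames:
        raise ParameterError("frames must be non-empty")
    if model is None:
        model = MasterSaliencyModel(grid)
    sub_maps = {f: maps_by_frame[f] for f in frames}
    if reuse_bandwidths:
        from .kde import select_bandwidth

        pooled = {}
        for f in frames:
            pts = gaze.loc[
                gaze["frame_index"] == f, ["x_stim", "y_stim"]
            ].to_numpy(dtype=float)
            if len(pts) >= 2:
                pooled[f] = select_bandwidth(
                    pts, grid, getattr(model, "kde_search", None)
                )
        model = _clone_with(model)
        model.set_params(fixed_bandwidth=pooled, kde_policy="fixed")
    observed_model = _clone_with(model).fit(gaze, sub_maps)
    obs_fits = {f.frame_index: f for f in observed_model.frame_fits_}

    rng = np.random.default_rng(seed)
    perm_records: dict[int, dict[str, list[float]]] = {
        f: {lab: [] for lab in _interaction_betas(obs_fits[f])}
        for f in frames
        if not obs_fits[f].skipped
    }
    for _ in range(P):
        permuted = permute_groups(gaze, rng)
        pm = _clone_with(model, observed_model, reuse_lambda=reuse_lambda, obs_fits=obs_fits)
        pm.fit(permuted, sub_maps)
        for f_fit in pm.frame_fits_:
            f = f_fit.frame_index
            if f not in perm_records:
                continue
            betas = _interaction_betas(f_fit) if not f_fit.skipped else {}
            for lab in perm_records[f]:
                perm_records[f][lab].append(betas.get(lab, np.nan))

    results = []
    for f in frames:
        fit = obs_fits[f]
        if fit.skipped:
            results.append(
                PermutationResult(f, {}, {}, {}, skipped=True, reason=fit.reason)
            )
            continue
        obs = _interaction_betas(fit)
        permuted_arrays = {}
        pvals = {}
        for lab, vals in perm_records[f].items():
            arr = np.asarray(vals, dtype=float)
            permuted_arrays[lab] = arr
            ok = arr[np.isfinite(arr)]
            pvals[lab] = float(
                (1 + np.sum(np.abs(ok) >= abs(obs[lab]))) / (len(ok) + 1)
            )
        results.append(PermutationResult(f, obs, permuted_arrays, pvals))
    return results


def _clone_with(
    model: MasterSaliencyModel,
    observed: MasterSaliencyModel | None = None,
    reuse_lambda: bool = False,
    obs_fits: dict[int, FrameFit] | None = None,
) -> MasterSaliencyModel:
    from sklearn.base import clone

    m = clone(model)
    if observed is not None and reuse_lambda and obs_fits:
        lams = sorted(
            {f.lambda_ for f in obs_fits.values() if not f.skipped}, reverse=True
        )
        if lams:
            m.set_params(lambdas=np.asarray(lams))
    return m


def results_to_tables(results: list[PermutationResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy (frame, feature, observed, p_value) plus quartile box summaries."""
    rows, boxes = [], []
    for r in results:
        if r.skipped:
            continue
        for lab, obs in r.observed.items():
            rows.append(
                {"frame_index": r.frame_index, "feature": lab, "observed": obs,
                 "p_value": r.p_values[lab]}
            )
            arr = r.permuted[lab]
            arr = arr[np.isfinite(arr)]
            q1, q2, q3 = np.percentile(arr, [25, 50, 75]) if len(arr) else (np.nan,) * 3
            boxes.append(
                {"frame_index": r.frame_index, "feature": lab, "q1": q1,
                 "median": q2, "q3": q3, "lo": arr.min() if len(arr) else np.nan,
                 "hi": arr.max() if len(arr) else np.nan}
            )
    return pd.DataFrame(rows), pd.DataFrame(boxes)
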