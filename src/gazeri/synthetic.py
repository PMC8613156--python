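"""Synthetic stimuli and gaze data with known ground truth.

The generator emulates the structure of a typical dynamic-stimulus
experiment: a high-contrast object (the dynamic AoI) moves linearly toward a
static target region (the static AoI) over a textured background, while two
groups of participants are tracked at a higher rate than the stimulus
refreshes.  Fixations are drawn per participant and frame from a known
mixture of feature maps

    f(x | t, group) = sum_k w_k(t, group) * M_k(t)(x),

so the whole estimation pipeline can be validated by parameter recovery: the
fitted relative-importance curves should track the generating weight curves.

Real-data artifacts that are emulated: tracker/refresh rate mismatch (2.4
samples per frame at the default 60/25 Hz), untrackable ``(0, 0)`` samples,
samples landing in the black side bars, and ragged per-participant record
counts.  Fixations are i.i.d. across frames given the weight curves — no
scanpath autocorrelation — which matches the frame-marginal model under test
but not real oculomotor behavior.

The default grid is 90 x 72 pixels (1/8 scale of a PAL video stimulus) with
the monitor geometry scaled accordingly, so the full pipeline runs in
seconds.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .features import AoiPolygon, CenterBiasParams, FeatureMap, aoi_map, center_bias_map, uniform_map
from .gaze_io import Geometry
from .grid import GridSpec

__all__ = [
    "ScenarioSpec",
    "default_scenario",
    "make_two_group_scenario",
    "render_stimulus",
    "build_feature_maps",
    "sample_gaze",
    "write_dataset",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete description of a synthetic two-or-more-group experiment.

    ``weight_curves[group][feature]`` is an array of per-frame mixture
    weights; per frame and group the weights must sum to 1.  The moving
    object follows a linear trajectory from ``object_start`` with per-frame
    ``object_velocity`` (continuous stimulus coordinates); the static target
    is an axis-aligned rectangle ``target_box = (x0, y0, x1, y1)``.
    """

    grid: GridSpec
    n_participants: dict[str, int]
    weight_curves: dict[str, dict[str, np.ndarray]]
    object_start: tuple[float, float]
    object_velocity: tuple[float, float]
    object_size: float
    target_box: tuple[float, float, float, float]
    dropout_p: float = 0.05
    off_stimulus_p: float = 0.02
    tracker_hz: float = 60.0
    refresh_hz: float = 25.0
    ragged_max_extra: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        for p, name in ((self.dropout_p, "dropout_p"), (self.off_stimulus_p, "off_stimulus_p")):
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {p}")
        for g, curves in self.weight_curves.items():
            total = None
            for feat, w in curves.items():
                w = np.asarray(w, dtype=float)
                if len(w) != self.grid.n_frames or np.any(w < 0):
                    raise ParameterError(
                        f"weight curve {feat!r} of group {g!r} must be nonnegative "
                        f"with length n_frames={self.grid.n_frames}"
                    )
                total = w if total is None else total + w
            if total is None or np.any(np.abs(total - 1.0) > 1e-9):
                raise ParameterError(f"weights of group {g!r} must sum to 1 per frame")
        # trajectory must stay on the stimulus
        half = self.object_size / 2.0
        for t in range(self.grid.n_frames):
            cx, cy = self.object_center(t)
            if not (half <= cx <= self.grid.w - half and half <= cy <= self.grid.h - half):
                raise ParameterError(
                    f"object trajectory leaves the frame at frame {t} (center {cx:.1f},{cy:.1f})"
                )

    def object_center(self, frame_index: int) -> tuple[float, float]:
        return (
            self.object_start[0] + frame_index * self.object_velocity[0],
            self.object_start[1] + frame_index * self.object_velocity[1],
        )

    def object_polygon(self, frame_index: int) -> AoiPolygon:
        cx, cy = self.object_center(frame_index)
        half = self.object_size / 2.0
        return AoiPolygon(
            "object",
            frame_index,
            ((cx - half, cy - half), (cx + half, cy - half), (cx + half, cy + half), (cx - half, cy + half)),
        )

    def target_polygon(self) -> AoiPolygon:
        x0, y0, x1, y1 = self.target_box
        return AoiPolygon("target", None, ((x0, y0), (x1, y0), (x1, y1), (x0, y1)))

    @property
    def groups(self) -> list[str]:
        return list(self.n_participants)

    @property
    def geometry(self) -> Geometry:
        """Letterboxed monitor geometry scaled to the synthetic grid (full
        monitor height, black bars left and right)."""
        scale = 1.875
        return Geometry(
            mon_w=self.grid.w * scale * 1920.0 / 1350.0,
            mon_h=self.grid.h * scale,
            stim_w=self.grid.w,
            stim_h=self.grid.h,
            tracker_hz=self.tracker_hz,
            refresh_hz=self.refresh_hz,
        )

    @property
    def feature_labels(self) -> list[str]:
        return list(next(iter(self.weight_curves.values())))


def _base_curves(n_frames: int) -> dict[str, np.ndarray]:
    """Smooth, time-varying control-group weights summing to 1 per frame."""
    t = np.linspace(0.0, 1.0, n_frames)
    curves = {
        "uniform": np.full(n_frames, 0.10),
        "center_bias": 0.30 - 0.15 * t,
        "aoi:object": 0.40 + 0.10 * np.sin(np.pi * t),
        "aoi:target": None,  # remainder
    }
    rest = 1.0 - curves["uniform"] - curves["center_bias"] - curves["aoi:object"]
    curves["aoi:target"] = rest
    return curves


def default_scenario(
    n_frames: int = 30,
    n_per_group: int = 25,
    groups: tuple[str, ...] = ("treatment", "control"),
    seed: int = 0,
    w: int = 90,
    h: int = 72,
    **overrides,
) -> ScenarioSpec:
    """Null scenario: every group shares the same base weight curves."""
    grid = GridSpec(w=w, h=h, fps=25.0, n_frames=n_frames)
    base = _base_curves(n_frames)
    kwargs = dict(
        grid=grid,
        n_participants={g: n_per_group for g in groups},
        weight_curves={g: {k: v.copy() for k, v in base.items()} for g in groups},
        object_start=(w * 0.15, h * 0.60),
        object_velocity=((w * 0.62) / max(n_frames - 1, 1), 0.0),
        object_size=w / 9.0,
        target_box=(w * 0.80, h * 0.35, w * 0.95, h * 0.60),
        seed=seed,
    )
    kwargs.update(overrides)
    return ScenarioSpec(**kwargs)


def make_two_group_scenario(
    effect: str,
    delta: float,
    base: ScenarioSpec | None = None,
    treatment: str = "treatment",
    **kwargs,
) -> ScenarioSpec:
    """Shift weight ``delta`` onto ``effect`` in the treatment group.

    The other features give up weight proportionally, frame by frame;
    ``delta = 0`` yields the exchangeable null scenario.
    """
    if base is None:
        base = default_scenario(**kwargs)
    if treatment not in base.weight_curves:
        raise ParameterError(f"group {treatment!r} not in scenario")
    curves = {g: {k: v.copy() for k, v in c.items()} for g, c in base.weight_curves.items()}
    tc = curves[treatment]
    if effect not in tc:
        raise ParameterError(f"feature {effect!r} not in weight curves")
    w_eff = tc[effect]
    new_eff = w_eff + delta
    if np.any(new_eff < -1e-12) or np.any(new_eff > 1.0 + 1e-12):
        raise ParameterError(f"delta {delta} drives {effect!r} weights outside [0, 1]")
    shrink = (1.0 - new_eff) / (1.0 - w_eff)
    for k in tc:
        tc[k] = tc[k] * shrink
    tc[effect] = new_eff
    return replace(base, weight_curves=curves)


# ---------------------------------------------------------------------------
# stimulus rendering


def render_stimulus(spec: ScenarioSpec) -> tuple[np.ndarray, list[AoiPolygon]]:
    """Deterministic frame sequence plus consistent AoI polygons.

    Each frame is a float luminance image in [0, 255]: a mid-gray textured
    background (fixed by the scenario seed), a dark static target rectangle
    and a bright moving square whose centroid advances linearly.
    """
    rng = np.random.default_rng(spec.seed + 7)
    h, w = spec.grid.shape
    texture = 96.0 + 12.0 * rng.standard_normal((h, w))
    frames = np.empty((spec.grid.n_frames, h, w))
    x0, y0, x1, y1 = (int(round(v)) for v in spec.target_box)
    aois: list[AoiPolygon] = [spec.target_polygon()]
    for t in range(spec.grid.n_frames):
        img = texture.copy()
        img[y0:y1, x0:x1] = 30.0
        poly = spec.object_polygon(t)
        xs = [v[0] for v in poly.vertices]
        ys = [v[1] for v in poly.vertices]
        img[int(round(min(ys))):int(round(max(ys))), int(round(min(xs))):int(round(max(xs)))] = 230.0
        frames[t] = np.clip(img, 0.0, 255.0)
        aois.append(poly)
    return frames, aois


def build_feature_maps(spec: ScenarioSpec) -> dict[int, list[FeatureMap]]:
    """Ground-truth mixture component maps for every frame.

    Labels follow the scenario's weight curves: ``uniform``, ``center_bias``,
    ``aoi:object`` (the moving square), ``aoi:target`` (the static box).
    """
    grid = spec.grid
    labels = spec.feature_labels
    cb = center_bias_map(grid, CenterBiasParams.defaults(grid))
    target = aoi_map(spec.target_polygon(), grid)
    out: dict[int, list[FeatureMap]] = {}
    for t in range(grid.n_frames):
        maps = []
        for lab in labels:
            if lab == "uniform":
                maps.append(uniform_map(grid, t))
            elif lab == "center_bias":
                maps.append(FeatureMap(lab, t, cb.values))
            elif lab == "aoi:object":
                maps.append(FeatureMap(lab, t, aoi_map(spec.object_polygon(t), grid).values))
            elif lab == "aoi:target":
                maps.append(FeatureMap(lab, t, target.values))
            else:
                raise ParameterError(f"no generator for feature {lab!r}")
        out[t] = maps
    return out


# ---------------------------------------------------------------------------
# gaze sampling


def _sample_from_map(values: np.ndarray, rng: np.random.Generator, size: int) -> np.ndarray:
    """Draw continuous stimulus coordinates from a normalized pixel density."""
    h, w = values.shape
    flat = rng.choice(values.size, size=size, p=values.ravel())
    iy, ix = np.divmod(flat, w)
    jitter = rng.random((size, 2))
    return np.column_stack([ix + jitter[:, 0], iy + jitter[:, 1]])


def _frame_of_sample_start(s: np.ndarray, tracker_hz: float, refresh_hz: float) -> np.ndarray:
    """1-based frame containing each 1-based sample's start time."""
    q = Fraction(tracker_hz).limit_denominator(10**6) / Fraction(refresh_hz).limit_denominator(10**6)
    return ((s - 1) * q.denominator // q.numerator).astype(np.int64) + 1


def sample_gaze(
    spec: ScenarioSpec, feature_maps: dict[int, list[FeatureMap]] | None = None
) -> pd.DataFrame:
    """Raw monitor-coordinate gaze logs drawn from the scenario mixture.

    Per participant and frame one fixation is drawn from the frame's mixture
    density; every tracker sample whose start time falls in that frame
    repeats the fixation.  Dropout samples become ``(0, 0)``, off-stimulus
    samples are displaced into a black side bar, and participants receive a
    random number of extra trailing samples so record counts are ragged.
    Deterministic given the scenario seed.
    """
    if feature_maps is None:
        feature_maps = build_feature_maps(spec)
    rng = np.random.default_rng(spec.seed)
    geom = spec.geometry
    grid = spec.grid
    labels = spec.feature_labels
    n_frames = grid.n_frames
    q = spec.tracker_hz / spec.refresh_hz
    n_base = int(np.ceil(n_frames * q))
    s_all = np.arange(1, n_base + spec.ragged_max_extra + 1)
    frame_of_s = np.minimum(
        _frame_of_sample_start(s_all, spec.tracker_hz, spec.refresh_hz), n_frames
    )

    records = []
    for group in spec.groups:
        n_p = spec.n_participants[group]
        curves = spec.weight_curves[group]
        weight_matrix = np.column_stack([curves[lab] for lab in labels])  # frames x K
        cum = np.cumsum(weight_matrix, axis=1)
        cum[:, -1] = 1.0  # guard rounding
        # mixture component per participant and frame
        u = rng.random((n_p, n_frames))
        comp = np.empty((n_p, n_frames), dtype=np.int64)
        for t in range(n_frames):
            comp[:, t] = np.searchsorted(cum[t], u[:, t], side="right")
        # one fixation per participant and frame, drawn in batches per component
        fix = np.empty((n_p, n_frames, 2))
        for t in range(n_frames):
            for k in range(len(labels)):
                idx = np.flatnonzero(comp[:, t] == k)
                if len(idx):
                    fix[idx, t] = _sample_from_map(feature_maps[t][k].values, rng, len(idx))
        extras = rng.integers(0, spec.ragged_max_extra + 1, size=n_p)
        for p in range(n_p):
            pid = f"{group}_{p:03d}"
            n_samp = n_base + int(extras[p])
            s_ids = s_all[:n_samp]
            fr = frame_of_s[:n_samp]
            x_mon = fix[p, fr - 1, 0] * geom.scale + geom.side_bar
            y_mon = fix[p, fr - 1, 1] * geom.scale
            u_noise = rng.random(n_samp)
            off = u_noise < spec.off_stimulus_p
            drop = u_noise >= 1.0 - spec.dropout_p
            x_mon = np.where(off, rng.random(n_samp) * geom.side_bar, x_mon)
            x_mon = np.where(drop, 0.0, x_mon)
            y_mon = np.where(drop, 0.0, y_mon)
            records.append(
                pd.DataFrame(
                    {
                        "participant": pid,
                        "group": group,
                        "sample_index": s_ids,
                        "x": x_mon,
                        "y": y_mon,
                    }
                )
            )
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# on-disk dataset (the exact formats the readers consume)


def write_dataset(spec: ScenarioSpec, outdir: str | os.PathLike) -> dict[str, str]:
    """Write gaze CSV, PNG frames, AoI JSON, geometry JSON and ground truth.

    Returns the paths written, keyed by artifact name.  The emitted files are
    loadable by the reading functions in :mod:`gazeri.gaze_io` and
    :mod:`gazeri.features` without modification.
    """
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames, aois = render_stimulus(spec)
    frame_dir = outdir / "frames"
    frame_dir.mkdir(exist_ok=True)
    for t in range(spec.grid.n_frames):
        iio.imwrite(frame_dir / f"frame_{t:04d}.png", frames[t].astype(np.uint8))
    gaze = sample_gaze(spec)
    gaze_path = outdir / "gaze.csv"
    gaze.to_csv(gaze_path, index=False)
    aoi_path = outdir / "aois.json"
    with open(aoi_path, "w") as fh:
        json.dump(
            [
                {"label": a.label, "frame_index": a.frame_index,
                 "vertices": [list(v) for v in a.vertices]}
                for a in aois
            ],
            fh,
            indent=1,
        )
    geom = spec.geometry
    geom_path = outdir / "geometry.json"
    with open(geom_path, "w") as fh:
        json.dump(
            {k: getattr(geom, k) for k in
             ("mon_w", "mon_h", "stim_w", "stim_h", "tracker_hz", "refresh_hz")},
            fh,
            indent=1,
        )
    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "seed": spec.seed,
                "n_frames": spec.grid.n_frames,
                "weight_curves": {
                    g: {k: list(map(float, v)) for k, v in c.items()}
                    for g, c in spec.weight_curves.items()
                },
            },
            fh,
            indent=1,
        )
    return {
        "gaze": str(gaze_path),
        "frames": str(frame_dir),
        "aois": str(aoi_path),
        "geometry": str(geom_path),
        "truth": str(truth_path),
    }
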