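"""Feature map construction.

A feature map is a nonnegative grid over the stimulus pixels, normalized to a
discrete bivariate probability density (entries sum to 1).  Each map encodes
one candidate driver of visual attention on one frame:

* ``uniform`` — the catch-all hypothesis, the same value 1/(w*h) everywhere;
* ``center_bias`` — the tendency to look near the stimulus center, a bivariate
  Gaussian with diagonal covariance, time independent;
* ``static_saliency`` — image regions that stand out by luminance contrast and
  orientation, computed with a Gabor filter bank;
* ``dynamic_saliency`` — regions of inter-frame luminance change (low spatial
  frequency motion energy); undefined for the first frame;
* ``aoi:<label>`` — an analyst-defined polygon region, rasterized to a binary
  mask; "dynamic" AoIs move across frames, "static" ones do not;
* ``custom:<label>`` — an externally computed saliency grid loaded from disk,
  so outputs of full video-saliency models can be substituted for the built-in
  saliency operators.
"""

from __future__ import annotations

import json
import logging
import os
import re
from dataclasses import dataclass
from pathlib import Path as FsPath

import numpy as np

from .exceptions import (
    DegenerateMapError,
    FormatError,
    GeometryError,
    ParameterError,
    UndefinedMapError,
)
from .grid import GridSpec

logger = logging.getLogger(__name__)

_NAME_RE = re.compile(
    r"^(uniform|center_bias|static_saliency|dynamic_saliency|aoi:[\w\- ]+|custom:[\w\- ]+)$"
)

#: Normalization tolerance for all density maps.
NORM_TOL = 1e-9


@dataclass(frozen=True)
class FeatureMap:
    """One named, density-normalized grid for one frame."""

    name: str
    frame_index: int
    values: np.ndarray  # shape (h, w), nonnegative, sums to 1

    def __post_init__(self) -> None:
        if not _NAME_RE.match(self.name):
            raise ParameterError(f"invalid feature map name {self.name!r}")
        v = self.values
        if np.any(v < 0):
            raise ParameterError(f"map {self.name!r} has negative entries")
        if abs(float(v.sum()) - 1.0) > NORM_TOL:
            raise ParameterError(
                f"map {self.name!r} is not normalized (sum = {v.sum()!r})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class CenterBiasParams:
    """Parameters of the center-bias Gaussian.

    ``sigma_x`` / ``sigma_y`` are standard deviations in pixels; the defaults
    divide the stimulus width and height by 12.  ``center`` is in pixel-index
    units, default ``((w-1)/2, (h-1)/2)`` — the exact middle of the pixel
    array, i.e. the continuous stimulus center ``(w/2, h/2)``.
    """

    sigma_x: float
    sigma_y: float
    center: tuple[float, float]

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ParameterError(
                f"sigmas must be positive, got ({self.sigma_x}, {self.sigma_y})"
            )

    @classmethod
    def defaults(cls, grid: GridSpec) -> "CenterBiasParams":
        return cls(
            sigma_x=grid.w / 12.0,
            sigma_y=grid.h / 12.0,
            center=((grid.w - 1) / 2.0, (grid.h - 1) / 2.0),
        )


@dataclass(frozen=True)
class AoiPolygon:
    """Polygonal area of interest on one frame.

    ``frame_index=None`` marks a static AoI that applies to every frame.
    Vertices are continuous stimulus coordinates; values outside
    ``[0, w] x [0, h]`` are clipped at map construction.
    """

    label: str
    frame_index: int | None
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ParameterError(
                f"AoI {self.label!r} needs >= 3 vertices, got {len(self.vertices)}"
            )


# ---------------------------------------------------------------------------
# construction operations


def normalize_map(raw: np.ndarray, name: str = "custom:map", frame_index: int = 0) -> np.ndarray:
    """Normalize a nonnegative grid to sum 1.

    Raises :class:`DegenerateMapError` naming the map and frame when every
    entry is zero.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ParameterError(f"map {name!r} has negative raw entries")
    total = float(raw.sum())
    if total <= 0.0:
        raise DegenerateMapError(
            f"map {name!r} on frame {frame_index} is identically zero"
        )
    return raw / total


def uniform_map(grid: GridSpec, frame_index: int = 0) -> FeatureMap:
    """The catch-all map with every entry equal to 1/(w*h)."""
    values = np.full(grid.shape, 1.0 / grid.n_pixels)
    return FeatureMap("uniform", frame_index, values)


def center_bias_map(
    grid: GridSpec,
    params: CenterBiasParams | None = None,
    frame_index: int = 0,
) -> FeatureMap:
    """Bivariate Gaussian centered on the stimulus, normalized over the grid.

    The density is evaluated at pixel centers (equivalently, at integer pixel
    indices relative to the index-space center) and is identical for all
    frames.
    """
    if params is None:
        params = CenterBiasParams.defaults(grid)
    cx, cy = params.center
    dx = (np.arange(grid.w) - cx) / params.sigma_x
    dy = (np.arange(grid.h) - cy) / params.sigma_y
    raw = np.exp(-0.5 * dy[:, None] ** 2) * np.exp(-0.5 * dx[None, :] ** 2)
    return FeatureMap("center_bias", frame_index, normalize_map(raw, "center_bias", frame_index))


def aoi_mask(polygon: AoiPolygon, grid: GridSpec) -> np.ndarray:
    """Binary point-in-polygon mask at pixel centers (boundary inclusive)."""
    import shapely

    verts = np.asarray(polygon.vertices, dtype=float)
    verts[:, 0] = np.clip(verts[:, 0], 0.0, grid.w)
    verts[:, 1] = np.clip(verts[:, 1], 0.0, grid.h)
    poly = shapely.Polygon(verts)
    xs, ys = np.meshgrid(grid.pixel_centers_x(), grid.pixel_centers_y())
    # covers (unlike contains) counts boundary points as inside
    inside = shapely.covers(poly, shapely.points(xs.ravel(), ys.ravel()))
    return inside.reshape(grid.shape).astype(float)


def aoi_map(polygon: AoiPolygon, grid: GridSpec) -> FeatureMap:
    """Rasterize an AoI polygon to a normalized binary map.

    Raises :class:`DegenerateMapError` when the polygon covers no pixel
    center.
    """
    mask = aoi_mask(polygon, grid)
    name = f"aoi:{polygon.label}"
    frame = polygon.frame_index if polygon.frame_index is not None else 0
    return FeatureMap(name, frame, normalize_map(mask, name, frame))


# --- saliency -------------------------------------------------------------

# Gabor bank: 4 orientations x 2 spatial frequencies (cycles/pixel)
_GABOR_THETAS = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
_GABOR_FREQS = (0.10, 0.20)


def _gabor_bank() -> list[np.ndarray]:
    from skimage.filters import gabor_kernel

    return [
        np.asarray(gabor_kernel(frequency=f, theta=t))
        for f in _GABOR_FREQS
        for t in _GABOR_THETAS
    ]


_BANK_CACHE: list[np.ndarray] | None = None


def static_saliency_map(frame: np.ndarray, grid: GridSpec, frame_index: int = 0) -> FeatureMap:
    """Simplified luminance-contrast saliency.

    The mean-subtracted luminance image is filtered with a bank of Gabor
    kernels (4 orientations x 2 scales); response magnitudes are
    max-normalized per channel and summed.  A constant-luminance frame has no
    contrast anywhere and falls back to the uniform map.  Deterministic for
    fixed input.
    """
    global _BANK_CACHE
    from scipy.signal import fftconvolve

    img = grid.validate_frame(frame, "stimulus frame")
    img = img - img.mean()
    if _BANK_CACHE is None:
        _BANK_CACHE = _gabor_bank()
    raw = np.zeros(grid.shape)
    for kernel in _BANK_CACHE:
        resp = np.abs(fftconvolve(img, kernel, mode="same"))
        peak = resp.max()
        if peak > 1e-12:
            raw += resp / peak
    if raw.sum() <= 1e-12:
        return FeatureMap("static_saliency", frame_index, uniform_map(grid).values)
    return FeatureMap(
        "static_saliency", frame_index, normalize_map(raw, "static_saliency", frame_index)
    )


def dynamic_saliency_map(
    frame_t: np.ndarray,
    frame_prev: np.ndarray | None,
    grid: GridSpec,
    frame_index: int | None = None,
    on_degenerate: str = "raise",
) -> FeatureMap:
    """Simplified motion-energy saliency from two consecutive frames.

    Both frames are Gaussian-blurred (sigma = 2 px) so only low spatial
    frequencies contribute; the absolute luminance difference is then smoothed
    (sigma = 3 px) and normalized.  Undefined for the first frame (there is no
    previous frame to difference against).

    ``on_degenerate`` controls identical-frame input: ``"raise"`` (default)
    raises :class:`DegenerateMapError`; ``"uniform"`` substitutes the uniform
    map and logs a warning.
    """
    from scipy.ndimage import gaussian_filter

    if frame_prev is None or (frame_index is not None and frame_index == 0):
        raise UndefinedMapError(
            "dynamic saliency is undefined for the first frame (no previous frame)"
        )
    if on_degenerate not in ("raise", "uniform"):
        raise ParameterError(f"unknown degenerate policy {on_degenerate!r}")
    idx = 1 if frame_index is None else frame_index
    cur = gaussian_filter(grid.validate_frame(frame_t, "frame_t"), sigma=2.0)
    prev = gaussian_filter(grid.validate_frame(frame_prev, "frame_prev"), sigma=2.0)
    raw = gaussian_filter(np.abs(cur - prev), sigma=3.0)
    if raw.sum() <= 1e-12:
        if on_degenerate == "uniform":
            logger.warning(
                "dynamic saliency degenerate on frame %d (identical frames); "
                "substituting uniform map",
                idx,
            )
            return FeatureMap("dynamic_saliency", idx, uniform_map(grid).values)
        raise DegenerateMapError(
            f"dynamic saliency on frame {idx} is identically zero (identical frames)"
        )
    return FeatureMap("dynamic_saliency", idx, normalize_map(raw, "dynamic_saliency", idx))


def load_external_saliency(
    path: str | os.PathLike, grid: GridSpec, name: str, frame_index: int = 0
) -> FeatureMap:
    """Load a precomputed saliency grid (dense h x w CSV) as ``custom:<name>``.

    Negative entries are clipped at zero (with a logged warning); NaNs or a
    wrong shape raise :class:`FormatError`.
    """
    try:
        raw = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as exc:
        raise FormatError(f"could not parse saliency grid {path}: {exc}") from exc
    if raw.shape != grid.shape:
        raise FormatError(
            f"saliency grid {path} has shape {raw.shape}, expected {grid.shape}"
        )
    if np.any(~np.isfinite(raw)):
        raise FormatError(f"saliency grid {path} contains NaN/inf entries")
    if np.any(raw < 0):
        logger.warning("saliency grid %s has negative entries; clipping at 0", path)
        raw = np.clip(raw, 0.0, None)
    label = f"custom:{name}"
    return FeatureMap(label, frame_index, normalize_map(raw, label, frame_index))


# ---------------------------------------------------------------------------
# external interfaces


def luminance(rgb: np.ndarray) -> np.ndarray:
    """ITU-R BT.601 luminance of an (h, w, 3) image; grayscale passes through."""
    arr = np.asarray(rgb, dtype=float)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] >= 3:
        return 0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
    raise FormatError(f"cannot convert image of shape {arr.shape} to luminance")


def load_frames(directory: str | os.PathLike, grid: GridSpec | None = None) -> np.ndarray:
    """Load a lexicographically ordered PNG/TIFF sequence as luminance frames."""
    import imageio.v3 as iio

    directory = FsPath(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not paths:
        raise FormatError(f"no image frames found in {directory}")
    frames = np.stack([luminance(iio.imread(p)) for p in paths])
    if grid is not None and frames.shape[1:] != grid.shape:
        raise GeometryError(
            f"frames in {directory} have shape {frames.shape[1:]}, expected {grid.shape}"
        )
    return frames


def load_aoi_json(path: str | os.PathLike) -> list[AoiPolygon]:
    """Read AoI definitions from JSON.

    Format: a list of ``{"label": ..., "frame_index": int or null,
    "vertices": [[x, y], ...]}``; ``frame_index = null`` marks a static AoI.
    """
    with open(path) as fh:
        records = json.load(fh)
    if not isinstance(records, list):
        raise FormatError(f"AoI file {path} must contain a JSON list")
    out = []
    for rec in records:
        try:
            out.append(
                AoiPolygon(
                    label=str(rec["label"]),
                    frame_index=rec.get("frame_index"),
                    vertices=tuple(tuple(map(float, v)) for v in rec["vertices"]),
                )
            )
        except (KeyError, TypeError) as exc:
            raise FormatError(f"malformed AoI record in {path}: {rec!r}") from exc
    return out


def aoi_maps_for_frame(
    aois: list[AoiPolygon], grid: GridSpec, frame_index: int
) -> list[FeatureMap]:
    """All AoI maps applying to one frame (static AoIs apply to every frame)."""
    maps = []
    for poly in aois:
        if poly.frame_index is None or poly.frame_index == frame_index:
            m = aoi_map(poly, grid)
            maps.append(FeatureMap(m.name, frame_index, m.values))
    return maps


def standard_maps(
    grid: GridSpec,
    frames: np.ndarray | None = None,
    aois: list[AoiPolygon] | None = None,
    include_uniform: bool = True,
    include_center_bias: bool = True,
    include_static: bool | None = None,
    include_dynamic: bool | None = None,
    center_bias_params: CenterBiasParams | None = None,
    external_dir: str | os.PathLike | None = None,
    external_stem: str = "saliency",
    first_frame: str = "skip",
    dynamic_degenerate: str = "raise",
) -> dict[int, list[FeatureMap]]:
    """Assemble the per-frame feature-map stacks for a whole stimulus.

    Saliency maps default to on when ``frames`` are provided.  Because the
    dynamic map is undefined on the first frame, ``first_frame="skip"``
    (default) omits frame 0 from the result when dynamic maps are included;
    ``first_frame="reduce"`` keeps frame 0 with the dynamic map dropped.
    External per-frame saliency grids (``<stem>_<frame>.csv`` under
    ``external_dir``) are added as ``custom:<stem>`` maps.
    """
    if include_static is None:
        include_static = frames is not None
    if include_dynamic is None:
        include_dynamic = frames is not None and grid.n_frames > 1
    if (include_static or include_dynamic) and frames is None:
        raise ParameterError("saliency maps require stimulus frames")
    if first_frame not in ("skip", "reduce"):
        raise ParameterError(f"unknown first_frame policy {first_frame!r}")
    cb = center_bias_map(grid, center_bias_params) if include_center_bias else None
    out: dict[int, list[FeatureMap]] = {}
    for t in range(grid.n_frames):
        if t == 0 and include_dynamic and first_frame == "skip":
            continue
        maps: list[FeatureMap] = []
        if include_uniform:
            maps.append(uniform_map(grid, t))
        if cb is not None:
            maps.append(FeatureMap("center_bias", t, cb.values))
        if include_static:
            maps.append(static_saliency_map(frames[t], grid, t))
        if include_dynamic and t > 0:
            maps.append(
                dynamic_saliency_map(
                    frames[t], frames[t - 1], grid, t, on_degenerate=dynamic_degenerate
                )
            )
        if aois:
            maps.extend(aoi_maps_for_frame(aois, grid, t))
        if external_dir is not None:
            path = FsPath(external_dir) / f"{external_stem}_{t}.csv"
            maps.append(load_external_saliency(path, grid, external_stem, t))
        out[t] = maps
    return out
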