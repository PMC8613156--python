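"""Raw eye-tracker log ingestion and preprocessing.

The cleaning pipeline runs in a fixed order:

1. :func:`truncate_to_min` — participants differ slightly in how many samples
   the tracker recorded; all streams are truncated to the shortest one by
   discarding trailing samples.
2. :func:`drop_invalid` — ``(0, 0)`` samples mark tracking loss (blinks) and
   are removed, as are samples landing in the black side bars or off the
   monitor.
3. :func:`align_to_frames` — the tracker samples faster than the stimulus
   refreshes (e.g. 60 Hz vs 25 Hz, i.e. 2.4 samples per frame on average);
   per frame and participant the first sample whose tracker interval lies
   entirely within the frame interval is selected.
4. :func:`monitor_to_stimulus` — monitor coordinates are mapped to stimulus
   coordinates by undoing the letterbox scaling (stimulus enlarged to full
   monitor height, centered horizontally between black bars).

Log tables are plain :class:`pandas.DataFrame` objects with columns
``participant, group, sample_index, x, y`` (raw logs, ``sample_index``
1-based at tracker rate) or ``participant, group, frame_index, x_stim,
y_stim`` (cleaned gaze tables, ``frame_index`` 0-based internally).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .exceptions import FormatError, GeometryError, InputError

logger = logging.getLogger(__name__)

RAW_COLUMNS = ["participant", "group", "sample_index", "x", "y"]
GAZE_COLUMNS = ["participant", "group", "frame_index", "x_stim", "y_stim"]


@dataclass(frozen=True)
class Geometry:
    """Monitor/stimulus geometry and sampling rates.

    The stimulus is enlarged to full monitor height and proportionally in
    width; ``scale = mon_h / stim_h`` and the leftover horizontal space is
    split into two equal black side bars.
    """

    mon_w: float
    mon_h: float
    stim_w: float
    stim_h: float
    tracker_hz: float
    refresh_hz: float

    def __post_init__(self) -> None:
        for name in ("mon_w", "mon_h", "stim_w", "stim_h", "tracker_hz", "refresh_hz"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.stim_w * self.scale > self.mon_w + 1e-9:
            raise GeometryError(
                "scaled stimulus width exceeds monitor width "
                f"({self.stim_w * self.scale:.1f} > {self.mon_w})"
            )
        if self.tracker_hz < self.refresh_hz:
            raise GeometryError("tracker_hz must be >= refresh_hz")

    @property
    def scale(self) -> float:
        """Stimulus-to-monitor magnification factor."""
        return self.mon_h / self.stim_h

    @property
    def scaled_stim_w(self) -> float:
        """Width of the video area on the monitor, in monitor pixels."""
        return self.stim_w * self.scale

    @property
    def side_bar(self) -> float:
        """Width of each black side bar, in monitor pixels."""
        return (self.mon_w - self.scaled_stim_w) / 2.0

    @property
    def samples_per_frame(self) -> float:
        """Average tracker samples per stimulus frame."""
        return self.tracker_hz / self.refresh_hz

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "Geometry":
        """Read geometry from JSON or ``key=value`` text."""
        text = open(path).read()
        try:
            cfg = json.loads(text)
        except json.JSONDecodeError:
            cfg = {}
            for line in text.splitlines():
                line = line.split("#")[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise FormatError(f"bad geometry line in {path}: {line!r}")
                key, val = line.split("=", 1)
                cfg[key.strip()] = float(val)
        try:
            return cls(**{k: float(cfg[k]) for k in (
                "mon_w", "mon_h", "stim_w", "stim_h", "tracker_hz", "refresh_hz")})
        except KeyError as exc:
            raise FormatError(f"geometry file {path} is missing key {exc}") from exc


def read_gaze_csv(path: str | os.PathLike, delimiter: str = ",") -> pd.DataFrame:
    """Read a raw gaze log CSV with header ``participant,group,sample_index,x,y``."""
    df = pd.read_csv(path, delimiter=delimiter)
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"gaze log {path} is missing columns {missing}")
    return _validate_raw(df[RAW_COLUMNS])


def _validate_raw(df: pd.DataFrame) -> pd.DataFrame:
    df = df.sort_values(["participant", "sample_index"], kind="stable").reset_index(drop=True)
    bad = df.groupby("participant")["sample_index"].apply(
        lambda s: bool((np.diff(s.to_numpy()) <= 0).any())
    )
    if bad.any():
        raise InputError(
            f"sample_index not strictly increasing for participants {list(bad[bad].index)}"
        )
    return df


def truncate_to_min(logs: pd.DataFrame) -> pd.DataFrame:
    """Truncate every participant's stream to the minimum per-participant count.

    Only trailing samples are discarded; record counts vary because trackers
    lose a few samples per run and the lost time points are unknown.
    """
    if len(logs) == 0:
        raise InputError("empty gaze log collection")
    counts = logs.groupby("participant")["sample_index"].size()
    n_min = int(counts.min())
    out = (
        logs.sort_values(["participant", "sample_index"], kind="stable")
        .groupby("participant", group_keys=False)[logs.columns]
        .head(n_min)
        .reset_index(drop=True)
    )
    return out


def drop_invalid(logs: pd.DataFrame, geom: Geometry) -> pd.DataFrame:
    """Remove untrackable ``(0, 0)`` samples and samples outside the video area.

    The video area spans ``[side_bar, mon_w - side_bar) x [0, mon_h)`` on the
    monitor (half-open on the right/bottom).
    """
    x = logs["x"].to_numpy(dtype=float)
    y = logs["y"].to_numpy(dtype=float)
    lost = (x == 0.0) & (y == 0.0)
    lo, hi = geom.side_bar, geom.mon_w - geom.side_bar
    on_stim = (x >= lo) & (x < hi) & (y >= 0.0) & (y < geom.mon_h)
    keep = ~lost & on_stim
    return logs.loc[keep].reset_index(drop=True)


def monitor_to_stimulus(
    x_mon: np.ndarray | float, y_mon: np.ndarray | float, geom: Geometry
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Map monitor coordinates to stimulus coordinates.

    ``x_stim = (x_mon - side_bar) / scale``, ``y_stim = y_mon / scale``.
    Inputs must already have passed :func:`drop_invalid`.
    """
    return (np.asarray(x_mon, dtype=float) - geom.side_bar) / geom.scale, np.asarray(
        y_mon, dtype=float
    ) / geom.scale


def selected_sample_indices(geom: Geometry, n_frames: int) -> np.ndarray:
    """Nominal 1-based sample index selected for each frame.

    Frame ``f`` (1-based) spans ``[(f-1)/refresh, f/refresh)``; sample ``s``
    (1-based) spans ``[(s-1)/tracker, s/tracker)``.  The selected sample is
    the first whose interval lies entirely inside the frame interval.  At
    60 Hz tracking over a 25 Hz stimulus this yields 1, 4, 6, 9, 11, 13, ...
    """
    q = Fraction(geom.tracker_hz).limit_denominator(10**6) / Fraction(
        geom.refresh_hz
    ).limit_denominator(10**6)
    # containment of [s-1, s)/T in [f-1, f)/R <=> (s-1)*qd >= (f-1)*qn and s*qd <= f*qn
    qn, qd = q.numerator, q.denominator
    f = np.arange(1, n_frames + 1, dtype=np.int64)
    # smallest s with (s-1)*qd >= (f-1)*qn
    s = -(-(f - 1) * qn // qd) + 1  # ceil division
    ok = s * qd <= f * qn
    if not ok.all():
        raise InputError("no tracker sample fits inside some frame interval")
    return s


def _frame_of_sample(sample_index: np.ndarray, geom: Geometry) -> np.ndarray:
    """1-based frame whose interval fully contains each sample, else 0."""
    q = Fraction(geom.tracker_hz).limit_denominator(10**6) / Fraction(
        geom.refresh_hz
    ).limit_denominator(10**6)
    qn, qd = q.numerator, q.denominator
    s = np.asarray(sample_index, dtype=np.int64)
    f = -(-s * qd // qn)  # smallest f with s*qd <= f*qn
    contained = (f - 1) * qn <= (s - 1) * qd
    return np.where(contained, f, 0)


def align_to_frames(logs: pd.DataFrame, geom: Geometry, n_frames: int) -> pd.DataFrame:
    """Select one coordinate per participant per frame and map to stimulus space.

    For each frame the first remaining sample fully contained in the frame
    interval is used.  Participant/frame cells with no qualifying sample are
    absent from the output (logged at debug level).  Returns a gaze table with
    0-based ``frame_index`` and stimulus coordinates.
    """
    frame_1b = _frame_of_sample(logs["sample_index"].to_numpy(), geom)
    df = logs.assign(_frame=frame_1b)
    df = df[(df["_frame"] >= 1) & (df["_frame"] <= n_frames)]
    df = df.sort_values(["participant", "sample_index"], kind="stable")
    picked = df.groupby(["participant", "_frame"], as_index=False).first()
    n_missing = len(logs["participant"].unique()) * n_frames - len(picked)
    if n_missing > 0:
        logger.debug("%d participant/frame cells have no qualifying sample", n_missing)
    x_stim, y_stim = monitor_to_stimulus(
        picked["x"].to_numpy(), picked["y"].to_numpy(), geom
    )
    out = pd.DataFrame(
        {
            "participant": picked["participant"],
            "group": picked["group"],
            "frame_index": picked["_frame"].to_numpy() - 1,
            "x_stim": x_stim,
            "y_stim": y_stim,
        }
    )
    return out.sort_values(["participant", "frame_index"], kind="stable").reset_index(
        drop=True
    )


def preprocess(logs: pd.DataFrame, geom: Geometry, n_frames: int) -> pd.DataFrame:
    """Full cleaning pipeline: truncate -> drop invalid -> align -> map.

    Returns the cleaned gaze table; every coordinate lies inside
    ``[0, stim_w) x [0, stim_h)``.
    """
    logs = _validate_raw(logs)
    logs = truncate_to_min(logs)
    logs = drop_invalid(logs, geom)
    table = align_to_frames(logs, geom, n_frames)
    eps = 1e-9
    assert table["x_stim"].between(-eps, geom.stim_w).all()
    assert table["y_stim"].between(-eps, geom.stim_h).all()
    return table
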