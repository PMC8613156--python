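"""Stimulus pixel grid.

Coordinate convention used throughout the package: 0-based pixel indices in
image orientation (x rightward, y downward).  Pixel ``(i, j)`` — row ``i``,
column ``j`` — occupies the unit square ``[j, j+1) x [i, i+1)`` in continuous
stimulus coordinates and has center ``(j + 0.5, i + 0.5)``.  Continuous gaze
coordinates therefore live in ``[0, w) x [0, h)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError


@dataclass(frozen=True)
class GridSpec:
    """Dimensions and timing of a stimulus.

    Parameters
    ----------
    w, h : int
        Stimulus width and height in pixels.
    fps : float
        Stimulus refresh rate in frames per second.
    n_frames : int
        Number of frames in the stimulus.
    """

    w: int
    h: int
    fps: float = 25.0
    n_frames: int = 1

    def __post_init__(self) -> None:
        if self.w < 2 or self.h < 2:
            raise ParameterError(f"grid must be at least 2x2, got {self.w}x{self.h}")
        if self.fps <= 0:
            raise ParameterError(f"fps must be positive, got {self.fps}")
        if self.n_frames < 1:
            raise ParameterError(f"n_frames must be >= 1, got {self.n_frames}")

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(h, w)`` of one frame."""
        return (self.h, self.w)

    @property
    def n_pixels(self) -> int:
        return self.w * self.h

    def pixel_centers_x(self) -> np.ndarray:
        """Continuous x coordinate of every pixel column center."""
        return np.arange(self.w, dtype=float) + 0.5

    def pixel_centers_y(self) -> np.ndarray:
        """Continuous y coordinate of every pixel row center."""
        return np.arange(self.h, dtype=float) + 0.5

    def validate_frame(self, values: np.ndarray, what: str = "array") -> np.ndarray:
        """Return ``values`` as a float array, checking it matches this grid."""
        from .exceptions import GeometryError

        arr = np.asarray(values, dtype=float)
        if arr.shape != self.shape:
            raise GeometryError(
                f"{what} has shape {arr.shape}, expected (h, w) = {self.shape}"
            )
        return arr
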