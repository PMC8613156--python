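import numpy as np
import pytest

from gazeri.gaze_io import Geometry
from gazeri.grid import GridSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return GridSpec(w=20, h=16, fps=25.0, n_frames=4)


@pytest.fixture
def pal_grid():
    """Full-resolution PAL stimulus grid (720 x 576 at 25 Hz, 174 frames)."""
    return GridSpec(w=720, h=576, fps=25.0, n_frames=174)


@pytest.fixture
def pal_geometry():
    """Full HD monitor showing the PAL stimulus letterboxed at 60 Hz tracking."""
    return Geometry(
        mon_w=1920, mon_h=1080, stim_w=720, stim_h=576, tracker_hz=60, refresh_hz=25
    )
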