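import numpy as np
import pytest

from pathfractal.trajectory import Trajectory


def make_traj(x, y, frames=None, fps=25.0, px_per_cm=None, specimen_id="t"):
    x = np.asarray(x, dtype=float)
    if frames is None:
        frames = np.arange(len(x))
    return Trajectory(
        specimen_id=specimen_id,
        frames=np.asarray(frames),
        x=x,
        y=np.asarray(y, dtype=float),
        fps=fps,
        px_per_cm=px_per_cm,
    )


@pytest.fixture
def simple_traj():
    """Three tracked frames along a 3-4-5 right triangle hypotenuse."""
    return make_traj([0.0, 3.0, 6.0], [0.0, 4.0, 8.0], px_per_cm=1.0)


@pytest.fixture
def gappy_traj():
    """Five frames with the middle one untracked."""
    return make_traj([0.0, 1.0, np.nan, 3.0, 4.0], [0.0, 1.0, np.nan, 3.0, 4.0],
                     px_per_cm=1.0)
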