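"""Drawing a trajectory onto a binary occupancy grid.

All three fractal-dimension estimators operate on a pixel set, so a
coordinate path must first be rendered. The mapping into the grid is affine
and aspect-preserving (one isotropic scale for both axes), which makes the
raster — and therefore every dimension estimate — invariant under uniform
scaling of the input coordinates. Consecutive tracked positions are joined
with 8-connected Bresenham lines by default, so a straight path stays
one-dimensional at any orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.draw import line as _bresenham

from .errors import DegenerateInputError, ParameterError
from .trajectory import Trajectory

DEFAULT_RESOLUTION = 1024
#: empty border in cells so small dilations never truncate at the edge
DEFAULT_MARGIN = 2


@dataclass
class RasterPath:
    """Binary occupancy grid of one rendered trajectory (row = y, col = x).

    ``sample_spacing_cells`` is the median distance in grid cells between
    consecutive trajectory vertices — the finest scale at which the raster
    carries information about the path rather than about line drawing.
    """

    grid: np.ndarray
    resolution: int
    bbox: tuple[float, float, float, float]  # (xmin, xmax, ymin, ymax) source units
    sample_spacing_cells: float = 1.0

    @property
    def n_on(self) -> int:
        return int(self.grid.sum())

    def occupied(self) -> np.ndarray:
        """(n_on, 2) array of occupied (row, col) cell coordinates."""
        return np.argwhere(self.grid)


def rasterize_trajectory(
    traj: Trajectory,
    resolution: int = DEFAULT_RESOLUTION,
    connect: bool = True,
    margin: int = DEFAULT_MARGIN,
) -> RasterPath:
    """Render a trajectory into a ``resolution`` × ``resolution`` binary grid.

    Interior missing frames are linearly interpolated before drawing (the
    animal did not teleport; the tracker lost it). With ``connect`` the path
    is a chain of 8-connected line segments; without it only visited cells
    are set, so the connected raster is always a superset of the
    unconnected one.
    """
    if resolution < 16:
        raise ParameterError(f"resolution must be >= 16, got {resolution}")
    if margin < 0 or 2 * margin >= resolution:
        raise ParameterError(f"margin {margin} incompatible with resolution {resolution}")
    if traj.n_tracked < 1:
        raise DegenerateInputError("cannot rasterize a trajectory with no tracked frames")

    x, y = traj.interpolated_xy()
    xmin, xmax = float(x.min()), float(x.max())
    ymin, ymax = float(y.min()), float(y.max())
    span = max(xmax - xmin, ymax - ymin)
    usable = resolution - 1 - 2 * margin
    scale = usable / span if span > 0 else 0.0

    cols = np.rint((x - xmin) * scale).astype(np.intp) + margin
    rows = np.rint((y - ymin) * scale).astype(np.intp) + margin

    grid = np.zeros((resolution, resolution), dtype=bool)
    if connect and len(rows) > 1:
        for i in range(len(rows) - 1):
            rr, cc = _bresenham(rows[i], cols[i], rows[i + 1], cols[i + 1])
            grid[rr, cc] = True
    else:
        grid[rows, cols] = True
    if len(x) > 1:
        spacing = float(np.median(np.hypot(np.diff(x), np.diff(y))) * scale)
    else:
        spacing = 1.0
    return RasterPath(
        grid=grid,
        resolution=resolution,
        bbox=(xmin, xmax, ymin, ymax),
        sample_spacing_cells=max(spacing, 1.0),
    )


def raster_summary(r: RasterPath) -> dict:
    """Occupancy fraction, bounding-box fill and centroid of a raster."""
    occ = r.occupied()
    if len(occ) == 0:
        raise DegenerateInputError("raster has no occupied cells")
    rmin, cmin = occ.min(axis=0)
    rmax, cmax = occ.max(axis=0)
    bbox_cells = (rmax - rmin + 1) * (cmax - cmin + 1)
    return {
        "n_on": r.n_on,
        "occupancy_fraction": r.n_on / float(r.resolution**2),
        "bbox_fill": r.n_on / float(bbox_cells),
        "centroid": (float(occ[:, 0].mean()), float(occ[:, 1].mean())),
    }


def export_text(r: RasterPath, path: str | Path) -> None:
    """Write the grid as a plain 0/1 matrix (debugging aid)."""
    with open(path, "w") as fh:
        for row in r.grid:
            fh.write("".join("1" if v else "0" for v in row) + "\n")


def export_png(r: RasterPath, path: str | Path) -> None:
    """Write the grid as a binary PNG (occupied = black)."""
    from PIL import Image

    img = Image.fromarray(np.where(r.grid, 0, 255).astype(np.uint8), mode="L")
    img.save(str(path))
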