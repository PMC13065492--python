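"""Trajectories, track-table I/O, calibration and segmentation.

A trajectory is the ordered sequence of 2D positions of one tracked animal,
one row per video frame, in image coordinates (origin top-left, y increases
downward, 0-based frame indices). Untracked frames are kept in place and
flagged missing rather than dropped, so frame indices stay aligned with the
source video.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError, TrackFormatError

DEFAULT_FPS = 25.0
DEFAULT_SEGMENT_LENGTH = 1500

#: column maps for supported track-table dialects
DIALECTS = {
    "generic": {"frame": "frame", "x": "x", "y": "y"},
    "animaltracker": {"frame": "Frame", "x": "X-coordinate", "y": "Y-coordinate"},
}


@dataclass
class Trajectory:
    """One tracked path: per-frame planar positions in pixels.

    ``x``/``y`` hold NaN wherever ``missing_mask`` is True. ``px_per_cm`` is
    None until :func:`calibrate` (or the reader) sets it; pixel coordinates
    are never rescaled in place — conversion to cm happens when metrics are
    computed.
    """

    specimen_id: str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fps: float = DEFAULT_FPS
    px_per_cm: float | None = None
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.x) | np.isnan(self.y)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n = len(self.frames)
        if not (len(self.x) == len(self.y) == len(self.missing_mask) == n):
            raise TrackFormatError("frames, x, y and missing_mask lengths differ")
        if n > 1 and np.any(np.diff(self.frames) <= 0):
            bad = int(np.flatnonzero(np.diff(self.frames) <= 0)[0]) + 1
            raise TrackFormatError(
                f"frame indices not strictly increasing at row {bad} "
                f"(frame {self.frames[bad]})"
            )
        if self.fps <= 0:
            raise ParameterError(f"fps must be positive, got {self.fps}")
        if self.px_per_cm is not None and self.px_per_cm <= 0:
            raise ParameterError(f"px_per_cm must be positive, got {self.px_per_cm}")
        tracked = ~self.missing_mask
        if np.any(~np.isfinite(self.x[tracked])) or np.any(~np.isfinite(self.y[tracked])):
            raise TrackFormatError("non-finite coordinates on tracked frames")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_tracked(self) -> int:
        return int((~self.missing_mask).sum())

    @property
    def missing_fraction(self) -> float:
        return float(self.missing_mask.mean()) if len(self) else 0.0

    def tracked_xy(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (frames, x, y) restricted to tracked frames."""
        m = ~self.missing_mask
        return self.frames[m], self.x[m], self.y[m]

    def interpolated_xy(self) -> tuple[np.ndarray, np.ndarray]:
        """x/y with interior missing frames linearly interpolated over frame
        index; leading/trailing missing frames are dropped."""
        fr, xt, yt = self.tracked_xy()
        if len(fr) == 0:
            raise DegenerateInputError("trajectory has no tracked frames")
        lo, hi = self.frames.searchsorted(fr[0]), self.frames.searchsorted(fr[-1])
        frames = self.frames[lo : hi + 1]
        return np.interp(frames, fr, xt), np.interp(frames, fr, yt)

    def replace(self, **kw) -> "Trajectory":
        return dataclasses.replace(self, **kw)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Trajectory):
            return NotImplemented
        same_cal = (self.px_per_cm is None) == (other.px_per_cm is None) and (
            self.px_per_cm is None or self.px_per_cm == other.px_per_cm
        )
        return (
            self.specimen_id == other.specimen_id
            and self.fps == other.fps
            and same_cal
            and np.array_equal(self.frames, other.frames)
            and np.array_equal(self.missing_mask, other.missing_mask)
            and np.array_equal(self.x, other.x, equal_nan=True)
            and np.array_equal(self.y, other.y, equal_nan=True)
        )


@dataclass
class ArenaSpec:
    """Circular recording arena and its location in the image."""

    diameter_cm: float = 20.0
    water_height_cm: float = 2.8
    center_px: tuple[float, float] = (0.0, 0.0)
    radius_px: float = 0.0

    def __post_init__(self) -> None:
        if self.diameter_cm <= 0:
            raise ParameterError("arena diameter must be positive")


@dataclass
class SegmentSet:
    """Consecutive non-overlapping fixed-length slices of one trajectory."""

    parent_id: str
    segment_length_frames: int
    segments: list[Trajectory]

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)


def read_track_table(
    path: str | Path,
    dialect: str = "generic",
    fps: float | None = None,
    specimen_id: str | None = None,
) -> Trajectory:
    """Read a delimited track table (one row per frame) into a Trajectory.

    Untracked frames — rows where x or y is blank — are kept and flagged in
    ``missing_mask``. Header comment lines ``# key=value`` written by
    :func:`write_track_table` restore fps, calibration and specimen id.
    Duplicate or decreasing frame indices are a format error.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ParameterError(f"unknown dialect {dialect!r}; options: {sorted(DIALECTS)}")
    try:
        text = path.read_text()
    except OSError as exc:
        raise TrackFormatError(f"cannot read track table {path}: {exc}") from exc

    meta: dict[str, str] = {}
    for line in text.splitlines():
        if not line.startswith("#"):
            break
        if "=" in line:
            k, v = line[1:].split("=", 1)
            meta[k.strip()] = v.strip()

    header = next(
        (ln for ln in text.splitlines() if ln and not ln.startswith("#")), ""
    )
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(io.StringIO(text), comment="#", sep=sep,
                     float_precision="round_trip")
    cols = DIALECTS[dialect]
    missing_cols = [c for c in cols.values() if c not in df.columns]
    if missing_cols:
        raise TrackFormatError(
            f"{path}: missing column(s) {missing_cols}; found {list(df.columns)}"
        )

    frames = df[cols["frame"]].to_numpy()
    if np.any(pd.isna(frames)):
        raise TrackFormatError(f"{path}: blank frame index")
    frames = frames.astype(np.int64)
    order = np.argsort(frames, kind="stable")
    frames = frames[order]
    dup = np.flatnonzero(np.diff(frames) == 0)
    if dup.size:
        raise TrackFormatError(
            f"{path}: duplicate frame index {frames[dup[0]]} at row {int(dup[0]) + 1}"
        )
    x = df[cols["x"]].to_numpy(dtype=float)[order]
    y = df[cols["y"]].to_numpy(dtype=float)[order]

    traj = Trajectory(
        specimen_id=specimen_id or meta.get("specimen_id", path.stem),
        frames=frames,
        x=x,
        y=y,
        fps=fps if fps is not None else float(meta.get("fps", DEFAULT_FPS)),
        px_per_cm=float(meta["px_per_cm"]) if "px_per_cm" in meta else None,
    )
    if traj.n_tracked < 2:
        raise DegenerateInputError(
            f"{path}: only {traj.n_tracked} tracked frame(s); need at least 2"
        )
    return traj


def write_track_table(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as a comma-separated track table.

    Floats use shortest round-trip repr, so
    ``read_track_table(write_track_table(t))`` is the identity, missing
    flags included.
    """
    path = Path(path)
    lines = [f"# specimen_id={traj.specimen_id}", f"# fps={traj.fps!r}"]
    if traj.px_per_cm is not None:
        lines.append(f"# px_per_cm={traj.px_per_cm!r}")
    lines.append("frame,x,y")
    for f, x, y, m in zip(traj.frames, traj.x, traj.y, traj.missing_mask):
        if m:
            lines.append(f"{f},,")
        else:
            lines.append(f"{f},{float(x)!r},{float(y)!r}")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise TrackFormatError(f"cannot write track table {path}: {exc}") from exc


def segment_trajectory(
    traj: Trajectory, seg_len: int = DEFAULT_SEGMENT_LENGTH
) -> SegmentSet:
    """Cut a trajectory into consecutive full segments of ``seg_len`` frames.

    A trailing partial segment is discarded rather than padded, so every
    segment analysed has identical length and scale profiles are comparable.
    """
    if seg_len < 2:
        raise ParameterError(f"seg_len must be >= 2, got {seg_len}")
    k = len(traj) // seg_len
    segments = []
    for i in range(k):
        sl = slice(i * seg_len, (i + 1) * seg_len)
        segments.append(
            Trajectory(
                specimen_id=f"{traj.specimen_id}/seg{i}",
                frames=traj.frames[sl].copy(),
                x=traj.x[sl].copy(),
                y=traj.y[sl].copy(),
                fps=traj.fps,
                px_per_cm=traj.px_per_cm,
                missing_mask=traj.missing_mask[sl].copy(),
            )
        )
    return SegmentSet(traj.specimen_id, seg_len, segments)


def calibrate(traj: Trajectory, arena: ArenaSpec) -> Trajectory:
    """Set the pixel-to-centimetre scale from the arena circle.

    px_per_cm = (2 * radius_px) / diameter_cm; coordinates stay in pixels.
    """
    if arena.radius_px <= 0:
        raise ParameterError(f"arena radius_px must be positive, got {arena.radius_px}")
    return traj.replace(px_per_cm=2.0 * arena.radius_px / arena.diameter_cm)


def read_metadata_table(path: str | Path) -> pd.DataFrame:
    """Read the specimen metadata table (delimited text, header row)."""
    path = Path(path)
    text = path.read_text()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep)
    required = {
        "specimen_id",
        "family",
        "microhabitat",
        "treatment",
        "site",
        "body_length_cm",
        "lyo_weight_mg",
    }
    missing = required - set(df.columns)
    if missing:
        raise TrackFormatError(f"{path}: metadata missing columns {sorted(missing)}")
    return df
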