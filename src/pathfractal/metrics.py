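"""Locomotor trait extraction: mean speed, maximum speed reached (MSR) and
total path length (TPL), all in centimetres via the arena calibration.

Missing frames are bridged by the straight chord between the flanking
tracked positions — the shortest path consistent with the observations — so
TPL is a lower bound during tracker dropouts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import medfilt

from .errors import (
    CalibrationError,
    DegenerateInputError,
    ParameterError,
    PathfractalError,
)
from .trajectory import Trajectory

FAMILIES = ("Baetidae", "Leptophlebiidae")
MICROHABITATS = ("boulders", "gravels", "macrophytes", "detritus", "pebbles", "sand")
TREATMENTS = ("control", "+5C", "+10C")

FDI_COLUMNS = ("FDIr", "FDIb", "FDId")
TRAIT_COLUMNS = ("mean_speed", "msr", "tpl")
MORPH_COLUMNS = ("body_length_cm", "lyo_weight_mg")


@dataclass
class LocomotorTraits:
    mean_speed: float  # cm/s
    msr: float  # maximum speed reached, cm/s
    tpl: float  # total path length, cm
    duration_s: float


def _require_calibrated(traj: Trajectory) -> float:
    if traj.px_per_cm is None:
        raise CalibrationError(
            f"{traj.specimen_id}: px_per_cm unset; calibrate before computing cm metrics"
        )
    return traj.px_per_cm


def total_path_length(traj: Trajectory) -> float:
    """Sum of Euclidean inter-frame displacements over tracked frames, in cm."""
    ppc = _require_calibrated(traj)
    _, x, y = traj.tracked_xy()
    if len(x) < 2:
        raise DegenerateInputError(
            f"{traj.specimen_id}: need >= 2 tracked frames for path length"
        )
    return float(np.hypot(np.diff(x), np.diff(y)).sum() / ppc)


def speeds(traj: Trajectory, smoothing_window: int = 1) -> np.ndarray:
    """Per-interval speeds (cm/s) between consecutive tracked frames.

    Each interval's speed is chord length over elapsed time, so a gap of k
    missing frames yields one (conservative) speed over k/fps seconds. An
    odd ``smoothing_window`` > 1 applies a median filter, damping
    single-frame tracking glitches before the maximum is taken.
    """
    ppc = _require_calibrated(traj)
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ParameterError(f"smoothing_window must be odd and >= 1, got {smoothing_window}")
    fr, x, y = traj.tracked_xy()
    if len(x) < 2:
        raise DegenerateInputError(f"{traj.specimen_id}: need >= 2 tracked frames")
    disp_cm = np.hypot(np.diff(x), np.diff(y)) / ppc
    dt = np.diff(fr) / traj.fps
    v = disp_cm / dt
    if smoothing_window > 1 and len(v) >= smoothing_window:
        v = medfilt(v, kernel_size=smoothing_window)
    return v


def locomotor_traits(traj: Trajectory, smoothing_window: int = 1) -> LocomotorTraits:
    """TPL, mean speed (= TPL / tracked duration) and MSR for one trajectory."""
    fr, _, _ = traj.tracked_xy()
    tpl = total_path_length(traj)
    duration = (fr[-1] - fr[0]) / traj.fps
    v = speeds(traj, smoothing_window=smoothing_window)
    return LocomotorTraits(
        mean_speed=tpl / duration,
        msr=float(v.max()),
        tpl=tpl,
        duration_s=float(duration),
    )


def assemble_specimen_table(
    traits: dict[str, LocomotorTraits],
    metadata: pd.DataFrame,
    fdi: dict[str, dict[str, float]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join traits, metadata and FDI estimates into wide and long tables.

    ``traits`` and ``fdi`` are keyed by specimen id; ``fdi`` values map
    column name (FDIr/FDIb/FDId) to the estimate (NaN allowed). The wide
    table has one row per specimen; the long view is keyed by
    (specimen_id, variable) with missing values dropped, matching the
    reshaping used for plotting and per-variable NA exclusion.
    """
    meta_ids = set(metadata["specimen_id"])
    orphans = sorted((set(traits) | set(fdi)) - meta_ids)
    if orphans:
        raise PathfractalError(f"specimens without metadata: {orphans}")
    levels = {"family": FAMILIES, "microhabitat": MICROHABITATS, "treatment": TREATMENTS}
    for col, allowed in levels.items():
        bad = set(metadata[col]) - set(allowed)
        if bad:
            raise PathfractalError(f"unknown {col} level(s): {sorted(bad)}")

    rows = []
    for _, m in metadata.iterrows():
        sid = m["specimen_id"]
        t = traits.get(sid)
        f = fdi.get(sid, {})
        rows.append(
            {
                "specimen_id": sid,
                "family": m["family"],
                "microhabitat": m["microhabitat"],
                "treatment": m["treatment"],
                "site": m["site"],
                "body_length_cm": m["body_length_cm"],
                "lyo_weight_mg": m["lyo_weight_mg"],
                "mean_speed": t.mean_speed if t else np.nan,
                "msr": t.msr if t else np.nan,
                "tpl": t.tpl if t else np.nan,
                **{c: f.get(c, np.nan) for c in FDI_COLUMNS},
            }
        )
    wide = pd.DataFrame(rows)
    long = wide.melt(
        id_vars=["specimen_id", "family", "microhabitat", "treatment", "site"],
        value_vars=list(FDI_COLUMNS) + list(TRAIT_COLUMNS),
        var_name="variable",
        value_name="value",
    ).dropna(subset=["value"]).reset_index(drop=True)
    return wide, long
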