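"""End-to-end glue: trajectories -> specimen table -> statistics tables.

The CLI wraps these functions; they are equally usable from a notebook.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import fractal, metrics, stats
from .errors import PathfractalError
from .trajectory import (
    DEFAULT_SEGMENT_LENGTH,
    Trajectory,
    read_track_table,
    segment_trajectory,
)

log = logging.getLogger("pathfractal")


def load_tracks(tracks_dir: str | Path, dialect: str = "generic") -> list[Trajectory]:
    """Read every ``*.csv``/``*.tsv`` track table in a directory."""
    tracks_dir = Path(tracks_dir)
    paths = sorted(list(tracks_dir.glob("*.csv")) + list(tracks_dir.glob("*.tsv")))
    if not paths:
        raise PathfractalError(f"no track tables found in {tracks_dir}")
    return [read_track_table(p, dialect=dialect) for p in paths]


def estimate_specimens(
    trajectories: list[Trajectory],
    metadata: pd.DataFrame,
    resolution: int = 256,
    seg_len: int = DEFAULT_SEGMENT_LENGTH,
    aggregate: str = "mean",
    max_missing: float = fractal.DEFAULT_MAX_MISSING,
    smoothing_window: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute locomotor traits and the three FDIs for every specimen.

    ``aggregate="mean"`` estimates each index per full ``seg_len``-frame
    segment and averages over segments; ``"whole"`` estimates on the whole
    path. Specimens with no full segment get NaN indices (flagged in the
    log) but keep their locomotor traits.
    """
    if aggregate not in ("mean", "whole"):
        raise PathfractalError(f"aggregate must be 'mean' or 'whole', got {aggregate!r}")
    traits: dict[str, metrics.LocomotorTraits] = {}
    fdis: dict[str, dict[str, float]] = {}
    for traj in trajectories:
        sid = traj.specimen_id
        traits[sid] = metrics.locomotor_traits(traj, smoothing_window=smoothing_window)
        if aggregate == "whole":
            est = fractal.estimate_all_fdis(
                traj, resolution=resolution, max_missing=max_missing
            )
            fdis[sid] = {k: v.D for k, v in est.items()}
        else:
            segs = segment_trajectory(traj, seg_len=seg_len)
            if len(segs) == 0:
                log.warning("%s: %d frames < one %d-frame segment; FDIs missing",
                            sid, len(traj), seg_len)
                fdis[sid] = {k: np.nan for k in metrics.FDI_COLUMNS}
                continue
            est = fractal.estimate_all_fdis(
                segs, resolution=resolution, max_missing=max_missing
            )
            fdis[sid] = {k: v.D for k, v in est.items()}
            log.info(
                "%s: %d segments, FDIb=%.3f FDIr=%.3f FDId=%.3f",
                sid, est["FDIb"].n_segments, fdis[sid]["FDIb"],
                fdis[sid]["FDIr"], fdis[sid]["FDId"],
            )
    return metrics.assemble_specimen_table(traits, metadata, fdis)


def analyze_h1(wide: pd.DataFrame) -> pd.DataFrame:
    """Levene (Brown–Forsythe) and one-way ANOVA of each FDI by treatment."""
    rows = []
    for col in metrics.FDI_COLUMNS:
        if col not in wide or wide[col].notna().sum() < 6:
            continue
        sub = wide.dropna(subset=[col])
        w, p_lev = stats.levene_test(sub[col], sub["treatment"])
        an = stats.oneway_anova(sub[col], sub["treatment"])
        rows.append(
            {"variable": col, "levene_W": w, "levene_p": p_lev,
             "anova_F": an.F, "anova_p": an.p,
             "df_between": an.df_between, "df_within": an.df_within}
        )
    return pd.DataFrame(rows)


def analyze_h2(
    wide: pd.DataFrame, candidates=stats.CANDIDATE_FORMULAS
) -> dict[str, object]:
    """Model selection per FDI, per-microhabitat ANOVA of FDIr, PCA,
    MANOVA and Tukey HSD tables."""
    out: dict[str, object] = {}
    selection = {}
    for col in metrics.FDI_COLUMNS:
        if col not in wide or wide[col].notna().sum() < 10:
            continue
        selection[col] = stats.aic_model_selection(wide, col, candidates=candidates)
    out["model_selection"] = selection

    if "FDIr" in wide:
        rows = []
        for hab, sub in wide.dropna(subset=["FDIr"]).groupby("microhabitat"):
            if sub["treatment"].nunique() < 2 or len(sub) < 6:
                continue
            an = stats.oneway_anova(sub["FDIr"], sub["treatment"])
            rows.append({"microhabitat": hab, "F": an.F, "p": an.p, "n": len(sub)})
        out["fdir_by_microhabitat"] = pd.DataFrame(rows)

    have_all = all(c in wide for c in metrics.FDI_COLUMNS)
    if have_all and wide.dropna(subset=list(metrics.FDI_COLUMNS)).shape[0] >= 3:
        out["pca"] = stats.pca_fdi(wide)
        out["manova"] = stats.manova_pillai(wide)
    else:
        out["notices"] = ["pca/manova skipped: need all three FDI columns"]
    tukey = {}
    for col in metrics.FDI_COLUMNS:
        if col not in wide:
            continue
        sub = wide.dropna(subset=[col])
        tabs = []
        for factor in ("family", "microhabitat"):
            counts = sub.groupby(factor)[col].count()
            keep = counts[counts >= 2].index
            s2 = sub[sub[factor].isin(keep)]
            if s2[factor].nunique() < 2:
                continue
            t = stats.tukey_hsd(s2[col], s2[factor])
            t.insert(0, "factor", factor)
            tabs.append(t)
        if tabs:
            tukey[col] = pd.concat(tabs, ignore_index=True)
    out["tukey"] = tukey
    return out


def analyze_h3(wide: pd.DataFrame) -> dict[str, object]:
    """RDA constrained by family and the Pearson correlation matrix."""
    variables = [
        c
        for c in list(metrics.FDI_COLUMNS)
        + list(metrics.TRAIT_COLUMNS)
        + list(metrics.MORPH_COLUMNS)
        if c in wide and wide[c].notna().sum() >= 3
    ]
    out: dict[str, object] = {}
    out["rda"] = stats.rda_traits(wide, tuple(variables), constraint="family")
    out["correlation"] = stats.pearson_matrix(wide, variables)
    return out
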