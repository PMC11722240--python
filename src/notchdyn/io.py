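"""Readers and writers for the pipeline's flat-table interchange formats.

Upstream segmentation and tracking are out of scope, so everything enters
and leaves as CSV: single-cell intensity tables, long-format track tables,
trajectory and phase-map exports, and a JSON run manifest.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .circuit import PhaseMap, Trajectory
from .exceptions import DataError, SchemaError

__all__ = [
    "CELL_COLUMNS",
    "TRACK_COLUMNS",
    "read_cell_table",
    "read_track_table",
    "write_trajectory",
    "write_phase_map",
    "write_manifest",
]

logger = logging.getLogger(__name__)

CELL_COLUMNS = ["cell_id", "gut_id", "condition", "intensity", "esg_pos", "delta_pos", "ph3_pos"]
TRACK_COLUMNS = ["movie_id", "cell_id", "condition", "frame", "time_min", "gfp", "rfp"]
_BOOL_COLUMNS = ["esg_pos", "delta_pos", "ph3_pos"]


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {missing}")


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a single-cell intensity table.

    Rows with non-numeric or non-positive intensity (the log-transform
    precondition) are rejected and reported with their 1-based data line
    numbers; boolean marker flags accept 0/1 or true/false.
    """
    df = pd.read_csv(Path(path))
    _require_columns(df, CELL_COLUMNS, f"cell table {path}")
    intensity = pd.to_numeric(df["intensity"], errors="coerce")
    bad = ~(intensity > 0) | intensity.isna()
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad][:20]]  # +2: header + 1-based
        logger.warning(
            "cell table %s: rejected %d row(s) with non-positive/non-numeric intensity (lines %s)",
            path, int(bad.sum()), lines,
        )
    out = df.loc[~bad].copy()
    if len(out) == 0:
        raise DataError(f"cell table {path} has no valid rows")
    out["intensity"] = intensity[~bad]
    for col in _BOOL_COLUMNS:
        out[col] = out[col].map(
            {True: True, False: False, 1: True, 0: False, "1": True, "0": False,
             "true": True, "false": False, "True": True, "False": False}
        )
        if out[col].isna().any():
            raise SchemaError(f"cell table {path}: column {col!r} has non-boolean values")
        out[col] = out[col].astype(bool)
    return out.reset_index(drop=True)


def read_track_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format track table, sorted by (movie, cell, frame).

    Duplicate (movie, cell, frame) rows are an error naming the offenders;
    frame gaps are tolerated but logged per track.
    """
    df = pd.read_csv(Path(path))
    _require_columns(df, TRACK_COLUMNS, f"track table {path}")
    dup = df.duplicated(subset=["movie_id", "cell_id", "frame"], keep=False)
    if dup.any():
        offenders = df.loc[dup, ["movie_id", "cell_id", "frame"]].drop_duplicates().head(10)
        raise DataError(f"duplicate (cell, frame) rows in {path}:\n{offenders.to_string(index=False)}")
    df = df.sort_values(["movie_id", "cell_id", "frame"]).reset_index(drop=True)
    for (movie_id, cell_id), grp in df.groupby(["movie_id", "cell_id"]):
        frames = grp["frame"].to_numpy()
        gaps = int((np.diff(frames) > 1).sum())
        if gaps:
            logger.warning("track %s/%s has %d frame gap(s)", movie_id, cell_id, gaps)
    return df


def write_trajectory(traj: Trajectory, path: str | Path) -> pd.DataFrame:
    """Write a trajectory as long CSV: time, cell, notch, delta, reporter."""
    frames = []
    for cell in range(traj.n_cells):
        frames.append(
            pd.DataFrame(
                {
                    "time": traj.times,
                    "cell": cell,
                    "notch": traj.notch[:, cell],
                    "delta": traj.delta[:, cell],
                    "reporter": traj.reporter[:, cell],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False)
    return out


def write_phase_map(pm: PhaseMap, path: str | Path) -> pd.DataFrame:
    """Write a phase map as long CSV: kn, kd, value."""
    kn, kd = np.meshgrid(pm.kn_values, pm.kd_values, indexing="ij")
    out = pd.DataFrame({"kn": kn.ravel(), "kd": kd.ravel(), "value": pm.values.ravel()})
    out.to_csv(path, index=False)
    return out


def write_manifest(path: str | Path, seed: int | None = None, **entries) -> dict:
    """Write a machine-readable run manifest (versions, seed, parameters)."""
    import notchdyn

    manifest = {
        "package": "notchdyn",
        "version": notchdyn.__version__,
        "python": platform.python_version(),
        "seed": seed,
        **entries,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
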