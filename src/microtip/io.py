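"""File I/O: CSV profiles and trajectories, TIFF kymographs, YAML configs.

Conventions: axial positions in nm with 0 at the left profile edge,
kymograph rows = time increasing downward, profiles oriented lattice at
lower x.  Profile CSVs carry pixel size (and other scalars) as
``# key: value`` comment headers so files round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .containers import AveragedProfile, IntensityProfile, Trajectory
from .dynamics import PhaseSegment

__all__ = [
    "write_profile_csv", "read_profile_csv",
    "write_trajectory_csv", "read_trajectory_csv",
    "write_kymograph_tiff", "read_kymograph_tiff",
    "write_averaged_profile_csv", "read_averaged_profile_csv",
    "write_segments_csv", "read_segments_csv",
    "load_config", "save_config", "save_report",
    "load_inputs",
]


def _write_csv_with_meta(path, df: pd.DataFrame, meta: dict):
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def _read_csv_with_meta(path):
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return df, meta


def write_profile_csv(profile: IntensityProfile, path):
    _write_csv_with_meta(path, pd.DataFrame({"x_nm": profile.x,
                                             "intensity": profile.intensity}),
                         {"pixel_size_nm": profile.pixel_size})


def read_profile_csv(path) -> IntensityProfile:
    df, meta = _read_csv_with_meta(path)
    for col in ("x_nm", "intensity"):
        if col not in df.columns:
            raise ValueError(f"profile CSV {path} is missing column {col!r}")
    if "pixel_size_nm" not in meta:
        raise ValueError(f"profile CSV {path} is missing the "
                         "'# pixel_size_nm:' metadata header")
    return IntensityProfile(df["x_nm"].to_numpy(), df["intensity"].to_numpy(),
                            float(meta["pixel_size_nm"]))


def write_trajectory_csv(traj: Trajectory, path):
    df = pd.DataFrame({"t_s": traj.times, "length_nm": traj.observed_lengths,
                       "true_length_nm": traj.true_lengths})
    if traj.phases is not None:
        df["phase"] = traj.phases
    _write_csv_with_meta(path, df, {})


def read_trajectory_csv(path) -> Trajectory:
    df, _ = _read_csv_with_meta(path)
    for col in ("t_s", "length_nm"):
        if col not in df.columns:
            raise ValueError(f"trajectory CSV {path} is missing column {col!r}")
    true = df["true_length_nm"].to_numpy() if "true_length_nm" in df.columns \
        else df["length_nm"].to_numpy()
    phases = df["phase"].to_numpy() if "phase" in df.columns else None
    return Trajectory(df["t_s"].to_numpy(), true, df["length_nm"].to_numpy(),
                      phases=phases)


def write_kymograph_tiff(kymo, path):
    """Write a single-channel kymograph (rows = time) as float32 TIFF."""
    tifffile.imwrite(path, np.asarray(kymo, dtype=np.float32))


def read_kymograph_tiff(path, time_axis="rows"):
    """Read a kymograph TIFF; ``time_axis='columns'`` transposes on load.

    The time-axis orientation is a config flag, never guessed from shape.
    """
    arr = np.asarray(tifffile.imread(path), dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"kymograph TIFF {path} must be single-channel 2D, "
                         f"got shape {arr.shape}")
    if time_axis == "columns":
        return arr.T
    if time_axis != "rows":
        raise ValueError("time_axis must be 'rows' or 'columns'")
    return arr


def write_averaged_profile_csv(ap: AveragedProfile, path):
    _write_csv_with_meta(
        path,
        pd.DataFrame({"x_nm": ap.grid, "mean": ap.mean, "sem": ap.sem}),
        {"grid_step_nm": ap.grid_step, "n_profiles": ap.n_profiles,
         "n_kymographs": ap.n_kymographs},
    )


def read_averaged_profile_csv(path) -> AveragedProfile:
    df, meta = _read_csv_with_meta(path)
    return AveragedProfile(df["x_nm"].to_numpy(), df["mean"].to_numpy(),
                           df["sem"].to_numpy(),
                           n_profiles=int(meta.get("n_profiles", 0)),
                           n_kymographs=int(meta.get("n_kymographs", 0)),
                           grid_step=float(meta.get("grid_step_nm", 32.5)))


def write_segments_csv(segments, path):
    df = pd.DataFrame({
        "t_start_s": [s.t_start for s in segments],
        "t_end_s": [s.t_end for s in segments],
        "slope_nm_per_s": [s.slope for s in segments],
        "phase": [s.phase for s in segments],
        "y_start_nm": [s.y_start for s in segments],
        "y_end_nm": [s.y_end for s in segments],
    })
    _write_csv_with_meta(path, df, {})


def read_segments_csv(path):
    df, _ = _read_csv_with_meta(path)
    return [PhaseSegment(r.t_start_s, r.t_end_s, r.slope_nm_per_s,
                         phase=None if pd.isna(r.phase) else r.phase,
                         y_start=r.y_start_nm, y_end=r.y_end_nm)
            for r in df.itertuples()]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path):
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def save_report(report: dict, path):
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


_LOADERS = {
    "profile_csv": read_profile_csv,
    "trajectory_csv": read_trajectory_csv,
    "kymograph_tiff": read_kymograph_tiff,
    "averaged_profile_csv": read_averaged_profile_csv,
    "events_csv": read_segments_csv,
}


def load_inputs(path, kind):
    """Load a typed input file; ``kind`` selects schema and container."""
    if kind not in _LOADERS:
        raise ValueError(f"unknown input kind {kind!r}; "
                         f"expected one of {sorted(_LOADERS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return _LOADERS[kind](path)
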