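"""Readers and writers for the package's tabular formats.

Gaze recordings are plain CSV/TSV, one row per sample. Three column
dialects are supported, declared in a YAML/JSON config or inferred from
the columns present:

* precombined gaze: ``t, gaze_lon, gaze_lat`` (optional ``head_lon,
  head_lat``);
* head + eye-in-head angles: ``t, head_lon, head_lat, eye_lon, eye_lat``;
* head quaternion + eye-in-head: ``t, qw, qx, qy, qz, eye_lon, eye_lat``.

In the last two dialects gaze (eye-in-space) is computed by rotating the
eye-in-head direction by the head orientation.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import yaml

from . import geometry
from .search import SceneObject, load_scene_layout, save_scene_layout  # re-exported

__all__ = [
    "read_gaze_samples", "write_gaze_samples", "read_trials", "write_trials",
    "load_scene_layout", "save_scene_layout", "load_config",
]


def load_config(path) -> dict:
    with open(path) as fh:
        if str(path).endswith(".json"):
            return json.load(fh)
        return yaml.safe_load(fh) or {}


def read_gaze_samples(path, dialect: str | None = None, sep: str = ",") -> pd.DataFrame:
    """Load a gaze recording and return t, gaze_lon/lat (+ head if present)."""
    df = pd.read_csv(path, sep=sep)
    cols = set(df.columns)
    if dialect is None:
        if {"gaze_lon", "gaze_lat"} <= cols:
            dialect = "gaze"
        elif {"qw", "qx", "qy", "qz", "eye_lon", "eye_lat"} <= cols:
            dialect = "quaternion"
        elif {"head_lon", "head_lat", "eye_lon", "eye_lat"} <= cols:
            dialect = "head_eye"
        else:
            raise ValueError(f"unrecognized gaze columns: {sorted(cols)}")
    if dialect == "gaze":
        out = df[["t", "gaze_lon", "gaze_lat"]].copy()
        if {"head_lon", "head_lat"} <= cols:
            out["head_lon"] = df["head_lon"]
            out["head_lat"] = df["head_lat"]
        return out
    if dialect == "head_eye":
        rot = geometry.head_rotation(df["head_lon"].to_numpy(), df["head_lat"].to_numpy())
        vec = rot.apply(geometry.unit_vector(df["eye_lon"].to_numpy(), df["eye_lat"].to_numpy()))
        lon, lat = geometry.to_lonlat(vec)
        return pd.DataFrame({"t": df["t"], "gaze_lon": lon, "gaze_lat": lat,
                             "head_lon": df["head_lon"], "head_lat": df["head_lat"]})
    if dialect == "quaternion":
        rot = geometry.head_rotation_from_quat(df["qw"].to_numpy(), df["qx"].to_numpy(),
                                               df["qy"].to_numpy(), df["qz"].to_numpy())
        vec = rot.apply(geometry.unit_vector(df["eye_lon"].to_numpy(), df["eye_lat"].to_numpy()))
        lon, lat = geometry.to_lonlat(vec)
        head_fwd = rot.apply(np.array([1.0, 0.0, 0.0]))
        hlon, hlat = geometry.to_lonlat(head_fwd)
        return pd.DataFrame({"t": df["t"], "gaze_lon": lon, "gaze_lat": lat,
                             "head_lon": hlon, "head_lat": hlat})
    raise ValueError(f"unknown dialect {dialect!r}")


def write_gaze_samples(df: pd.DataFrame, path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)


def read_trials(path, sep: str = ",") -> pd.DataFrame:
    """Trial metadata: participant, scene, condition, trial_index, target,
    cue_offset_t, response_t, selected_object, timeout."""
    df = pd.read_csv(path, sep=sep)
    df["timeout"] = df["timeout"].astype(bool)
    if "selected_object" in df.columns:
        df["selected_object"] = df["selected_object"].replace({np.nan: None, "": None})
    return df


def write_trials(df: pd.DataFrame, path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)
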