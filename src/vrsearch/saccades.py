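"""Saccade direction and latitude statistics.

Absolute direction angles are measured against the longitudinal axis in
the local tangent plane at saccade onset: 0 deg = rightward (increasing
longitude), 90 deg = up, 180 deg = left, 270 deg = down. Relative angles
are measured against the previous saccade's absolute angle (0 = forward
continuation, 180 = backward/return saccade). Absolute directions are
binned into four 90-degree sectors centered on the cardinal directions
(e.g. "left" covers [135, 225), lower edge inclusive).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import geometry
from .events import SACCADE, GazeEvent

SECTORS = ("right", "up", "left", "down")


class UndefinedAngleError(ValueError):
    """Direction angle of a zero-amplitude displacement."""


def displacement_angle(lon0, lat0, lon1, lat1, scale_by_cos_lat: bool = True) -> float:
    """Angle of the onset->offset displacement in degrees [0, 360).

    The longitudinal component is scaled by cos(latitude at onset) so the
    angle is geometrically correct away from the horizon; ``scale_by_cos_lat
    = False`` gives the raw equirectangular angle.
    """
    dlon = float(geometry.wrap_longitude(lon1 - lon0))
    dlat = float(lat1 - lat0)
    if scale_by_cos_lat:
        dlon *= math.cos(math.radians(lat0))
    if dlon == 0.0 and dlat == 0.0:
        raise UndefinedAngleError("zero-amplitude displacement has no direction")
    return math.degrees(math.atan2(dlat, dlon)) % 360.0


def absolute_angle(saccade: GazeEvent, scale_by_cos_lat: bool = True) -> float:
    """Absolute direction of a saccade (0 = right, CCW positive)."""
    if saccade.amplitude <= 0.0:
        raise UndefinedAngleError("zero-amplitude saccade has no direction")
    return displacement_angle(
        saccade.onset.lon, saccade.onset.lat, saccade.offset.lon, saccade.offset.lat,
        scale_by_cos_lat,
    )


def relative_angle(angle: float, previous_angle: float) -> float:
    """Direction relative to the previous saccade, degrees [0, 360)."""
    return (angle - previous_angle) % 360.0


def bin_direction(angle_abs: float) -> str:
    """Sector of an absolute angle: right/up/left/down (90 deg each).

    Lower sector edge inclusive, upper exclusive; e.g. 135 -> left,
    225 -> down.
    """
    a = float(angle_abs) % 360.0
    return SECTORS[int(((a + 45.0) % 360.0) // 90.0)]


def gaze_latitude(fixations: list[GazeEvent]) -> float:
    """Duration-weighted mean fixation-centroid latitude of a trial.

    Positive = above the horizon. Returns NaN when the trial has no
    fixations.
    """
    durs = np.array([f.duration for f in fixations if f.kind == "fixation"])
    lats = np.array([f.centroid.lat for f in fixations if f.kind == "fixation"])
    if durs.size == 0 or durs.sum() <= 0:
        return float("nan")
    return float(np.average(lats, weights=durs))


def saccade_angles(events: list[GazeEvent], scale_by_cos_lat: bool = True) -> pd.DataFrame:
    """Absolute and relative angles for every saccade of a trial.

    The first saccade has no relative angle (NaN); zero-amplitude
    saccades (possible after heavy smoothing) are skipped.
    """
    rows = []
    prev = None
    for ev in events:
        if ev.kind != SACCADE:
            continue
        try:
            ang = absolute_angle(ev, scale_by_cos_lat)
        except UndefinedAngleError:
            continue
        rows.append(
            {
                "onset_t": ev.onset_t,
                "amplitude_deg": ev.amplitude,
                "abs_angle_deg": ang,
                "rel_angle_deg": relative_angle(ang, prev) if prev is not None else np.nan,
                "sector": bin_direction(ang),
            }
        )
        prev = ang
    return pd.DataFrame(rows, columns=["onset_t", "amplitude_deg", "abs_angle_deg",
                                       "rel_angle_deg", "sector"])


def tabulate_directions(saccade_table: pd.DataFrame,
                        by=("participant", "condition", "channel")) -> pd.DataFrame:
    """Sector counts and proportions per participant x condition x channel.

    ``saccade_table`` needs the grouping columns plus ``abs_angle_deg``
    (movements pooled per cell, not averaged per trial first). All four
    sectors are present in the output, zero-filled.
    """
    df = saccade_table.dropna(subset=["abs_angle_deg"]).copy()
    df["sector"] = [bin_direction(a) for a in df["abs_angle_deg"]]
    by = [b for b in by if b in df.columns]
    counts = (
        df.groupby(by + ["sector"], observed=True).size().rename("count").reset_index()
    )
    full = []
    for keys, sub in counts.groupby(by, observed=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        base = dict(zip(by, keys))
        total = int(sub["count"].sum())
        present = dict(zip(sub["sector"], sub["count"]))
        for sector in SECTORS:
            c = int(present.get(sector, 0))
            full.append({**base, "sector": sector, "count": c,
                         "proportion": c / total if total else np.nan, "total": total})
    return pd.DataFrame(full)


def plot_direction_histogram(angles_deg, ax=None, bins: int = 36, **kwargs):
    """Polar histogram of saccade directions (0 deg = right, CCW)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    theta = np.radians(np.asarray(angles_deg, dtype=float) % 360.0)
    edges = np.linspace(0, 2 * np.pi, bins + 1)
    hist, _ = np.histogram(theta, bins=edges)
    ax.bar((edges[:-1] + edges[1:]) / 2, hist, width=np.diff(edges), align="center", **kwargs)
    return ax
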