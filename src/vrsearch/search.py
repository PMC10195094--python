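"""Trial-level visual-search measures.

A search trial runs from cue offset to button press (or the 15 s
timeout). Fixations are assigned to scene objects by angular containment
(each object is an angular disc seen from the viewpoint); from the
resulting object stream the trial yields:

* accuracy, with the gaze-based correction for mis-clicks (a wrong
  selection counts as correct when gaze is on the target at selection);
* the additive decomposition of response time into initiation time (cue
  offset -> first saccade onset), scanning time (first saccade onset ->
  first target-fixation onset) and verification time (first
  target-fixation onset -> button press);
* count measures (fixations, distinct fixated objects, target
  refixations) and gaze duration per object;
* the exclusion cascade: incorrect trials, trials without saccades,
  trials whose first fixation already lands on the target, and trials
  beyond a +3 SD cut-off on log initiation or verification time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry
from .events import FIXATION, SACCADE, GazeEvent

EXCLUSION_LABELS = ("incorrect", "no_saccade", "first_fix_on_target", "sd_cutoff")


@dataclass
class SceneObject:
    """An object's angular footprint from the participant's viewpoint."""

    object_id: str
    lon: float
    lat: float
    radius_deg: float
    kind: str = "local"  # "local" or "anchor"


def save_scene_layout(layout: list[SceneObject], path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {o.object_id: {"lon": o.lon, "lat": o.lat, "radius_deg": o.radius_deg, "kind": o.kind}
             for o in layout},
            fh, indent=1,
        )


def load_scene_layout(path) -> list[SceneObject]:
    with open(path) as fh:
        raw = json.load(fh)
    return [SceneObject(k, v["lon"], v["lat"], v["radius_deg"], v.get("kind", "local"))
            for k, v in raw.items()]


def assign_fixations_to_objects(lons, lats, layout: list[SceneObject]) -> list[str | None]:
    """Map fixation centroids to objects by angular-disc containment.

    A fixation belongs to the object whose disc contains it; when discs
    overlap the nearest center wins; outside all discs -> ``None``.
    """
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    if not layout:
        return [None] * lons.size
    obj_lon = np.array([o.lon for o in layout])
    obj_lat = np.array([o.lat for o in layout])
    radii = np.array([o.radius_deg for o in layout])
    ids = [o.object_id for o in layout]
    dists = geometry.orthodromic_distance(
        lons[:, None], lats[:, None], obj_lon[None, :], obj_lat[None, :]
    )
    inside = dists <= radii[None, :]
    out: list[str | None] = []
    for i in range(lons.size):
        if not inside[i].any():
            out.append(None)
            continue
        masked = np.where(inside[i], dists[i], np.inf)
        out.append(ids[int(np.argmin(masked))])
    return out


def fixation_object_stream(events: list[GazeEvent], layout: list[SceneObject]) -> list[str | None]:
    """Object assignment for each fixation event, in order."""
    fixs = [ev for ev in events if ev.kind == FIXATION]
    if not fixs:
        return []
    return assign_fixations_to_objects(
        [f.centroid.lon for f in fixs], [f.centroid.lat for f in fixs], layout
    )


def object_at_time(events: list[GazeEvent], stream: list[str | None], t: float) -> str | None:
    """Object of the fixation active at (or last ending before) time t."""
    current = None
    k = -1
    for ev in events:
        if ev.kind != FIXATION:
            continue
        k += 1
        if ev.onset_t <= t:
            current = stream[k]
        else:
            break
    return current


def apply_accuracy_correction(selected_object, target, timeout: bool,
                              gaze_object_at_selection) -> bool:
    """Correct = right object selected, or gaze on target at selection.

    Timeout trials are always incorrect (the gaze correction does not
    apply to them).
    """
    if timeout:
        return False
    return selected_object == target or gaze_object_at_selection == target


def decompose_rt(cue_offset_t: float, response_t: float, events: list[GazeEvent],
                 stream: list[str | None], target) -> dict:
    """Split RT into initiation / scanning / verification (seconds).

    Initiation = cue offset to the onset of the first saccade; scanning =
    first saccade onset to the onset of the first target fixation that
    follows it; verification = that onset to the button press. The three
    phases are additive to RT by construction. Flags:
    ``no_saccade`` (no saccade detected), ``first_fix_on_target`` (the
    first post-saccade fixation is already on the target),
    ``target_not_fixated`` (correct trial without a target fixation;
    retained for RT only).
    """
    out = {"initiation": np.nan, "scanning": np.nan, "verification": np.nan,
           "no_saccade": False, "first_fix_on_target": False, "target_not_fixated": False}
    first_sacc = next((ev for ev in events if ev.kind == SACCADE), None)
    if first_sacc is None:
        out["no_saccade"] = True
        return out
    out["initiation"] = first_sacc.onset_t - cue_offset_t
    fix_events = [ev for ev in events if ev.kind == FIXATION]
    post = [(ev, obj) for ev, obj in zip(fix_events, stream) if ev.onset_t >= first_sacc.onset_t]
    first_target = next(((ev, obj) for ev, obj in post if obj == target), None)
    if first_target is None:
        out["target_not_fixated"] = True
        return out
    ev_target = first_target[0]
    if post and post[0][1] == target and post[0][0] is ev_target:
        out["first_fix_on_target"] = True
    out["scanning"] = ev_target.onset_t - first_sacc.onset_t
    out["verification"] = response_t - ev_target.onset_t
    return out


def count_measures(events: list[GazeEvent], stream: list[str | None], target) -> dict:
    """Fixation counts, distinct fixated objects, target refixations.

    Target refixations = number of maximal runs of consecutive target
    fixations minus one (floored at zero): each extra run is a return to
    the target after a non-target fixation.
    """
    fixs = [ev for ev in events if ev.kind == FIXATION]
    n_fix = len(fixs)
    mean_dur = float(np.mean([f.duration for f in fixs])) if fixs else np.nan
    objs = {o for o in stream if o is not None}
    runs = 0
    prev_target = False
    for o in stream:
        is_t = o == target
        if is_t and not prev_target:
            runs += 1
        prev_target = is_t
    return {
        "fixation_count": n_fix,
        "mean_fixation_duration": mean_dur,
        "fixated_objects_count": len(objs),
        "target_refixations": max(runs - 1, 0),
    }


def gaze_duration_by_object(events: list[GazeEvent], stream: list[str | None],
                            t_max: float | None = None) -> dict:
    """Summed fixation duration (s) per assigned object in a trial.

    ``t_max`` (typically the response time) clips fixations that extend
    past the end of the trial.
    """
    durs: dict = {}
    k = -1
    for ev in events:
        if ev.kind != FIXATION:
            continue
        k += 1
        obj = stream[k]
        if obj is None:
            continue
        end = ev.offset_t if t_max is None else min(ev.offset_t, t_max)
        if end > ev.onset_t:
            durs[obj] = durs.get(obj, 0.0) + (end - ev.onset_t)
    return durs


def prior_target_gaze(trial_targets: list, trial_gaze_durations: list[dict]) -> list[float]:
    """Per-trial summed gaze on the trial's target during earlier trials.

    Inputs are ordered by trial index within one scene: the target of
    each trial and the per-object gaze-duration dict of each trial. The
    first trial of a scene gets 0.
    """
    out = []
    for k, target in enumerate(trial_targets):
        out.append(float(sum(d.get(target, 0.0) for d in trial_gaze_durations[:k])))
    return out


def exclusion_cascade(metrics: pd.DataFrame, sd_k: float = 3.0, log_scale: bool = True) -> pd.DataFrame:
    """Label trials with their (single, first-triggered) exclusion cause.

    Order: (1) incorrect, (2) no saccade detected, (3) first fixation on
    the target, (4) initiation or verification beyond mean + ``sd_k`` SD,
    computed per measure on the trials surviving steps 1-3 (log scale by
    default). Returns a copy of ``metrics`` with an ``excluded`` column
    ("none" for included trials).

    Required columns: correct (bool), no_saccade (bool),
    first_fix_on_target (bool), initiation_ms, verification_ms.
    """
    df = metrics.copy()
    excluded = pd.Series("none", index=df.index, dtype=object)
    excluded[~df["correct"].astype(bool)] = "incorrect"
    mask = excluded == "none"
    excluded[mask & df["no_saccade"].astype(bool)] = "no_saccade"
    mask = excluded == "none"
    excluded[mask & df["first_fix_on_target"].astype(bool)] = "first_fix_on_target"
    mask = excluded == "none"
    for col in ("initiation_ms", "verification_ms"):
        vals = df.loc[mask, col].astype(float)
        ok = vals.notna() & (vals > 0 if log_scale else vals.notna())
        x = np.log(vals[ok]) if log_scale else vals[ok]
        if len(x) >= 2 and x.std(ddof=1) > 0:
            cut = x.mean() + sd_k * x.std(ddof=1)
            over = x.index[x > cut]
            excluded[over] = "sd_cutoff"
    df["excluded"] = excluded
    return df


def exclusion_summary(metrics: pd.DataFrame) -> pd.DataFrame:
    """Percentage of trials per exclusion label (of all trials)."""
    n = len(metrics)
    rows = []
    for label in EXCLUSION_LABELS + ("none",):
        c = int((metrics["excluded"] == label).sum())
        rows.append({"label": label, "count": c, "percent": 100.0 * c / n if n else np.nan})
    return pd.DataFrame(rows)
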