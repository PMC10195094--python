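"""End-to-end analysis: sample traces -> events -> trial metrics -> stats.

``process_experiment`` runs gaze-event detection, object assignment, the
accuracy correction, RT decomposition, count measures and the exclusion
cascade over a full experiment (synthetic or loaded from files),
returning a tidy per-trial metrics table and a per-saccade table (gaze
and head amplitudes and direction angles). ``analyze_experiment`` then
fits the study's models on the included trials.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from . import events as ev
from . import saccades as sac
from . import search, stats
from .synthgen import Experiment, present_layout


@dataclass
class AnalysisConfig:
    """Detection and exclusion parameters (units: deg/s, samples, s)."""

    velocity_threshold: float = 120.0
    sg_window: int = 7
    sg_polyorder: int = 2
    min_fix_dur: float = 0.05
    min_sacc_samples: int = 2
    gap_factor: float = 2.0
    sd_cutoff: float = 3.0
    sd_cutoff_log_scale: bool = True
    scale_by_cos_lat: bool = True

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def process_trial(trial, layout, cfg: AnalysisConfig, with_saccade_table: bool = True):
    """Detect events and derive one metrics row for a single trial."""
    s = trial.samples
    gaze_events = ev.detect_gaze_events(
        s["t"], s["gaze_lon"], s["gaze_lat"],
        threshold=cfg.velocity_threshold, sg_window=cfg.sg_window,
        sg_polyorder=cfg.sg_polyorder, min_fix_dur=cfg.min_fix_dur,
        min_sacc_samples=cfg.min_sacc_samples, gap_factor=cfg.gap_factor,
    )
    stream = search.fixation_object_stream(gaze_events, layout)
    rt = trial.response_t - trial.cue_offset_t
    decomp = search.decompose_rt(trial.cue_offset_t, trial.response_t, gaze_events,
                                 stream, trial.target)
    counts = search.count_measures(gaze_events, stream, trial.target)
    gaze_at_sel = search.object_at_time(gaze_events, stream, trial.response_t)
    correct = search.apply_accuracy_correction(trial.selected_object, trial.target,
                                               trial.timeout, gaze_at_sel)
    fixs = [e for e in gaze_events if e.kind == ev.FIXATION]
    row = {
        "participant": trial.participant,
        "scene": trial.scene,
        "condition": trial.condition,
        "trial_index": trial.trial_index,
        "target": trial.target,
        "correct": bool(correct),
        "gaze_corrected": bool(correct and trial.selected_object != trial.target),
        "timeout": bool(trial.timeout),
        "rt_ms": 1000.0 * rt,
        "initiation_ms": 1000.0 * decomp["initiation"],
        "scanning_ms": 1000.0 * decomp["scanning"],
        "verification_ms": 1000.0 * decomp["verification"],
        "no_saccade": decomp["no_saccade"],
        "first_fix_on_target": decomp["first_fix_on_target"],
        "target_not_fixated": decomp["target_not_fixated"],
        "fixation_count": counts["fixation_count"],
        "mean_fixation_duration_ms": 1000.0 * counts["mean_fixation_duration"],
        "fixated_objects_count": counts["fixated_objects_count"],
        "target_refixations": counts["target_refixations"],
        "latitude_deg": sac.gaze_latitude(fixs),
    }
    if not with_saccade_table:
        gaze_durations = search.gaze_duration_by_object(gaze_events, stream,
                                                        t_max=trial.response_t)
        return row, None, gaze_durations, gaze_events, stream
    angles = sac.saccade_angles(gaze_events, cfg.scale_by_cos_lat)
    head_moves = ev.detect_head_movements(s["t"], s["head_lon"], s["head_lat"], gaze_events)
    head_amp = []
    head_ang = []
    for hm in head_moves:
        head_amp.append(hm.amplitude)
        try:
            head_ang.append(sac.displacement_angle(hm.onset.lon, hm.onset.lat,
                                                   hm.offset.lon, hm.offset.lat,
                                                   cfg.scale_by_cos_lat))
        except sac.UndefinedAngleError:
            head_ang.append(np.nan)
    saccs = [e for e in gaze_events if e.kind == ev.SACCADE]
    if len(head_amp) == len(angles) and len(angles) == len(saccs):
        angles["head_amplitude_deg"] = head_amp
        angles["head_abs_angle_deg"] = head_ang
    else:  # zero-amplitude saccades were skipped in the angle table
        amp_by_onset = {round(hm.onset_t, 9): (a, g) for hm, a, g in
                        zip(head_moves, head_amp, head_ang)}
        angles["head_amplitude_deg"] = [amp_by_onset.get(round(t, 9), (np.nan, np.nan))[0]
                                        for t in angles["onset_t"]]
        angles["head_abs_angle_deg"] = [amp_by_onset.get(round(t, 9), (np.nan, np.nan))[1]
                                        for t in angles["onset_t"]]
    gaze_durations = search.gaze_duration_by_object(gaze_events, stream,
                                                    t_max=trial.response_t)
    return row, angles, gaze_durations, gaze_events, stream


def process_experiment(exp: Experiment, cfg: AnalysisConfig | None = None,
                       with_saccade_table: bool = True):
    """Metrics and saccade tables for every trial of an experiment.

    Adds the accumulated prior-target-gaze covariate (per participant and
    scene, trials in presentation order) and the exclusion labels.
    """
    cfg = cfg or AnalysisConfig()
    rows = []
    sacc_frames = []
    durations = []
    for i, trial in enumerate(exp.trials):
        layout = present_layout(exp.layouts[trial.scene], trial.condition)
        row, angles, gdur, _, _ = process_trial(trial, layout, cfg, with_saccade_table)
        row["trial_id"] = i
        rows.append(row)
        durations.append(gdur)
        if angles is not None:
            angles.insert(0, "trial_id", i)
            angles.insert(0, "trial_index", trial.trial_index)
            angles.insert(0, "condition", trial.condition)
            angles.insert(0, "participant", trial.participant)
            sacc_frames.append(angles)
    metrics = pd.DataFrame(rows)

    prior = np.zeros(len(metrics))
    for (_, _), idx in metrics.groupby(["participant", "scene"], observed=True).groups.items():
        sub = metrics.loc[idx].sort_values("trial_index")
        targets = sub["target"].tolist()
        gd = [durations[metrics.index.get_loc(j)] for j in sub.index]
        vals = search.prior_target_gaze(targets, gd)
        prior[[metrics.index.get_loc(j) for j in sub.index]] = vals
    metrics["prior_target_gaze_s"] = prior

    metrics = search.exclusion_cascade(metrics, sd_k=cfg.sd_cutoff,
                                       log_scale=cfg.sd_cutoff_log_scale)
    nonempty = [f for f in sacc_frames if not f.empty]
    saccade_table = pd.concat(nonempty, ignore_index=True) if nonempty else pd.DataFrame()
    return metrics, saccade_table


def included(metrics: pd.DataFrame) -> pd.DataFrame:
    return metrics[metrics["excluded"] == "none"]


def analyze_experiment(metrics: pd.DataFrame, saccade_table: pd.DataFrame,
                       fit_directions: bool = True) -> dict:
    """The study's statistical contrasts on a processed experiment."""
    inc = included(metrics)
    results: dict = {"exclusions": search.exclusion_summary(metrics)}

    results["accuracy"] = stats.fit_measure(metrics, "accuracy", include_target_re=False)
    for measure in ("response_time", "initiation", "scanning", "verification",
                    "fixation_duration", "fixation_count", "fixated_objects_count",
                    "target_refixations", "gaze_latitude"):
        results[measure] = stats.fit_measure(inc, measure)

    results["rt_by_trial"] = stats.fit_rt_by_trial(inc)
    slopes = stats.per_participant_slopes(inc)
    results["slopes"] = slopes
    wide = slopes.pivot(index="participant", columns="condition", values="slope").dropna()
    results["slope_bf"] = stats.jzs_bayes_factor(x=wide["inverted"], y=wide["upright"])

    # per-condition descriptive means with within-subject SEs
    desc = {}
    for col in ("rt_ms", "initiation_ms", "scanning_ms", "verification_ms", "latitude_deg"):
        means = inc.groupby("condition", observed=True)[col].mean()
        desc[col] = {"mean": means, "wse": stats.within_subject_se(inc, col)}
    acc = metrics.groupby(["participant", "condition"], observed=True)["correct"].mean()
    desc["accuracy"] = {"mean": acc.groupby("condition", observed=True).mean()}
    results["descriptives"] = desc

    if not saccade_table.empty:
        inc_ids = set(inc["trial_id"])
        sac_inc = saccade_table[saccade_table["trial_id"].isin(inc_ids)]
        gaze_tab = sac_inc.rename(columns={"abs_angle_deg": "abs_angle_deg"}).copy()
        gaze_tab["channel"] = "gaze"
        head_tab = sac_inc.copy()
        head_tab["channel"] = "head"
        head_tab["abs_angle_deg"] = head_tab["head_abs_angle_deg"]
        both = pd.concat([gaze_tab, head_tab], ignore_index=True)
        both["condition"] = both["condition"].astype(str)
        counts = sac.tabulate_directions(both)
        results["direction_counts"] = counts
        if fit_directions:
            for channel in ("gaze", "head"):
                sub = counts[counts["channel"] == channel]
                long_df = stats.direction_count_model_data(sub)
                results[f"{channel}_direction_model"] = stats.fit_direction_model(long_df)
    return results
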