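"""Fixation/saccade classification on the sphere.

The detection pipeline follows the velocity-threshold scheme standard for
360-degree gaze recordings: orthodromic sample-to-sample velocity,
Savitzky-Golay smoothing of the velocity trace, a strict threshold
(samples with smoothed velocity < 120 deg/s are fixation samples, >= 120
deg/s saccade samples), and run-length segmentation with minimum-duration
post-processing so the event stream alternates fixation/saccade.

Recordings with dropped samples are split at gaps larger than
``gap_factor`` nominal sample intervals; events never span a gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from . import geometry
from .geometry import SphericalDirection

FIXATION = "fixation"
SACCADE = "saccade"

DEFAULT_THRESHOLD = 120.0  # deg/s, strict: < threshold is fixation
DEFAULT_SG_WINDOW = 7
DEFAULT_SG_POLYORDER = 2
DEFAULT_MIN_FIX_DUR = 0.05  # s
DEFAULT_MIN_SACC_SAMPLES = 2


class TooShortTraceError(ValueError):
    """Trace shorter than the smoothing window."""


@dataclass
class GazeEvent:
    """A labeled contiguous gaze segment.

    Sample indices are half-open ``[i0, i1)``; ``offset_t`` is the
    timestamp of sample ``i1`` (or the last sample of the trace for the
    final event), so consecutive events tile the trace without gaps.
    Fixation amplitude is 0 by convention; saccade amplitude is the
    orthodromic onset-to-offset displacement.
    """

    kind: str
    i0: int
    i1: int
    onset_t: float
    offset_t: float
    onset: SphericalDirection
    offset: SphericalDirection
    centroid: SphericalDirection | None = None
    amplitude: float = 0.0

    @property
    def duration(self) -> float:
        return self.offset_t - self.onset_t


@dataclass
class HeadMovement:
    """Head displacement measured over a gaze-saccade interval."""

    onset_t: float
    offset_t: float
    onset: SphericalDirection
    offset: SphericalDirection
    amplitude: float

    @property
    def duration(self) -> float:
        return self.offset_t - self.onset_t


def smooth_velocity(v, window: int = DEFAULT_SG_WINDOW, polyorder: int = DEFAULT_SG_POLYORDER):
    """Savitzky-Golay smooth a velocity trace; negatives clamped to 0."""
    v = np.asarray(v, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if v.size < window:
        raise TooShortTraceError(f"trace of {v.size} samples shorter than window {window}")
    return np.clip(savgol_filter(v, window, polyorder), 0.0, None)


def classify_samples(v_smoothed, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Boolean saccade mask: velocity >= threshold (fixation is strict <)."""
    v = np.asarray(v_smoothed, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite velocity")
    return v >= threshold


def _runs(labels: np.ndarray) -> list[list]:
    """Maximal runs of identical labels as mutable [start, end, label]."""
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels.astype(np.int8))) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [[int(s), int(e), bool(labels[s])] for s, e in zip(starts, ends)]


def _coalesce(runs: list[list]) -> list[list]:
    out: list[list] = []
    for r in runs:
        if out and out[-1][2] == r[2]:
            out[-1][1] = r[1]
        else:
            out.append(list(r))
    return out


def segment_events(
    is_saccade_sample,
    t,
    lon,
    lat,
    min_fix_dur: float = DEFAULT_MIN_FIX_DUR,
    min_sacc_samples: int = DEFAULT_MIN_SACC_SAMPLES,
    index_offset: int = 0,
) -> list[GazeEvent]:
    """Segment per-sample saccade labels into alternating gaze events.

    Saccade runs shorter than ``min_sacc_samples`` are absorbed into the
    flanking fixations; fixations shorter than ``min_fix_dur`` are
    absorbed into a flanking saccade. Adjacent same-kind runs coalesce,
    so the output alternates kinds.
    """
    labels = np.asarray(is_saccade_sample, dtype=bool)
    t = np.asarray(t, dtype=float)
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    n = labels.size
    if n == 0:
        return []
    runs = _runs(labels)

    def _dur(run) -> float:
        s, e, _ = run
        return t[min(e, n - 1)] - t[s]

    # absorb too-short saccades into fixations, then too-short fixations
    # into saccades; iterate to a fixed point (bounded by run count).
    for _ in range(len(runs) + 1):
        changed = False
        for r in runs:
            if r[2] and (r[1] - r[0]) < min_sacc_samples:
                r[2] = False
                changed = True
        runs = _coalesce(runs)
        for i, r in enumerate(runs):
            if not r[2] and _dur(r) < min_fix_dur:
                has_sacc_flank = (i > 0 and runs[i - 1][2]) or (i + 1 < len(runs) and runs[i + 1][2])
                if has_sacc_flank:
                    r[2] = True
                    changed = True
        runs = _coalesce(runs)
        if not changed:
            break

    events: list[GazeEvent] = []
    for s, e, is_sacc in runs:
        j = min(e, n - 1)
        onset = SphericalDirection(float(geometry.wrap_longitude(lon[s])), float(lat[s]))
        offset = SphericalDirection(float(geometry.wrap_longitude(lon[j])), float(lat[j]))
        if is_sacc:
            amp = float(geometry.orthodromic_distance(onset.lon, onset.lat, offset.lon, offset.lat))
            ev = GazeEvent(SACCADE, s + index_offset, e + index_offset, float(t[s]), float(t[j]),
                           onset, offset, centroid=None, amplitude=amp)
        else:
            centroid = geometry.spherical_mean(lon[s:e], lat[s:e])
            ev = GazeEvent(FIXATION, s + index_offset, e + index_offset, float(t[s]), float(t[j]),
                           onset, offset, centroid=centroid, amplitude=0.0)
        if ev.duration > 0 or (is_sacc and e - s > 0):
            events.append(ev)
    return [ev for ev in events if ev.duration > 0]


def detect_gaze_events(
    t,
    lon,
    lat,
    threshold: float = DEFAULT_THRESHOLD,
    sg_window: int = DEFAULT_SG_WINDOW,
    sg_polyorder: int = DEFAULT_SG_POLYORDER,
    min_fix_dur: float = DEFAULT_MIN_FIX_DUR,
    min_sacc_samples: int = DEFAULT_MIN_SACC_SAMPLES,
    gap_factor: float = 2.0,
) -> list[GazeEvent]:
    """Full detection pipeline for one recording.

    Velocity -> Savitzky-Golay smoothing -> strict threshold -> run
    segmentation, applied independently to chunks separated by sampling
    gaps longer than ``gap_factor`` median intervals. Chunks shorter than
    the smoothing window fall back to unsmoothed velocities (warning).
    """
    t = np.asarray(t, dtype=float)
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if t.size < 2:
        return []
    dt = np.diff(t)
    nominal = float(np.median(dt))
    breaks = np.flatnonzero(dt > gap_factor * nominal) + 1
    bounds = np.concatenate([[0], breaks, [t.size]])
    events: list[GazeEvent] = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e - s < 2:
            continue
        v = geometry.angular_velocity(t[s:e], lon[s:e], lat[s:e])
        try:
            vs = smooth_velocity(v, sg_window, sg_polyorder)
        except TooShortTraceError:
            warnings.warn("chunk shorter than smoothing window; using unsmoothed velocities",
                          stacklevel=2)
            vs = v
        sacc = classify_samples(vs, threshold)
        # per-sample labels: sample i takes the label of interval i -> i+1;
        # the final sample inherits the last interval's label.
        labels = np.append(sacc, sacc[-1])
        events.extend(
            segment_events(labels, t[s:e], lon[s:e], lat[s:e], min_fix_dur, min_sacc_samples,
                           index_offset=int(s))
        )
    return events


def detect_head_movements(t, head_lon, head_lat, gaze_events: list[GazeEvent]) -> list[HeadMovement]:
    """Head displacement over each gaze-saccade interval.

    The head channel is not segmented on its own; one head-movement
    record is produced per gaze saccade, measuring the orthodromic head
    displacement between the saccade's onset and offset samples.
    """
    t = np.asarray(t, dtype=float)
    head_lon = np.asarray(head_lon, dtype=float)
    head_lat = np.asarray(head_lat, dtype=float)
    n = t.size
    moves: list[HeadMovement] = []
    for ev in gaze_events:
        if ev.kind != SACCADE:
            continue
        i0, i1 = ev.i0, min(ev.i1, n - 1)
        onset = SphericalDirection(float(geometry.wrap_longitude(head_lon[i0])), float(head_lat[i0]))
        offset = SphericalDirection(float(geometry.wrap_longitude(head_lon[i1])), float(head_lat[i1]))
        amp = float(geometry.orthodromic_distance(onset.lon, onset.lat, offset.lon, offset.lat))
        moves.append(HeadMovement(float(t[i0]), float(t[i1]), onset, offset, amp))
    return moves


def events_to_frame(events: list[GazeEvent], trial_id=None) -> pd.DataFrame:
    """Tidy event table (one row per event)."""
    rows = []
    for ev in events:
        rows.append(
            {
                "trial_id": trial_id,
                "kind": ev.kind,
                "onset_t": ev.onset_t,
                "offset_t": ev.offset_t,
                "duration": ev.duration,
                "amplitude_deg": ev.amplitude,
                "centroid_lon": ev.centroid.lon if ev.centroid else np.nan,
                "centroid_lat": ev.centroid.lat if ev.centroid else np.nan,
            }
        )
    return pd.DataFrame(rows)
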