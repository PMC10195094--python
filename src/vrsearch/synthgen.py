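"""Synthetic VR visual-search experiment generator.

Emulates the structure of a repeated-search eye-tracking study in
immersive scenes: 20 participants search 10 scenes (5 presented upright,
5 inverted, balanced across participants and randomly interleaved), 10
consecutive searches per scene against a 15 s timeout, with gaze sampled
at 120 Hz. Each scene holds 8 large "anchor" objects and 20 smaller
local objects placed on the viewing sphere; inverting a scene mirrors
object latitudes.

Every trial is built as an explicit fixation-saccade chain with known
ground truth:

* initiation latency (lognormal), then a walk over distractor objects
  whose total duration realizes a drawn scanning time, then the target;
* scanning and verification times are lognormal with condition effects
  on the log scale (defaults 0.41 and 0.14, inverted minus upright), an
  across-trial log slope (default -0.02 per trial applied to both
  phases), participant/target random effects, and a negative effect of
  accumulated gaze on the target from earlier trials;
* saccade direction choices follow a configurable sector bias
  (rightward > leftward, horizontal > vertical), shifted in inverted
  scenes; target refixation excursions occur during verification at a
  condition-dependent rate;
* saccades travel great circles with a raised-cosine velocity profile
  (duration increasing with amplitude, peak velocity well above the
  120 deg/s threshold); fixation jitter is a slow AR(1) wander; the head
  follows gaze with a configurable gain, recentering toward gaze during
  fixations;
* degenerate trial types occur at configurable rates: wrong selection
  while gaze is on the target (exercises the accuracy correction),
  incorrect selections and timeouts (more frequent in inverted scenes),
  trials without saccades, and trials whose first fixation lands on the
  target. Verification outliers at +5 pooled SD can be injected.

All Gaussian noise (residuals and random effects) is truncated at
+/- ``trunc`` sigma: single-trial variability is bounded, so an
injected outlier is separable from the clean tail.

One seed fully determines the output; per-participant substreams are
spawned deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import geometry
from .saccades import SECTORS
from .search import SceneObject


@dataclass
class GeneratorConfig:
    # design
    n_participants: int = 20
    n_scenes: int = 10
    trials_per_scene: int = 10
    n_local: int = 20
    n_anchor: int = 8
    sample_rate: float = 120.0
    timeout_s: float = 15.0
    threshold_degps: float = 120.0  # defines the fixation/saccade boundary in truth
    # layout (degrees)
    local_radius: tuple = (2.0, 3.0)
    anchor_radius: tuple = (4.0, 6.0)
    lat_range: tuple = (-55.0, 25.0)
    lon_range: tuple = (-170.0, 170.0)
    min_sep_margin: float = 2.0
    start_clearance: float = 8.0
    # event-chain timing (seconds / log-scale effects)
    fix_dur_mean: float = 0.25
    fix_dur_shape: float = 4.0
    min_fix_floor: float = 0.07
    sacc_dur_intercept: float = 0.02
    sacc_dur_slope: float = 0.0025  # s per degree of amplitude
    init_median: float = 0.25
    init_sigma: float = 0.30
    scan_median: float = 1.85
    scan_sigma: float = 0.25
    verif_median: float = 0.64
    verif_sigma: float = 0.15
    delta_scan: float = 0.41
    delta_verif: float = 0.14
    trial_slope: float = -0.02
    trial_slope_inverted: float | None = None  # None -> same as upright
    participant_sd: float = 0.12
    target_sd: float = 0.08
    participant_condition_sd: float = 0.03
    gaze_covariate_gain: float = -0.10
    gaze_covariate_scale: float = 2.0  # s of prior target gaze per unit effect
    trunc: float = 2.5
    # refixations during verification
    refix_rate: float = 0.30
    refix_condition_logfx: float = 0.37
    # direction bias (sector probabilities, upright)
    dir_weights: dict = field(default_factory=lambda: {
        "right": 0.40, "left": 0.25, "up": 0.175, "down": 0.175})
    inverted_dir_shift: dict = field(default_factory=lambda: {
        "right": -0.04, "left": 0.0, "up": -0.02, "down": 0.06})
    amp_softness: float = 30.0  # deg; preference for nearer objects
    # degenerate trial rates
    p_misclick: float = 0.057
    p_incorrect: float = 0.072
    incorrect_condition_logfx: float = 0.50
    p_timeout_share: float = 0.4  # share of incorrect trials that time out
    p_no_saccade: float = 0.0215
    p_first_fix: float = 0.0355
    outlier_rate: float = 0.0
    outlier_sd_mult: float = 5.0
    # trace
    noise_sd: float = 0.3
    noise_ar: float = 0.9
    head_gain: float = 0.6
    head_lag_s: float = 0.0
    head_tau: float = 0.3
    head_noise_sd: float = 0.08

    def verification_log_sd(self) -> float:
        """Pooled SD of log verification under the clean model."""
        slope = self.trial_slope if self.trial_slope_inverted is None else \
            0.5 * (self.trial_slope + self.trial_slope_inverted)
        var_trial = (self.trials_per_scene ** 2 - 1) / 12.0
        return math.sqrt(
            self.verif_sigma ** 2 + self.participant_sd ** 2 + self.target_sd ** 2
            + 0.25 * self.participant_condition_sd ** 2 + 0.25 * self.delta_verif ** 2
            + slope ** 2 * var_trial
        )


@dataclass
class TrialTruth:
    """Generator-side ground truth for one trial."""

    events: list  # (kind, t0, t1, object_id or None)
    trial_type: str
    initiation: float
    scanning: float
    verification: float
    first_sacc_onset: float | None
    first_target_onset: float | None
    outlier: bool
    gaze_by_object: dict
    drawn_scanning: float = float("nan")
    drawn_verification: float = float("nan")


@dataclass
class TrialRecord:
    participant: int
    scene: str
    condition: str
    trial_index: int
    target: str
    cue_offset_t: float
    response_t: float
    selected_object: str | None
    timeout: bool
    samples: dict
    truth: TrialTruth


@dataclass
class Experiment:
    config: GeneratorConfig
    layouts: dict
    trials: list


def _tnorm(rng, sd: float, trunc: float, size=None):
    """Zero-mean normal truncated at +/- trunc sigma (rejection)."""
    if sd == 0.0:
        return 0.0 if size is None else np.zeros(size)
    n = 1 if size is None else int(np.prod(size))
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.standard_normal(n - filled)
        keep = draw[np.abs(draw) <= trunc]
        out[filled:filled + keep.size] = keep
        filled += keep.size
    out *= sd
    return float(out[0]) if size is None else out.reshape(size)


def generate_scene_layout(rng, config: GeneratorConfig, scene_id: str) -> list[SceneObject]:
    """Place anchor and local objects with minimum angular separation."""
    objects: list[SceneObject] = []
    specs = [("anchor", config.anchor_radius)] * config.n_anchor + \
            [("local", config.local_radius)] * config.n_local
    for i, (kind, rad_range) in enumerate(specs):
        radius = float(rng.uniform(*rad_range))
        for _ in range(4000):
            lon = float(rng.uniform(*config.lon_range))
            lat = float(rng.uniform(*config.lat_range))
            if geometry.orthodromic_distance(lon, lat, 0.0, 0.0) < radius + config.start_clearance:
                continue
            ok = True
            for o in objects:
                sep = geometry.orthodromic_distance(lon, lat, o.lon, o.lat)
                if sep < radius + o.radius_deg + config.min_sep_margin:
                    ok = False
                    break
            if ok:
                name = f"{scene_id}_{kind}{i}"
                objects.append(SceneObject(name, lon, lat, radius, kind))
                break
        else:
            raise RuntimeError(
                "could not satisfy object separation; use fewer or smaller objects")
    return objects


def present_layout(layout: list[SceneObject], condition: str) -> list[SceneObject]:
    """Layout as seen by the participant; inversion mirrors latitudes."""
    if condition == "upright":
        return layout
    return [replace(o, lat=-o.lat) for o in layout]


def _sector_weights(config: GeneratorConfig, condition: str) -> dict:
    w = dict(config.dir_weights)
    if condition == "inverted":
        for k, v in config.inverted_dir_shift.items():
            w[k] = max(w.get(k, 0.0) + v, 1e-6)
    total = sum(w.values())
    return {k: v / total for k, v in w.items()}


def _availability(layout: list[SceneObject]) -> np.ndarray:
    """Sector availability (positions x 4) from each object's viewpoint."""
    lons = np.array([o.lon for o in layout])
    lats = np.array([o.lat for o in layout])
    n = lons.size
    avail = np.zeros((n, 4), dtype=bool)
    for i in range(n):
        dlon = np.asarray(geometry.wrap_longitude(lons - lons[i])) * math.cos(math.radians(lats[i]))
        dlat = lats - lats[i]
        ang = np.degrees(np.arctan2(dlat, dlon)) % 360.0
        sec = (((ang + 45.0) % 360.0) // 90.0).astype(int)
        sec = np.delete(sec, i)
        for s in sec:
            avail[i, s] = True
    return avail


def calibrate_direction_weights(layout: list[SceneObject], target: dict,
                                n_iter: int = 60) -> dict:
    """Sampling weights that realize the target sector proportions.

    Scenes are wider than tall, so the vertical sectors are often empty
    from a given object; naive sector sampling would leak their mass
    into the horizontal sectors. A fixed-point adjustment over the
    layout's availability pattern compensates, so the realized direction
    distribution of the fixation walk matches the configured one.
    """
    avail = _availability(layout).astype(float)
    t = np.array([target[s] for s in SECTORS])
    w = t.copy()
    for _ in range(n_iter):
        z = avail @ w
        realized = (avail * w / np.maximum(z, 1e-12)[:, None]).mean(axis=0)
        w = np.clip(w * (t / np.maximum(realized, 1e-9)) ** 0.7, 1e-6, None)
        w /= w.sum()
    return dict(zip(SECTORS, w))


def _choose_next(rng, cur, candidates: list[SceneObject], weights: dict,
                 amp_softness: float) -> SceneObject:
    """Direction-biased object choice: sample a sector, prefer nearer objects."""
    lons = np.array([o.lon for o in candidates])
    lats = np.array([o.lat for o in candidates])
    dlon = np.asarray(geometry.wrap_longitude(lons - cur[0])) * math.cos(math.radians(cur[1]))
    dlat = lats - cur[1]
    angles = np.degrees(np.arctan2(dlat, dlon)) % 360.0
    dists = np.asarray(geometry.orthodromic_distance(cur[0], cur[1], lons, lats))
    sector_idx = (((angles + 45.0) % 360.0) // 90.0).astype(int)
    avail = set(sector_idx.tolist())
    w = np.array([weights[SECTORS[i]] if i in avail else 0.0 for i in range(4)])
    sector = rng.choice(4, p=w / w.sum())
    in_sector = np.flatnonzero(sector_idx == sector)
    pw = np.exp(-dists[in_sector] / amp_softness)
    pick = in_sector[rng.choice(in_sector.size, p=pw / pw.sum())]
    return candidates[pick]


def _sacc_dur(config: GeneratorConfig, amplitude: float) -> float:
    return config.sacc_dur_intercept + config.sacc_dur_slope * amplitude


def _partition(rng, total: float, k: int, floor: float, shape: float) -> np.ndarray:
    """Split ``total`` into k parts >= floor, gamma-proportioned."""
    raw = rng.gamma(shape, 1.0, size=k)
    return floor + (total - floor * k) * raw / raw.sum()


class _ParticipantEffects:
    def __init__(self, rng, config: GeneratorConfig):
        c = config
        self.init = _tnorm(rng, c.participant_sd, c.trunc)
        self.scan = _tnorm(rng, c.participant_sd, c.trunc)
        self.verif = _tnorm(rng, c.participant_sd, c.trunc)
        self.scan_cond = _tnorm(rng, c.participant_condition_sd, c.trunc)
        self.verif_cond = _tnorm(rng, c.participant_condition_sd, c.trunc)


def _trial_type(rng, config: GeneratorConfig, cval: float) -> str:
    p_inc = config.p_incorrect * math.exp(config.incorrect_condition_logfx * cval)
    u = rng.uniform()
    edges = [
        ("no_saccade", config.p_no_saccade),
        ("first_fix", config.p_first_fix),
        ("timeout", p_inc * config.p_timeout_share),
        ("incorrect_sel", p_inc * (1.0 - config.p_timeout_share)),
        ("misclick", config.p_misclick),
    ]
    acc = 0.0
    for name, p in edges:
        acc += p
        if u < acc:
            return name
    return "normal"


def generate_trial(rng, config: GeneratorConfig, layout: list[SceneObject], target_id: str,
                   condition: str, trial_index: int, effects: _ParticipantEffects,
                   target_effects: dict, prior_gaze_s: float = 0.0,
                   force_outlier: bool | None = None,
                   direction_weights: dict | None = None) -> TrialRecord:
    """One search trial: event chain, sample trace and ground truth."""
    c = config
    cval = 0.5 if condition == "inverted" else -0.5
    slope = c.trial_slope if (condition == "upright" or c.trial_slope_inverted is None) \
        else c.trial_slope_inverted
    tc = trial_index - (c.trials_per_scene + 1) / 2.0
    objects = {o.object_id: o for o in layout}
    target = objects[target_id]
    covar = c.gaze_covariate_gain * prior_gaze_s / c.gaze_covariate_scale

    trial_type = _trial_type(rng, c, cval)
    outlier = force_outlier if force_outlier is not None else \
        (c.outlier_rate > 0 and rng.uniform() < c.outlier_rate)

    initiation = c.init_median * math.exp(
        c.init_sigma * _tnorm(rng, 1.0, c.trunc) + effects.init)
    t_scan, t_verif = target_effects.get(target_id, (0.0, 0.0))
    scan = c.scan_median * math.exp(
        c.delta_scan * cval + slope * tc + effects.scan + effects.scan_cond * cval
        + t_scan + covar + _tnorm(rng, c.scan_sigma, c.trunc))
    if outlier:
        log_v = math.log(c.verif_median) + c.outlier_sd_mult * c.verification_log_sd()
        verif = math.exp(log_v)
    else:
        verif = c.verif_median * math.exp(
            c.delta_verif * cval + slope * tc + effects.verif + effects.verif_cond * cval
            + t_verif + _tnorm(rng, c.verif_sigma, c.trunc))

    weights = direction_weights if direction_weights is not None else \
        calibrate_direction_weights(layout, _sector_weights(c, condition))
    events: list = []  # (kind, t0, t1, object_id or None)
    start = (0.0, 0.0)

    def sub_threshold_edge(amp: float, dur: float) -> float:
        """Time a raised-cosine saccade spends below threshold at one edge."""
        v_peak = 2.0 * amp / dur if dur > 0 else 0.0
        if v_peak <= c.threshold_degps:
            return dur / 2.0
        return math.acos(1.0 - 2.0 * c.threshold_degps / v_peak) / (2.0 * math.pi) * dur

    def chain_to(goal: SceneObject, scan_budget: float, cur, init_dur: float, k_hint: int,
                 exclude: set) -> tuple[float, float]:
        """Initial fixation + distractor walk ending on ``goal``.

        Timed so that the threshold-defined truth matches the drawn
        values: the initial fixation is shortened by the first saccade's
        sub-threshold edge (true initiation = ``init_dur``) and the
        distractor fixation budget is expanded by the two outer edges
        (true scanning = ``scan_budget`` when the walk is feasible).
        Returns (chain arrival time at goal, arrival-edge duration).
        """
        k = k_hint
        while True:
            pool = [o for o in layout if o.object_id not in exclude]
            seq: list[SceneObject] = []
            pos = cur
            for _ in range(k):
                cands = [o for o in pool if o.object_id != goal.object_id
                         and (not seq or o.object_id != seq[-1].object_id)]
                nxt = _choose_next(rng, pos, cands, weights, c.amp_softness)
                seq.append(nxt)
                pos = (nxt.lon, nxt.lat)
            legs = []
            amps = []
            pos = cur
            for o in seq + [goal]:
                amp = geometry.orthodromic_distance(pos[0], pos[1], o.lon, o.lat)
                amps.append(amp)
                legs.append(_sacc_dur(c, amp))
                pos = (o.lon, o.lat)
            e_first = sub_threshold_edge(amps[0], legs[0])
            e_last = sub_threshold_edge(amps[-1], legs[-1])
            fix_time = scan_budget + e_first + e_last - sum(legs)
            if k == 0 or fix_time >= c.min_fix_floor * k:
                break
            k -= 1
        if k > 0:
            fix_durs = _partition(rng, fix_time, k, c.min_fix_floor, c.fix_dur_shape)
        else:
            fix_durs = np.empty(0)
        t = max(init_dur - e_first, c.min_fix_floor)
        events.append(("fixation", 0.0, t, None))
        for i, o in enumerate(seq):
            events.append(("saccade", t, t + legs[i], None))
            t += legs[i]
            events.append(("fixation", t, t + fix_durs[i], o.object_id))
            t += float(fix_durs[i])
        events.append(("saccade", t, t + legs[-1], None))
        t += legs[-1]
        return t, e_last

    samples_end_pad = 0.05
    first_sacc_onset: float | None = None
    first_target_onset: float | None = None
    scanning_real = float("nan")
    selected: str | None = None
    timeout = False

    if trial_type == "no_saccade":
        # participant already oriented on the target during the cue
        response_t = initiation + verif
        events.append(("fixation", 0.0, response_t + samples_end_pad, target_id))
        selected = target_id
        first_target_onset = 0.0
    elif trial_type == "timeout":
        # target never found: distractor walk until the 15 s budget
        events.append(("fixation", 0.0, initiation, None))
        t = initiation
        pos = start
        prev = None
        while t < c.timeout_s + 0.1:
            cands = [o for o in layout if o.object_id != target_id and o.object_id != prev]
            nxt = _choose_next(rng, pos, cands, weights, c.amp_softness)
            amp = geometry.orthodromic_distance(pos[0], pos[1], nxt.lon, nxt.lat)
            d = _sacc_dur(c, amp)
            events.append(("saccade", t, t + d, None))
            t += d
            fd = float(rng.gamma(c.fix_dur_shape, c.fix_dur_mean / c.fix_dur_shape))
            fd = max(fd, c.min_fix_floor)
            events.append(("fixation", t, t + fd, nxt.object_id))
            t += fd
            pos = (nxt.lon, nxt.lat)
            prev = nxt.object_id
        response_t = c.timeout_s
        timeout = True
        first_sacc_onset = initiation
    else:
        goal = target
        if trial_type == "incorrect_sel":
            decoy_pool = [o for o in layout if o.object_id != target_id]
            goal = decoy_pool[int(rng.integers(len(decoy_pool)))]
        cycle = c.fix_dur_mean + 0.06
        k_hint = 0 if trial_type == "first_fix" else max(0, int(round((scan - 0.05) / cycle)))
        exclude = {target_id} if trial_type == "incorrect_sel" else set()
        t_arrive, e_arrival = chain_to(goal, scan, start, initiation, k_hint, exclude)
        first_sacc_onset = events[0][2]  # end of the initial fixation
        scanning_real = t_arrive - first_sacc_onset
        first_target_onset = t_arrive if goal.object_id == target_id else None

        # verification on the goal object, with optional refixation
        # excursions; the button press lands so that the threshold-true
        # verification (from the true target-fixation onset) equals the draw
        chain_verif = max(verif - e_arrival, 0.12)
        n_exc = int(rng.poisson(c.refix_rate * math.exp(c.refix_condition_logfx * cval)))
        exc_legs = []
        for _ in range(n_exc):
            cands = [o for o in layout if o.object_id != goal.object_id]
            away = _choose_next(rng, (goal.lon, goal.lat), cands, weights, c.amp_softness)
            amp = geometry.orthodromic_distance(goal.lon, goal.lat, away.lon, away.lat)
            d = _sacc_dur(c, amp)
            exc_legs.append((away, d, max(0.12, float(rng.gamma(4.0, 0.045)))))
        while exc_legs and chain_verif < 0.11 * (len(exc_legs) + 1) + \
                sum(2 * d + f for _, d, f in exc_legs):
            exc_legs.pop()
        n_exc = len(exc_legs)
        on_target_total = chain_verif - sum(2 * d + f for _, d, f in exc_legs)
        t_durs = _partition(rng, on_target_total, n_exc + 1, 0.1, c.fix_dur_shape)
        t = t_arrive
        for i, (away, d, f) in enumerate(exc_legs):
            events.append(("fixation", t, t + t_durs[i], goal.object_id))
            t += float(t_durs[i])
            events.append(("saccade", t, t + d, None))
            t += d
            events.append(("fixation", t, t + f, away.object_id))
            t += f
            events.append(("saccade", t, t + d, None))
            t += d
        response_t = t_arrive + chain_verif
        events.append(("fixation", t, response_t + samples_end_pad, goal.object_id))
        if trial_type == "misclick":
            others = [o.object_id for o in layout if o.object_id != target_id]
            selected = others[int(rng.integers(len(others)))]
        else:
            selected = goal.object_id

    samples = _synthesize_trace(rng, c, events, objects)
    true_events = _threshold_truth(events, objects, c.threshold_degps)
    gaze_by_object: dict = {}
    for kind, t0, t1, obj in true_events:
        if kind == "fixation" and obj is not None:
            end = min(t1, response_t)
            if end > t0:
                gaze_by_object[obj] = gaze_by_object.get(obj, 0.0) + (end - t0)
    true_first_sacc = next((e for e in true_events if e[0] == "saccade"), None)
    if true_first_sacc is not None:
        t_sacc0 = true_first_sacc[1]
        tgt_fix = next((e for e in true_events
                        if e[0] == "fixation" and e[3] == target_id and e[1] >= t_sacc0), None)
        true_init = t_sacc0
        true_scan = tgt_fix[1] - t_sacc0 if tgt_fix else float("nan")
        true_verif = response_t - tgt_fix[1] if tgt_fix else float("nan")
        true_tgt_onset = tgt_fix[1] if tgt_fix else None
    else:
        true_init = float("nan")
        true_scan = float("nan")
        true_verif = response_t if trial_type == "no_saccade" else float("nan")
        true_tgt_onset = 0.0 if trial_type == "no_saccade" else None
        t_sacc0 = None
    truth = TrialTruth(
        events=true_events,
        trial_type=trial_type,
        initiation=true_init,
        scanning=true_scan,
        verification=true_verif,
        first_sacc_onset=t_sacc0,
        first_target_onset=true_tgt_onset,
        outlier=bool(outlier),
        gaze_by_object=gaze_by_object,
        drawn_scanning=scan,
        drawn_verification=verif,
    )
    return TrialRecord(
        participant=-1, scene="", condition=condition, trial_index=trial_index,
        target=target_id, cue_offset_t=0.0, response_t=float(response_t),
        selected_object=selected, timeout=timeout, samples=samples, truth=truth,
    )


def _raised_cosine_progress(frac: np.ndarray) -> np.ndarray:
    return frac - np.sin(2.0 * np.pi * frac) / (2.0 * np.pi)


def _threshold_truth(chain: list, objects: dict, thr: float) -> list:
    """Re-express an event chain with threshold-defined boundaries.

    The raised-cosine saccade profile starts and ends below the velocity
    threshold; the true saccade, under the threshold definition of the
    fixation/saccade boundary, is the interval where angular speed is at
    or above ``thr``. Flanking fixation spans absorb the sub-threshold
    edges (keeping their object labels). Saccades whose peak velocity
    never reaches the threshold dissolve into fixation time.
    """
    saccades = []
    for i, (kind, t0, t1, obj) in enumerate(chain):
        if kind != "saccade":
            continue
        prev = next(e for e in reversed(chain[:i]) if e[0] == "fixation")
        nxt = next(e for e in chain[i + 1:] if e[0] == "fixation")
        p0 = objects[prev[3]] if prev[3] is not None else None
        p1 = objects[nxt[3]] if nxt[3] is not None else None
        lon0, lat0 = (p0.lon, p0.lat) if p0 else (0.0, 0.0)
        lon1, lat1 = (p1.lon, p1.lat) if p1 else (0.0, 0.0)
        amp = float(geometry.orthodromic_distance(lon0, lat0, lon1, lat1))
        dur = t1 - t0
        v_peak = 2.0 * amp / dur if dur > 0 else 0.0
        if v_peak <= thr:
            continue
        tau = math.acos(1.0 - 2.0 * thr / v_peak) / (2.0 * math.pi)
        saccades.append((t0 + tau * dur, t1 - tau * dur))
    # fixation spans are the complement, labeled by the chain fixation
    # covering (or preceding) each span
    out: list = []
    fixes = [e for e in chain if e[0] == "fixation"]
    t_start = chain[0][1]
    t_end = chain[-1][2]
    cursor = t_start
    for s0, s1 in saccades:
        if s0 > cursor:
            mid = 0.5 * (cursor + s0)
            obj = next((f[3] for f in fixes if f[1] <= mid < f[2]), None)
            if obj is None:
                covering = [f for f in fixes if f[1] <= mid]
                obj = covering[-1][3] if covering else None
            out.append(("fixation", cursor, s0, obj))
        out.append(("saccade", s0, s1, None))
        cursor = s1
    if cursor < t_end:
        mid = 0.5 * (cursor + t_end)
        obj = next((f[3] for f in fixes if f[1] <= mid < f[2]), fixes[-1][3])
        out.append(("fixation", cursor, t_end, obj))
    return out


def _ar1(rng, n: int, sd: float, rho: float) -> np.ndarray:
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    from scipy.signal import lfilter

    innov = rng.standard_normal(n) * sd * math.sqrt(1.0 - rho * rho)
    innov[0] = rng.standard_normal() * sd
    return lfilter([1.0], [1.0, -rho], innov)


def _synthesize_trace(rng, config: GeneratorConfig, events: list, objects: dict) -> dict:
    """120 Hz gaze + head trace realizing an event chain."""
    c = config
    t_end = events[-1][2]
    ts = np.arange(0.0, t_end, 1.0 / c.sample_rate)
    n = ts.size
    glon = np.zeros(n)
    glat = np.zeros(n)
    hlon = np.zeros(n)
    hlat = np.zeros(n)

    # nominal gaze path and head offset dynamics, segment by segment
    off_lon = 0.0
    off_lat = 0.0
    pos = None
    for kind, t0, t1, obj in events:
        idx = np.flatnonzero((ts >= t0 - 1e-9) & (ts < t1 - 1e-9))
        if kind == "fixation":
            if obj is not None:
                o = objects[obj]
                pos = (o.lon, o.lat)
            elif pos is None:
                pos = (0.0, 0.0)
            glon[idx] = pos[0]
            glat[idx] = pos[1]
            if idx.size:
                decay = np.exp(-(ts[idx] - t0) / c.head_tau)
                hlon[idx] = pos[0] - off_lon * decay
                hlat[idx] = pos[1] - off_lat * decay
            k = math.exp(-(t1 - t0) / c.head_tau)
            off_lon *= k
            off_lat *= k
        else:
            # saccade: next event's fixation position is the endpoint
            nxt = next((e for e in events if e[0] == "fixation" and e[1] >= t1 - 1e-9), None)
            if nxt is None or pos is None:
                continue
            tgt = objects[nxt[3]] if nxt[3] is not None else None
            end = (tgt.lon, tgt.lat) if tgt is not None else (0.0, 0.0)
            if idx.size:
                frac = (ts[idx] - t0) / (t1 - t0)
                prog = _raised_cosine_progress(frac)
                slon, slat = geometry.slerp(pos[0], pos[1], end[0], end[1], prog)
                glon[idx] = slon
                glat[idx] = slat
                dlon = geometry.wrap_longitude(slon - pos[0])
                dlat = slat - pos[1]
                hlon[idx] = slon - (off_lon + (1.0 - c.head_gain) * dlon)
                hlat[idx] = slat - (off_lat + (1.0 - c.head_gain) * dlat)
            off_lon += (1.0 - c.head_gain) * float(geometry.wrap_longitude(end[0] - pos[0]))
            off_lat += (1.0 - c.head_gain) * (end[1] - pos[1])
            pos = end

    # slow oculomotor wander on the gaze channel
    jlat = _ar1(rng, n, c.noise_sd, c.noise_ar)
    jlon = _ar1(rng, n, c.noise_sd, c.noise_ar) / np.clip(np.cos(np.radians(glat)), 0.2, None)
    glon = np.asarray(geometry.wrap_longitude(glon + jlon))
    glat = np.clip(glat + jlat, -89.9, 89.9)
    hlat = np.clip(hlat + _ar1(rng, n, c.head_noise_sd, 0.95), -89.9, 89.9)
    hlon = np.asarray(geometry.wrap_longitude(hlon + _ar1(rng, n, c.head_noise_sd, 0.95)))
    if c.head_lag_s > 0:
        k = int(round(c.head_lag_s * c.sample_rate))
        if k and n:
            hlon = np.concatenate([np.repeat(hlon[:1], k), hlon[:-k]]) if k < n else hlon
            hlat = np.concatenate([np.repeat(hlat[:1], k), hlat[:-k]]) if k < n else hlat
    return {"t": ts, "gaze_lon": glon, "gaze_lat": glat, "head_lon": hlon, "head_lat": hlat}


def scene_condition(participant: int, scene_idx: int) -> str:
    """Balanced assignment: half the participants see each scene upright."""
    return "inverted" if (participant + scene_idx) % 2 else "upright"


def generate_experiment(config: GeneratorConfig, seed: int) -> Experiment:
    """The full design: all participants, scenes and trials."""
    ss = np.random.SeedSequence(seed)
    master, *pstreams = [np.random.default_rng(s) for s in ss.spawn(config.n_participants + 1)]
    layouts = {f"scene{j}": generate_scene_layout(master, config, f"scene{j}")
               for j in range(config.n_scenes)}
    # target random effects, shared across participants
    target_effects: dict = {}
    for layout in layouts.values():
        for o in layout:
            if o.kind == "local":
                target_effects[o.object_id] = (
                    _tnorm(master, config.target_sd, config.trunc),
                    _tnorm(master, config.target_sd, config.trunc),
                )
    dir_weights = {}
    for scene, layout in layouts.items():
        for condition in ("upright", "inverted"):
            dir_weights[(scene, condition)] = calibrate_direction_weights(
                present_layout(layout, condition), _sector_weights(config, condition))
    trials: list[TrialRecord] = []
    for p in range(config.n_participants):
        rng = pstreams[p]
        effects = _ParticipantEffects(rng, config)
        order = rng.permutation(config.n_scenes)
        for scene_idx in order:
            scene = f"scene{scene_idx}"
            condition = scene_condition(p, int(scene_idx))
            layout = present_layout(layouts[scene], condition)
            locals_ = [o.object_id for o in layout if o.kind == "local"]
            targets = list(rng.choice(locals_, size=config.trials_per_scene, replace=False))
            gaze_hist: dict = {}
            for k, target_id in enumerate(targets, start=1):
                prior = float(gaze_hist.get(target_id, 0.0))
                rec = generate_trial(rng, config, layout, target_id, condition, k,
                                     effects, target_effects, prior_gaze_s=prior,
                                     direction_weights=dir_weights[(scene, condition)])
                rec.participant = p
                rec.scene = scene
                trials.append(rec)
                for obj, dur in rec.truth.gaze_by_object.items():
                    gaze_hist[obj] = gaze_hist.get(obj, 0.0) + dur
    return Experiment(config=config, layouts=layouts, trials=trials)


def write_experiment(exp: Experiment, outdir) -> None:
    """File bundle: per-trial gaze CSVs, trial metadata, layouts, truth."""
    import json
    import os

    os.makedirs(outdir, exist_ok=True)
    meta_rows = []
    truth_rows = []
    gaze_frames = []
    for i, tr in enumerate(exp.trials):
        meta_rows.append({
            "trial_id": i, "participant": tr.participant, "scene": tr.scene,
            "condition": tr.condition, "trial_index": tr.trial_index, "target": tr.target,
            "cue_offset_t": tr.cue_offset_t, "response_t": tr.response_t,
            "selected_object": tr.selected_object or "", "timeout": tr.timeout,
        })
        for kind, t0, t1, obj in tr.truth.events:
            truth_rows.append({"trial_id": i, "kind": kind, "onset_t": t0, "offset_t": t1,
                               "object": obj or ""})
        df = pd.DataFrame(tr.samples)
        df.insert(0, "trial_id", i)
        gaze_frames.append(df)
    pd.DataFrame(meta_rows).to_csv(os.path.join(outdir, "trials.csv"), index=False)
    pd.DataFrame(truth_rows).to_csv(os.path.join(outdir, "ground_truth_events.csv"), index=False)
    pd.concat(gaze_frames, ignore_index=True).to_csv(
        os.path.join(outdir, "gaze_samples.csv"), index=False)
    layouts = {
        scene: {o.object_id: {"lon": o.lon, "lat": o.lat, "radius_deg": o.radius_deg,
                              "kind": o.kind} for o in layout}
        for scene, layout in exp.layouts.items()
    }
    with open(os.path.join(outdir, "scene_layouts.json"), "w") as fh:
        json.dump(layouts, fh, indent=1)
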