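"""Velocity smoothing, thresholding and event segmentation."""

import numpy as np
import pytest

from vrsearch import events as ev
from vrsearch import geometry as geo


def sg_coeffs_oracle(window, polyorder):
    """Savitzky-Golay weights from the least-squares normal equations."""
    half = window // 2
    x = np.arange(-half, half + 1, dtype=float)
    A = np.vander(x, polyorder + 1, increasing=True)
    # value of the fitted polynomial at x=0 is the first row of the
    # pseudo-inverse applied to the window
    return np.linalg.pinv(A)[0]


class TestSmoothVelocity:
    def test_preserves_constants(self):
        v = np.full(100, 50.0)
        assert np.allclose(ev.smooth_velocity(v, 7, 2), 50.0)

    def test_exact_on_quadratic(self):
        x = np.arange(100, dtype=float)
        v = 0.01 * x ** 2 + 0.5 * x + 3
        out = ev.smooth_velocity(v, 7, 2)
        assert np.allclose(out[3:-3], v[3:-3], atol=1e-9)

    def test_matches_convolution_oracle(self, rng):
        v = np.abs(rng.normal(100, 40, 200))
        v[100:] += 200.0  # step
        w = sg_coeffs_oracle(7, 2)
        want = np.clip(np.convolve(v, w[::-1], mode="same"), 0, None)
        got = ev.smooth_velocity(v, 7, 2)
        assert np.allclose(got[3:-3], want[3:-3], atol=1e-9)

    def test_too_short_trace(self):
        with pytest.raises(ev.TooShortTraceError):
            ev.smooth_velocity(np.ones(5), 7, 2)


class TestClassifySamples:
    def test_threshold_is_strict(self):
        labels = ev.classify_samples(np.array([119.9, 120.0, 0.0]))
        assert labels.tolist() == [False, True, False]

    def test_all_zero_trace_is_fixation(self):
        assert not ev.classify_samples(np.zeros(50)).any()


def _mk(t_n, labels):
    """Helper trace: equator positions, 120 Hz, given saccade labels."""
    t = np.arange(t_n) / 120.0
    lon = np.cumsum(np.where(labels, 1.0, 0.0))  # drift during saccades
    return t, lon, np.zeros(t_n)


class TestSegmentEvents:
    def test_single_fixation(self):
        t, lon, lat = _mk(100, np.zeros(100, bool))
        out = ev.segment_events(np.zeros(100, bool), t, lon, lat)
        assert len(out) == 1 and out[0].kind == ev.FIXATION

    def test_fix_sacc_fix(self):
        labels = np.array([False] * 30 + [True] * 5 + [False] * 30)
        t, lon, lat = _mk(65, labels)
        out = ev.segment_events(labels, t, lon, lat, min_fix_dur=0.05, min_sacc_samples=2)
        assert [e.kind for e in out] == [ev.FIXATION, ev.SACCADE, ev.FIXATION]

    def test_short_saccade_absorbed(self):
        labels = np.array([False] * 30 + [True] + [False] * 30)
        t, lon, lat = _mk(61, labels)
        out = ev.segment_events(labels, t, lon, lat, min_sacc_samples=2)
        assert len(out) == 1 and out[0].kind == ev.FIXATION

    def test_short_fixation_absorbed_into_saccade(self):
        labels = np.array([False] * 30 + [True] * 4 + [False] * 2 + [True] * 4 + [False] * 30)
        t, lon, lat = _mk(70, labels)
        out = ev.segment_events(labels, t, lon, lat, min_fix_dur=0.05, min_sacc_samples=2)
        assert [e.kind for e in out] == [ev.FIXATION, ev.SACCADE, ev.FIXATION]

    def test_empty_input(self):
        assert ev.segment_events(np.array([], bool), [], [], []) == []

    def test_durations_tile_the_trace(self, rng):
        labels = rng.random(400) < 0.15
        t, lon, lat = _mk(400, labels)
        out = ev.segment_events(labels, t, lon, lat)
        assert sum(e.duration for e in out) == pytest.approx(t[-1] - t[0], abs=1e-9)
        for a, b in zip(out[:-1], out[1:]):
            assert a.offset_t == pytest.approx(b.onset_t)
            assert a.kind != b.kind  # alternation after post-processing

    def test_fixation_time_monotone_in_threshold(self, rng):
        t = np.arange(600) / 120.0
        lon = np.cumsum(rng.gamma(1.0, 1.0, 600) * 0.5)
        lat = np.zeros(600)
        v = geo.angular_velocity(t, lon, lat)
        vs = ev.smooth_velocity(v)
        prev = -1.0
        for thr in (30, 60, 90, 120, 200, 400):
            labels = np.append(ev.classify_samples(vs, thr), False)
            out = ev.segment_events(labels, t, lon, lat, min_fix_dur=0.0, min_sacc_samples=1)
            fix_time = sum(e.duration for e in out if e.kind == ev.FIXATION)
            assert fix_time >= prev - 1e-9
            prev = fix_time


class TestDetectGazeEvents:
    def test_events_do_not_span_gaps(self):
        t = np.concatenate([np.arange(60) / 120.0, 1.0 + np.arange(60) / 120.0])
        lon = np.zeros(120)
        out = ev.detect_gaze_events(t, lon, lon)
        assert len(out) == 2
        assert all(e.kind == ev.FIXATION for e in out)
        assert out[0].offset_t <= 60 / 120.0 and out[1].onset_t >= 1.0

    def test_ground_truth_fixation_counts_zero_noise(self, clean_experiment):
        for tr in clean_experiment.trials[:10]:
            s = tr.samples
            out = ev.detect_gaze_events(s["t"], s["gaze_lon"], s["gaze_lat"])
            n_true = sum(1 for e in tr.truth.events if e[0] == "fixation")
            n_det = sum(1 for e in out if e.kind == ev.FIXATION)
            assert abs(n_det - n_true) <= 1


class TestHeadMovements:
    def test_stationary_head_zero_amplitude(self, clean_experiment):
        tr = clean_experiment.trials[0]
        s = tr.samples
        out = ev.detect_gaze_events(s["t"], s["gaze_lon"], s["gaze_lat"])
        still = np.zeros_like(s["t"])
        moves = ev.detect_head_movements(s["t"], still, still, out)
        assert moves and all(m.amplitude == 0.0 for m in moves)

    def test_uniform_head_rotation_during_saccade(self):
        # gaze: 0.25 s fixation, fast 20-degree shift, 0.3 s fixation;
        # head rotates rightward at 20 deg/s throughout
        t = np.arange(72) / 120.0
        lon = np.concatenate([np.zeros(30), np.linspace(0, 20, 6), np.full(36, 20.0)])
        lat = np.zeros(72)
        head_lon = 20.0 * t
        out = ev.detect_gaze_events(t, lon, lat)
        sacc = [e for e in out if e.kind == ev.SACCADE]
        assert len(sacc) == 1
        moves = ev.detect_head_movements(t, head_lon, lat, out)
        m = moves[0]
        assert m.amplitude == pytest.approx(20.0 * m.duration, rel=1e-6)
        from vrsearch.saccades import displacement_angle

        ang = displacement_angle(m.onset.lon, m.onset.lat, m.offset.lon, m.offset.lat)
        assert ang == pytest.approx(0.0, abs=1e-6)

    def test_head_gain_recovered_from_generator(self, clean_experiment):
        ratios = []
        for tr in clean_experiment.trials:
            s = tr.samples
            out = ev.detect_gaze_events(s["t"], s["gaze_lon"], s["gaze_lat"])
            sacc = [e for e in out if e.kind == ev.SACCADE]
            if not sacc:
                continue
            moves = ev.detect_head_movements(s["t"], s["head_lon"], s["head_lat"], out)
            ratios.append(np.mean([m.amplitude for m in moves]) /
                          np.mean([e.amplitude for e in sacc]))
        gain = clean_experiment.config.head_gain
        assert np.mean(ratios) == pytest.approx(gain, rel=0.10)
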