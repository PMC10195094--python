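"""Object assignment, accuracy correction, RT decomposition, exclusions."""

import numpy as np
import pandas as pd
import pytest

from vrsearch import geometry, search
from vrsearch.events import FIXATION, SACCADE, GazeEvent
from vrsearch.geometry import SphericalDirection
from vrsearch.search import SceneObject


def _fix(t0, t1, lon, lat):
    return GazeEvent(FIXATION, 0, 1, t0, t1, SphericalDirection(lon, lat),
                     SphericalDirection(lon, lat), centroid=SphericalDirection(lon, lat))


def _sacc(t0, t1):
    return GazeEvent(SACCADE, 0, 1, t0, t1, SphericalDirection(0, 0),
                     SphericalDirection(5, 0), amplitude=5.0)


LAYOUT = [
    SceneObject("a", 0.0, 0.0, 3.0),
    SceneObject("b", 20.0, 10.0, 3.0),
    SceneObject("c", -30.0, -10.0, 5.0, kind="anchor"),
]


class TestAssignment:
    def test_center_hit(self):
        assert search.assign_fixations_to_objects([20.0], [10.0], LAYOUT) == ["b"]

    def test_outside_all_discs(self):
        assert search.assign_fixations_to_objects([10.0], [0.0], LAYOUT) == [None]

    def test_empty_layout(self):
        assert search.assign_fixations_to_objects([0.0], [0.0], []) == [None]

    def test_matches_brute_force_oracle(self, rng):
        objs = [SceneObject(f"o{i}", rng.uniform(-150, 150), rng.uniform(-60, 60),
                            rng.uniform(2, 8)) for i in range(30)]
        lons = rng.uniform(-160, 160, 500)
        lats = rng.uniform(-70, 70, 500)
        got = search.assign_fixations_to_objects(lons, lats, objs)
        for i in range(500):
            best, bd = None, np.inf
            for o in objs:
                d = geometry.orthodromic_distance(lons[i], lats[i], o.lon, o.lat)
                if d <= o.radius_deg and d < bd:
                    best, bd = o.object_id, d
            assert got[i] == best


class TestAccuracyCorrection:
    def test_direct_selection(self):
        assert search.apply_accuracy_correction("t", "t", False, None)

    def test_wrong_selection_with_gaze_on_target(self):
        assert search.apply_accuracy_correction("x", "t", False, "t")

    def test_timeout_never_correct(self):
        assert not search.apply_accuracy_correction(None, "t", True, "t")

    def test_plain_miss(self):
        assert not search.apply_accuracy_correction("x", "t", False, "y")


class TestDecomposeRT:
    def test_three_phase_arithmetic(self):
        events = [_fix(0.0, 0.2, 50, 0), _sacc(0.2, 0.25), _fix(0.25, 1.0, 0, 0),
                  _sacc(1.0, 1.5), _fix(1.5, 2.2, 20, 10)]
        stream = [None, "a", "b"]
        out = search.decompose_rt(0.0, 2.0, events, stream, "b")
        assert out["initiation"] == pytest.approx(0.2)
        assert out["scanning"] == pytest.approx(1.3)
        assert out["verification"] == pytest.approx(0.5)
        rt = out["initiation"] + out["scanning"] + out["verification"]
        assert rt == pytest.approx(2.0)

    def test_no_saccade_flag(self):
        out = search.decompose_rt(0.0, 1.0, [_fix(0, 1, 0, 0)], ["a"], "a")
        assert out["no_saccade"]

    def test_first_fixation_on_target_flag(self):
        events = [_fix(0.0, 0.2, 50, 0), _sacc(0.2, 0.25), _fix(0.25, 1.0, 20, 10)]
        out = search.decompose_rt(0.0, 1.0, events, [None, "b"], "b")
        assert out["first_fix_on_target"]

    def test_target_never_fixated(self):
        events = [_fix(0.0, 0.2, 50, 0), _sacc(0.2, 0.25), _fix(0.25, 1.0, 0, 0)]
        out = search.decompose_rt(0.0, 1.0, events, [None, "a"], "b")
        assert out["target_not_fixated"]
        assert np.isnan(out["scanning"])


class TestCountMeasures:
    @pytest.mark.parametrize("stream, want", [
        (["a", "t"], 0),
        (["t", "b", "t", "c", "t"], 2),
        (["t", "t", "b", "t"], 1),
    ])
    def test_refixation_examples(self, stream, want):
        events = [_fix(i * 0.3, i * 0.3 + 0.25, 0, 0) for i in range(len(stream))]
        out = search.count_measures(events, stream, "t")
        assert out["target_refixations"] == want

    def test_matches_run_length_oracle(self, rng):
        for _ in range(100):
            stream = list(rng.choice(["t", "a", "b", None], size=12))
            events = [_fix(i * 0.3, i * 0.3 + 0.2, 0, 0) for i in range(12)]
            out = search.count_measures(events, stream, "t")
            runs = sum(1 for i, o in enumerate(stream)
                       if o == "t" and (i == 0 or stream[i - 1] != "t"))
            assert out["target_refixations"] == max(runs - 1, 0)
            assert out["fixated_objects_count"] <= out["fixation_count"]
            assert out["target_refixations"] <= out["fixation_count"]


class TestPriorTargetGaze:
    def test_first_trial_is_zero(self):
        assert search.prior_target_gaze(["t"], [{}])[0] == 0.0

    def test_accumulates_earlier_trials(self):
        durs = [{"x": 0.4}, {"x": 0.3, "y": 1.0}, {"z": 2.0}]
        got = search.prior_target_gaze(["a", "b", "x"], durs)
        assert got[2] == pytest.approx(0.7)

    def test_matches_exhaustive_oracle(self, rng):
        objs = list("abcdef")
        targets = list(rng.choice(objs, 10))
        durs = [{o: float(rng.uniform(0, 1)) for o in rng.choice(objs, 3, replace=False)}
                for _ in range(10)]
        got = search.prior_target_gaze(targets, durs)
        for k in range(10):
            want = sum(d.get(targets[k], 0.0) for d in durs[:k])
            assert got[k] == pytest.approx(want)


def _toy_metrics():
    rows = []
    for i in range(10):
        rows.append({
            "correct": i != 0,
            "no_saccade": i == 1,
            "first_fix_on_target": i == 2,
            "initiation_ms": 200.0,
            "verification_ms": 500.0,
        })
    return pd.DataFrame(rows)


class TestExclusionCascade:
    def test_constructed_fixture_counts(self):
        out = search.exclusion_cascade(_toy_metrics())
        counts = out["excluded"].value_counts()
        assert counts.get("incorrect", 0) == 1
        assert counts.get("no_saccade", 0) == 1
        assert counts.get("first_fix_on_target", 0) == 1
        assert counts.get("none", 0) == 7
        summary = search.exclusion_summary(out)
        assert summary.set_index("label").loc["none", "percent"] == pytest.approx(70.0)

    def test_zero_variance_no_sd_exclusions(self):
        out = search.exclusion_cascade(_toy_metrics())
        assert (out["excluded"] == "sd_cutoff").sum() == 0

    def test_labels_are_exclusive_and_exhaustive(self, rng):
        # enough clean trials that a gross outlier can exceed +3 SD
        # (with n points the largest possible z is (n-1)/sqrt(n))
        df = pd.concat([_toy_metrics()] * 4, ignore_index=True)
        df["verification_ms"] += rng.normal(0.0, 10.0, len(df))
        df.loc[5, "verification_ms"] = 1e6
        out = search.exclusion_cascade(df)
        assert out.loc[5, "excluded"] == "sd_cutoff"
        valid = set(search.EXCLUSION_LABELS) | {"none"}
        assert set(out["excluded"]) <= valid

    def test_cascade_order_first_label_wins(self):
        df = _toy_metrics()
        df.loc[1, "correct"] = False  # incorrect AND saccade-free
        out = search.exclusion_cascade(df)
        assert out.loc[1, "excluded"] == "incorrect"
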