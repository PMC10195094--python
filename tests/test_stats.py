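"""Model specs, slopes, JZS Bayes factor, within-subject SE, contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy import stats as sps

from vrsearch import stats


def jzs_bf01_delta_oracle(t, n, r=0.707):
    """Independent quadrature of the JZS integral over effect size."""
    nu = n - 1

    def f(d):
        return sps.nct.pdf(t, nu, d * np.sqrt(n)) * sps.cauchy.pdf(d, scale=r)

    m1, _ = integrate.quad(f, -np.inf, np.inf, limit=400)
    return sps.t.pdf(t, nu) / m1


def wsse_oracle(df, value):
    """Independent Cousineau-Morey implementation."""
    cell = df.pivot_table(index="participant", columns="condition", values=value,
                          aggfunc="mean").dropna()
    C = cell.shape[1]
    norm = cell.values - cell.values.mean(axis=1, keepdims=True) + cell.values.mean()
    se = norm.std(axis=0, ddof=1) / np.sqrt(cell.shape[0]) * np.sqrt(C / (C - 1))
    return pd.Series(se, index=cell.columns)


class TestModelSpec:
    @pytest.mark.parametrize("measure, family", [
        ("response_time", "gaussian_on_log"),
        ("accuracy", "binomial"),
        ("gaze_amplitude", "gamma"),
        ("fixation_count", "poisson"),
        ("gaze_latitude", "gaussian"),
    ])
    def test_family_per_measure(self, measure, family):
        assert stats.build_model_spec(measure).family == family

    def test_rt_keeps_participant_slope_but_phases_drop_it(self):
        assert stats.build_model_spec("response_time").participant_slope
        for m in ("initiation", "scanning", "verification", "fixation_duration"):
            assert not stats.build_model_spec(m).participant_slope

    def test_direction_models_have_no_covariate(self):
        assert not stats.build_model_spec("gaze_direction").include_covariate

    def test_unknown_measure_lists_supported(self):
        with pytest.raises(ValueError, match="accuracy"):
            stats.build_model_spec("nope")

    def test_difference_contrast_coding(self):
        c = stats.condition_contrast(["inverted", "upright"])
        assert c.tolist() == [0.5, -0.5]


def _slope_frame(fn):
    rows = []
    for cond in ("upright", "inverted"):
        for trial in range(1, 11):
            rows.append({"participant": 1, "condition": cond, "trial_index": trial,
                         "rt_ms": fn(trial)})
    return pd.DataFrame(rows)


class TestPerParticipantSlopes:
    def test_constant_rt_gives_zero(self):
        out = stats.per_participant_slopes(_slope_frame(lambda k: 1000.0))
        assert np.allclose(out["slope"], 0.0)

    def test_exact_exponential_slope(self):
        out = stats.per_participant_slopes(_slope_frame(lambda k: np.exp(1 - 0.05 * k)))
        assert np.allclose(out["slope"], -0.05)

    def test_invariant_to_multiplicative_scaling(self, rng):
        df = _slope_frame(lambda k: float(rng.lognormal(7, 0.3)))
        s1 = stats.per_participant_slopes(df)["slope"]
        df2 = df.copy()
        df2["rt_ms"] *= 3.7
        s2 = stats.per_participant_slopes(df2)["slope"]
        assert np.allclose(s1, s2)

    def test_single_point_is_nan(self):
        df = pd.DataFrame({"participant": [1], "condition": ["upright"],
                           "trial_index": [1], "rt_ms": [900.0]})
        assert np.isnan(stats.per_participant_slopes(df)["slope"].iloc[0])


class TestJZSBayesFactor:
    def test_reciprocity_exact(self, rng):
        r = stats.jzs_bayes_factor(x=rng.normal(0.2, 1.0, 20))
        assert r.bf01 * r.bf10 == 1.0

    def test_large_t_vanishing_bf01(self):
        assert stats.jzs_bayes_factor(t=10.0, n=20).bf01 < 1e-4
        assert stats.jzs_bayes_factor(t=10.0, n=20).bf01 < \
            stats.jzs_bayes_factor(t=2.0, n=20).bf01

    def test_null_favored_at_t_zero(self):
        for n in range(2, 31):
            assert stats.jzs_bayes_factor(t=0.0, n=n).bf01 > 1.0

    @pytest.mark.parametrize("t, n", [(0.0, 5), (0.5, 20), (1.0, 10), (2.0, 20), (3.0, 50)])
    def test_matches_independent_quadrature(self, t, n):
        mine = stats.jzs_bayes_factor(t=t, n=n).bf01
        assert mine == pytest.approx(jzs_bf01_delta_oracle(t, n), rel=0.005)

    def test_zero_variance_rejected(self):
        with pytest.raises(stats.DegenerateDataError):
            stats.jzs_bayes_factor(x=np.ones(10))

    def test_interpretation_bands(self):
        assert stats.interpret_bf01(4.0) == "evidence for null"
        assert stats.interpret_bf01(0.2) == "evidence for alternative"
        assert stats.interpret_bf01(1.0) == "inconclusive"


def _wsse_frame(rng, n=12, effect=None):
    rows = []
    for p in range(n):
        base = rng.normal(1000, 150)
        for cond in ("upright", "inverted"):
            delta = effect(p, cond) if effect else rng.normal(0, 40)
            rows.append({"participant": p, "condition": cond, "value": base + delta})
    return pd.DataFrame(rows)


class TestWithinSubjectSE:
    def test_identical_condition_difference_gives_zero(self, rng):
        df = _wsse_frame(rng, effect=lambda p, c: 50.0 if c == "inverted" else 0.0)
        se = stats.within_subject_se(df, "value")
        assert np.allclose(se, 0.0, atol=1e-10)

    def test_matches_independent_oracle(self, rng):
        df = _wsse_frame(rng)
        got = stats.within_subject_se(df, "value")
        want = wsse_oracle(df, "value")
        assert np.allclose(got.sort_index(), want.sort_index(), atol=1e-12)

    def test_morey_factor_two_conditions(self, rng):
        # with the participant means removed, the two normalized columns
        # are +/- half the difference: SE = sd(diff)/2/sqrt(n) * sqrt(2)
        df = _wsse_frame(rng)
        cell = df.pivot(index="participant", columns="condition", values="value")
        diff = cell["inverted"] - cell["upright"]
        want = diff.std(ddof=1) / 2 / np.sqrt(len(cell)) * np.sqrt(2.0)
        se = stats.within_subject_se(df, "value")
        assert np.allclose(se, want, atol=1e-12)

    def test_not_larger_than_between_se_without_interaction(self, rng):
        df = _wsse_frame(rng, effect=lambda p, c: 30.0 if c == "inverted" else 0.0)
        wse = stats.within_subject_se(df, "value").max()
        cell = df.pivot(index="participant", columns="condition", values="value")
        between = cell.std(ddof=1).max() / np.sqrt(len(cell))
        assert wse <= between + 1e-9

    def test_incomplete_participant_dropped_with_warning(self, rng):
        df = _wsse_frame(rng).iloc[:-1]  # last participant misses a condition
        with pytest.warns(UserWarning):
            stats.within_subject_se(df, "value")


class TestDirectionCountModel:
    def _counts(self, fn):
        rows = []
        for p in range(8):
            for cond in ("upright", "inverted"):
                for sector in ("right", "up", "left", "down"):
                    rows.append({"participant": p, "condition": cond, "sector": sector,
                                 "count": fn(p, cond, sector)})
        return pd.DataFrame(rows)

    def test_contrast_columns(self):
        out = stats.direction_count_model_data(self._counts(lambda p, c, s: 10))
        r = out[out.sector == "right"].iloc[0]
        assert r["rl_c"] == 0.5 and r["ud_c"] == 0.0
        u = out[(out.sector == "up") & (out.condition == "inverted")].iloc[0]
        assert u["ud_c"] == 0.5 and u["orient_ud"] == 0.25

    def test_balanced_counts_yield_null_contrasts(self):
        """Perfectly balanced cells: a plain Poisson GLM oracle finds ~0 effects."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        out = stats.direction_count_model_data(self._counts(lambda p, c, s: 40))
        fit = smf.glm("count ~ orient_c + rl_c + ud_c + orient_rl + orient_ud", out,
                      family=sm.families.Poisson()).fit()
        assert np.allclose(fit.params[1:], 0.0, atol=1e-8)

    def test_inflated_inverted_counts_give_positive_orientation_effect(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        out = stats.direction_count_model_data(
            self._counts(lambda p, c, s: 80 if c == "inverted" else 40))
        fit = smf.glm("count ~ orient_c + rl_c + ud_c + orient_rl + orient_ud", out,
                      family=sm.families.Poisson()).fit()
        assert fit.params["orient_c"] == pytest.approx(np.log(2.0), abs=1e-6)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            stats.direction_count_model_data(pd.DataFrame())
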