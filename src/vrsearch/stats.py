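"""Statistical layer: model specifications, slopes, Bayes factors, SEs.

The condition factor is always coded with a difference contrast
(inverted = +0.5, upright = -0.5) so the reported coefficient *b* is the
inverted-minus-upright difference. Response-time family measures are
log-transformed before Gaussian mixed-model fitting (gaze latitude is
left untransformed); accuracy uses a binomial family, count measures a
Poisson family, and movement amplitudes a Gamma family. The summed gaze
duration on the target object from previous trials enters as a z-scored
covariate except in the direction-count models (data averaged across
trials).

Model fitting itself is delegated to established estimation routines
(statsmodels); this module owns the specification, the contrast and
covariate coding, and result extraction. The JZS Bayes factor for the
one-sample/paired t contrast (Cauchy prior on effect size, default width
r = 0.707) is computed here by numerical quadrature, and condition means
are accompanied by within-subject standard errors (Cousineau
normalization with the Morey correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps

CONDITIONS = ("upright", "inverted")
DEFAULT_CAUCHY_WIDTH = 0.707


class DegenerateDataError(ValueError):
    """Data with zero variance cannot support a t-based Bayes factor."""


def condition_contrast(condition) -> np.ndarray:
    """Difference contrast: inverted -> +0.5, upright -> -0.5."""
    cond = np.asarray(condition)
    return np.where(cond == "inverted", 0.5, -0.5)


@dataclass
class StatResult:
    """One model term: estimate, SE, test statistic, p, optional BF01."""

    term: str
    b: float
    se: float
    stat: float
    p: float
    stat_name: str = "t"
    bf01: float | None = None

    @property
    def bf10(self) -> float | None:
        return None if self.bf01 is None else 1.0 / self.bf01


@dataclass
class ModelSpec:
    """Family, transform and random-effects structure for one measure."""

    measure: str
    response: str
    family: str  # gaussian_on_log | gaussian | binomial | poisson | gamma
    fixed: list = field(default_factory=lambda: ["condition", "prior_target_gaze"])
    participant_slope: bool = True
    target_intercept: bool = True
    include_covariate: bool = True


# measure -> (response column, family, participant random slope, covariate)
_MEASURES = {
    "accuracy": ("correct", "binomial", True, True),
    "response_time": ("rt_ms", "gaussian_on_log", True, True),
    "initiation": ("initiation_ms", "gaussian_on_log", False, True),
    "scanning": ("scanning_ms", "gaussian_on_log", False, True),
    "verification": ("verification_ms", "gaussian_on_log", False, True),
    "fixation_duration": ("mean_fixation_duration_ms", "gaussian_on_log", False, True),
    "fixation_count": ("fixation_count", "poisson", True, True),
    "fixated_objects_count": ("fixated_objects_count", "poisson", True, True),
    "target_refixations": ("target_refixations", "poisson", True, True),
    "gaze_latitude": ("latitude_deg", "gaussian", True, True),
    "gaze_amplitude": ("amplitude_deg", "gamma", True, True),
    "head_amplitude": ("head_amplitude_deg", "gamma", True, True),
    "gaze_direction": ("count", "poisson", False, False),
    "head_direction": ("count", "poisson", False, False),
}


def build_model_spec(measure: str) -> ModelSpec:
    """Model specification for one of the study's dependent measures."""
    if measure not in _MEASURES:
        raise ValueError(
            f"unknown measure {measure!r}; supported: {', '.join(sorted(_MEASURES))}"
        )
    response, family, p_slope, covariate = _MEASURES[measure]
    fixed = ["condition"] + (["prior_target_gaze"] if covariate else [])
    return ModelSpec(measure, response, family, fixed, p_slope, True, covariate)


def _prepare(df: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    data = df.copy()
    data["cond_c"] = condition_contrast(data["condition"])
    if spec.include_covariate and "prior_target_gaze_s" in data.columns:
        x = data["prior_target_gaze_s"].astype(float)
        sd = x.std(ddof=1)
        data["prior_z"] = (x - x.mean()) / sd if sd > 0 else 0.0
    else:
        data["prior_z"] = 0.0
    y = data[spec.response].astype(float)
    if spec.family == "gaussian_on_log":
        data["_y"] = np.log(y)
    elif spec.family == "binomial":
        data["_y"] = y.astype(int)
    else:
        data["_y"] = y
    return data.dropna(subset=["_y"])


def fit_measure(df: pd.DataFrame, measure: str, include_target_re: bool = True) -> dict[str, StatResult]:
    """Fit the study model for one measure on included trials.

    Gaussian families use a linear mixed model (REML) with a participant
    random intercept (plus a condition slope where the measure's model
    specification allows it)
    and a target-object variance component; binomial and Poisson
    families use a Bayesian mixed GLM (variational fit) with the same
    random structure; the Gamma family uses GEE with a log link,
    clustered by participant. Returns results keyed by term.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    spec = build_model_spec(measure)
    data = _prepare(df, spec)
    terms = ["cond_c"] + (["prior_z"] if spec.include_covariate else [])
    formula = "_y ~ " + " + ".join(terms)
    vc = {"target": "0 + C(target)"} if (include_target_re and "target" in data.columns) else None

    if spec.family in ("gaussian_on_log", "gaussian"):
        re_f = "~cond_c" if spec.participant_slope else "~1"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data, groups=data["participant"],
                                re_formula=re_f, vc_formula=vc)
            fit = model.fit(reml=True, method="lbfgs")
        out = {}
        for term in terms:
            out[term] = StatResult(term, float(fit.params[term]), float(fit.bse[term]),
                                   float(fit.tvalues[term]), float(fit.pvalues[term]), "t")
        return out

    if spec.family in ("binomial", "poisson"):
        from statsmodels.genmod.bayes_mixed_glm import (
            BinomialBayesMixedGLM,
            PoissonBayesMixedGLM,
        )

        vcf = {"participant": "0 + C(participant)"}
        if include_target_re and "target" in data.columns:
            vcf["target"] = "0 + C(target)"
        cls = BinomialBayesMixedGLM if spec.family == "binomial" else PoissonBayesMixedGLM
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = cls.from_formula(formula, vcf, data)
            fit = model.fit_vb()
        names = list(fit.model.exog_names)
        out = {}
        for term in terms:
            i = names.index(term)
            b = float(fit.fe_mean[i])
            se = float(fit.fe_sd[i])
            z = b / se
            out[term] = StatResult(term, b, se, z, 2 * sps.norm.sf(abs(z)), "z")
        return out

    if spec.family == "gamma":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.gee(formula, groups="participant", data=data,
                            family=sm.families.Gamma(link=sm.families.links.Log()),
                            cov_struct=sm.cov_struct.Exchangeable())
            fit = model.fit()
        out = {}
        for term in terms:
            z = float(fit.tvalues[term])
            out[term] = StatResult(term, float(fit.params[term]), float(fit.bse[term]),
                                   z, float(fit.pvalues[term]), "z")
        return out

    raise ValueError(f"unsupported family {spec.family!r}")


def fit_rt_by_trial(df: pd.DataFrame, include_target_re: bool = True) -> dict[str, StatResult]:
    """Log-RT across trials: condition x trial-number interaction model."""
    import statsmodels.formula.api as smf

    data = df.copy()
    data["cond_c"] = condition_contrast(data["condition"])
    x = data.get("prior_target_gaze_s")
    if x is not None and x.std(ddof=1) > 0:
        data["prior_z"] = (x - x.mean()) / x.std(ddof=1)
    else:
        data["prior_z"] = 0.0
    data["trial_c"] = data["trial_index"].astype(float) - data["trial_index"].astype(float).mean()
    data["_y"] = np.log(data["rt_ms"].astype(float))
    data = data.dropna(subset=["_y"])
    vc = {"target": "0 + C(target)"} if (include_target_re and "target" in data.columns) else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("_y ~ cond_c * trial_c + prior_z", data,
                            groups=data["participant"], re_formula="~1", vc_formula=vc)
        fit = model.fit(reml=True, method="lbfgs")
    out = {}
    for term in ("cond_c", "trial_c", "cond_c:trial_c", "prior_z"):
        out[term] = StatResult(term, float(fit.params[term]), float(fit.bse[term]),
                               float(fit.tvalues[term]), float(fit.pvalues[term]), "t")
    return out


def per_participant_slopes(metrics: pd.DataFrame, response: str = "rt_ms") -> pd.DataFrame:
    """OLS slope of log response on trial index per participant x condition.

    A participant's scenes are pooled within condition (trial index runs
    1..10 within every scene). Cells with fewer than two valid trials
    yield NaN.
    """
    rows = []
    for (p, cond), sub in metrics.groupby(["participant", "condition"], observed=True):
        y = np.log(sub[response].astype(float))
        x = sub["trial_index"].astype(float)
        ok = np.isfinite(y) & np.isfinite(x)
        if ok.sum() >= 2 and x[ok].nunique() >= 2:
            slope = float(np.polyfit(x[ok], y[ok], 1)[0])
        else:
            slope = np.nan
        rows.append({"participant": p, "condition": cond, "slope": slope})
    return pd.DataFrame(rows)


def jzs_bayes_factor(t: float | None = None, n: int | None = None, x=None, y=None,
                     r: float = DEFAULT_CAUCHY_WIDTH) -> StatResult:
    """JZS Bayes factor for a one-sample (or paired) t contrast.

    Either pass the t statistic and sample size directly, or data ``x``
    (one sample of differences) or paired samples ``x, y``. The prior on
    the standardized effect size is a zero-centered Cauchy of width
    ``r``; the marginal likelihood under the alternative integrates the
    t likelihood over that prior (g-representation, adaptive
    quadrature). BF01 > 1 favors the null.
    """
    if x is not None:
        x = np.asarray(x, dtype=float)
        if y is not None:
            x = x - np.asarray(y, dtype=float)
        n = x.size
        if n < 2:
            raise DegenerateDataError("need at least two observations")
        sd = x.std(ddof=1)
        if sd == 0:
            raise DegenerateDataError("zero-variance data")
        t = float(x.mean() / (sd / np.sqrt(n)))
    if t is None or n is None or n < 2:
        raise DegenerateDataError("need t and n >= 2")
    nu = n - 1

    def integrand(g: float) -> float:
        c = 1.0 + n * g * r * r
        like = c ** -0.5 * (1.0 + t * t / (nu * c)) ** (-(nu + 1) / 2.0)
        # g ~ InverseGamma(1/2, 1/2)
        prior = g ** -1.5 * np.exp(-1.0 / (2.0 * g)) / np.sqrt(2.0 * np.pi)
        return like * prior

    m1a, _ = integrate.quad(integrand, 0.0, 2.0, points=[0.01, 0.1, 1.0], limit=200)
    m1b, _ = integrate.quad(integrand, 2.0, np.inf, limit=200)
    m1 = m1a + m1b
    m0 = (1.0 + t * t / nu) ** (-(nu + 1) / 2.0)
    bf01 = m0 / m1
    p = 2 * sps.t.sf(abs(t), nu)
    d = float(t) / np.sqrt(n)  # standardized effect estimate
    return StatResult("jzs", d, np.nan, float(t), float(p), "t", bf01=float(bf01))


def results_to_frame(results: dict) -> pd.DataFrame:
    """Flatten fitted model terms into a tidy table.

    Accepts either ``{term: StatResult}`` for one model or
    ``{model: {term: StatResult}}`` for several; one row per term with
    columns model, term, b, SE, stat, p (and BF01 where present).
    """
    rows = []

    def emit(model, term, r):
        rows.append({"model": model, "term": term, "b": r.b, "SE": r.se,
                     "stat_name": r.stat_name, "stat": r.stat, "p": r.p,
                     "BF01": r.bf01})

    for key, val in results.items():
        if isinstance(val, StatResult):
            emit(None, key, val)
        elif isinstance(val, dict):
            for term, r in val.items():
                if isinstance(r, StatResult):
                    emit(key, term, r)
    return pd.DataFrame(rows)


def interpret_bf01(bf01: float) -> str:
    """Evidence band: null (BF01 > 3), alternative (< 0.3), inconclusive."""
    if bf01 > 3.0:
        return "evidence for null"
    if bf01 < 0.3:
        return "evidence for alternative"
    return "inconclusive"


def within_subject_se(metrics: pd.DataFrame, value: str, participant: str = "participant",
                      condition: str = "condition") -> pd.Series:
    """Within-subject SE per condition (Cousineau-Morey).

    Each participant's condition means are normalized by removing the
    participant mean and adding the grand mean; the SE of each condition
    column is then scaled by the Morey factor sqrt(C / (C - 1)).
    Participants missing a condition are dropped with a warning.
    """
    cell = metrics.groupby([participant, condition], observed=True)[value].mean().unstack(condition)
    complete = cell.dropna()
    if len(complete) < len(cell):
        warnings.warn(f"dropping {len(cell) - len(complete)} participant(s) missing a condition",
                      stacklevel=2)
    c_count = complete.shape[1]
    normalized = complete.sub(complete.mean(axis=1), axis=0) + complete.values.mean()
    se = normalized.std(ddof=1) / np.sqrt(len(complete))
    return se * np.sqrt(c_count / (c_count - 1.0))


def direction_count_model_data(counts: pd.DataFrame) -> pd.DataFrame:
    """Long-format direction counts with the planned contrasts.

    Input: the sector-count table (participant, condition, sector,
    count). Adds orientation (inverted = +0.5), right-vs-left and
    up-vs-down contrasts and their orientation interactions — the inputs
    of the Poisson model on movement counts (no gaze-duration covariate:
    counts are pooled across trials).
    """
    if counts.empty:
        raise ValueError("empty direction counts")
    df = counts.copy()
    df["orient_c"] = condition_contrast(df["condition"])
    df["rl_c"] = df["sector"].map({"right": 0.5, "left": -0.5}).fillna(0.0)
    df["ud_c"] = df["sector"].map({"up": 0.5, "down": -0.5}).fillna(0.0)
    df["orient_rl"] = df["orient_c"] * df["rl_c"]
    df["orient_ud"] = df["orient_c"] * df["ud_c"]
    return df


def fit_direction_model(long_df: pd.DataFrame) -> dict[str, StatResult]:
    """Poisson mixed model on sector counts with participant intercept."""
    from statsmodels.genmod.bayes_mixed_glm import PoissonBayesMixedGLM

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PoissonBayesMixedGLM.from_formula(
            "count ~ orient_c + rl_c + ud_c + orient_rl + orient_ud",
            {"participant": "0 + C(participant)"},
            long_df,
        )
        fit = model.fit_vb()
    names = list(fit.model.exog_names)
    out = {}
    for term in ("orient_c", "rl_c", "ud_c", "orient_rl", "orient_ud"):
        i = names.index(term)
        b = float(fit.fe_mean[i])
        se = float(fit.fe_sd[i])
        z = b / se
        out[term] = StatResult(term, b, se, z, 2 * sps.norm.sf(abs(z)), "z")
    return out
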