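"""Mixed-effect models for proximal, symptom and distal analyses.

All fits are linear mixed models with a participant random intercept,
estimated by REML (statsmodels ``MixedLM``) with Wald 95% confidence
intervals:

* proximal model -- night-level sleep minutes on feedback, elapsed day,
  their interaction, and controls (previous night's sleep hours, age,
  sex); the feedback coefficient is the day-0 proximal effect in minutes
  and the interaction its per-day decay.  Subgroup (per phenotype group)
  and message-content-stratified variants reuse the same specification.
* symptom models -- momentary EMA outcomes (depressive mood, anxiety,
  morning subjective sleep quality) on the six intraindividual sleep
  features plus age and sex; the slope on sleep-hour IIV is the quantity
  of interest.
* distal model -- 2 (study) x 2 (group) mixed-effect ANOVA per sleep
  feature with age/sex covariates, Wald F tests for the main effects and
  interaction, and Tukey-adjusted within-group study contrasts
  (studentized-range adjustment over the four study-x-group cells).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

from .habitual_stats import (
    FEATURE_COLUMNS,
    IIV_COLUMNS,
    IntraindividualStats,
    log_transform_iiv,
)

logger = logging.getLogger(__name__)

PROXIMAL_FORMULA = "sleep_min ~ age + sex + sleep_prev_h + feedback + day + feedback:day"
SYMPTOM_OUTCOMES = ("depressive", "anxious", "sleep_quality")


@dataclass
class Coefficient:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI bounds must bracket the point estimate")


@dataclass
class MixedModelFit:
    """Fixed-effect coefficient set of a random-intercept linear mixed model."""

    coefficients: dict[str, Coefficient]
    random_intercept_var: float
    residual_var: float
    n_obs: int
    n_participants: int
    converged: bool

    def __post_init__(self) -> None:
        if self.n_obs < self.n_participants:
            raise ValueError("cannot have fewer observations than participants")

    def coef_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": list(self.coefficients),
                "estimate": [c.estimate for c in self.coefficients.values()],
                "se": [c.se for c in self.coefficients.values()],
                "ci_low": [c.ci_low for c in self.coefficients.values()],
                "ci_high": [c.ci_high for c in self.coefficients.values()],
                "p": [c.p_value for c in self.coefficients.values()],
            }
        )

    def to_dict(self) -> dict:
        return {
            "coefficients": {
                k: vars(c).copy() for k, c in self.coefficients.items()
            },
            "random_intercept_var": self.random_intercept_var,
            "residual_var": self.residual_var,
            "n_obs": self.n_obs,
            "n_participants": self.n_participants,
            "converged": self.converged,
        }


class ProximalFit(MixedModelFit):
    pass


@dataclass
class SymptomFit(MixedModelFit):
    outcome: str = ""

    @property
    def iiv_sh_slope(self) -> Coefficient:
        return self.coefficients["iiv_sh"]


@dataclass
class DistalContrast:
    group: str
    estimate: float  # study-2 minus study-1 cell mean difference
    se: float
    p_tukey: float


@dataclass
class DistalResult:
    feature: str
    f_study: float
    p_study: float
    f_group: float
    p_group: float
    f_interaction: float
    p_interaction: float
    contrasts: dict[str, DistalContrast] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for f in (self.f_study, self.f_group, self.f_interaction):
            if f < 0:
                raise ValueError("F statistics must be non-negative")


def _fit_mixedlm(formula: str, data: pd.DataFrame, groups: pd.Series):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=groups)
        try:
            result = model.fit(reml=True)
        except Exception:  # singular fits: fall back to a more robust optimizer
            result = model.fit(reml=True, method="powell")
    return result


def _extract_fit(result, data: pd.DataFrame, cls=MixedModelFit, **extra) -> MixedModelFit:
    conf = result.conf_int()
    coefficients = {}
    for name in result.fe_params.index:
        coefficients[name] = Coefficient(
            estimate=float(result.fe_params[name]),
            se=float(result.bse[name]),
            ci_low=float(conf.loc[name, 0]),
            ci_high=float(conf.loc[name, 1]),
            p_value=float(result.pvalues[name]),
        )
    return cls(
        coefficients=coefficients,
        random_intercept_var=float(np.asarray(result.cov_re)[0, 0]),
        residual_var=float(result.scale),
        n_obs=int(result.nobs),
        n_participants=int(data["participant_id"].nunique()),
        converged=bool(result.converged),
        **extra,
    )


# --------------------------------------------------------------------------
# Proximal models
# --------------------------------------------------------------------------


def _check_proximal_inputs(nights: pd.DataFrame) -> None:
    if nights["participant_id"].nunique() < 2:
        raise ValueError("proximal model requires at least 2 participants")
    if nights["feedback"].nunique() < 2:
        raise ValueError("feedback indicator is constant; effect not identifiable")


def fit_proximal(nights: pd.DataFrame) -> ProximalFit:
    """Fit the proximal mixed model on a night-level table.

    Expected columns: ``participant_id, day, feedback, sleep_min,
    sleep_prev_h, age, sex``.  ``day`` is 0-based so the feedback
    coefficient is the day-0 effect in minutes; the ``feedback:day``
    coefficient is its decay in minutes/day.
    """
    _check_proximal_inputs(nights)
    # constant controls (e.g. a single-sex subgroup) make the design singular
    terms = []
    for control in ("age", "sex", "sleep_prev_h"):
        if nights[control].nunique() > 1:
            terms.append(control)
        else:
            logger.info("proximal model: dropping constant control %r", control)
    formula = "sleep_min ~ " + " + ".join(terms + ["feedback", "day", "feedback:day"])
    result = _fit_mixedlm(formula, nights, nights["participant_id"])
    return _extract_fit(result, nights, cls=ProximalFit)


def fit_proximal_subgroup(nights: pd.DataFrame) -> dict[str, ProximalFit]:
    """Proximal fits per phenotype group (expects a ``group`` column)."""
    out = {}
    for group, rows in nights.groupby("group"):
        if rows["participant_id"].nunique() < 2:
            raise ValueError(f"group {group} has fewer than 2 participants")
        out[group] = fit_proximal(rows)
    return out


def fit_proximal_stratified(nights: pd.DataFrame) -> dict[str, ProximalFit]:
    """Proximal fits per feedback-content stratum ('longer' / 'shorter').

    For each stratum, feedback nights of the *other* stratum are excluded
    (rather than recoded 0) so the no-feedback reference level stays clean.
    Expects a ``message_direction`` column, non-empty on feedback nights.
    """
    out = {}
    directions = nights.loc[nights["feedback"] == 1, "message_direction"]
    for stratum in ("longer", "shorter"):
        if (directions == stratum).sum() == 0:
            raise ValueError(f"no feedback messages in the {stratum!r} stratum")
        keep = (nights["feedback"] == 0) | (nights["message_direction"] == stratum)
        out[stratum] = fit_proximal(nights.loc[keep])
    return out


# --------------------------------------------------------------------------
# Symptom models (observational study)
# --------------------------------------------------------------------------


def _features_frame(stats: Sequence[IntraindividualStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [s.participant_id for s in stats],
            "iim_sh": [s.iim_sh for s in stats],
            "iim_mid": [s.iim_mid_since_noon for s in stats],
            "iim_se": [s.iim_se for s in stats],
            "iiv_sh": [s.iiv_sh for s in stats],
            "iiv_mid": [s.iiv_mid for s in stats],
            "iiv_se": [s.iiv_se for s in stats],
        }
    )


def fit_symptom_models(
    scored_ema: pd.DataFrame,
    stats: Sequence[IntraindividualStats],
    demographics: pd.DataFrame,
    outcomes: Sequence[str] = SYMPTOM_OUTCOMES,
) -> dict[str, SymptomFit]:
    """Mixed models of momentary symptoms on intraindividual sleep features.

    ``scored_ema`` carries one row per EMA prompt with columns
    ``participant_id, prompt_type, depressive, anxious, sleep_quality``
    (sleep quality present on wake prompts only).  Fixed effects are the
    six IIM/IIV features plus age and sex; participants without a feature
    vector are dropped with a log message.
    """
    features = _features_frame(stats)
    merged = scored_ema.merge(features, on="participant_id", how="inner").merge(
        demographics, on="participant_id", how="left"
    )
    if merged["age"].isna().any() or merged["sex"].isna().any():
        raise ValueError("demographics missing for some participants in the EMA table")
    dropped = set(scored_ema["participant_id"]) - set(features["participant_id"])
    if dropped:
        logger.info("symptom models: %d participants without sleep statistics dropped", len(dropped))
    rhs = " + ".join(["iim_sh", "iim_mid", "iim_se", "iiv_sh", "iiv_mid", "iiv_se", "age", "sex"])
    fits: dict[str, SymptomFit] = {}
    for outcome in outcomes:
        rows = merged
        if outcome == "sleep_quality":
            rows = merged[merged["prompt_type"] == "wake"]
        rows = rows.dropna(subset=[outcome])
        if rows.empty:
            raise ValueError(f"no usable rows for outcome {outcome!r}")
        result = _fit_mixedlm(f"{outcome} ~ {rhs}", rows, rows["participant_id"])
        fits[outcome] = _extract_fit(result, rows, cls=SymptomFit, outcome=outcome)
    return fits


# --------------------------------------------------------------------------
# Distal mixed-effect ANOVA
# --------------------------------------------------------------------------


def _distal_long_table(
    stats_study1: Sequence[IntraindividualStats],
    stats_study2: Sequence[IntraindividualStats],
    group_of: dict[str, str],
    demographics: pd.DataFrame,
    feature: str,
) -> pd.DataFrame:
    by_study = {0: stats_study1, 1: stats_study2}
    ids = [
        {s.participant_id for s in stats} for stats in by_study.values()
    ]
    paired = ids[0] & ids[1] & set(group_of)
    unpaired = (ids[0] | ids[1]) - paired
    if unpaired:
        logger.info("distal ANOVA: %d unpaired participants dropped", len(unpaired))
    demo = demographics.set_index("participant_id")
    rows = []
    for study, stats in by_study.items():
        for s in stats:
            if s.participant_id not in paired:
                continue
            value = s.iim_mid_since_noon if feature == "iim_mid" else getattr(s, feature)
            if feature in IIV_COLUMNS:
                value = float(log_transform_iiv([value])[0])
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "study": study,
                    "group_b": int(group_of[s.participant_id] == "B"),
                    "value": value,
                    "age": demo.loc[s.participant_id, "age"],
                    "sex": demo.loc[s.participant_id, "sex"],
                }
            )
    return pd.DataFrame(rows)


def fit_distal_anova(
    stats_study1: Sequence[IntraindividualStats],
    stats_study2: Sequence[IntraindividualStats],
    group_of: dict[str, str],
    demographics: pd.DataFrame,
    features: Sequence[str] = FEATURE_COLUMNS,
) -> dict[str, DistalResult]:
    """2 (study) x 2 (group) mixed-effect ANOVA per sleep feature.

    Study is the repeated factor (participant random intercept), group is
    between-participant; age and sex are covariates and IIV features are
    log-transformed.  Wald F tests (1 numerator df; denominator df
    approximated as participants - 2) assess both main effects and their
    interaction; within-group study-2 vs study-1 contrasts are adjusted
    with the Tukey studentized-range correction over the four cells.
    """
    results: dict[str, DistalResult] = {}
    for feature in features:
        long = _distal_long_table(
            stats_study1, stats_study2, group_of, demographics, feature
        )
        if long.empty:
            raise ValueError("no paired participants across the two studies")
        if long["group_b"].nunique() < 2:
            raise ValueError("both groups must be present for the distal ANOVA")
        result = _fit_mixedlm(
            "value ~ study * group_b + age + sex", long, long["participant_id"]
        )
        n_participants = long["participant_id"].nunique()
        df_denom = max(n_participants - 2, 1)

        def wald_f(term: str) -> tuple[float, float]:
            t = float(result.fe_params[term] / result.bse[term])
            f = t * t
            return f, float(sps.f.sf(f, 1, df_denom))

        f_study, p_study = wald_f("study")
        f_group, p_group = wald_f("group_b")
        f_int, p_int = wald_f("study:group_b")

        cov = result.cov_params().loc[result.fe_params.index, result.fe_params.index]
        contrasts = {}
        for label, terms in {"A": ["study"], "B": ["study", "study:group_b"]}.items():
            vec = pd.Series(0.0, index=result.fe_params.index)
            for t in terms:
                vec[t] = 1.0
            est = float(vec @ result.fe_params)
            se = float(np.sqrt(vec @ cov @ vec))
            # Tukey adjustment over the 4 study-x-group cell means
            q = abs(est) / se * np.sqrt(2.0)
            p_adj = float(sps.studentized_range.sf(q, 4, df_denom))
            contrasts[label] = DistalContrast(group=label, estimate=est, se=se, p_tukey=p_adj)

        results[feature] = DistalResult(
            feature=feature,
            f_study=f_study,
            p_study=p_study,
            f_group=f_group,
            p_group=p_group,
            f_interaction=f_int,
            p_interaction=p_int,
            contrasts=contrasts,
        )
    return results
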