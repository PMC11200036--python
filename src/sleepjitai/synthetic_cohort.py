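"""Synthetic two-study trial generator with known ground truth.

Emulates the data structure the pipeline consumes end to end:

* an observational cohort ("study 1"): two latent sleep phenotypes -- a
  stable group A and an unstable group B that differs chiefly in the
  intraindividual variability (IIV) of sleep hours, midpoint and
  efficiency -- each participant contributing 14 nights of planted sleep
  intervals, minute-level zero-crossing counts emitted low-during-sleep /
  high-during-wake so Cole-Kripke scoring recovers the planted intervals,
  and EMA prompts whose mood levels depend linearly on the participant's
  true sleep-hour IIV;
* a microrandomized trial ("study 2"): nightly sleep responds to the
  previous noon's feedback decision with a linearly decaying effect
  (day-0 effect b0 min, slope b1 min/day), with group-specific
  responsiveness, and next-morning symptoms respond to realized sleep
  hours (the cascade path).

Every random quantity flows from a single seeded generator, so a dataset
is regenerable bit for bit from (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import mrt_engine
from .sleep_scoring import EPOCHS_PER_DAY, ActivityEpochSeries, SleepRecord

# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupParams:
    """Latent sleep-behaviour distribution of one phenotype group.

    Nightly sleep duration for participant i is N(iim_sh_i, iiv_sh_i) hours
    with iim_sh_i ~ N(iim_sh_mean, iim_sh_between_sd) and iiv_sh_i
    log-normal with the given median and sigma; midpoint of sleep behaves
    analogously on the hours-since-noon axis.  ``frag`` is the per-minute
    probability of wake inside the sleep interval and controls sleep
    efficiency (efficiency ~ 1 - frag); it jitters night to night by a
    log-normal factor so efficiency itself has intraindividual variability.
    """

    iim_sh_mean: float
    iim_sh_between_sd: float
    iiv_sh_median: float
    iiv_sh_sigma: float
    mid_mean_clock: float  # clock hours, e.g. 3.0 = 03:00
    mid_between_sd: float
    iiv_mid_median: float
    iiv_mid_sigma: float
    frag_median: float
    frag_sigma: float
    frag_night_sigma: float


#: Stable phenotype: ~7.3 h sleep, midpoint ~03:00, tight night-to-night spread.
GROUP_A_DEFAULT = GroupParams(
    iim_sh_mean=7.3,
    iim_sh_between_sd=0.6,
    iiv_sh_median=0.45,
    iiv_sh_sigma=0.45,
    mid_mean_clock=3.0,
    mid_between_sd=0.7,
    iiv_mid_median=0.45,
    iiv_mid_sigma=0.25,
    frag_median=0.02,
    frag_sigma=0.30,
    frag_night_sigma=0.30,
)

#: Unstable phenotype: shorter and later sleep, ~3x the IIV of group A.
GROUP_B_DEFAULT = GroupParams(
    iim_sh_mean=6.5,
    iim_sh_between_sd=0.7,
    iiv_sh_median=1.40,
    iiv_sh_sigma=0.45,
    mid_mean_clock=4.0,
    mid_between_sd=1.0,
    iiv_mid_median=1.50,
    iiv_mid_sigma=0.30,
    frag_median=0.07,
    frag_sigma=0.30,
    frag_night_sigma=0.35,
)


@dataclass(frozen=True)
class SymptomParams:
    """Participant-level linear dependence of a momentary symptom on true IIV(SH)."""

    baseline: float
    iiv_sh_slope: float  # units per hour of sleep-hour IIV
    intercept_sd: float  # participant random-intercept SD
    residual_sd: float  # prompt-to-prompt noise SD


#: Defaults mirror the reported associations: depressive mood +3.83, anxiety
#: +5.70, subjective sleep quality -3.37 units per hour of sleep-hour IIV.
SYMPTOMS_DEFAULT: dict[str, SymptomParams] = {
    "depressive": SymptomParams(baseline=15.0, iiv_sh_slope=3.83, intercept_sd=5.0, residual_sd=8.0),
    "anxious": SymptomParams(baseline=30.0, iiv_sh_slope=5.70, intercept_sd=6.0, residual_sd=10.0),
    "sleep_quality": SymptomParams(baseline=60.0, iiv_sh_slope=-3.37, intercept_sd=8.0, residual_sd=12.0),
}


@dataclass(frozen=True)
class CountEmission:
    """Zero-crossing count distributions: zero-inflated Poisson by state."""

    sleep_zero_prob: float = 0.75
    sleep_mean: float = 3.0
    wake_mean: float = 150.0


@dataclass(frozen=True)
class CohortConfig:
    """Study-1 cohort conditions (sizes per the observational study)."""

    n_participants: int = 140
    group_b_fraction: float = 67.0 / 140.0
    n_days: int = 14
    group_a: GroupParams = GROUP_A_DEFAULT
    group_b: GroupParams = GROUP_B_DEFAULT
    symptoms: dict[str, SymptomParams] = field(default_factory=lambda: dict(SYMPTOMS_DEFAULT))
    counts: CountEmission = CountEmission()
    age_mean: float = 39.15
    age_sd: float = 10.09
    female_fraction: float = 0.277
    missing_day_rate: float = 0.0
    positive_share: float = 0.65  # split of (positive+negative) when back-solving adjectives

    def __post_init__(self) -> None:
        if not (0.0 < self.group_b_fraction < 1.0):
            raise ValueError("group_b_fraction must lie in (0, 1)")
        if self.n_days < 4:
            raise ValueError("n_days must be >= 4 (exclusion rule needs 4 nights)")


@dataclass(frozen=True)
class TrialConfig:
    """Study-2 microrandomized-trial conditions.

    Feedback effects are (day-0 effect in minutes, decay in minutes/day)
    per group; the subgroup-analysis defaults plant responsiveness only in
    the unstable group, matching the trial's reported heterogeneity.
    ``iiv_scale_*`` rescales the within-person nightly SD relative to the
    participant's observational-study value (values < 1 emulate
    intervention-driven sleep stabilization, the distal outcome).
    """

    n_group_a: int = 23
    n_group_b: int = 44
    n_days: int = 14
    feedback_effect_a: tuple[float, float] = (0.0, 0.0)
    feedback_effect_b: tuple[float, float] = (59.0, -6.0)
    p_randomize: float = mrt_engine.RANDOMIZATION_PROBABILITY
    night_extra_sd_min: float = 10.0  # trial-specific nightly noise on top of IIV
    iiv_scale_a: float = 1.0
    iiv_scale_b: float = 1.0
    cascade_theta: dict[str, float] = field(
        default_factory=lambda: {"depressive": -0.05, "anxious": -0.04, "sleep_quality": 0.08}
    )
    cascade_intercepts: dict[str, float] = field(
        default_factory=lambda: {"depressive": 45.0, "anxious": 48.0, "sleep_quality": 38.0}
    )
    cascade_intercept_sd: float = 5.0
    cascade_residual_sd: float = 8.0
    group_a: GroupParams = GROUP_A_DEFAULT
    group_b: GroupParams = GROUP_B_DEFAULT
    age_mean: float = 39.15
    age_sd: float = 10.09
    female_fraction: float = 0.22


#: A whole-sample homogeneous-effect variant of the trial (every participant
#: responds with the pooled day-0 effect and decay) -- the conditions under
#: which the pooled proximal model's coefficients are planted directly.
def pooled_effect_trial_config(
    b0_min: float = 40.0, b1_min_per_day: float = -4.0, **overrides
) -> TrialConfig:
    return TrialConfig(
        feedback_effect_a=(b0_min, b1_min_per_day),
        feedback_effect_b=(b0_min, b1_min_per_day),
        **overrides,
    )


# --------------------------------------------------------------------------
# Ground truth containers
# --------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Planted quantities: group labels, per-participant parameters, nightly
    intervals, and the coefficients every downstream model should recover."""

    participants: pd.DataFrame  # per-participant latent parameters
    nights: pd.DataFrame  # planted nightly intervals / durations
    coefficients: dict

    def group_labels(self) -> pd.Series:
        return self.participants.set_index("participant_id")["group"]

    def to_json(self, path) -> None:
        payload = {
            "participants": self.participants.to_dict(orient="records"),
            "nights": self.nights.to_dict(orient="records"),
            "coefficients": self.coefficients,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


@dataclass
class Study1Data:
    epoch_series: dict[str, ActivityEpochSeries]
    ema: pd.DataFrame
    demographics: pd.DataFrame
    truth: GroundTruth


@dataclass
class Study2Data:
    nights: pd.DataFrame  # analysis-ready night-level table
    decisions: pd.DataFrame
    morning_symptoms: pd.DataFrame
    demographics: pd.DataFrame
    truth: GroundTruth
    epoch_series: dict[str, ActivityEpochSeries] = field(default_factory=dict)


# --------------------------------------------------------------------------
# Participant-level draws
# --------------------------------------------------------------------------

START_TIME = pd.Timestamp("2022-02-01 12:00:00")  # day-0 noon anchor


def _draw_participants(
    rng: np.random.Generator,
    n_a: int,
    n_b: int,
    params_a: GroupParams,
    params_b: GroupParams,
    age_mean: float,
    age_sd: float,
    female_fraction: float,
    prefix: str,
) -> pd.DataFrame:
    rows = []
    labels = ["A"] * n_a + ["B"] * n_b
    for i, group in enumerate(labels):
        p = params_a if group == "A" else params_b
        iim = rng.normal(p.iim_sh_mean, p.iim_sh_between_sd)
        iim = float(np.clip(iim, 4.5, 10.0))
        # nightly-sleep SDs above ~1.6 h are implausible and would pile nights
        # onto the duration floor, distorting planted linear effects
        iiv = float(min(p.iiv_sh_median * np.exp(rng.normal(0.0, p.iiv_sh_sigma)), 1.6))
        mid_sn = 12.0 + ((p.mid_mean_clock + rng.normal(0.0, p.mid_between_sd)) - 12.0) % 24.0
        iiv_mid = float(p.iiv_mid_median * np.exp(rng.normal(0.0, p.iiv_mid_sigma)))
        frag = float(np.clip(p.frag_median * np.exp(rng.normal(0.0, p.frag_sigma)), 0.005, 0.35))
        rows.append(
            {
                "participant_id": f"{prefix}{i:03d}",
                "group": group,
                "iim_sh": iim,
                "iiv_sh": iiv,
                "mid_since_noon": float(mid_sn),
                "iiv_mid": iiv_mid,
                "frag": frag,
                "frag_night_sigma": p.frag_night_sigma,
                "age": float(np.clip(rng.normal(age_mean, age_sd), 20.0, 65.0)),
                "sex": int(rng.random() < female_fraction),  # 0 = male (reference)
            }
        )
    return pd.DataFrame(rows)


def _plant_night(
    rng: np.random.Generator, row: pd.Series, duration_h: float
) -> tuple[int, int, float]:
    """Place one night's interval in its noon-to-noon window.

    Returns (onset_min, offset_min, frag_night) with minutes relative to the
    window's opening noon.
    """
    duration_h = float(np.clip(duration_h, 2.0, 11.5))
    half = duration_h / 2.0
    mid = rng.normal(row["mid_since_noon"], row["iiv_mid"])
    mid = float(np.clip(mid, 12.0 + half + 0.25, 36.0 - half - 0.25)) - 12.0  # h into window
    onset = int(round((mid - half) * 60.0))
    offset = int(round((mid + half) * 60.0))
    offset = min(offset, EPOCHS_PER_DAY - 1)
    frag_night = float(
        np.clip(row["frag"] * np.exp(rng.normal(0.0, row["frag_night_sigma"])), 0.0, 0.45)
    )
    return onset, offset, frag_night


def _emit_counts(
    rng: np.random.Generator,
    asleep: np.ndarray,
    counts_cfg: CountEmission,
) -> np.ndarray:
    """Zero-crossing counts given a per-minute asleep indicator."""
    n = len(asleep)
    counts = rng.poisson(counts_cfg.wake_mean, size=n)
    sleep_idx = np.flatnonzero(asleep)
    sleep_counts = rng.poisson(counts_cfg.sleep_mean, size=len(sleep_idx))
    zeros = rng.random(len(sleep_idx)) < counts_cfg.sleep_zero_prob
    sleep_counts[zeros] = 0
    counts[sleep_idx] = sleep_counts
    return counts


def _asleep_vector(
    rng: np.random.Generator,
    n_days: int,
    intervals: list[tuple[int, int, int, float]],
) -> np.ndarray:
    """Minute-level asleep indicator across the whole recording.

    ``intervals``: (day, onset_min, offset_min, frag_night) with minutes
    relative to each day's noon.
    """
    asleep = np.zeros(n_days * EPOCHS_PER_DAY, dtype=bool)
    for day, onset, offset, frag in intervals:
        base = day * EPOCHS_PER_DAY
        block = np.ones(offset - onset, dtype=bool)
        if frag > 0:
            block &= rng.random(offset - onset) >= frag
            block[0] = True  # interval edges stay asleep so onset/offset are planted
            block[-1] = True
        asleep[base + onset : base + offset] = block
    return asleep


# --------------------------------------------------------------------------
# Study 1
# --------------------------------------------------------------------------


def generate_study1_cohort(
    config: CohortConfig = CohortConfig(),
    seed: Optional[int] = None,
    *,
    emit_epochs: bool = True,
) -> Study1Data:
    """Generate a full observational cohort with known ground truth.

    Per participant x day: a planted sleep interval drawn from the group's
    latent distributions; minute-level counts (when ``emit_epochs``) whose
    Cole-Kripke scoring recovers the planted intervals; five EMA prompts
    per day (wake, three fixed clock times, bedtime) whose mood scores
    depend linearly on the participant's true sleep-hour IIV.
    """
    rng = np.random.default_rng(seed)
    n_b = int(round(config.n_participants * config.group_b_fraction))
    n_a = config.n_participants - n_b
    if min(n_a, n_b) < 2:
        raise ValueError("infeasible config: each group needs >= 2 participants")
    participants = _draw_participants(
        rng,
        n_a,
        n_b,
        config.group_a,
        config.group_b,
        config.age_mean,
        config.age_sd,
        config.female_fraction,
        prefix="s1-",
    )

    night_rows = []
    epoch_series: dict[str, ActivityEpochSeries] = {}
    ema_rows = []
    sym = config.symptoms
    intercepts = {
        name: rng.normal(0.0, p.intercept_sd, size=len(participants))
        for name, p in sym.items()
    }

    for idx, row in participants.iterrows():
        durations = rng.normal(row["iim_sh"], row["iiv_sh"], size=config.n_days)
        intervals = []
        for day in range(config.n_days):
            onset, offset, frag = _plant_night(rng, row, durations[day])
            intervals.append((day, onset, offset, frag))
            night_rows.append(
                {
                    "participant_id": row["participant_id"],
                    "day": day,
                    "onset_min": onset,
                    "offset_min": offset,
                    "duration_h": (offset - onset) / 60.0,
                    "frag_night": frag,
                }
            )
        realized = np.array([(o2 - o1) / 60.0 for _, o1, o2, _ in intervals])
        true_iiv = float(realized.std(ddof=1))
        participants.loc[idx, "true_iiv_sh_realized"] = true_iiv

        if emit_epochs:
            asleep = _asleep_vector(rng, config.n_days, intervals)
            counts = _emit_counts(rng, asleep, config.counts)
            worn = np.ones(len(counts), dtype=bool)
            if config.missing_day_rate > 0:
                for day in range(config.n_days):
                    if rng.random() < config.missing_day_rate:
                        worn[day * EPOCHS_PER_DAY : (day + 1) * EPOCHS_PER_DAY] = False
            epoch_series[row["participant_id"]] = ActivityEpochSeries(
                participant_id=row["participant_id"],
                start_time=START_TIME,
                counts=counts,
                worn=worn,
            )

        # EMA prompts: wake (offset+15'), fixed 15:00 / 19:00 / 11:00, bedtime (onset-15')
        for day, onset, offset, _ in intervals:
            base = day * EPOCHS_PER_DAY
            prompts = [
                ("wake", base + offset + 15),
                ("fixed", base + 180),  # 15:00
                ("fixed", base + 420),  # 19:00
                ("fixed", base + 1380),  # 11:00 next clock day, same analysis day
                ("bedtime", base + max(onset - 15, 0)),
            ]
            for prompt_type, minute in prompts:
                dep = float(
                    np.clip(
                        sym["depressive"].baseline
                        + sym["depressive"].iiv_sh_slope * true_iiv
                        + intercepts["depressive"][idx]
                        + rng.normal(0.0, sym["depressive"].residual_sd),
                        # representable range of the printed formula given the
                        # positive/negative split (both adjectives must stay in 0-100)
                        -26.0,
                        49.5,
                    )
                )
                anx = float(
                    np.clip(
                        sym["anxious"].baseline
                        + sym["anxious"].iiv_sh_slope * true_iiv
                        + intercepts["anxious"][idx]
                        + rng.normal(0.0, sym["anxious"].residual_sd),
                        0.0,
                        100.0,
                    )
                )
                pos_plus_neg = 100.0 - 2.0 * dep
                positive = pos_plus_neg * config.positive_share
                negative = pos_plus_neg * (1.0 - config.positive_share)
                record = {
                    "participant_id": row["participant_id"],
                    "timestamp": START_TIME + pd.Timedelta(minutes=int(minute)),
                    "prompt_type": prompt_type,
                    "day": day,
                    "vigorous": positive,
                    "happy": positive,
                    "cheerful": positive,
                    "gloomy": negative,
                    "unpleasant": negative,
                    "depressed": negative,
                    "concerned": anx,
                    "anxious": anx,
                    "worried": anx,
                    "sleep_quality": np.nan,
                }
                if prompt_type == "wake":
                    record["sleep_quality"] = float(
                        np.clip(
                            sym["sleep_quality"].baseline
                            + sym["sleep_quality"].iiv_sh_slope * true_iiv
                            + intercepts["sleep_quality"][idx]
                            + rng.normal(0.0, sym["sleep_quality"].residual_sd),
                            0.0,
                            100.0,
                        )
                    )
                ema_rows.append(record)

    truth = GroundTruth(
        participants=participants,
        nights=pd.DataFrame(night_rows),
        coefficients={
            "symptom_slopes": {name: p.iiv_sh_slope for name, p in sym.items()},
            "symptom_baselines": {name: p.baseline for name, p in sym.items()},
        },
    )
    demographics = participants[["participant_id", "age", "sex"]].copy()
    return Study1Data(
        epoch_series=epoch_series,
        ema=pd.DataFrame(ema_rows),
        demographics=demographics,
        truth=truth,
    )


def records_from_truth(truth: GroundTruth) -> dict[str, list[SleepRecord]]:
    """Materialize noiseless sleep records directly from planted intervals.

    Bypasses count emission and scoring; efficiency is 1 - frag_night.
    Useful for isolating downstream stages from scoring error.
    """
    out: dict[str, list[SleepRecord]] = {}
    for r in truth.nights.itertuples():
        onset = START_TIME + pd.Timedelta(minutes=int(r.day * EPOCHS_PER_DAY + r.onset_min))
        offset = START_TIME + pd.Timedelta(minutes=int(r.day * EPOCHS_PER_DAY + r.offset_min))
        mid = onset + (offset - onset) / 2
        rec = SleepRecord(
            participant_id=r.participant_id,
            analysis_day=(START_TIME + pd.Timedelta(days=int(r.day))).normalize(),
            onset=onset,
            offset=offset,
            sleep_hours=(r.offset_min - r.onset_min) / 60.0,
            midpoint=(mid.hour + mid.minute / 60.0 + mid.second / 3600.0) % 24.0,
            sleep_efficiency=max(1.0 - r.frag_night, 1e-6),
            r_squared=1.0,
        )
        out.setdefault(r.participant_id, []).append(rec)
    return out


# --------------------------------------------------------------------------
# Study 2
# --------------------------------------------------------------------------


def generate_study2_trial(
    config: TrialConfig = TrialConfig(),
    seed: Optional[int] = None,
    *,
    participants: Optional[pd.DataFrame] = None,
    emit_epochs: bool = False,
) -> Study2Data:
    """Generate a microrandomized feedback trial with known ground truth.

    Nightly sleep (minutes) for participant i on trial day d:

        sleep = 60 * iim_i + resp_g * (b0 + b1 * d) * feedback_d + eps,

    where feedback is assigned by the MRT engine with probability 0.5 and
    eps ~ N(0, (60 * iiv_i * iiv_scale_g)^2 + night_extra_sd^2).  Feedback
    responsiveness (resp, b0, b1) is per group.  Next-morning symptoms
    follow the cascade path: symptom_{d+1} = intercept_i + theta * sleep_d
    + noise, so feedback influences symptoms only through sleep.

    ``participants`` may carry forward a study-1 truth table (columns as
    produced by :func:`generate_study1_cohort`); otherwise fresh
    participants are drawn from the group distributions.
    """
    rng = np.random.default_rng(seed)
    if participants is None:
        participants = _draw_participants(
            rng,
            config.n_group_a,
            config.n_group_b,
            config.group_a,
            config.group_b,
            config.age_mean,
            config.age_sd,
            config.female_fraction,
            prefix="s2-",
        )
    participants = participants.reset_index(drop=True)

    effects = {"A": config.feedback_effect_a, "B": config.feedback_effect_b}
    iiv_scale = {"A": config.iiv_scale_a, "B": config.iiv_scale_b}

    night_rows = []
    decision_objs = []
    symptom_rows = []
    epoch_series: dict[str, ActivityEpochSeries] = {}
    theta = config.cascade_theta
    kappa = {
        name: rng.normal(0.0, config.cascade_intercept_sd, size=len(participants))
        for name in theta
    }

    for idx, row in participants.iterrows():
        pid = row["participant_id"]
        group = row["group"]
        b0, b1 = effects[group]
        sd_min = float(
            np.hypot(60.0 * row["iiv_sh"] * iiv_scale[group], config.night_extra_sd_min)
        )
        reference = float(row["iim_sh"])  # study-1 IIM(SH) as the set point
        prev_night_h = float(np.clip(rng.normal(row["iim_sh"], sd_min / 60.0), 3.0, 11.5))
        intervals = []
        feedbacks = np.zeros(config.n_days, dtype=int)
        for day in range(config.n_days):
            decision = mrt_engine.decide_day(
                rng,
                participant_id=pid,
                day_index=day,
                uploaded_epoch_count=EPOCHS_PER_DAY,
                last_night_hours=prev_night_h,
                reference_iim_sh=reference,
                p=config.p_randomize,
            )
            decision_objs.append(decision)
            fb = int(decision.randomized_on and decision.data_sufficient)
            feedbacks[day] = fb
            base_min = 60.0 * row["iim_sh"]
            sleep_min = base_min + fb * (b0 + b1 * day) + rng.normal(0.0, sd_min)
            sleep_min = float(np.clip(sleep_min, 120.0, 700.0))
            onset, offset, frag = _plant_night(rng, row, sleep_min / 60.0)
            intervals.append((day, onset, offset, frag))
            sleep_min = float(offset - onset)  # rounding to whole minutes
            night_rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "day": day,
                    "feedback": fb,
                    "message_direction": (
                        ("longer" if decision.relative_sufficiency_min >= 0 else "shorter")
                        if fb
                        else ""
                    ),
                    "sleep_min": sleep_min,
                    "sleep_prev_h": prev_night_h,
                    "age": row["age"],
                    "sex": row["sex"],
                    "onset_min": onset,
                    "offset_min": offset,
                    "frag_night": frag,
                }
            )
            for name, th in theta.items():
                symptom_rows.append(
                    {
                        "participant_id": pid,
                        "day": day,
                        "symptom": name,
                        "value": float(
                            config.cascade_intercepts[name]
                            + th * sleep_min
                            + kappa[name][idx]
                            + rng.normal(0.0, config.cascade_residual_sd)
                        ),
                    }
                )
            prev_night_h = sleep_min / 60.0

        if emit_epochs:
            asleep = _asleep_vector(rng, config.n_days, intervals)
            counts = _emit_counts(rng, asleep, CountEmission())
            epoch_series[pid] = ActivityEpochSeries(
                participant_id=pid,
                start_time=START_TIME,
                counts=counts,
                worn=np.ones(len(counts), dtype=bool),
            )
    nights = pd.DataFrame(night_rows)
    truth_nights = nights[
        ["participant_id", "day", "feedback", "sleep_min", "onset_min", "offset_min", "frag_night"]
    ].copy()
    nights = nights.drop(columns=["onset_min", "offset_min", "frag_night"])
    truth = GroundTruth(
        participants=participants,
        nights=truth_nights,
        coefficients={
            "feedback_effect_a": list(config.feedback_effect_a),
            "feedback_effect_b": list(config.feedback_effect_b),
            "cascade_theta": dict(theta),
            "p_randomize": config.p_randomize,
        },
    )
    symptoms = (
        pd.DataFrame(symptom_rows)
        .pivot(index=["participant_id", "day"], columns="symptom", values="value")
        .reset_index()
    )
    return Study2Data(
        nights=nights,
        decisions=mrt_engine.decisions_to_frame(decision_objs),
        morning_symptoms=symptoms,
        demographics=participants[["participant_id", "age", "sex"]].copy(),
        truth=truth,
        epoch_series=epoch_series,
    )
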