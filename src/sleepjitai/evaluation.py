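"""Replicated parameter-recovery studies over the synthetic trial generator.

The study's raw data are not deposited, so the pipeline is validated by
simulation: cohorts are generated with the reported estimates planted as
ground truth, the full estimation machinery is run, and the recovered
coefficients are compared with what was planted.  These routines back both
the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import bayesian_cascade as bc
from . import effect_models as em
from . import ema_scoring as es
from . import habitual_stats as hs
from . import mrt_engine as me
from . import phenotyping as ph
from . import sleep_scoring as ss
from . import synthetic_cohort as sc


def _child_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def proximal_recovery(
    n_replicates: int = 50,
    seed: int = 0,
    b0_min: float = 40.0,
    b1_min_per_day: float = -4.0,
) -> dict:
    """Pooled proximal-model recovery: plant a homogeneous (b0, b1) feedback
    effect in n=67 trial cohorts and refit the mixed model."""
    feedback, interaction = [], []
    for child in _child_seeds(seed, n_replicates):
        cfg = sc.pooled_effect_trial_config(b0_min, b1_min_per_day)
        fit = em.fit_proximal(sc.generate_study2_trial(cfg, seed=child).nights)
        feedback.append(fit.coefficients["feedback"].estimate)
        interaction.append(fit.coefficients["feedback:day"].estimate)
    return {
        "mean_feedback_min": float(np.mean(feedback)),
        "mean_interaction_min_per_day": float(np.mean(interaction)),
        "feedback": feedback,
        "interaction": interaction,
        "n_replicates": n_replicates,
    }


def subgroup_recovery(n_replicates: int = 50, seed: int = 0) -> dict:
    """Subgroup heterogeneity: group B responds (59, -6), group A not at all."""
    b_feedback, a_covers_zero = [], []
    for child in _child_seeds(seed, n_replicates):
        data = sc.generate_study2_trial(sc.TrialConfig(), seed=child)
        fits = em.fit_proximal_subgroup(data.nights)
        b_feedback.append(fits["B"].coefficients["feedback"].estimate)
        ca = fits["A"].coefficients["feedback"]
        a_covers_zero.append(ca.ci_low <= 0.0 <= ca.ci_high)
    return {
        "mean_b_feedback_min": float(np.mean(b_feedback)),
        "a_ci_covers_zero_fraction": float(np.mean(a_covers_zero)),
        "b_feedback": b_feedback,
        "n_replicates": n_replicates,
    }


def randomization_rate(n_days: int = 10_000, seed: int = 0) -> dict:
    """Empirical microrandomization rate over many participant-days."""
    rng = np.random.default_rng(seed)
    on = sum(me.randomize_day(rng) for _ in range(n_days))
    return {"rate": on / n_days, "n_days": n_days}


def symptom_recovery(n_replicates: int = 50, seed: int = 0) -> dict:
    """Full-pipeline recovery of the symptom ~ IIV(SH) slopes at n=140.

    Each replicate runs count emission -> sleep scoring -> intraindividual
    statistics -> symptom mixed models, so the recovered slopes carry every
    upstream error source.
    """
    slopes: dict[str, list[float]] = {k: [] for k in em.SYMPTOM_OUTCOMES}
    for child in _child_seeds(seed, n_replicates):
        data = sc.generate_study1_cohort(sc.CohortConfig(), seed=child)
        records = {
            pid: ss.score_participant_nights(s) for pid, s in data.epoch_series.items()
        }
        stats = hs.cohort_stats(records)
        fits = em.fit_symptom_models(
            es.score_frame(data.ema), stats, data.demographics
        )
        for outcome, fit in fits.items():
            slopes[outcome].append(fit.iiv_sh_slope.estimate)
    truth = sc.SYMPTOMS_DEFAULT
    return {
        outcome: {
            "mean_slope": float(np.mean(v)),
            "sign_agreement": float(
                np.mean(np.sign(v) == np.sign(truth[outcome].iiv_sh_slope))
            ),
            "slopes": v,
            "true_slope": truth[outcome].iiv_sh_slope,
        }
        for outcome, v in slopes.items()
    }


def cascade_calibration(
    n_replicates: int = 20,
    seed: int = 0,
    config: Optional[bc.CascadeModelConfig] = None,
) -> dict:
    """Scaled-down sampler calibration: Rhat convergence and CI coverage of
    the planted sleep-path and symptom-path parameters."""
    config = config or bc.CascadeModelConfig(
        iterations=1000, burn_in=500, symptoms=("depressive",)
    )
    truth = {"feedback": 40.0, "feedback_day": -4.0, "depressive.sleep": -0.05}
    rhat_ok, covered = [], {k: [] for k in truth}
    for child in _child_seeds(seed, n_replicates):
        cfg = sc.pooled_effect_trial_config(40.0, -4.0)
        data = sc.generate_study2_trial(cfg, seed=child)
        merged = data.nights.merge(data.morning_symptoms, on=["participant_id", "day"])
        fit = bc.fit_cascade(merged, config, seed=int(child.generate_state(1)[0] % 2**31))
        rhat_ok.append(max(fit.rhat.values()) < config.rhat_threshold)
        for name, value in truth.items():
            covered[name].append(fit.ci_low[name] <= value <= fit.ci_high[name])
    return {
        "rhat_ok_fraction": float(np.mean(rhat_ok)),
        "coverage": {k: float(np.mean(v)) for k, v in covered.items()},
        "n_replicates": n_replicates,
    }


def phenotyping_end_to_end(seed: int = 0) -> dict:
    """Full-pipeline phenotype recovery: ARI vs planted groups and Hedges g."""
    data = sc.generate_study1_cohort(sc.CohortConfig(), seed=seed)
    records = {pid: ss.score_participant_nights(s) for pid, s in data.epoch_series.items()}
    stats = hs.cohort_stats(records)
    assignments = ph.ward_dichotomize(hs.feature_matrix(stats))
    truth = data.truth.group_labels()
    pred = {a.participant_id: a.group_label for a in assignments}
    agree = [truth[p] == g for p, g in pred.items()]
    # adjusted Rand index for a 2x2 contingency, computed directly
    n = len(agree)
    tp = sum((truth[p] == "B") and (g == "B") for p, g in pred.items())
    fp = sum((truth[p] == "A") and (g == "B") for p, g in pred.items())
    fn = sum((truth[p] == "B") and (g == "A") for p, g in pred.items())
    tn = n - tp - fp - fn

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(tp) + comb2(fp) + comb2(fn) + comb2(tn)
    sum_a = comb2(tp + fp) + comb2(fn + tn)
    sum_b = comb2(tp + fn) + comb2(fp + tn)
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2.0
    ari = (sum_ij - expected) / (max_index - expected)
    comparisons = ph.compare_groups(stats, assignments)
    g_iiv = {c.feature: c.hedges_g for c in comparisons if c.feature in hs.IIV_COLUMNS}
    return {"ari": float(ari), "hedges_g_iiv": g_iiv}
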