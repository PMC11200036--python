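"""Hierarchical Bayesian model of the day-varying feedback effect and its
cascade onto next-morning symptoms.

The model is a reconstruction of the two-level structure the analysis
requires (the original equations are not published in the main text):

* sleep path (level 1a):
  ``sleep_it = alpha_i + (b0 + b1 * day) * feedback_it + g*age_i + d*sex_i + eps``,
  with participant intercepts ``alpha_i ~ N(mu, tau^2)``;
* symptom path (level 1b), one per morning symptom:
  ``symptom_{i,t+1} = kappa_i + theta * sleep_it + g'*age_i + d'*sex_i + eps'``.

Feedback is assumed to influence next-morning symptoms only through
changed sleep (a pure mediation structure): the cascading effect on day
*d* is the product ``(b0 + b1*d) * theta``, computed draw-wise.

Because every conditional is Gaussian or inverse-gamma, the posterior is
sampled by a blocked Gibbs sampler with conjugate updates: weakly
informative N(0, 1000^2) priors on all slopes and intercept means,
inverse-gamma(0.001, 0.001) on the residual and random-intercept
variances.  Convergence is declared when the Gelman-Rubin statistic
(Rhat, split across chains) is below 1.10 for every tracked parameter;
estimates are refused (flagged, and the counterfactual step raises) when
it is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

SLOPE_PRIOR_VAR = 1000.0**2
VAR_PRIOR_SHAPE = 0.001
VAR_PRIOR_RATE = 0.001


@dataclass(frozen=True)
class CascadeModelConfig:
    """Sampler settings; the full analysis settings are the defaults."""

    chains: int = 4
    iterations: int = 8000
    burn_in: int = 4000
    rhat_threshold: float = 1.10
    symptoms: tuple[str, ...] = ("depressive", "anxious", "sleep_quality")

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for Rhat")


#: Scaled-down settings used by the test suite (documented in the methods note).
TEST_SAMPLER_SETTINGS = dict(iterations=1000, burn_in=500)


@dataclass
class CascadeFit:
    """Posterior draws and summaries of the sleep and symptom paths.

    ``draws`` maps parameter names to arrays of shape (chains, kept_draws).
    Sleep-path parameters: ``feedback`` (day-0 effect, minutes),
    ``feedback_day`` (decay, minutes/day), ``intercept``, ``age``, ``sex``,
    ``resid_var``, ``intercept_var``.  Symptom paths are prefixed, e.g.
    ``depressive.sleep`` is theta for depressive mood (units per minute of
    sleep).
    """

    config: CascadeModelConfig
    draws: dict[str, np.ndarray]
    eap: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    rhat: dict[str, float]
    converged: bool

    def flat(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(self.draws),
                "eap": [self.eap[k] for k in self.draws],
                "ci_low": [self.ci_low[k] for k in self.draws],
                "ci_high": [self.ci_high[k] for k in self.draws],
                "rhat": [self.rhat[k] for k in self.draws],
            }
        )

    def to_dict(self) -> dict:
        return {
            "eap": self.eap,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "rhat": self.rhat,
            "converged": self.converged,
        }


# --------------------------------------------------------------------------
# Conjugate Gibbs sampler for a random-intercept Gaussian linear model
# --------------------------------------------------------------------------


def _gibbs_random_intercept(
    rng: np.random.Generator,
    X: np.ndarray,
    y: np.ndarray,
    participant_idx: np.ndarray,
    n_participants: int,
    iterations: int,
    burn_in: int,
) -> dict[str, np.ndarray]:
    """One chain of the blocked Gibbs sampler.

    Model: y = X beta + a[participant] + eps, a_i ~ N(0, tau2),
    eps ~ N(0, sigma2); the intercept column of X carries the random-effect
    mean.  Returns post-burn-in draws for each column of X plus the two
    variances.
    """
    n, p = X.shape
    XtX = X.T @ X
    counts = np.bincount(participant_idx, minlength=n_participants).astype(float)

    beta = np.zeros(p)
    a = np.zeros(n_participants)
    sigma2 = float(np.var(y)) or 1.0
    tau2 = sigma2 / 2.0 or 1.0

    kept = iterations - burn_in
    out = np.empty((kept, p + 2))

    prior_prec = np.eye(p) / SLOPE_PRIOR_VAR
    for it in range(iterations):
        # beta | a, sigma2
        resid = y - a[participant_idx]
        prec = XtX / sigma2 + prior_prec
        mean_rhs = X.T @ resid / sigma2
        chol = np.linalg.cholesky(prec)
        mu = np.linalg.solve(prec, mean_rhs)
        z = rng.standard_normal(p)
        beta = mu + np.linalg.solve(chol.T, z)

        # a_i | beta, sigma2, tau2
        resid = y - X @ beta
        sums = np.bincount(participant_idx, weights=resid, minlength=n_participants)
        post_prec = counts / sigma2 + 1.0 / tau2
        post_mean = (sums / sigma2) / post_prec
        a = post_mean + rng.standard_normal(n_participants) / np.sqrt(post_prec)

        # tau2 | a
        tau2 = 1.0 / rng.gamma(
            VAR_PRIOR_SHAPE + n_participants / 2.0,
            1.0 / (VAR_PRIOR_RATE + 0.5 * float(a @ a)),
        )

        # sigma2 | beta, a
        err = resid - a[participant_idx]
        sigma2 = 1.0 / rng.gamma(
            VAR_PRIOR_SHAPE + n / 2.0, 1.0 / (VAR_PRIOR_RATE + 0.5 * float(err @ err))
        )

        if it >= burn_in:
            out[it - burn_in, :p] = beta
            out[it - burn_in, p] = sigma2
            out[it - burn_in, p + 1] = tau2
    return out


def _run_chains(
    rng: np.random.Generator,
    X: np.ndarray,
    y: np.ndarray,
    participant_idx: np.ndarray,
    n_participants: int,
    config: CascadeModelConfig,
    names: Sequence[str],
) -> dict[str, np.ndarray]:
    kept = config.iterations - config.burn_in
    all_draws = np.empty((config.chains, kept, len(names)))
    for c in range(config.chains):
        all_draws[c] = _gibbs_random_intercept(
            rng, X, y, participant_idx, n_participants, config.iterations, config.burn_in
        )
    return {name: all_draws[:, :, j] for j, name in enumerate(names)}


def _rhat(draws: dict[str, np.ndarray]) -> dict[str, float]:
    import arviz as az

    ds = az.convert_to_dataset({k: v for k, v in draws.items()})
    r = az.rhat(ds)
    return {k: float(r[k].values) for k in draws}


# --------------------------------------------------------------------------
# Public fitting interface
# --------------------------------------------------------------------------


def fit_cascade(
    data: pd.DataFrame,
    config: CascadeModelConfig = CascadeModelConfig(),
    seed: Optional[int] = None,
) -> CascadeFit:
    """Fit the sleep path and all symptom paths by MCMC.

    ``data`` is night-level with columns ``participant_id, day, feedback,
    sleep_min, age, sex`` plus one column per symptom in
    ``config.symptoms`` holding the next morning's score (NaN rows are
    dropped per path).  Estimates are still returned when Rhat exceeds the
    threshold, but ``converged`` is False and the counterfactual step
    refuses to run.
    """
    required = {"participant_id", "day", "feedback", "sleep_min", "age", "sex"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"cascade data missing columns: {sorted(missing)}")
    # symptom columns may carry NaN (missed prompts); everything else must be finite
    core = data[["day", "feedback", "sleep_min", "age", "sex"]].to_numpy(dtype=float)
    if not np.isfinite(core).all():
        raise ValueError("non-finite values in cascade model inputs")

    rng = np.random.default_rng(seed)
    pid_codes, _ = pd.factorize(data["participant_id"])
    n_participants = int(pid_codes.max()) + 1

    day = data["day"].to_numpy(float)
    fb = data["feedback"].to_numpy(float)
    X_sleep = np.column_stack(
        [np.ones(len(data)), fb, fb * day, data["age"].to_numpy(float), data["sex"].to_numpy(float)]
    )
    y_sleep = data["sleep_min"].to_numpy(float)
    draws = _run_chains(
        rng,
        X_sleep,
        y_sleep,
        pid_codes,
        n_participants,
        config,
        names=["intercept", "feedback", "feedback_day", "age", "sex", "resid_var", "intercept_var"],
    )

    for symptom in config.symptoms:
        if symptom not in data.columns:
            raise ValueError(f"symptom column {symptom!r} missing from cascade data")
        rows = data.dropna(subset=[symptom])
        codes, _ = pd.factorize(rows["participant_id"])
        X_sym = np.column_stack(
            [
                np.ones(len(rows)),
                rows["sleep_min"].to_numpy(float),
                rows["age"].to_numpy(float),
                rows["sex"].to_numpy(float),
            ]
        )
        sym_draws = _run_chains(
            rng,
            X_sym,
            rows[symptom].to_numpy(float),
            codes,
            int(codes.max()) + 1,
            config,
            names=[
                f"{symptom}.intercept",
                f"{symptom}.sleep",
                f"{symptom}.age",
                f"{symptom}.sex",
                f"{symptom}.resid_var",
                f"{symptom}.intercept_var",
            ],
        )
        draws.update(sym_draws)

    rhat = _rhat(draws)
    eap = {k: float(v.mean()) for k, v in draws.items()}
    ci_low = {k: float(np.quantile(v, 0.025)) for k, v in draws.items()}
    ci_high = {k: float(np.quantile(v, 0.975)) for k, v in draws.items()}
    converged = max(rhat.values()) < config.rhat_threshold
    return CascadeFit(
        config=config,
        draws=draws,
        eap=eap,
        ci_low=ci_low,
        ci_high=ci_high,
        rhat=rhat,
        converged=converged,
    )


def counterfactual_effect_by_day(
    fit: CascadeFit, days: Sequence[int] = range(14)
) -> pd.DataFrame:
    """Posterior per-day feedback effects on sleep and each morning symptom.

    For day *d*, the sleep effect is the posterior of ``b0 + b1*d``
    (minutes of additional sleep with vs without feedback) and each
    symptom effect is the draw-wise product with that symptom's
    sleep coefficient.  A day is "effective" when the 95% credible
    interval excludes 0.  Refuses to run on a non-converged fit.
    """
    if not fit.converged:
        raise ValueError("cascade fit did not converge (max Rhat >= threshold)")
    b0 = fit.flat("feedback")
    b1 = fit.flat("feedback_day")
    rows = []
    for d in days:
        sleep_effect = b0 + b1 * float(d)
        targets = {"sleep": sleep_effect}
        for symptom in fit.config.symptoms:
            targets[symptom] = sleep_effect * fit.flat(f"{symptom}.sleep")
        for target, eff in targets.items():
            lo, hi = np.quantile(eff, [0.025, 0.975])
            rows.append(
                {
                    "day": int(d),
                    "target": target,
                    "eap": float(eff.mean()),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "effective": bool(lo > 0.0 or hi < 0.0),
                }
            )
    return pd.DataFrame(rows)
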