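"""Microrandomized sleep-feedback engine.

Each participant-day of the 14-day trial is an independent decision point:

1. Randomize: feedback is switched on with probability 0.5 (Bernoulli draw
   from a seeded stream, so a trial is reproducible bit for bit).
2. Data-sufficiency gate: the preceding noon-to-noon day must have uploaded
   at least 720 one-minute activity records; otherwise a BLE-check notice
   is sent and the computation is retried once at 2 PM with whatever has
   arrived by then.
3. Relative sleep sufficiency: last night's estimated sleep hours minus the
   participant's reference mean sleep hours (IIM of sleep hours from the
   observational study), in signed minutes.
4. Message rendering: the feedback template filled with the absolute
   difference and "longer"/"shorter" by sign (a zero difference takes the
   "longer" wording).

A sleep feedback message is delivered iff the day is randomized on *and*
the data are sufficient (possibly after the retry).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

RANDOMIZATION_PROBABILITY = 0.5
SUFFICIENCY_THRESHOLD = 720  # 1-minute records per preceding day
TRIAL_DAYS = 14

FEEDBACK_TEMPLATE = (
    "You slept {minutes} minutes {direction} than your average yesterday. "
    "Stabilize your sleep habits with reference to sleep hygiene guidelines."
)
BLE_CHECK_MESSAGE = (
    "It seems that your data have not been uploaded successfully. "
    "We will analyze the data again at 2 PM. "
    "Please check the BLE connection of your HIT app before then."
)


@dataclass
class FeedbackDecision:
    """One participant-day record of the microrandomization pipeline."""

    participant_id: str
    day_index: int  # 0-based from the first trial day
    randomized_on: bool
    data_sufficient: bool
    relative_sufficiency_min: Optional[int]  # defined only when data sufficient
    message: Optional[str]  # non-empty iff randomized_on and data_sufficient
    retry_used: bool = False
    ble_notified: bool = False

    def __post_init__(self) -> None:
        if self.day_index < 0:
            raise ValueError("day_index must be >= 0")
        has_message = bool(self.message)
        if has_message != (self.randomized_on and self.data_sufficient):
            raise ValueError(
                "message must be present exactly when the day is randomized on "
                "and data are sufficient"
            )
        if not self.data_sufficient and self.relative_sufficiency_min is not None:
            raise ValueError("relative sufficiency is undefined without sufficient data")


def randomize_day(rng: np.random.Generator, *, p: float = RANDOMIZATION_PROBABILITY) -> bool:
    """Independent Bernoulli(p) draw for one participant-day."""
    return bool(rng.random() < p)


def check_data_sufficiency(
    uploaded_epoch_count: int, *, threshold: int = SUFFICIENCY_THRESHOLD
) -> bool:
    """Sufficient iff at least ``threshold`` 1-minute records were uploaded."""
    if uploaded_epoch_count < 0:
        raise ValueError("record count must be non-negative")
    return uploaded_epoch_count >= threshold


def compute_relative_sufficiency(last_night_hours: float, reference_iim_sh: float) -> int:
    """Signed minutes of last night's sleep relative to the participant's reference.

    Positive values mean the participant slept longer than their
    observational-study average.  Raises when the reference is missing or
    either quantity is non-positive.
    """
    if reference_iim_sh is None or not np.isfinite(reference_iim_sh):
        raise ValueError("participant lacks a reference mean sleep duration")
    if last_night_hours <= 0 or reference_iim_sh <= 0:
        raise ValueError("sleep durations must be positive")
    return int(round((last_night_hours - reference_iim_sh) * 60.0))


def render_feedback_message(relative_min: int) -> str:
    """Fill the feedback template; zero difference takes the 'longer' wording."""
    direction = "longer" if relative_min >= 0 else "shorter"
    return FEEDBACK_TEMPLATE.format(minutes=abs(int(relative_min)), direction=direction)


def decide_day(
    rng: np.random.Generator,
    *,
    participant_id: str,
    day_index: int,
    uploaded_epoch_count: int,
    last_night_hours: Optional[float],
    reference_iim_sh: float,
    retry_epoch_count: Optional[int] = None,
    p: float = RANDOMIZATION_PROBABILITY,
    threshold: int = SUFFICIENCY_THRESHOLD,
) -> FeedbackDecision:
    """Run one participant-day through the full decision pipeline.

    Randomization is drawn first (one draw per day, so the assignment
    stream does not depend on data availability), then the sufficiency gate
    is applied.  When noon data are insufficient the BLE notice is recorded
    and ``retry_epoch_count`` (the 2 PM state) is checked once.
    """
    on = randomize_day(rng, p=p)
    sufficient = check_data_sufficiency(uploaded_epoch_count, threshold=threshold)
    retry_used = False
    ble_notified = False
    if not sufficient:
        ble_notified = True
        if retry_epoch_count is not None:
            retry_used = True
            sufficient = check_data_sufficiency(retry_epoch_count, threshold=threshold)
    sufficient = sufficient and last_night_hours is not None
    relative = None
    message = None
    if sufficient:
        relative = compute_relative_sufficiency(last_night_hours, reference_iim_sh)
        if on:
            message = render_feedback_message(relative)
    return FeedbackDecision(
        participant_id=participant_id,
        day_index=day_index,
        randomized_on=on,
        data_sufficient=sufficient,
        relative_sufficiency_min=relative,
        message=message,
        retry_used=retry_used,
        ble_notified=ble_notified,
    )


def decisions_to_frame(decisions: Sequence[FeedbackDecision]) -> pd.DataFrame:
    """Decision log in the documented CSV schema."""
    return pd.DataFrame(
        {
            "participant_id": [d.participant_id for d in decisions],
            "day_index": [d.day_index for d in decisions],
            "randomized_on": [int(d.randomized_on) for d in decisions],
            "data_sufficient": [int(d.data_sufficient) for d in decisions],
            "relative_sufficiency_min": [
                d.relative_sufficiency_min for d in decisions
            ],
            "message": [d.message if d.message else "" for d in decisions],
            "retry_used": [int(d.retry_used) for d in decisions],
            "ble_notified": [int(d.ble_notified) for d in decisions],
        }
    )
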