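"""Scoring of ecological momentary assessment (EMA) mood prompts.

Each prompt rates nine mood adjectives on a 0-100 visual analogue scale.
Composite scores:

* anxious    = mean(concerned, anxious, worried)
* positive   = mean(vigorous, happy, cheerful)
* negative   = mean(gloomy, unpleasant, depressed)
* depressive = (100 - (positive + negative)) / 2

The depressive formula is implemented exactly as printed by default.  Its
sign on negative mood is counterintuitive (higher negative mood lowers the
score); a ``sign_corrected`` variant, (100 - positive + negative) / 2, is
available behind a switch but is never the default.

Morning (wake) prompts additionally carry a subjective sleep quality rating
on the same 0-100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

PROMPT_TYPES = ("wake", "fixed", "bedtime")
ANXIOUS_ITEMS = ("concerned", "anxious", "worried")
POSITIVE_ITEMS = ("vigorous", "happy", "cheerful")
NEGATIVE_ITEMS = ("gloomy", "unpleasant", "depressed")
ADJECTIVES = (
    "vigorous",
    "gloomy",
    "concerned",
    "happy",
    "unpleasant",
    "anxious",
    "cheerful",
    "depressed",
    "worried",
)

DEPRESSIVE_FORMULA_PRINTED = "printed"
DEPRESSIVE_FORMULA_SIGN_CORRECTED = "sign_corrected"


class IncompleteRecord(ValueError):
    """Raised when a prompt is missing adjective ratings (record is skipped)."""


@dataclass
class EMARecord:
    """One EMA prompt: nine adjective ratings plus optional sleep quality."""

    participant_id: str
    timestamp: object
    prompt_type: str
    vigorous: Optional[float] = None
    gloomy: Optional[float] = None
    concerned: Optional[float] = None
    happy: Optional[float] = None
    unpleasant: Optional[float] = None
    anxious: Optional[float] = None
    cheerful: Optional[float] = None
    depressed: Optional[float] = None
    worried: Optional[float] = None
    subjective_sleep_quality: Optional[float] = None

    def __post_init__(self) -> None:
        if self.prompt_type not in PROMPT_TYPES:
            raise ValueError(f"prompt_type must be one of {PROMPT_TYPES}")
        for item in ADJECTIVES:
            v = getattr(self, item)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{item} score {v} outside the 0-100 VAS range")
        if self.subjective_sleep_quality is not None:
            if self.prompt_type != "wake":
                raise ValueError("subjective sleep quality belongs to wake prompts only")
            if not (0.0 <= self.subjective_sleep_quality <= 100.0):
                raise ValueError("subjective sleep quality outside the 0-100 VAS range")


@dataclass
class MoodScores:
    anxious: float
    positive: float
    negative: float
    depressive: float


def score_dams(
    record: EMARecord,
    *,
    depressive_formula: str = DEPRESSIVE_FORMULA_PRINTED,
) -> MoodScores:
    """Derive the four mood scores from one EMA record.

    Stateless: the output depends only on the single record.  Raises
    :class:`IncompleteRecord` when any of the nine adjectives is missing,
    so callers can skip and log partial responses.
    """
    missing = [item for item in ADJECTIVES if getattr(record, item) is None]
    if missing:
        raise IncompleteRecord(
            f"participant {record.participant_id} at {record.timestamp}: "
            f"missing {', '.join(missing)}"
        )
    anxious = sum(getattr(record, i) for i in ANXIOUS_ITEMS) / 3.0
    positive = sum(getattr(record, i) for i in POSITIVE_ITEMS) / 3.0
    negative = sum(getattr(record, i) for i in NEGATIVE_ITEMS) / 3.0
    if depressive_formula == DEPRESSIVE_FORMULA_PRINTED:
        depressive = (100.0 - (positive + negative)) / 2.0
    elif depressive_formula == DEPRESSIVE_FORMULA_SIGN_CORRECTED:
        depressive = (100.0 - positive + negative) / 2.0
    else:
        raise ValueError(f"unknown depressive_formula: {depressive_formula!r}")
    return MoodScores(
        anxious=anxious, positive=positive, negative=negative, depressive=depressive
    )


def score_frame(
    ema: pd.DataFrame,
    *,
    depressive_formula: str = DEPRESSIVE_FORMULA_PRINTED,
) -> pd.DataFrame:
    """Score a table of EMA prompts, dropping incomplete records.

    Input columns: ``participant_id, timestamp, prompt_type``, the nine
    adjectives, and optionally ``sleep_quality``.  Returns the table with
    ``anxious, positive, negative, depressive`` columns appended (the raw
    ``anxious`` adjective column is preserved as ``anxious_item``); rows
    with any missing adjective are dropped, mirroring the record-level
    skip-and-log contract.
    """
    complete = ema.dropna(subset=list(ADJECTIVES))
    out = complete.rename(columns={"anxious": "anxious_item"}).copy()
    anx = complete[list(ANXIOUS_ITEMS)].mean(axis=1)
    pos = complete[list(POSITIVE_ITEMS)].mean(axis=1)
    neg = complete[list(NEGATIVE_ITEMS)].mean(axis=1)
    if depressive_formula == DEPRESSIVE_FORMULA_PRINTED:
        dep = (100.0 - (pos + neg)) / 2.0
    elif depressive_formula == DEPRESSIVE_FORMULA_SIGN_CORRECTED:
        dep = (100.0 - pos + neg) / 2.0
    else:
        raise ValueError(f"unknown depressive_formula: {depressive_formula!r}")
    out["anxious"] = anx
    out["positive"] = pos
    out["negative"] = neg
    out["depressive"] = dep
    return out
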