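"""Intraindividual sleep statistics: means and variabilities per participant.

For each participant with at least four scored nights, the module computes
the intraindividual mean (IIM) and intraindividual variability (IIV, sample
SD) of sleep hours, midpoint of sleep, and sleep efficiency.  Midpoint of
sleep is a clock time and is treated circularly (24 h = full circle): the
IIM is the direction of the mean resultant vector and the IIV is the
circular SD ``sqrt(-2 ln R)`` converted to hours.

Downstream transforms provided here: cohort-level standardization of the
six-feature vector (for clustering) and natural-log transformation of the
IIV features (for t tests and ANOVA, to satisfy normality).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sleep_scoring import SleepRecord

logger = logging.getLogger(__name__)

MIN_NIGHTS = 4  # participants with fewer scored nights are excluded
LOG_IIV_FLOOR = 1e-6  # hours; zero IIVs are floored here before log transform

#: Fixed column order of the six-feature vector.
FEATURE_COLUMNS = ("iim_sh", "iim_mid", "iim_se", "iiv_sh", "iiv_mid", "iiv_se")
IIV_COLUMNS = ("iiv_sh", "iiv_mid", "iiv_se")


class ParticipantExcluded(ValueError):
    """Raised when a participant fails an inclusion rule (e.g. <4 nights)."""


@dataclass
class IntraindividualStats:
    """Six-feature summary of one participant's habitual sleep behaviour."""

    participant_id: str
    n_nights: int
    iim_sh: float  # mean sleep hours
    iim_mid: float  # circular mean midpoint, clock hours [0, 24)
    iim_se: float  # mean sleep efficiency, (0, 1]
    iiv_sh: float  # SD of sleep hours
    iiv_mid: float  # circular SD of midpoint, hours
    iiv_se: float  # SD of sleep efficiency

    def __post_init__(self) -> None:
        if self.n_nights < MIN_NIGHTS:
            raise ParticipantExcluded(
                f"participant {self.participant_id}: {self.n_nights} nights < {MIN_NIGHTS}"
            )
        if min(self.iiv_sh, self.iiv_mid, self.iiv_se) < 0:
            raise ValueError("IIV statistics must be non-negative")
        if not (0.0 < self.iim_se <= 1.0):
            raise ValueError("mean sleep efficiency must lie in (0, 1]")

    @property
    def iim_mid_since_noon(self) -> float:
        """Midpoint re-expressed as hours since the preceding noon, [12, 36).

        A linear encoding of the circular midpoint that is continuous across
        midnight for nocturnal sleepers; used wherever the midpoint enters a
        linear model or distance computation.
        """
        return clock_to_hours_since_noon(self.iim_mid)


def clock_to_hours_since_noon(clock_hours: float) -> float:
    """Map a clock time in hours to the continuous [12, 36) noon-anchored axis."""
    return (clock_hours - 12.0) % 24.0 + 12.0


# --------------------------------------------------------------------------
# Circular statistics
# --------------------------------------------------------------------------


def circular_mean_sd(times: Sequence[float]) -> tuple[float, float]:
    """Circular mean and SD of clock times (hours; 24 h = full circle).

    The mean is the direction of the resultant vector; the SD is
    ``sqrt(-2 ln R) * 24 / (2 pi)`` hours, where R is the mean resultant
    length.  Raises for fewer than two times or a vanishing resultant
    (perfectly antipodal configuration, mean direction undefined).
    """
    t = np.asarray(times, dtype=float)
    if t.size < 2:
        raise ValueError("circular statistics require at least 2 times")
    angles = t * (2.0 * np.pi / 24.0)
    resultant = np.abs(np.mean(np.exp(1j * angles)))
    if resultant < 1e-12:
        raise ValueError("mean resultant length is 0: circular mean undefined")
    mean_h = float(sps.circmean(t, high=24.0, low=0.0))
    sd_h = float(sps.circstd(t, high=24.0, low=0.0))
    return mean_h % 24.0, sd_h


# --------------------------------------------------------------------------
# IIM / IIV
# --------------------------------------------------------------------------


def compute_iim_iiv(records: Sequence[SleepRecord]) -> IntraindividualStats:
    """Summarise one participant's sleep records into the six-feature vector.

    Linear mean/SD (n-1 denominator) for sleep hours and efficiency;
    circular mean/SD for the midpoint.  Participants with fewer than four
    records are excluded via :class:`ParticipantExcluded`.
    """
    if len(records) < MIN_NIGHTS:
        pid = records[0].participant_id if records else "<unknown>"
        raise ParticipantExcluded(f"participant {pid}: {len(records)} nights < {MIN_NIGHTS}")
    pid = records[0].participant_id
    if any(r.participant_id != pid for r in records):
        raise ValueError("records mix participants")
    hours = np.array([r.sleep_hours for r in records], dtype=float)
    eff = np.array([r.sleep_efficiency for r in records], dtype=float)
    mids = np.array([r.midpoint for r in records], dtype=float)
    mid_mean, mid_sd = circular_mean_sd(mids)
    return IntraindividualStats(
        participant_id=pid,
        n_nights=len(records),
        iim_sh=float(hours.mean()),
        iim_mid=mid_mean,
        iim_se=float(eff.mean()),
        iiv_sh=float(hours.std(ddof=1)),
        iiv_mid=mid_sd,
        iiv_se=float(eff.std(ddof=1)),
    )


def cohort_stats(
    records_by_participant: dict[str, Sequence[SleepRecord]],
) -> list[IntraindividualStats]:
    """Compute intraindividual statistics for a cohort, skipping excluded participants."""
    out: list[IntraindividualStats] = []
    for pid, records in records_by_participant.items():
        try:
            out.append(compute_iim_iiv(records))
        except ParticipantExcluded as exc:
            logger.info("excluded: %s", exc)
    return out


def stats_to_frame(stats: Iterable[IntraindividualStats]) -> pd.DataFrame:
    """One row per participant with the six features and night count."""
    rows = [
        {
            "participant_id": s.participant_id,
            "n_nights": s.n_nights,
            **{c: getattr(s, c) for c in FEATURE_COLUMNS},
        }
        for s in stats
    ]
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Transforms for downstream models
# --------------------------------------------------------------------------


def feature_matrix(stats: Sequence[IntraindividualStats]) -> pd.DataFrame:
    """Standardized six-feature matrix across the cohort (z-scores, ddof=0).

    Columns follow :data:`FEATURE_COLUMNS`; the circular midpoint mean is
    standardized on its linear noon-anchored encoding.  A zero-variance
    feature raises, naming the offending column.
    """
    if len(stats) < 2:
        raise ValueError("standardization requires at least 2 participants")
    raw = pd.DataFrame(
        {
            "iim_sh": [s.iim_sh for s in stats],
            "iim_mid": [s.iim_mid_since_noon for s in stats],
            "iim_se": [s.iim_se for s in stats],
            "iiv_sh": [s.iiv_sh for s in stats],
            "iiv_mid": [s.iiv_mid for s in stats],
            "iiv_se": [s.iiv_se for s in stats],
        },
        index=[s.participant_id for s in stats],
    )
    sd = raw.std(ddof=0)
    zero = sd[sd <= 0]
    if len(zero):
        raise ValueError(f"zero-variance feature(s): {', '.join(zero.index)}")
    return (raw - raw.mean()) / sd


def log_transform_iiv(values: Sequence[float], *, floor: float = LOG_IIV_FLOOR) -> np.ndarray:
    """Natural log of IIV values, flooring non-positive entries with a warning."""
    v = np.asarray(values, dtype=float)
    if np.any(v < floor):
        warnings.warn(
            f"IIV values below {floor} floored before log transform", stacklevel=2
        )
        v = np.maximum(v, floor)
    return np.log(v)
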