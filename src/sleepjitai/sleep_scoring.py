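"""Actigraphy sleep-wake scoring and nightly sleep-interval estimation.

Turns raw 1-minute zero-crossing activity counts into per-night sleep
records in three steps:

1. Cole-Kripke classification -- each epoch is scored sleep or wake from a
   weighted 7-epoch window of counts (4 preceding epochs, the current epoch,
   2 following epochs); an epoch is sleep when the weighted sum falls below
   a threshold of 1.
2. Webster rescoring -- heuristic rules that reclassify sleep epochs
   adjacent to long wake runs as wake, correcting the classifier's known
   bias toward sleep during quiet wakefulness.
3. Square-wave fitting -- within each noon-to-noon analysis day, the single
   (onset, offset) interval whose indicator best matches the binary
   sleep/wake sequence (maximal Pearson correlation, i.e. maximal R^2 among
   positively associated intervals) defines the night's sleep episode.

Sleep hours are the interval length, midpoint of sleep is the interval's
centre expressed as clock time, and sleep efficiency is the fraction of
epochs inside the interval that were scored sleep.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# Scoring constants
# --------------------------------------------------------------------------

#: Cole-Kripke weights for counts scored in 1-minute epochs: the scale P and
#: the window weights (W-4 ... W+2).  An epoch is sleep when
#: P * sum(W_k * A_k) < 1 over the centred window, with zero-padding at the
#: series boundaries.
COLE_KRIPKE_SCALE_1MIN: float = 0.00001
COLE_KRIPKE_WEIGHTS_1MIN: tuple[float, ...] = (404.0, 598.0, 326.0, 441.0, 1408.0, 508.0, 350.0)
COLE_KRIPKE_THRESHOLD: float = 1.0
#: Offsets of the window weights relative to the scored epoch.
COLE_KRIPKE_OFFSETS: tuple[int, ...] = (-4, -3, -2, -1, 0, 1, 2)

#: Webster rescoring rules.  (min_wake_run, n_following_sleep_rescored): after a
#: wake run at least this long, the next so-many sleep epochs become wake.
WEBSTER_AFTER_WAKE_RULES: tuple[tuple[int, int], ...] = ((4, 1), (10, 3), (15, 4))
#: (max_sleep_run, min_surrounding_wake): sleep runs no longer than the first
#: value flanked on both sides by wake runs at least the second value long
#: are rescored wake.
WEBSTER_SURROUNDED_RULES: tuple[tuple[int, int], ...] = ((6, 10), (10, 20))

STAGE_RAW = "raw-cole-kripke"
STAGE_RESCORED = "rescored"

#: Minimum worn epochs overlapping a noon-to-noon window for the day to count.
MIN_WORN_EPOCHS_PER_DAY = 120

EPOCHS_PER_DAY = 1440


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass
class ActivityEpochSeries:
    """One participant's uniform 1-minute zero-crossing count series.

    Epochs are contiguous: a minute with no usable wear is flagged
    ``worn=False``, never dropped.
    """

    participant_id: str
    start_time: pd.Timestamp
    counts: np.ndarray
    worn: np.ndarray
    epoch_seconds: int = 60

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.worn = np.asarray(self.worn, dtype=bool)
        self.start_time = pd.Timestamp(self.start_time)
        if self.epoch_seconds != 60:
            raise ValueError("epoch_seconds must be 60 (1-minute epochs)")
        if self.counts.ndim != 1 or self.worn.ndim != 1:
            raise ValueError("counts and worn must be 1-d sequences")
        if len(self.counts) != len(self.worn):
            raise ValueError("counts and worn must have equal length")
        if len(self.counts) and np.nanmin(self.counts) < 0:
            raise ValueError("zero-crossing counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)

    def epoch_time(self, index: int) -> pd.Timestamp:
        return self.start_time + pd.Timedelta(seconds=self.epoch_seconds * index)


@dataclass
class SleepWakeSeries:
    """Per-epoch binary sleep(1)/wake(0) labels aligned to an epoch series."""

    states: np.ndarray
    stage: str = STAGE_RAW

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.uint8)
        if not np.all((self.states == 0) | (self.states == 1)):
            raise ValueError("states must be binary (0=wake, 1=sleep)")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def total_sleep_epochs(self) -> int:
        return int(self.states.sum())


@dataclass
class SleepRecord:
    """One night's estimated sleep interval within a noon-anchored day."""

    participant_id: str
    analysis_day: pd.Timestamp  # date label: noon that opens the window
    onset: pd.Timestamp
    offset: pd.Timestamp
    sleep_hours: float
    midpoint: float  # clock time in hours, [0, 24)
    sleep_efficiency: float
    r_squared: float
    degenerate: bool = False  # whole window scored sleep

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("sleep offset must follow onset")
        if not (0.0 < self.sleep_efficiency <= 1.0):
            raise ValueError("sleep_efficiency must lie in (0, 1]")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-9):
            raise ValueError("r_squared must lie in [0, 1]")


# --------------------------------------------------------------------------
# Cole-Kripke classification
# --------------------------------------------------------------------------


def classify_cole_kripke(
    series: ActivityEpochSeries,
    *,
    scale: float = COLE_KRIPKE_SCALE_1MIN,
    weights: Sequence[float] = COLE_KRIPKE_WEIGHTS_1MIN,
    threshold: float = COLE_KRIPKE_THRESHOLD,
) -> SleepWakeSeries:
    """Score each epoch sleep/wake with the 1-minute Cole-Kripke weighting.

    The weighted activity ``D_t = scale * sum_k W_k * A_{t+k}`` is computed
    over the centred window (offsets -4..+2) with zero-padding outside the
    series; epoch *t* is sleep iff ``D_t < threshold``.  Non-worn epochs are
    forced to wake regardless of their (typically zero) counts.
    """
    n = len(series)
    if n < len(weights):
        raise ValueError(
            f"series has {n} epochs; at least {len(weights)} are required for "
            "the Cole-Kripke scoring window"
        )
    counts = np.asarray(series.counts, dtype=np.float64)
    kernel = np.asarray(weights, dtype=np.float64)
    # np.convolve flips the kernel; build it so position t picks up
    # weights[j] * counts[t + offsets[j]] with zero padding.
    lead = -min(COLE_KRIPKE_OFFSETS)  # epochs of history used (4)
    lag = max(COLE_KRIPKE_OFFSETS)  # epochs of future used (2)
    padded = np.concatenate([np.zeros(lead), counts, np.zeros(lag)])
    windows = np.lib.stride_tricks.sliding_window_view(padded, len(kernel))
    d = scale * windows @ kernel
    states = (d < threshold).astype(np.uint8)
    states[~series.worn] = 0
    return SleepWakeSeries(states=states, stage=STAGE_RAW)


# --------------------------------------------------------------------------
# Webster rescoring
# --------------------------------------------------------------------------


def _run_lengths(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode a binary vector -> (values, lengths)."""
    if len(states) == 0:
        return np.empty(0, dtype=np.uint8), np.empty(0, dtype=np.int64)
    change = np.flatnonzero(np.diff(states)) + 1
    bounds = np.concatenate([[0], change, [len(states)]])
    lengths = np.diff(bounds)
    values = states[bounds[:-1]]
    return values, lengths


def apply_webster_rescoring(sw: SleepWakeSeries) -> SleepWakeSeries:
    """Apply the five Webster rescoring rules to raw Cole-Kripke labels.

    Rules are evaluated on the raw scoring (non-cascading): wake runs of at
    least 4/10/15 minutes rescore the following 1/3/4 sleep minutes, and
    short sleep runs (<=6 or <=10 min) flanked by long wake runs (>=10 or
    >=20 min on both sides) are rescored wake.  Rescoring only ever flips
    sleep to wake.
    """
    if sw.stage != STAGE_RAW:
        raise ValueError("Webster rescoring expects a raw Cole-Kripke series")
    states = sw.states.copy()
    values, lengths = _run_lengths(sw.states)
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    n = len(sw.states)

    for run_idx in range(len(values)):
        if values[run_idx] != 0:
            continue
        wake_len = lengths[run_idx]
        end = starts[run_idx] + wake_len
        n_rescore = 0
        for min_wake, n_following in WEBSTER_AFTER_WAKE_RULES:
            if wake_len >= min_wake:
                n_rescore = max(n_rescore, n_following)
        if n_rescore == 0:
            continue
        # Flip up to n_rescore *sleep-scored* epochs immediately after the run;
        # stop at the first epoch that the raw scoring already marked wake.
        pos = end
        while pos < n and n_rescore > 0 and sw.states[pos] == 1:
            states[pos] = 0
            pos += 1
            n_rescore -= 1

    for run_idx in range(len(values)):
        if values[run_idx] != 1:
            continue
        sleep_len = lengths[run_idx]
        before = lengths[run_idx - 1] if run_idx > 0 else 0
        after = lengths[run_idx + 1] if run_idx < len(values) - 1 else 0
        for max_sleep, min_wake in WEBSTER_SURROUNDED_RULES:
            if sleep_len <= max_sleep and before >= min_wake and after >= min_wake:
                s = starts[run_idx]
                states[s : s + sleep_len] = 0
                break

    return SleepWakeSeries(states=states, stage=STAGE_RESCORED)


# --------------------------------------------------------------------------
# Square-wave interval estimation
# --------------------------------------------------------------------------


@njit(cache=False)
def _scan_intervals(c, lo, hi, n_total, n_sleep):  # pragma: no cover - compiled
    """Exact scan for the interval maximizing the signed correlation.

    ``c`` is the cumulative sum of the binary labels (length N+1); onsets are
    searched in [lo, hi) and offsets in (onset, hi].  Returns
    (onset, offset, corr) with ties broken toward the longest interval and
    then the earliest onset.
    """
    p = n_sleep / n_total
    sst_y = n_sleep - n_sleep * p
    best_r = -2.0
    best_o = -1
    best_n = 0
    span = hi - lo
    for length in range(span, 0, -1):
        # best placement of this length = max sleep-count window (first argmax)
        best_s = -1
        best_start = lo
        for o in range(lo, hi - length + 1):
            s = c[o + length] - c[o]
            if s > best_s:
                best_s = s
                best_start = o
        num = best_s - length * p
        if num <= 0.0:
            continue
        denom = (length - length * length / n_total) * sst_y
        if denom <= 0.0:
            continue
        r = num / math.sqrt(denom)
        if r > best_r + 1e-12:
            best_r = r
            best_o = best_start
            best_n = length
    return best_o, best_o + best_n, best_r


@njit(cache=False)
def _long_interval_corr_bound(n_total, n_sleep):  # pragma: no cover - compiled
    """Upper bound on the correlation achievable by intervals longer than N/2."""
    p = n_sleep / n_total
    sst_y = n_sleep - n_sleep * p
    half = (n_total + 1) // 2 + 1
    best = -2.0
    for length in range(half, n_total):
        num = n_sleep - length * p
        if num <= 0.0:
            continue
        denom = (length - length * length / n_total) * sst_y
        if denom <= 0.0:
            continue
        r = num / math.sqrt(denom)
        if r > best:
            best = r
    return best


def _best_square_wave(states: np.ndarray) -> tuple[int, int, float]:
    """Locate the best-fitting single high segment in a binary vector.

    Returns (onset_idx, offset_idx, r_squared) where the interval is
    [onset, offset) in epoch indices.  Exact over all intervals; the search
    is first restricted to the span of sleep-labelled epochs (any optimal
    interval of length <= (N+1)/2 has sleep-labelled endpoints) and falls
    back to the full scan when a longer interval could in principle win.
    """
    y = np.asarray(states, dtype=np.int64)
    n_total = len(y)
    n_sleep = int(y.sum())
    if n_sleep == 0:
        raise ValueError("window contains no sleep-labelled epochs")
    if n_sleep == n_total:
        return 0, n_total, 1.0
    c = np.concatenate([[0], np.cumsum(y)])
    sleep_idx = np.flatnonzero(y)
    lo, hi = int(sleep_idx[0]), int(sleep_idx[-1]) + 1
    onset, offset, r = _scan_intervals(c, lo, hi, n_total, n_sleep)
    if hi - lo <= (n_total + 1) // 2:
        bound = _long_interval_corr_bound(n_total, n_sleep)
        if bound > r:
            onset, offset, r = _scan_intervals(c, 0, n_total, n_total, n_sleep)
    return onset, offset, float(r * r)


def fit_sleep_square_wave(
    sw: SleepWakeSeries,
    series: ActivityEpochSeries,
    window: tuple[int, int],
) -> Optional[SleepRecord]:
    """Fit the nightly square wave within a window of epoch indices.

    ``window`` is (start, stop) into the epoch series (a noon-to-noon day).
    Returns ``None`` when the window contains no sleep-labelled epochs (the
    day is excluded rather than zero-filled).  A window scored entirely
    sleep yields the whole window flagged ``degenerate=True``.
    """
    start, stop = window
    if not (0 <= start < stop <= len(sw)):
        raise ValueError("window out of range of the sleep/wake series")
    y = sw.states[start:stop]
    if int(y.sum()) == 0:
        return None
    onset_idx, offset_idx, r2 = _best_square_wave(y)
    degenerate = offset_idx - onset_idx == stop - start
    n_in = offset_idx - onset_idx
    n_sleep_in = int(y[onset_idx:offset_idx].sum())
    onset = series.epoch_time(start + onset_idx)
    offset = series.epoch_time(start + offset_idx)
    sleep_hours = n_in / 60.0
    mid_time = onset + (offset - onset) / 2
    midpoint = mid_time.hour + mid_time.minute / 60.0 + mid_time.second / 3600.0
    return SleepRecord(
        participant_id=series.participant_id,
        analysis_day=series.epoch_time(start).normalize(),
        onset=onset,
        offset=offset,
        sleep_hours=sleep_hours,
        midpoint=midpoint % 24.0,
        sleep_efficiency=n_sleep_in / n_in,
        r_squared=min(r2, 1.0),
        degenerate=degenerate,
    )


# --------------------------------------------------------------------------
# Per-participant orchestration
# --------------------------------------------------------------------------


def _noon_windows(series: ActivityEpochSeries) -> list[tuple[int, int]]:
    """Noon-to-noon windows as (start, stop) epoch indices, clipped to the series."""
    n = len(series)
    if n == 0:
        return []
    start = series.start_time
    minutes_since_noon = (start.hour - 12) * 60 + start.minute + (start.second + 59) // 60
    first_noon_offset = (-minutes_since_noon) % EPOCHS_PER_DAY  # epochs until next noon
    if first_noon_offset > 0:
        # series starts mid-window: the first (partial) window ends at next noon
        edges = [0, min(first_noon_offset, n)]
        k = first_noon_offset
    else:
        edges = [0]
        k = 0
    while k < n:
        edges.append(min(k + EPOCHS_PER_DAY, n))
        k += EPOCHS_PER_DAY
    edges = sorted(set(edges))
    return [(a, b) for a, b in zip(edges[:-1], edges[1:]) if b > a]


def score_participant_nights(
    series: ActivityEpochSeries,
    *,
    min_worn_epochs: int = MIN_WORN_EPOCHS_PER_DAY,
    rescoring: bool = True,
) -> list[SleepRecord]:
    """Run classification, rescoring and square-wave fitting day by day.

    Days with fewer than ``min_worn_epochs`` worn epochs in their
    noon-to-noon window, or with no sleep-labelled epochs, are skipped and
    logged.  An empty series yields an empty list.
    """
    if len(series) == 0:
        return []
    if len(series) < len(COLE_KRIPKE_WEIGHTS_1MIN):
        raise ValueError("series shorter than the Cole-Kripke scoring window")
    sw = classify_cole_kripke(series)
    if rescoring:
        sw = apply_webster_rescoring(sw)
    records: list[SleepRecord] = []
    for start, stop in _noon_windows(series):
        n_worn = int(series.worn[start:stop].sum())
        if n_worn < min_worn_epochs:
            logger.info(
                "participant %s: day starting %s skipped (%d worn epochs < %d)",
                series.participant_id,
                series.epoch_time(start),
                n_worn,
                min_worn_epochs,
            )
            continue
        record = fit_sleep_square_wave(sw, series, (start, stop))
        if record is None:
            logger.info(
                "participant %s: day starting %s skipped (no sleep-labelled epochs)",
                series.participant_id,
                series.epoch_time(start),
            )
            continue
        records.append(record)
    return records


def records_to_frame(records: Sequence[SleepRecord]) -> pd.DataFrame:
    """Tabulate sleep records in the documented CSV schema."""
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "date": [r.analysis_day.date() for r in records],
            "onset": [r.onset for r in records],
            "offset": [r.offset for r in records],
            "sleep_hours": [r.sleep_hours for r in records],
            "midpoint": [r.midpoint for r in records],
            "efficiency": [r.sleep_efficiency for r in records],
            "r_squared": [r.r_squared for r in records],
        }
    )
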