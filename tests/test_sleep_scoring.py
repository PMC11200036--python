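"""Sleep-wake scoring: Cole-Kripke weighting, Webster rules, square-wave fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepjitai import sleep_scoring as ss
from sleepjitai.sleep_scoring import (
    COLE_KRIPKE_OFFSETS,
    COLE_KRIPKE_SCALE_1MIN,
    COLE_KRIPKE_WEIGHTS_1MIN,
    SleepWakeSeries,
    apply_webster_rescoring,
    classify_cole_kripke,
    fit_sleep_square_wave,
    score_participant_nights,
)

from conftest import make_series


# --------------------------------------------------------------------------
# Independent oracles
# --------------------------------------------------------------------------


def cole_kripke_oracle(counts):
    """Literal per-epoch evaluation of the published weighted sum."""
    n = len(counts)
    states = np.zeros(n, dtype=np.uint8)
    for t in range(n):
        d = 0.0
        for w, k in zip(COLE_KRIPKE_WEIGHTS_1MIN, COLE_KRIPKE_OFFSETS):
            j = t + k
            if 0 <= j < n:
                d += w * counts[j]
        states[t] = 1 if COLE_KRIPKE_SCALE_1MIN * d < 1.0 else 0
    return states


def square_wave_oracle_r2(y):
    """Exhaustive scan over all (onset, offset): max squared correlation among
    positively associated intervals."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    s = y.sum()
    if s == n:
        return 1.0
    p = s / n
    sst = s - s * p
    c = np.concatenate([[0.0], np.cumsum(y)])
    best = -np.inf
    for onset in range(n):
        for offset in range(onset + 1, n + 1):
            n1 = offset - onset
            num = (c[offset] - c[onset]) - n1 * p
            if num <= 0:
                continue
            den = (n1 - n1 * n1 / n) * sst
            if den <= 0:
                continue
            best = max(best, num * num / den)
    return best


# --------------------------------------------------------------------------
# Cole-Kripke classification
# --------------------------------------------------------------------------


def test_all_zero_counts_score_sleep():
    sw = classify_cole_kripke(make_series(np.zeros(30, dtype=int)))
    assert sw.states.all()


def test_constant_high_counts_score_wake():
    # weighted sum = 1e-5 * 500 * sum(weights) = 20.2 >= 1 at every interior epoch,
    # and even the most zero-padded boundary epoch stays above threshold
    sw = classify_cole_kripke(make_series(np.full(30, 500)))
    assert not sw.states.any()


def test_classification_matches_per_epoch_formula():
    rng = np.random.default_rng(3)
    for _ in range(10):
        counts = rng.choice([0, 0, 0, 2, 5, 120, 300], size=20)
        sw = classify_cole_kripke(make_series(counts))
        np.testing.assert_array_equal(sw.states, cole_kripke_oracle(counts))


def test_single_spike_window_footprint():
    counts = np.zeros(20, dtype=int)
    counts[10] = 100_000  # large enough to wake every epoch whose window sees it
    sw = classify_cole_kripke(make_series(counts))
    np.testing.assert_array_equal(sw.states, cole_kripke_oracle(counts))
    # the spike wakes epochs t where t-4 <= 10 <= t+2, i.e. 8..14
    assert set(np.flatnonzero(sw.states == 0)) == set(range(8, 15))


def test_short_series_rejected():
    with pytest.raises(ValueError, match="scoring window"):
        classify_cole_kripke(make_series(np.zeros(6, dtype=int)))


def test_non_worn_epochs_forced_wake():
    worn = np.ones(30, dtype=bool)
    worn[5:10] = False
    sw = classify_cole_kripke(make_series(np.zeros(30, dtype=int), worn=worn))
    assert not sw.states[5:10].any()
    assert sw.states[10:].all()


# --------------------------------------------------------------------------
# Webster rescoring
# --------------------------------------------------------------------------


def webster_oracle(states):
    """Independent rule-by-rule application on the raw scoring."""
    states = np.asarray(states, dtype=int)
    out = states.copy()
    n = len(states)
    # wake-run rules
    i = 0
    while i < n:
        if states[i] == 0:
            j = i
            while j < n and states[j] == 0:
                j += 1
            run = j - i
            n_rescore = 0
            if run >= 15:
                n_rescore = 4
            elif run >= 10:
                n_rescore = 3
            elif run >= 4:
                n_rescore = 1
            k = j
            while k < n and n_rescore > 0 and states[k] == 1:
                out[k] = 0
                k += 1
                n_rescore -= 1
            i = j
        else:
            i += 1
    # surrounded-sleep rules
    i = 0
    while i < n:
        if states[i] == 1:
            j = i
            while j < n and states[j] == 1:
                j += 1
            run = j - i
            before = 0
            k = i - 1
            while k >= 0 and states[k] == 0:
                before += 1
                k -= 1
            after = 0
            k = j
            while k < n and states[k] == 0:
                after += 1
                k += 1
            if (run <= 6 and before >= 10 and after >= 10) or (
                run <= 10 and before >= 20 and after >= 20
            ):
                out[i:j] = 0
            i = j
        else:
            i += 1
    return out


def test_all_sleep_unchanged():
    sw = SleepWakeSeries(np.ones(25, dtype=int))
    assert apply_webster_rescoring(sw).states.all()


def test_all_wake_unchanged():
    sw = SleepWakeSeries(np.zeros(25, dtype=int))
    assert not apply_webster_rescoring(sw).states.any()


def test_four_minute_wake_run_rescore():
    # 4 wake minutes followed by sleep: first post-run sleep minute flips to wake
    states = np.ones(40, dtype=int)
    states[10:14] = 0
    rescored = apply_webster_rescoring(SleepWakeSeries(states))
    expected = webster_oracle(states)
    np.testing.assert_array_equal(rescored.states, expected)
    assert rescored.states[14] == 0 and rescored.states[15] == 1


@pytest.mark.parametrize(
    "wake_len,n_flipped", [(3, 0), (4, 1), (10, 3), (15, 4), (30, 4)]
)
def test_wake_run_thresholds(wake_len, n_flipped):
    states = np.ones(80, dtype=int)
    states[20 : 20 + wake_len] = 0
    rescored = apply_webster_rescoring(SleepWakeSeries(states))
    flipped = np.flatnonzero(states != rescored.states)
    assert len(flipped) == n_flipped
    assert all(flipped == np.arange(20 + wake_len, 20 + wake_len + n_flipped))


def test_surrounded_short_sleep_rescored():
    # 5-minute sleep island between 12-minute wake runs -> rescored wake
    states = np.ones(60, dtype=int)
    states[10:22] = 0
    states[27:39] = 0
    rescored = apply_webster_rescoring(SleepWakeSeries(states))
    np.testing.assert_array_equal(rescored.states, webster_oracle(states))
    assert not rescored.states[22:27].any()


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.integers(0, 1), min_size=1, max_size=120))
def test_rescoring_monotone_and_matches_oracle(bits):
    states = np.array(bits, dtype=int)
    rescored = apply_webster_rescoring(SleepWakeSeries(states))
    # only sleep -> wake flips, never the reverse
    assert not ((states == 0) & (rescored.states == 1)).any()
    assert rescored.states.sum() <= states.sum()
    np.testing.assert_array_equal(rescored.states, webster_oracle(states))


def test_rescoring_requires_raw_stage():
    sw = SleepWakeSeries(np.ones(10, dtype=int), stage=ss.STAGE_RESCORED)
    with pytest.raises(ValueError, match="raw"):
        apply_webster_rescoring(sw)


# --------------------------------------------------------------------------
# Square-wave interval estimation
# --------------------------------------------------------------------------


def test_contiguous_block_recovered_exactly():
    states = np.zeros(120, dtype=int)
    states[40:80] = 1
    onset, offset, r2 = ss._best_square_wave(states)
    assert (onset, offset) == (40, 80)
    assert r2 == pytest.approx(1.0)


def test_square_wave_matches_exhaustive_scan():
    rng = np.random.default_rng(7)
    for _ in range(60):
        n = int(rng.integers(5, 200))
        y = (rng.random(n) < rng.uniform(0.1, 0.9)).astype(int)
        if y.sum() == 0:
            y[int(rng.integers(n))] = 1
        _, _, r2 = ss._best_square_wave(y)
        assert r2 == pytest.approx(square_wave_oracle_r2(y), abs=1e-9)


def test_midpoint_and_hours_arithmetic():
    # interval 23:30 -> 06:30 gives midpoint 03:00 and 7.0 sleep hours
    states = np.zeros(1440, dtype=int)
    states[690:1110] = 1  # 23:30 and 06:30 as minutes past noon
    sw = SleepWakeSeries(states)
    series = make_series(np.zeros(1440, dtype=int))
    rec = fit_sleep_square_wave(sw, series, (0, 1440))
    assert rec.sleep_hours == pytest.approx(7.0)
    assert rec.midpoint == pytest.approx(3.0)
    assert rec.onset == pd.Timestamp("2022-02-01 23:30:00")
    assert rec.offset == pd.Timestamp("2022-02-02 06:30:00")
    assert rec.r_squared == pytest.approx(1.0)
    assert rec.sleep_efficiency == pytest.approx(1.0)


def test_no_sleep_window_excluded():
    sw = SleepWakeSeries(np.zeros(200, dtype=int))
    assert fit_sleep_square_wave(sw, make_series(np.zeros(200, dtype=int)), (0, 200)) is None


def test_all_sleep_window_degenerate():
    sw = SleepWakeSeries(np.ones(200, dtype=int))
    rec = fit_sleep_square_wave(sw, make_series(np.zeros(200, dtype=int)), (0, 200))
    assert rec.degenerate
    assert rec.sleep_hours == pytest.approx(200 / 60)


def test_efficiency_bound_and_interpretation():
    rng = np.random.default_rng(11)
    series = make_series(np.zeros(500, dtype=int))
    for _ in range(20):
        y = (rng.random(500) < 0.4).astype(int)
        rec = fit_sleep_square_wave(SleepWakeSeries(y), series, (0, 500))
        assert 0.0 < rec.sleep_efficiency <= 1.0
        start = int((rec.onset - series.start_time).total_seconds() // 60)
        stop = int((rec.offset - series.start_time).total_seconds() // 60)
        if rec.sleep_efficiency == 1.0:
            assert y[start:stop].all()


def test_equal_r2_tie_prefers_longest_then_earliest():
    # two disjoint single-sleep epochs: any single epoch has the same r2;
    # the earliest onset must win among equal lengths
    y = np.zeros(50, dtype=int)
    y[10] = 1
    y[30] = 1
    onset, offset, _ = ss._best_square_wave(y)
    # a lone sleep epoch beats the diluted spanning interval; the two lone
    # epochs tie exactly, and the earlier onset wins
    assert (onset, offset) == (10, 11)


# --------------------------------------------------------------------------
# Per-participant orchestration
# --------------------------------------------------------------------------


def test_planted_nights_recovered_within_ten_minutes(small_cohort):
    truth = small_cohort.truth.nights
    pid = "s1-000"
    recs = score_participant_nights(small_cohort.epoch_series[pid])
    t = truth[truth.participant_id == pid].sort_values("day")
    assert len(recs) == len(t)
    start = small_cohort.epoch_series[pid].start_time
    errors = []
    for rec, (_, night) in zip(recs, t.iterrows()):
        onset_min = (rec.onset - start).total_seconds() / 60 - night.day * 1440
        errors.append(abs(onset_min - night.onset_min))
    assert np.median(errors) < 15.0
    assert max(errors) < 30.0


def test_fully_nonworn_day_skipped(small_cohort):
    s = small_cohort.epoch_series["s1-001"]
    worn = s.worn.copy()
    worn[3 * 1440 : 4 * 1440] = False
    clone = make_series(s.counts, worn=worn, pid=s.participant_id)
    assert len(score_participant_nights(clone)) == 13


def test_empty_series_yields_empty():
    empty = make_series(np.array([], dtype=int))
    assert score_participant_nights(empty) == []


def test_noon_windows_mid_start_alignment():
    # series starting 15:00 has a first partial window ending at the next noon
    series = make_series(np.zeros(3000, dtype=int), start="2022-02-01 15:00:00")
    windows = ss._noon_windows(series)
    assert windows[0] == (0, 21 * 60)
    assert windows[1] == (21 * 60, 21 * 60 + 1440)
    assert windows[-1][1] == 3000
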