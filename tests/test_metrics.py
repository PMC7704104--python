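"""Behavioural scoring and per-CS axonal statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fearcalc.imaging import CalciumEvent
from fearcalc.metrics import (
    FreezingRecord,
    classify_learner,
    cumulative_dff,
    freezing_percent,
    learning_correlation,
    learning_index,
    per_cs_counts,
)
from fearcalc.stimuli import build_schedule


@pytest.fixture(scope="module")
def schedule():
    return build_schedule(1, seed=0)


def ev(t, amp=0.5, roi="b0"):
    return CalciumEvent(roi, t - 0.1, t, amp, 1.0)


# ---------------------------------------------------------------------------
# freezing
# ---------------------------------------------------------------------------

def test_freezing_full_cover_and_empty(schedule):
    cs = schedule.cs_plus
    full = FreezingRecord("m1", "recall", [(e.onset, e.offset) for e in cs])
    assert freezing_percent(full, cs) == pytest.approx(100.0)
    assert freezing_percent(FreezingRecord("m1", "recall", []), cs) == 0.0


def test_freezing_partial_overlap(schedule):
    cs = [schedule.cs_plus[0]]
    rec = FreezingRecord("m1", "recall", [(cs[0].onset + 5, cs[0].onset + 20)])
    assert freezing_percent(rec, cs) == pytest.approx(50.0)


def test_freezing_rejects_overlapping_bouts_and_empty_epochs(schedule):
    with pytest.raises(ValueError):
        FreezingRecord("m1", "recall", [(0, 10), (5, 12)])
    with pytest.raises(ValueError):
        freezing_percent(FreezingRecord("m1", "recall", []), [])


@settings(max_examples=40, deadline=None)
@given(st.floats(0.0, 25.0), st.floats(0.1, 29.0))
def test_freezing_invariant_to_splitting_bouts(start, length):
    sched = build_schedule(1, seed=0)
    cs = [sched.cs_plus[0]]
    a, b = cs[0].onset + start, min(cs[0].onset + start + length, cs[0].offset + 10)
    mid = (a + b) / 2
    whole = FreezingRecord("m", "recall", [(a, b)])
    split = FreezingRecord("m", "recall", [(a, mid), (mid, b)])
    assert freezing_percent(whole, cs) == pytest.approx(freezing_percent(split, cs))


# ---------------------------------------------------------------------------
# learning index
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "freezing,f_plus,f_minus,expected",
    [
        (50.0, 60.0, 20.0, 25.0),
        (40.0, 40.0, 40.0, 0.0),
        (70.0, 70.0, 0.0, 70.0),  # perfect discrimination identity
        (30.0, 20.0, 60.0, -15.0),  # negative discrimination, no clipping
        (0.0, 0.0, 0.0, 0.0),  # undefined discrimination -> 0
        (80.0, 50.0, 30.0, 20.0),
    ],
)
def test_learning_index_formula(freezing, f_plus, f_minus, expected):
    assert learning_index(freezing, f_plus, f_minus) == pytest.approx(expected)


def test_learning_index_antisymmetric_in_discrimination():
    a = learning_index(42.0, 55.0, 15.0)
    b = learning_index(42.0, 15.0, 55.0)
    assert a == pytest.approx(-b)


@pytest.mark.parametrize(
    "index,expected", [(25.0, True), (19.9, False), (20.0, False), (-5.0, False)]
)
def test_learner_boundary_is_strictly_above_20(index, expected):
    assert classify_learner(index) is expected


# ---------------------------------------------------------------------------
# per-CS counts
# ---------------------------------------------------------------------------

def test_event_at_cs_onset_counted_in_that_cs(schedule):
    cs1 = schedule.cs_plus[0]
    counts = per_cs_counts([ev(cs1.onset)], schedule)
    row = counts[(counts.label == "CS+") & (counts.epoch_index == 1)]
    assert row["count"].sum() == 1
    # and exactly at offset belongs to the next interval, not this CS
    counts = per_cs_counts([ev(cs1.offset)], schedule)
    row = counts[(counts.label == "CS+") & (counts.epoch_index == 1)]
    assert row["count"].sum() == 0


def test_counts_conservation(schedule):
    rng = np.random.default_rng(0)
    events = [ev(t, roi=f"b{i%3}") for i, t in
              enumerate(rng.uniform(0, schedule.duration - 1, 80))]
    counts = per_cs_counts(events, schedule)
    assert counts["count"].sum() == len(events)


def test_empty_event_list_gives_zero_counts(schedule):
    counts = per_cs_counts([], schedule)
    assert (counts["count"] == 0).all()


def test_event_beyond_schedule_rejected(schedule):
    with pytest.raises(ValueError):
        per_cs_counts([ev(schedule.duration + 100.0)], schedule)


# ---------------------------------------------------------------------------
# cumulative dff
# ---------------------------------------------------------------------------

def test_symmetric_event_sets_give_zero_delta(schedule):
    events = []
    for e in schedule.cs_plus + schedule.cs_minus:
        events.append(ev(e.onset + 3.0, amp=0.4))
        events.append(ev(e.onset + 10.0, amp=0.2))
    _, mp, mm, delta = cumulative_dff(events, schedule)
    assert mp == pytest.approx(0.6)
    assert delta == pytest.approx(0.0)


def test_extra_cs_minus_events_shift_delta_exactly(schedule):
    events = [ev(e.onset + 2.0, amp=0.5) for e in schedule.cs_minus]
    _, mp, mm, delta = cumulative_dff(events, schedule)
    assert mm == pytest.approx(0.5)
    assert delta == pytest.approx(0.5)


def test_delta_invariant_to_events_outside_cs(schedule):
    base = [ev(e.onset + 2.0, amp=0.5) for e in schedule.cs_minus]
    with_noise = base + [ev(1.0, amp=3.0), ev(schedule.us[0].onset + 0.5, amp=2.0)]
    d1 = cumulative_dff(base, schedule, n_rois=1)[3]
    d2 = cumulative_dff(with_noise, schedule, n_rois=1)[3]
    assert d1 == pytest.approx(d2)


def test_cumulative_normalised_per_roi(schedule):
    events = [ev(e.onset + 2.0, amp=0.5, roi=f"b{i}")
              for e in schedule.cs_minus for i in range(4)]
    _, _, mm, _ = cumulative_dff(events, schedule)
    assert mm == pytest.approx(0.5)  # mean over the 4 boutons


# ---------------------------------------------------------------------------
# learning correlation
# ---------------------------------------------------------------------------

def test_collinear_cohort_r2_is_one():
    df = pd.DataFrame(
        {"delta_cumulative": [0.0, 0.05, 0.1, 0.15], "freezing_pct": [10, 30, 50, 70]}
    )
    slope, intercept, r2 = learning_correlation(df)
    assert r2 == pytest.approx(1.0)
    assert slope == pytest.approx(400.0)


def test_correlation_input_validation():
    with pytest.raises(ValueError):
        learning_correlation(
            pd.DataFrame({"delta_cumulative": [0.1, 0.1], "freezing_pct": [1, 2]})
        )
    with pytest.raises(ValueError):
        learning_correlation(
            pd.DataFrame({"delta_cumulative": [0.1, 0.1, 0.1], "freezing_pct": [1, 2, 3]})
        )
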