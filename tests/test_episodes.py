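"""Episode assembly, merging, burden scores, trends, cohort summaries."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pshkit import (
    EpisodeSet,
    PointLabelSeries,
    SignalError,
    assemble_episodes,
    burden_score,
    burden_trend,
    cohort_effect_size,
    merge_episodes,
    read_episodes_csv,
    summarize_first14,
    trend_ci,
    write_episodes_csv,
)

DAY = 86400.0


def _labels(bits, period=2.0, gaps_at=()):
    """Binary labels on a uniform grid, optionally with timing gaps."""
    t = period * np.arange(len(bits), dtype=float)
    for idx in gaps_at:
        t[idx:] += 600.0  # open a 10-minute hole before sample idx
    return PointLabelSeries(t, np.asarray(bits, dtype=np.int8), nominal_rate_hz=1.0 / period)


# ---------------------------------------------------------------------------
# Container invariants
# ---------------------------------------------------------------------------

def test_episode_set_rejects_bad_intervals():
    with pytest.raises(SignalError):
        EpisodeSet("p1", ((10.0, 10.0),))
    with pytest.raises(SignalError):
        EpisodeSet("p1", ((0.0, 100.0), (50.0, 150.0)))  # overlap
    with pytest.raises(SignalError):
        EpisodeSet("p1", ((0.0, 10.0),), source="nonsense")


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def test_single_run_becomes_one_interval():
    eps = assemble_episodes(_labels([0, 1, 1, 1, 0]), "p1", "es")
    assert eps.intervals == ((2.0, 8.0),)  # 3 positives x 2 s


def test_all_zero_labels_yield_empty_set():
    assert len(assemble_episodes(_labels([0, 0, 0]), "p1", "es")) == 0
    assert len(assemble_episodes(_labels([]), "p1", "es")) == 0


def test_runs_split_by_negative_sample():
    eps = assemble_episodes(_labels([1, 1, 0, 1, 1]), "p1", "es")
    assert eps.intervals == ((0.0, 4.0), (6.0, 10.0))


def test_sampling_gap_splits_a_run():
    eps = assemble_episodes(_labels([1, 1, 1, 1], gaps_at=[2]), "p1", "es", max_sample_gap_s=60.0)
    assert len(eps) == 2


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=1), min_size=1, max_size=40))
def test_assembly_matches_run_enumeration_oracle(bits):
    labels = _labels(bits)
    eps = assemble_episodes(labels, "p1", "es")
    # oracle: scan runs directly
    expected = []
    run_start = None
    for i, b in enumerate(bits):
        if b and run_start is None:
            run_start = i
        if (not b or i == len(bits) - 1) and run_start is not None:
            last = i if b else i - 1
            expected.append((2.0 * run_start, 2.0 * last + 2.0))
            run_start = None
    assert eps.intervals == tuple(expected)


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def test_merge_short_break():
    eps = EpisodeSet("p1", ((0.0, 600.0), (630.0, 1200.0)), "es")
    assert merge_episodes(eps).intervals == ((0.0, 1200.0),)


def test_gap_of_exactly_one_minute_is_not_merged():
    eps = EpisodeSet("p1", ((0.0, 600.0), (660.0, 1200.0)), "es")
    assert len(merge_episodes(eps)) == 2
    wide = EpisodeSet("p1", ((0.0, 600.0), (720.0, 1200.0)), "es")
    assert len(merge_episodes(wide)) == 2


def test_merge_is_transitive_and_idempotent():
    chain = EpisodeSet("p1", ((0.0, 100.0), (130.0, 200.0), (230.0, 300.0)), "es")
    merged = merge_episodes(chain)
    assert merged.intervals == ((0.0, 300.0),)
    assert merge_episodes(merged).intervals == merged.intervals


def _merge_fixed_point_oracle(intervals, gap):
    ivs = [list(i) for i in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(ivs) - 1):
            if ivs[i + 1][0] - ivs[i][1] < gap:
                ivs[i][1] = max(ivs[i][1], ivs[i + 1][1])
                del ivs[i + 1]
                changed = True
                break
    return tuple((a, b) for a, b in ivs)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(st.tuples(st.floats(1.0, 100.0), st.floats(1.0, 100.0)), min_size=0, max_size=8),
    st.floats(min_value=1.0, max_value=120.0),
)
def test_merge_matches_fixed_point_oracle(chunks, gap):
    # build sorted non-overlapping intervals from (gap, duration) pairs
    cursor, intervals = 0.0, []
    for g, d in chunks:
        start = cursor + g
        intervals.append((start, start + d))
        cursor = start + d
    eps = EpisodeSet("p1", tuple(intervals), "es")
    assert merge_episodes(eps, gap).intervals == _merge_fixed_point_oracle(intervals, gap)


# ---------------------------------------------------------------------------
# Burden
# ---------------------------------------------------------------------------

def test_burden_worked_example_two_hours_in_four():
    eps = EpisodeSet("p1", ((1800.0, 5400.0), (7200.0, 10800.0)), "es")  # 1 h + 1 h
    assert burden_score(eps, 0.0, 4 * 3600.0) == 0.5


def test_burden_limits():
    assert burden_score(EpisodeSet("p1", (), "es"), 0.0, 100.0) == 0.0
    full = EpisodeSet("p1", ((0.0, 100.0),), "es")
    assert burden_score(full, 0.0, 100.0) == 1.0
    with pytest.raises(SignalError):
        burden_score(full, 50.0, 50.0)


def test_burden_clips_to_frame_and_partitions_additively():
    eps = EpisodeSet("p1", ((50.0, 250.0),), "es")
    whole = burden_score(eps, 0.0, 400.0)
    halves = burden_score(eps, 0.0, 200.0) * 0.5 + burden_score(eps, 200.0, 400.0) * 0.5
    assert whole == pytest.approx(halves) == pytest.approx(200.0 / 400.0)


def test_trend_has_28_windows_over_14_days():
    trend = burden_trend(EpisodeSet("p1", (), "es"), record_span_s=14 * DAY)
    assert len(trend.scores) == 28
    assert all(s == 0.0 for s in trend.scores)


def test_trend_isolates_an_aligned_episode():
    eps = EpisodeSet("p1", ((3 * 43200.0, 4 * 43200.0),), "es")
    trend = burden_trend(eps, record_span_s=14 * DAY)
    assert trend.scores[3] == 1.0
    assert sum(trend.scores) == 1.0


def test_trend_partial_final_window_scored_over_actual_length():
    eps = EpisodeSet("p1", ((43200.0, 43200.0 + 3600.0),), "es")
    trend = burden_trend(eps, record_span_s=43200.0 + 7200.0)  # 12 h + 2 h record
    assert len(trend.scores) == 2
    assert trend.scores[1] == pytest.approx(3600.0 / 7200.0)


# ---------------------------------------------------------------------------
# 14-day summaries and effect sizes
# ---------------------------------------------------------------------------

def test_summary_empty_set():
    s = summarize_first14(EpisodeSet("p1", (), "es"))
    assert (s.n_episodes, s.mean_duration_min, s.burden_14d) == (0, None, 0.0)


def test_summary_single_42_minute_episode():
    start = 2 * DAY
    s = summarize_first14(EpisodeSet("p1", ((start, start + 42 * 60.0),), "es"))
    assert s.n_episodes == 1
    assert s.mean_duration_min == pytest.approx(42.0)
    assert s.burden_14d == pytest.approx(42.0 / (14 * 24 * 60.0))


def test_summary_clips_episode_straddling_day_14():
    eps = EpisodeSet("p1", ((14 * DAY - 600.0, 14 * DAY + 600.0),), "es")
    s = summarize_first14(eps)
    assert s.n_episodes == 1
    assert s.mean_duration_min == pytest.approx(10.0)  # clipped half


def test_cohens_d():
    assert cohort_effect_size([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0
    assert cohort_effect_size([2.0, 4.0, 6.0], [1.0, 3.0, 5.0]) == pytest.approx(0.5)
    assert cohort_effect_size([1.0, 3.0, 5.0], [2.0, 4.0, 6.0]) == pytest.approx(-0.5)
    assert cohort_effect_size([1.0, 1.0], [1.0, 1.0]) is None
    with pytest.raises(SignalError):
        cohort_effect_size([1.0], [1.0, 2.0])


def test_trend_ci_identical_trends_have_zero_width():
    df = trend_ci([[0.3, 0.3], [0.3, 0.3], [0.3, 0.3]])
    assert (df["ci_lo"] == df["mean"]).all() and (df["ci_hi"] == df["mean"]).all()
    assert (df["mean"] == 0.3).all()


def test_trend_ci_two_patients_closed_form():
    df = trend_ci([[0.0], [1.0]], confidence=0.95)
    # mean 0.5, sd 1/sqrt(2), sem 0.5, t crit (1 df, 97.5%) = 12.7062
    assert df.loc[0, "mean"] == pytest.approx(0.5)
    assert df.loc[0, "ci_hi"] == pytest.approx(0.5 + 12.7062 * 0.5, rel=1e-4)
    assert df.loc[0, "ci_lo"] == pytest.approx(0.5 - 12.7062 * 0.5, rel=1e-4)


def test_trend_ci_contains_mean_and_handles_singletons():
    df = trend_ci([[0.1, 0.4, 0.9], [0.2, 0.6]])
    ok = df["n"] >= 2
    assert (df.loc[ok, "ci_lo"] <= df.loc[ok, "mean"]).all()
    assert (df.loc[ok, "ci_hi"] >= df.loc[ok, "mean"]).all()
    assert df.loc[2, "n"] == 1 and np.isnan(df.loc[2, "ci_lo"])


# ---------------------------------------------------------------------------
# Episode CSV dialect
# ---------------------------------------------------------------------------

def test_episode_csv_round_trip(tmp_path):
    sets = [
        EpisodeSet("p1", ((0.0, 60.0), (120.0, 240.0)), "es"),
        EpisodeSet("p2", ((10.5, 33.25),), "truth"),
    ]
    path = tmp_path / "eps.csv"
    write_episodes_csv(sets, path)
    again = read_episodes_csv(path)
    assert {(e.patient_id, e.source): e.intervals for e in again} == {
        ("p1", "es"): ((0.0, 60.0), (120.0, 240.0)),
        ("p2", "truth"): ((10.5, 33.25),),
    }
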