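"""Episode intervals, burden scores, trends, and cohort summaries.

Point-level binary labels from either detector are assembled into
maximal positive runs, each run becoming a half-open interval that
extends one sampling period past its last positive sample.  Episodes
separated by less than one minute are merged, on the reasoning that two
genuinely distinct sympathetic surges are unlikely to be that close.

The *burden score* is the temporal density of episodes within a frame:

    B = (1/T) * sum_n |episode_n  ∩  frame|

so a patient with a cumulative 2 h of episode time in a 4 h frame has
burden 0.5, whether from one long episode or several short ones.
Burden trends are evaluated over consecutive non-overlapping 12-hour
windows from time zero (28 points over 14 days), and 14-day summaries
report episode count, mean duration, and overall burden.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .signal_model import PointLabelSeries, SignalError

logger = logging.getLogger(__name__)

EPISODE_SOURCES = ("annotation", "es", "svm", "truth")
DAY_S = 86400.0
FOURTEEN_DAYS_S = 14 * DAY_S


@dataclass(frozen=True)
class EpisodeSet:
    """Sorted, non-overlapping half-open episode intervals for one patient."""

    patient_id: str
    intervals: tuple[tuple[float, float], ...]
    source: str = "truth"

    def __post_init__(self) -> None:
        ivs = tuple((float(a), float(b)) for a, b in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        if self.source not in EPISODE_SOURCES:
            raise SignalError(f"source must be one of {EPISODE_SOURCES}, got {self.source!r}")
        prev_end = -math.inf
        for a, b in ivs:
            if not b > a:
                raise SignalError(f"interval [{a}, {b}) must have end > start")
            if a < prev_end:
                raise SignalError("intervals must be sorted and non-overlapping")
            prev_end = b

    def __len__(self) -> int:
        return len(self.intervals)

    def durations_s(self) -> np.ndarray:
        return np.array([b - a for a, b in self.intervals], dtype=float)

    def total_duration_s(self) -> float:
        return float(self.durations_s().sum()) if self.intervals else 0.0


@dataclass(frozen=True)
class BurdenTrend:
    """Burden scores over consecutive windows from time zero."""

    patient_id: str
    window_s: float
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(not 0.0 <= s <= 1.0 for s in self.scores):
            raise SignalError("burden scores must lie in [0, 1]")


@dataclass(frozen=True)
class PatientSummary:
    """First-14-day episode summary: count, mean duration, overall burden."""

    patient_id: str
    n_episodes: int
    mean_duration_min: float | None
    burden_14d: float


# ---------------------------------------------------------------------------
# Assembly and merging
# ---------------------------------------------------------------------------

def assemble_episodes(
    labels: PointLabelSeries,
    patient_id: str,
    source: str,
    max_sample_gap_s: float = 60.0,
) -> EpisodeSet:
    """Turn maximal runs of positive samples into half-open intervals.

    A run spans ``[t_first, t_last + period)``.  A sampling gap longer
    than ``max_sample_gap_s`` between consecutive positive samples
    splits the run: a monitoring dropout should not silently bridge an
    episode.
    """
    t = labels.timestamps
    y = labels.labels
    period = 1.0 / labels.nominal_rate_hz
    pos = np.nonzero(y == 1)[0]
    if pos.size == 0:
        return EpisodeSet(patient_id, (), source)
    # break a run where positive indices are non-consecutive or the time gap is too large
    brk = (np.diff(pos) != 1) | (np.diff(t[pos]) > max_sample_gap_s)
    run_starts = np.concatenate(([0], np.nonzero(brk)[0] + 1))
    run_ends = np.concatenate((np.nonzero(brk)[0], [pos.size - 1]))
    intervals = tuple(
        (float(t[pos[i]]), float(t[pos[j]]) + period) for i, j in zip(run_starts, run_ends)
    )
    return EpisodeSet(patient_id, intervals, source)


def merge_episodes(eps: EpisodeSet, min_gap_s: float = 60.0) -> EpisodeSet:
    """Merge consecutive intervals separated by a gap strictly below ``min_gap_s``.

    Applied transitively in one left-to-right pass (the set is sorted);
    a gap of exactly ``min_gap_s`` is *not* merged.  Idempotent.
    """
    if len(eps) <= 1:
        return eps
    merged: list[list[float]] = [list(eps.intervals[0])]
    for a, b in eps.intervals[1:]:
        if a - merged[-1][1] < min_gap_s:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return replace(eps, intervals=tuple((a, b) for a, b in merged))


# ---------------------------------------------------------------------------
# Burden
# ---------------------------------------------------------------------------

def burden_score(eps: EpisodeSet, frame_start_s: float, frame_end_s: float) -> float:
    """Fraction of the frame covered by episodes (episodes clipped to frame)."""
    if not frame_end_s > frame_start_s:
        raise SignalError(f"frame requires end > start, got [{frame_start_s}, {frame_end_s})")
    covered = 0.0
    for a, b in eps.intervals:
        covered += max(0.0, min(b, frame_end_s) - max(a, frame_start_s))
    return covered / (frame_end_s - frame_start_s)


def burden_trend(eps: EpisodeSet, record_span_s: float, window_s: float = 43200.0) -> BurdenTrend:
    """Burden over consecutive non-overlapping windows from time zero.

    A 14-day record with 12-hour windows yields exactly 28 scores.  The
    final window, if partial, is scored over its actual length.
    """
    if window_s <= 0 or record_span_s <= 0:
        raise SignalError("record_span_s and window_s must be positive")
    n_win = int(math.ceil(record_span_s / window_s - 1e-12))
    scores = tuple(
        burden_score(eps, i * window_s, min((i + 1) * window_s, record_span_s)) for i in range(n_win)
    )
    return BurdenTrend(patient_id=eps.patient_id, window_s=window_s, scores=scores)


def summarize_first14(eps: EpisodeSet) -> PatientSummary:
    """Count, mean duration (min), and burden over the first 14 days.

    Episodes are clipped to [0, 14 days); an episode straddling the day
    14 boundary contributes its clipped duration.
    """
    clipped = [
        (max(a, 0.0), min(b, FOURTEEN_DAYS_S))
        for a, b in eps.intervals
        if min(b, FOURTEEN_DAYS_S) > max(a, 0.0)
    ]
    n = len(clipped)
    durations_min = [(b - a) / 60.0 for a, b in clipped]
    mean_dur = float(np.mean(durations_min)) if n else None
    burden = sum(b - a for a, b in clipped) / FOURTEEN_DAYS_S
    return PatientSummary(
        patient_id=eps.patient_id, n_episodes=n, mean_duration_min=mean_dur, burden_14d=burden
    )


# ---------------------------------------------------------------------------
# Cohort comparisons
# ---------------------------------------------------------------------------

def cohort_effect_size(group_a: Sequence[float], group_b: Sequence[float]) -> float | None:
    """Cohen's d between two groups using the pooled sample standard deviation.

    ``d = (mean_a - mean_b) / s_p`` with
    ``s_p = sqrt(((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2))``.
    Returns None when the pooled standard deviation is zero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SignalError("each group needs at least 2 values for Cohen's d")
    pooled = math.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
    )
    if pooled == 0.0:
        return None
    return float((a.mean() - b.mean()) / pooled)


def trend_ci(trends: Sequence[Sequence[float]], confidence: float = 0.95) -> pd.DataFrame:
    """Cross-patient mean and t-interval per trend window.

    Rows: ``window_index, n, mean, ci_lo, ci_hi``; the interval is
    ``mean ± t_{n-1} * sd / sqrt(n)`` and is NaN where fewer than two
    patients contribute.
    """
    if not 0 < confidence < 1:
        raise SignalError("confidence must lie in (0, 1)")
    n_win = max((len(tr) for tr in trends), default=0)
    rows = []
    for i in range(n_win):
        vals = np.array([tr[i] for tr in trends if len(tr) > i], dtype=float)
        n = vals.size
        mean = float(vals.mean()) if n else math.nan
        lo = hi = math.nan
        if n >= 2:
            sem = vals.std(ddof=1) / math.sqrt(n)
            tcrit = float(sps.t.ppf(0.5 + confidence / 2.0, df=n - 1))
            lo, hi = mean - tcrit * sem, mean + tcrit * sem
        rows.append({"window_index": i, "n": n, "mean": mean, "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows, columns=["window_index", "n", "mean", "ci_lo", "ci_hi"])


# ---------------------------------------------------------------------------
# CSV I/O (shared episode dialect)
# ---------------------------------------------------------------------------

def write_episodes_csv(episode_sets: Iterable[EpisodeSet], path: str | Path) -> None:
    """Write ``patient_id,start_s,end_s,source`` rows (UTF-8, LF)."""
    rows = [
        {"patient_id": e.patient_id, "start_s": a, "end_s": b, "source": e.source}
        for e in episode_sets
        for a, b in e.intervals
    ]
    df = pd.DataFrame(rows, columns=["patient_id", "start_s", "end_s", "source"])
    df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def read_episodes_csv(path: str | Path) -> list[EpisodeSet]:
    """Read the shared episode dialect, one set per (patient, source)."""
    try:
        df = pd.read_csv(path, dtype={"patient_id": str, "source": str})
    except pd.errors.EmptyDataError:
        return []
    required = ("patient_id", "start_s", "end_s", "source")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SignalError(f"episode CSV {path} missing required column(s): {', '.join(missing)}")
    out = []
    for (pid, src), grp in df.groupby(["patient_id", "source"], sort=True):
        grp = grp.sort_values("start_s", kind="stable")
        out.append(
            EpisodeSet(
                patient_id=str(pid),
                intervals=tuple(zip(grp["start_s"].astype(float), grp["end_s"].astype(float))),
                source=str(src),
            )
        )
    return out


def write_burden_csv(trends: Iterable[BurdenTrend], path: str | Path) -> None:
    """Write ``patient_id,window_index,burden`` rows."""
    rows = [
        {"patient_id": tr.patient_id, "window_index": i, "burden": s}
        for tr in trends
        for i, s in enumerate(tr.scores)
    ]
    df = pd.DataFrame(rows, columns=["patient_id", "window_index", "burden"])
    df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def write_summary_csv(summaries: Iterable[PatientSummary], path: str | Path) -> None:
    """Write ``patient_id,n_episodes,mean_duration_min,burden_14d`` rows."""
    rows = [
        {
            "patient_id": s.patient_id,
            "n_episodes": s.n_episodes,
            "mean_duration_min": s.mean_duration_min,
            "burden_14d": s.burden_14d,
        }
        for s in summaries
    ]
    df = pd.DataFrame(rows, columns=["patient_id", "n_episodes", "mean_duration_min", "burden_14d"])
    df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")
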