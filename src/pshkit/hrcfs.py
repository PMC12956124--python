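"""Hourly high-resolution Clinical Feature Scale (hrCFS).

The Clinical Feature Scale of the PSH-Assessment Measure scores each
vital sign 0-3 against fixed thresholds.  The high-resolution variant
computed here restricts the scale to the three densely monitored trends
— heart rate, respiratory rate, and systolic blood pressure — and
evaluates it hourly from 0.5 Hz trend data, so the composite ranges
0-9.

Per hour, each hour is divided into 24 five-minute rolling windows with
a 2.5-minute step (50 % overlap); the per-window maximum of each signal
is taken, the maximum of those 24 maxima summarises the hour, and that
hourly maximum is scored 0-3 by the CFS cut-points.  The three
subscores sum to the hourly composite.  The 24th window would overrun
the hour, so it is truncated at the hour boundary, keeping exactly 24
windows without cross-hour leakage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .signal_model import SignalError, SignalKind, VitalSignSeries

logger = logging.getLogger(__name__)

HOUR_S = 3600.0
WINDOW_S = 300.0
STEP_S = 150.0
WINDOWS_PER_HOUR = 24


def _default_cuts() -> dict[SignalKind, tuple[float, float, float]]:
    # CFS cut-points: subscore = number of cut-points <= value.
    return {
        SignalKind.HR: (100.0, 120.0, 140.0),
        SignalKind.RR: (18.0, 24.0, 30.0),
        SignalKind.SBP: (140.0, 160.0, 180.0),
    }


@dataclass(frozen=True)
class CfsThresholds:
    """Three ascending cut-points per signal mapping values to 0-3.

    With cut-points ``(c1, c2, c3)`` a value scores 0 below ``c1``, 1 in
    ``[c1, c2)``, 2 in ``[c2, c3)`` and 3 at or above ``c3`` — matching
    the CFS bands (e.g. heart rate <100 / 100-119 / 120-139 / >=140).
    """

    cuts: Mapping[SignalKind, tuple[float, float, float]] = field(default_factory=_default_cuts)

    def __post_init__(self) -> None:
        cuts = {SignalKind(k): tuple(float(c) for c in v) for k, v in self.cuts.items()}
        object.__setattr__(self, "cuts", cuts)
        for kind, c in cuts.items():
            if len(c) != 3 or not (c[0] < c[1] < c[2]):
                raise SignalError(f"{kind}: cut-points must be three strictly ascending values, got {c}")

    def for_kind(self, kind: SignalKind) -> tuple[float, float, float]:
        try:
            return self.cuts[SignalKind(kind)]
        except (KeyError, ValueError) as exc:
            raise SignalError(f"no thresholds for signal kind {kind!r}") from exc


@dataclass(frozen=True)
class HrCfsRecord:
    """One patient-hour of hrCFS: per-signal 0-3 subscores and 0-9 composite.

    A subscore is ``None`` when the signal's hourly coverage fell below
    the minimum; the composite is ``None`` unless all three subscores
    are present.  ``coverage`` maps each signal to the fraction of
    expected samples present in the hour.
    """

    patient_id: str
    hour_index: int
    hr_score: int | None
    rr_score: int | None
    sbp_score: int | None
    composite: int | None
    coverage: Mapping[SignalKind, float]

    def __post_init__(self) -> None:
        subs = (self.hr_score, self.rr_score, self.sbp_score)
        expected = sum(subs) if all(s is not None for s in subs) else None
        if self.composite != expected:
            raise SignalError("composite must equal the sum of present subscores, else be missing")
        if self.composite is not None and not 0 <= self.composite <= 9:
            raise SignalError("composite out of range 0-9")

    @property
    def min_coverage(self) -> float:
        return min(self.coverage.values())


def score_vital(kind: SignalKind, value: float, thresholds: CfsThresholds | None = None) -> int:
    """Map one value to its 0-3 CFS subscore: the number of cut-points <= value."""
    if not math.isfinite(value):
        raise SignalError(f"value must be finite, got {value}")
    cuts = (thresholds or CfsThresholds()).for_kind(kind)
    return int(np.searchsorted(cuts, value, side="right"))


def hourly_window_starts(hour_index: int) -> np.ndarray:
    """The 24 rolling-window start offsets of an hour, seconds from time zero."""
    if hour_index < 0:
        raise SignalError("hour_index must be >= 0")
    return hour_index * HOUR_S + STEP_S * np.arange(WINDOWS_PER_HOUR)


def hourly_vital_max(series: VitalSignSeries, hour_index: int) -> float | None:
    """Max-of-maxima over the hour's 24 rolling windows; None if all empty.

    Each window is 300 s wide, truncated at the hour boundary (the last
    spans [3450, 3600) s within the hour).  For a fully covered hour
    this equals the plain hourly maximum; the windowed construction is
    kept for fidelity to the method and for per-window extensions.
    """
    starts = hourly_window_starts(hour_index)
    hour_end = (hour_index + 1) * HOUR_S
    t = series.timestamps
    best: float | None = None
    for s in starts:
        lo, hi = np.searchsorted(t, [s, min(s + WINDOW_S, hour_end)], side="left")
        if hi > lo:
            w = float(np.max(series.values[lo:hi]))
            best = w if best is None else max(best, w)
    return best


def _hour_coverage(series: VitalSignSeries, hour_index: int) -> float:
    lo, hi = np.searchsorted(series.timestamps, [hour_index * HOUR_S, (hour_index + 1) * HOUR_S], side="left")
    expected = HOUR_S * series.nominal_rate_hz
    return float(min(1.0, (hi - lo) / expected))


def compute_hrcfs(
    hr: VitalSignSeries,
    rr: VitalSignSeries,
    sbp: VitalSignSeries,
    thresholds: CfsThresholds | None = None,
    min_coverage: float = 0.5,
) -> list[HrCfsRecord]:
    """Hourly hrCFS records for one patient from pre-filtered series.

    Emits one record per hour from hour 0 through the last hour holding
    any sample of any signal.  A signal's subscore is missing when its
    hourly coverage (present / expected 0.5 Hz samples) is below
    ``min_coverage``; the composite is missing unless all three
    subscores are present.
    """
    thresholds = thresholds or CfsThresholds()
    by_kind = {SignalKind.HR: hr, SignalKind.RR: rr, SignalKind.SBP: sbp}
    pids = {s.patient_id for s in by_kind.values()}
    if len(pids) != 1:
        raise SignalError(f"series belong to different patients: {sorted(pids)}")
    for kind, s in by_kind.items():
        if s.signal_kind is not kind:
            raise SignalError(f"expected a {kind} series, got {s.signal_kind}")
    pid = hr.patient_id

    last_t = max((float(s.timestamps[-1]) for s in by_kind.values() if len(s)), default=None)
    if last_t is None:
        return []
    n_hours = int(last_t // HOUR_S) + 1

    records: list[HrCfsRecord] = []
    for h in range(n_hours):
        subs: dict[SignalKind, int | None] = {}
        cov: dict[SignalKind, float] = {}
        for kind, s in by_kind.items():
            cov[kind] = _hour_coverage(s, h)
            vmax = hourly_vital_max(s, h) if cov[kind] >= min_coverage else None
            subs[kind] = None if vmax is None else score_vital(kind, vmax, thresholds)
        comp = (
            subs[SignalKind.HR] + subs[SignalKind.RR] + subs[SignalKind.SBP]
            if all(v is not None for v in subs.values())
            else None
        )
        records.append(
            HrCfsRecord(
                patient_id=pid,
                hour_index=h,
                hr_score=subs[SignalKind.HR],
                rr_score=subs[SignalKind.RR],
                sbp_score=subs[SignalKind.SBP],
                composite=comp,
                coverage=cov,
            )
        )
    return records


def hrcfs_to_frame(records: Iterable[HrCfsRecord]) -> pd.DataFrame:
    """Tabulate records; ``coverage`` reports the minimum across signals."""
    rows = [
        {
            "patient_id": r.patient_id,
            "hour_index": r.hour_index,
            "hr_score": r.hr_score,
            "rr_score": r.rr_score,
            "sbp_score": r.sbp_score,
            "composite": r.composite,
            "coverage": r.min_coverage,
        }
        for r in records
    ]
    df = pd.DataFrame(
        rows,
        columns=["patient_id", "hour_index", "hr_score", "rr_score", "sbp_score", "composite", "coverage"],
    )
    for col in ("hr_score", "rr_score", "sbp_score", "composite"):
        df[col] = df[col].astype("Int64")
    return df


def write_hrcfs_csv(records: Iterable[HrCfsRecord], path: str | Path) -> None:
    """Write hourly scores; missing subscores become empty fields."""
    hrcfs_to_frame(records).to_csv(path, index=False, lineterminator="\n", encoding="utf-8")
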