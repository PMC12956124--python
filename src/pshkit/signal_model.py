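"""Core vital-sign time-series model shared by every detector.

A :class:`VitalSignSeries` holds one patient's trend for one signal
(heart rate, respiratory rate, or systolic blood pressure) on a nominal
0.5 Hz grid, with timestamps in seconds from *time zero* — the start of
the recording.  All window intervals throughout the package are
half-open ``[start, end)`` in those record-relative seconds, which keeps
a sample from ever being counted by two abutting windows.

Besides the container this module provides the CSV dialect used for
vitals, the extreme-value artifact filter, and exact window statistics
(single-window and dense rolling) that feed both episode detectors.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VITALS_COLUMNS = ("patient_id", "signal", "timestamp_s", "value")

#: Default artifact-filter ranges per signal.  The heart-rate range is the
#: adult normal reference range 30-250 bpm; the respiratory-rate and systolic
#: blood-pressure ranges are implementation defaults (no published reference
#: range was adopted) and are configurable everywhere they are used.
DEFAULT_FILTER_RANGES: dict["SignalKind", "ValueRange"]


class SignalError(ValueError):
    """Invalid series, window, or argument in the signal model."""


class VitalsFormatError(SignalError):
    """A vitals CSV file does not follow the expected dialect."""


class SignalKind(str, enum.Enum):
    """Vital-sign trend channels used by the quantification methods."""

    HR = "HR"
    RR = "RR"
    SBP = "SBP"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ValueRange:
    """Closed interval of plausible signal values, ``lo <= value <= hi``."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise SignalError(f"ValueRange requires lo < hi, got [{self.lo}, {self.hi}]")

    def contains(self, values: np.ndarray) -> np.ndarray:
        return (values >= self.lo) & (values <= self.hi)


DEFAULT_FILTER_RANGES = {
    SignalKind.HR: ValueRange(30.0, 250.0),
    SignalKind.RR: ValueRange(4.0, 80.0),
    SignalKind.SBP: ValueRange(40.0, 300.0),
}


@dataclass(frozen=True)
class VitalSignSeries:
    """One patient's trend for one signal.

    Parameters
    ----------
    patient_id
        Opaque patient identifier.
    signal_kind
        Which channel this series carries.
    timestamps
        Seconds from time zero (start of recording); strictly increasing,
        non-negative.
    values
        Signal values in natural units (bpm, breaths/min, mmHg); finite.
    nominal_rate_hz
        Nominal sampling rate of the bedside monitor trend, 0.5 Hz by
        default.  Used to extend the last sample of an episode by one
        sampling period and to compute hourly coverage.
    """

    patient_id: str
    signal_kind: SignalKind
    timestamps: np.ndarray
    values: np.ndarray
    nominal_rate_hz: float = 0.5

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "signal_kind", SignalKind(self.signal_kind))
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise SignalError("timestamps and values must be 1-D arrays of equal length")
        if t.size:
            if t[0] < 0:
                raise SignalError("timestamps must be >= 0 (seconds from time zero)")
            if np.any(np.diff(t) <= 0):
                raise SignalError("timestamps must be strictly increasing")
            if not np.all(np.isfinite(v)):
                raise SignalError("values must be finite")
        if self.nominal_rate_hz <= 0:
            raise SignalError("nominal_rate_hz must be positive")

    def __len__(self) -> int:
        return int(self.timestamps.size)

    @property
    def period_s(self) -> float:
        """Nominal sampling period in seconds."""
        return 1.0 / self.nominal_rate_hz

    @property
    def record_end_s(self) -> float:
        """End of record: one sampling period past the last sample."""
        if not len(self):
            return 0.0
        return float(self.timestamps[-1]) + self.period_s


@dataclass(frozen=True)
class WindowStats:
    """Exact summary statistics of the samples in one half-open window.

    ``variance`` is the population variance (divide by ``n``); ``median``
    averages the two central order statistics for even ``n``.  A window
    containing no samples never yields a :class:`WindowStats` — callers
    receive ``None`` instead.
    """

    start_s: float
    end_s: float
    n: int
    mean: float
    sd: float
    variance: float
    min: float
    max: float
    median: float


@dataclass(frozen=True)
class PointLabelSeries:
    """Per-sample binary episode indicator on a series' sampling grid.

    Intermediate product between window voting and episode assembly: a
    sample is positive when at least one sliding window covering it voted
    positive.
    """

    timestamps: np.ndarray
    labels: np.ndarray
    nominal_rate_hz: float = 0.5

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        y = np.asarray(self.labels, dtype=np.int8)
        if t.shape != y.shape or t.ndim != 1:
            raise SignalError("labels must align 1:1 with timestamps")
        if y.size and not np.all((y == 0) | (y == 1)):
            raise SignalError("labels must be binary")
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "labels", y)

    def __len__(self) -> int:
        return int(self.timestamps.size)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_vitals_csv(path: str | Path) -> dict[tuple[str, SignalKind], VitalSignSeries]:
    """Read a vitals CSV into one series per ``(patient_id, signal)``.

    The dialect is ``patient_id,signal,timestamp_s,value`` with signal in
    {HR, RR, SBP}.  Rows whose timestamp or value fails to parse as a
    number are dropped (count logged); rows with an unknown signal code
    are dropped (logged); exact duplicate timestamps within a series
    collapse to the last-read value (logged).  An empty file yields an
    empty mapping.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"patient_id": str, "signal": str})
    except pd.errors.EmptyDataError:
        return {}
    missing = [c for c in VITALS_COLUMNS if c not in df.columns]
    if missing:
        raise VitalsFormatError(f"vitals CSV {path} missing required column(s): {', '.join(missing)}")
    if df.empty:
        return {}

    ts = pd.to_numeric(df["timestamp_s"], errors="coerce")
    val = pd.to_numeric(df["value"], errors="coerce")
    bad = ts.isna() | ~np.isfinite(val.fillna(np.nan))
    if bad.any():
        logger.warning("%s: dropped %d row(s) with unparseable numerics", path.name, int(bad.sum()))
    known = df["signal"].isin([k.value for k in SignalKind])
    if (~known).any():
        logger.warning("%s: dropped %d row(s) with unknown signal codes", path.name, int((~known).sum()))
    keep = ~bad & known
    df = pd.DataFrame(
        {
            "patient_id": df.loc[keep, "patient_id"],
            "signal": df.loc[keep, "signal"],
            "timestamp_s": ts[keep],
            "value": val[keep],
        }
    )

    out: dict[tuple[str, SignalKind], VitalSignSeries] = {}
    for (pid, sig), grp in df.groupby(["patient_id", "signal"], sort=True):
        grp = grp.sort_values("timestamp_s", kind="stable")
        dup = grp["timestamp_s"].duplicated(keep="last")
        if dup.any():
            logger.warning(
                "%s/%s: collapsed %d duplicate timestamp(s) to last-read value", pid, sig, int(dup.sum())
            )
            grp = grp[~dup]
        kind = SignalKind(sig)
        out[(str(pid), kind)] = VitalSignSeries(
            patient_id=str(pid),
            signal_kind=kind,
            timestamps=grp["timestamp_s"].to_numpy(float),
            values=grp["value"].to_numpy(float),
        )
    return out


def write_vitals_csv(series: Iterable[VitalSignSeries], path: str | Path) -> None:
    """Write series in the shared vitals dialect (UTF-8, LF line endings)."""
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": s.patient_id,
                    "signal": s.signal_kind.value,
                    "timestamp_s": s.timestamps,
                    "value": s.values,
                }
            )
        )
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=list(VITALS_COLUMNS))
    df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Artifact filtering and slicing
# ---------------------------------------------------------------------------

def filter_extreme_values(series: VitalSignSeries, value_range: ValueRange | None = None) -> VitalSignSeries:
    """Drop samples outside the plausible value range (bounds inclusive).

    With ``value_range=None`` the default range for the series' signal
    kind applies.  The input is never modified; sample order is
    preserved; an empty result is allowed.  Idempotent.
    """
    if value_range is None:
        value_range = DEFAULT_FILTER_RANGES[series.signal_kind]
    keep = value_range.contains(series.values)
    if keep.all():
        return series
    return replace(series, timestamps=series.timestamps[keep], values=series.values[keep])


def slice_series(series: VitalSignSeries, start_s: float, end_s: float) -> VitalSignSeries:
    """Samples with ``start_s <= t < end_s``; timestamps are not re-based."""
    if not start_s < end_s:
        raise SignalError(f"slice requires start_s < end_s, got [{start_s}, {end_s})")
    lo, hi = np.searchsorted(series.timestamps, [start_s, end_s], side="left")
    return replace(series, timestamps=series.timestamps[lo:hi], values=series.values[lo:hi])


# ---------------------------------------------------------------------------
# Window statistics
# ---------------------------------------------------------------------------

def _stats_of(values: np.ndarray, start_s: float, end_s: float) -> WindowStats:
    var = float(np.var(values))  # population variance
    return WindowStats(
        start_s=float(start_s),
        end_s=float(end_s),
        n=int(values.size),
        mean=float(np.mean(values)),
        sd=math.sqrt(var),
        variance=var,
        min=float(np.min(values)),
        max=float(np.max(values)),
        median=float(np.median(values)),
    )


def window_stats(series: VitalSignSeries, start_s: float, end_s: float) -> WindowStats | None:
    """Exact statistics over ``start_s <= t < end_s``, or None if empty."""
    if not start_s < end_s:
        raise SignalError(f"window requires start_s < end_s, got [{start_s}, {end_s})")
    lo, hi = np.searchsorted(series.timestamps, [start_s, end_s], side="left")
    if hi <= lo:
        return None
    return _stats_of(series.values[lo:hi], start_s, end_s)


@dataclass(frozen=True)
class RollingStats:
    """Vectorised exact statistics for a dense grid of sliding windows.

    Window ``k`` spans ``[k*step_s, k*step_s + window_s)`` for
    ``k = 0, 1, ...`` while the window start lies before the record end.
    ``lo[k]:hi[k]`` are the covered sample indices; statistics are NaN
    where ``n == 0``.
    """

    starts: np.ndarray
    ends: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n: np.ndarray
    mean: np.ndarray = field(repr=False)
    sd: np.ndarray = field(repr=False)
    var: np.ndarray = field(repr=False)
    min: np.ndarray = field(repr=False)
    max: np.ndarray = field(repr=False)
    median: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return int(self.starts.size)

    def window(self, k: int) -> WindowStats | None:
        """The ``k``-th window as a :class:`WindowStats` (None if empty)."""
        if self.n[k] == 0:
            return None
        return WindowStats(
            start_s=float(self.starts[k]),
            end_s=float(self.ends[k]),
            n=int(self.n[k]),
            mean=float(self.mean[k]),
            sd=float(self.sd[k]),
            variance=float(self.var[k]),
            min=float(self.min[k]),
            max=float(self.max[k]),
            median=float(self.median[k]),
        )


def _is_uniform_grid(t: np.ndarray, period: float) -> bool:
    if t.size < 2:
        return False
    d = np.diff(t)
    return bool(np.all(np.abs(d - period) <= 1e-9 * period))


def rolling_window_stats(series: VitalSignSeries, window_s: float, step_s: float) -> RollingStats:
    """Exact min/max/mean/median/population-variance for every sliding window.

    On a gapless uniform grid whose step and width are integer multiples
    of the sampling period, full windows all contain the same sample
    count and are computed with pandas' rolling kernels (O(N log m) for
    the median); trailing windows truncated by the record end, and any
    non-uniform series, fall back to exact per-window recomputation.
    Both paths satisfy the same contract: exact statistics per window.
    """
    if step_s <= 0 or window_s <= 0:
        raise SignalError("window_s and step_s must be positive")
    if step_s > window_s:
        raise SignalError("step_s must not exceed window_s")
    t, v = series.timestamps, series.values
    if t.size == 0:
        z = np.empty(0)
        zi = np.empty(0, dtype=np.int64)
        return RollingStats(z, z, zi, zi, zi, z, z, z, z, z, z)

    record_end = series.record_end_s
    n_win = int(math.ceil(record_end / step_s - 1e-12))
    starts = step_s * np.arange(n_win, dtype=float)
    ends = starts + window_s
    lo = np.searchsorted(t, starts, side="left").astype(np.int64)
    hi = np.searchsorted(t, ends, side="left").astype(np.int64)
    counts = hi - lo

    shape = (n_win,)
    mean = np.full(shape, np.nan)
    var = np.full(shape, np.nan)
    mn = np.full(shape, np.nan)
    mx = np.full(shape, np.nan)
    md = np.full(shape, np.nan)

    period = series.period_s
    m = window_s / period
    stride = step_s / period
    fast = (
        _is_uniform_grid(t, period)
        and abs(m - round(m)) < 1e-9
        and abs(stride - round(stride)) < 1e-9
        and n_win > 64
    )
    done = np.zeros(n_win, dtype=bool)
    if fast:
        m_i = int(round(m))
        full = counts == m_i
        if full.any():
            s = pd.Series(v)
            roll = s.rolling(window=m_i)
            pos = lo[full] + m_i - 1
            mean[full] = roll.mean().to_numpy()[pos]
            var[full] = roll.var(ddof=0).to_numpy()[pos]
            mn[full] = roll.min().to_numpy()[pos]
            mx[full] = roll.max().to_numpy()[pos]
            md[full] = roll.median().to_numpy()[pos]
            done |= full

    rest = np.nonzero(~done & (counts > 0))[0]
    for k in rest:
        w = v[lo[k] : hi[k]]
        mean[k] = w.mean()
        var[k] = w.var()
        mn[k] = w.min()
        mx[k] = w.max()
        md[k] = np.median(w)

    var = np.where(np.isnan(var), var, np.maximum(var, 0.0))
    return RollingStats(
        starts=starts,
        ends=ends,
        lo=lo,
        hi=hi,
        n=counts,
        mean=mean,
        sd=np.sqrt(var),
        var=var,
        min=mn,
        max=mx,
        median=md,
    )


def fuse_window_votes(n_samples: int, lo: np.ndarray, hi: np.ndarray, positive: np.ndarray) -> np.ndarray:
    """Per-sample max-fusion of binary window votes.

    A sample is labelled positive exactly when at least one covering
    window (sample indices ``lo[k]:hi[k]``) voted positive.
    """
    diff = np.zeros(n_samples + 1, dtype=np.int64)
    sel = np.asarray(positive, dtype=bool)
    np.add.at(diff, lo[sel], 1)
    np.add.at(diff, hi[sel], -1)
    return (np.cumsum(diff[:-1]) > 0).astype(np.int8)
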