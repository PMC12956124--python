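"""Expert-system (rule-based) PSH episode detector.

Clinician-annotated episodes show a sudden heart-rate rise followed by
a stably elevated, high-variance heart rate persisting minutes to
hours.  Three parameterised rules capture this on each sliding window
of heart-rate data:

    HR minimum  > a        (default a = 95 bpm)
    HR median   > b        (default b = 104 bpm)
    HR variance > c        (default c = 37 bpm^2)

Windows are 10 minutes wide with a 2-second step, anchored at time
zero.  A window satisfying at least two of the three rules votes
positive, every sample in a positive window is labelled positive, and
conflicting labels resolve by taking the per-sample maximum.  The
default thresholds were derived by grid search against single-patient
clinician annotation; :func:`grid_search_rules` reproduces that
derivation, maximising range-based F1 (the precision/recall trade-off
is not otherwise pinned down, so the balanced harmonic mean is this
implementation's choice).

All rules are derived from and applied to heart rate only.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .episodes import EpisodeSet, assemble_episodes, merge_episodes
from .range_metrics import f1_score, range_precision, range_recall
from .signal_model import (
    PointLabelSeries,
    RollingStats,
    SignalError,
    VitalSignSeries,
    WindowStats,
    fuse_window_votes,
    rolling_window_stats,
)

logger = logging.getLogger(__name__)


class RuleSetError(SignalError):
    """Invalid rule-set parameters or grid-search arguments."""


@dataclass(frozen=True)
class RuleSet:
    """Thresholds and window geometry of the expert-system detector.

    ``min_thr``/``median_thr`` in bpm, ``var_thr`` in bpm²; all rules
    use strict ``>``.  ``votes_required`` of the three rules must hold
    for a window to vote positive (2-of-3 by default).
    """

    min_thr: float = 95.0
    median_thr: float = 104.0
    var_thr: float = 37.0
    window_s: float = 600.0
    step_s: float = 2.0
    votes_required: int = 2

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise RuleSetError("window_s must be positive")
        if not 0 < self.step_s <= self.window_s:
            raise RuleSetError("step_s must satisfy 0 < step_s <= window_s")
        if not 1 <= self.votes_required <= 3:
            raise RuleSetError("votes_required must be between 1 and 3")


def evaluate_rules(stats: WindowStats, rules: RuleSet) -> bool:
    """2-of-3 (configurable) vote over min/median/variance thresholds."""
    votes = (
        int(stats.min > rules.min_thr)
        + int(stats.median > rules.median_thr)
        + int(stats.variance > rules.var_thr)
    )
    return votes >= rules.votes_required


def _window_votes(rs: RollingStats, rules: RuleSet) -> np.ndarray:
    # NaN stats (empty windows) compare False on every rule -> negative vote.
    with np.errstate(invalid="ignore"):
        votes = (
            (rs.min > rules.min_thr).astype(np.int8)
            + (rs.median > rules.median_thr).astype(np.int8)
            + (rs.var > rules.var_thr).astype(np.int8)
        )
    return votes >= rules.votes_required


def label_points_es(hr: VitalSignSeries, rules: RuleSet | None = None) -> PointLabelSeries:
    """Per-sample episode labels by max-fusion of sliding-window votes.

    Windows ``[k*step_s, k*step_s + window_s)`` are enumerated while the
    window start lies before the record end; empty windows vote
    negative.  A sample is positive exactly when at least one covering
    window voted positive.
    """
    rules = rules or RuleSet()
    if len(hr) == 0:
        return PointLabelSeries(hr.timestamps, np.zeros(0, dtype=np.int8), hr.nominal_rate_hz)
    rs = rolling_window_stats(hr, rules.window_s, rules.step_s)
    positive = _window_votes(rs, rules)
    labels = fuse_window_votes(len(hr), rs.lo, rs.hi, positive)
    return PointLabelSeries(hr.timestamps, labels, hr.nominal_rate_hz)


def detect_episodes_es(
    hr: VitalSignSeries,
    rules: RuleSet | None = None,
    merge_gap_s: float = 60.0,
    max_sample_gap_s: float = 60.0,
) -> EpisodeSet:
    """End-to-end rule-based detection: label, assemble runs, merge short breaks."""
    labels = label_points_es(hr, rules)
    eps = assemble_episodes(labels, hr.patient_id, source="es", max_sample_gap_s=max_sample_gap_s)
    return merge_episodes(eps, min_gap_s=merge_gap_s)


def grid_search_rules(
    hr: VitalSignSeries,
    truth: EpisodeSet,
    grid_a: Sequence[float],
    grid_b: Sequence[float],
    grid_c: Sequence[float],
    template: RuleSet | None = None,
    merge_gap_s: float = 60.0,
    max_sample_gap_s: float = 60.0,
) -> RuleSet:
    """Re-derive (a, b, c) by maximising range-based F1 against annotation.

    Every triple in the Cartesian grid is evaluated end-to-end (label →
    assemble → merge → range precision/recall); ties break toward the
    larger ``a``, then ``b``, then ``c`` — the more conservative rule
    set.  Window statistics are computed once and re-thresholded per
    triple.
    """
    if not (len(grid_a) and len(grid_b) and len(grid_c)):
        raise RuleSetError("grid_search_rules requires non-empty grids for a, b and c")
    template = template or RuleSet()
    rs = rolling_window_stats(hr, template.window_s, template.step_s)

    best: tuple[float, float, float, float] | None = None  # (f1, a, b, c)
    for a, b, c in itertools.product(grid_a, grid_b, grid_c):
        rules = RuleSet(
            min_thr=a,
            median_thr=b,
            var_thr=c,
            window_s=template.window_s,
            step_s=template.step_s,
            votes_required=template.votes_required,
        )
        positive = _window_votes(rs, rules)
        labels = PointLabelSeries(
            hr.timestamps, fuse_window_votes(len(hr), rs.lo, rs.hi, positive), hr.nominal_rate_hz
        )
        eps = merge_episodes(
            assemble_episodes(labels, hr.patient_id, source="es", max_sample_gap_s=max_sample_gap_s),
            min_gap_s=merge_gap_s,
        )
        f1 = f1_score(range_precision(truth, eps), range_recall(truth, eps))
        key = (f1, a, b, c)
        if best is None or key > best:
            best = key

    f1, a, b, c = best
    if f1 == 0.0:
        logger.warning("grid search: every rule triple scored F1 = 0; returning tie-break triple")
    return RuleSet(
        min_thr=a,
        median_thr=b,
        var_thr=c,
        window_s=template.window_s,
        step_s=template.step_s,
        votes_required=template.votes_required,
    )
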