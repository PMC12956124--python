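"""Range-based (interval) precision and recall for episode detection.

Detected and annotated PSH episodes are time ranges, so partial overlap
must be credited rather than forcing an all-or-nothing match.  Following
the range-based generalisation of precision/recall introduced by Tatbul
et al. (NeurIPS 2018), each detected episode P_i is scored against the
annotated set R and each annotated episode R_i against the detected set
P, then scores are averaged per side:

    Precision(R, P) = (1/N_p) * sum_i Precision(R, P_i)
    Recall(R, P)    = (1/N_r) * sum_i Recall(R_i, P)

The per-episode score used here is the simplest member of the Tatbul
family — the overlap proportion |P_i ∩ ∪R| / |P_i| (flat positional
bias, no existence bonus, cardinality factor 1).  The inner function is
pluggable for other family members.  Under the flat-bias variant the
two metrics are dual: Precision(R, P) = Recall(P, R).

When the set a metric averages over is empty the metric is *undefined*
(returned as None), not 0 or 1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

from .episodes import EpisodeSet

logger = logging.getLogger(__name__)

Interval = tuple[float, float]
#: Scores one episode against the union of the other side's intervals.
EpisodeScore = Callable[[Interval, Sequence[Interval]], float]


def interval_overlap(a: Interval, b: Interval) -> float:
    """Length of the intersection of two half-open intervals (>= 0)."""
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


def overlap_proportion(episode: Interval, others: Sequence[Interval]) -> float:
    """|episode ∩ ∪others| / |episode| — the flat-bias per-episode score.

    ``others`` must be non-overlapping (as episode sets are), so summed
    pairwise overlaps equal the overlap with the union.
    """
    covered = sum(interval_overlap(episode, o) for o in others)
    return covered / (episode[1] - episode[0])


def _per_episode(scored: EpisodeSet, against: EpisodeSet, score: EpisodeScore) -> list[float]:
    return [score(iv, against.intervals) for iv in scored.intervals]


def range_precision(
    annotated: EpisodeSet, detected: EpisodeSet, score: EpisodeScore = overlap_proportion
) -> float | None:
    """Mean per-detected-episode score; None (undefined) if nothing was detected."""
    if len(detected) == 0:
        logger.warning("range_precision undefined: no detected episodes")
        return None
    scores = _per_episode(detected, annotated, score)
    return sum(scores) / len(scores)


def range_recall(
    annotated: EpisodeSet, detected: EpisodeSet, score: EpisodeScore = overlap_proportion
) -> float | None:
    """Mean per-annotated-episode score; None (undefined) if nothing was annotated."""
    if len(annotated) == 0:
        logger.warning("range_recall undefined: no annotated episodes")
        return None
    scores = _per_episode(annotated, detected, score)
    return sum(scores) / len(scores)


def f1_score(precision: float | None, recall: float | None) -> float:
    """Harmonic mean of precision and recall; 0 when either is undefined or both 0."""
    if precision is None or recall is None or precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class EvalReport:
    """Range precision/recall of a detected set against an annotated set."""

    precision: float | None
    recall: float | None
    n_annotated: int
    n_detected: int
    precision_per_episode: tuple[float, ...]
    recall_per_episode: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "n_annotated": self.n_annotated,
            "n_detected": self.n_detected,
            "precision_per_episode": list(self.precision_per_episode),
            "recall_per_episode": list(self.recall_per_episode),
        }


def evaluate_episodes(
    annotated: EpisodeSet, detected: EpisodeSet, score: EpisodeScore = overlap_proportion
) -> EvalReport:
    """Full evaluation report with per-episode score lists."""
    p_scores = _per_episode(detected, annotated, score)
    r_scores = _per_episode(annotated, detected, score)
    return EvalReport(
        precision=sum(p_scores) / len(p_scores) if p_scores else None,
        recall=sum(r_scores) / len(r_scores) if r_scores else None,
        n_annotated=len(annotated),
        n_detected=len(detected),
        precision_per_episode=tuple(p_scores),
        recall_per_episode=tuple(r_scores),
    )


def write_report_json(report: EvalReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8")
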