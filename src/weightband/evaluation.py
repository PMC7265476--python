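"""Alarm classification and cohort-level performance metrics.

An alarm raised on the animal's actual endpoint day is a true positive
(the endpoint was detected); any other alarm day is a false alarm. Cohort
metrics follow the study-report conventions: the endpoint detection rate
(EDR) is the proportion of animals whose endpoint day raised an alarm, and
false alarms are counted per alarm day (no episode merging) and averaged per
animal. The *adjusted* mean additionally discounts alarms on the day before
the endpoint and on the day after a tumour-resection surgery — days on which
heightened attention is arguably warranted rather than spurious.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .datamodel import (
    Cohort,
    DetectorConfig,
    NoEvaluableDaysError,
    ValidationError,
    WeightCourse,
)
from .detector import (
    BoundarySeries,
    NormalizedCourse,
    detect_alarms,
    compute_boundaries,
    normalize_course,
)

__all__ = [
    "AlarmReport",
    "EvaluationSummary",
    "DetectionResult",
    "classify_alarms",
    "evaluate_cohort",
    "adjusted_false_alarms",
    "detect_and_classify",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlarmReport:
    """Classified alarms for one animal."""

    animal_id: str
    alarm_days: frozenset[int]
    endpoint_day: int
    endpoint_detected: bool
    false_alarm_days: frozenset[int]
    resection_day: Optional[int] = None

    @property
    def n_false_alarms(self) -> int:
        return len(self.false_alarm_days)


@dataclass(frozen=True)
class EvaluationSummary:
    """Cohort-level detector performance (one column of a results table)."""

    n: int
    failed_detections: int
    mean_false_alarms: float
    edr: float
    adjusted_mean_false_alarms: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "failed_detections": self.failed_detections,
            "mean_false_alarms": self.mean_false_alarms,
            "edr": self.edr,
            "adjusted_mean_false_alarms": self.adjusted_mean_false_alarms,
        }


@dataclass(frozen=True)
class DetectionResult:
    """Everything the detector produced for one animal.

    Bundles the normalized course, the boundary series (absent when the
    course was too short to evaluate) and the classified alarm report; this
    is the unit the alarm-report CSV serializes.
    """

    ncourse: NormalizedCourse
    boundaries: Optional[BoundarySeries]
    report: AlarmReport


def classify_alarms(alarm_days: Iterable[int], course: WeightCourse) -> AlarmReport:
    """Split an alarm-day set into the endpoint detection and false alarms.

    Every alarm day is classified exactly once: the endpoint day (if present
    in the set) is the true positive, everything else is a false alarm.
    """
    alarms = frozenset(int(d) for d in alarm_days)
    valid = set(course.days)
    stray = alarms - valid
    if stray:
        raise ValidationError(
            f"animal {course.animal_id!r}: alarm days {sorted(stray)} are not "
            f"measurement days of the course"
        )
    detected = course.endpoint_day in alarms
    return AlarmReport(
        animal_id=course.animal_id,
        alarm_days=alarms,
        endpoint_day=course.endpoint_day,
        endpoint_detected=detected,
        false_alarm_days=alarms - {course.endpoint_day},
        resection_day=course.resection_day,
    )


def adjusted_false_alarms(reports: Sequence[AlarmReport]) -> float:
    """Mean false alarms per animal after discounting explainable days.

    Discounted days are the day before the animal's endpoint and, for
    resected animals, the day after the resection surgery.
    """
    if not reports:
        raise ValidationError("cannot evaluate an empty report collection")
    total = 0
    for r in reports:
        excluded = {r.endpoint_day - 1}
        if r.resection_day is not None:
            excluded.add(r.resection_day + 1)
        total += len(r.false_alarm_days - excluded)
    return total / len(reports)


def evaluate_cohort(reports: Sequence[AlarmReport]) -> EvaluationSummary:
    """Aggregate per-animal reports into the cohort performance summary."""
    if not reports:
        raise ValidationError("cannot evaluate an empty report collection")
    n = len(reports)
    failed = sum(1 for r in reports if not r.endpoint_detected)
    mean_fa = sum(r.n_false_alarms for r in reports) / n
    return EvaluationSummary(
        n=n,
        failed_detections=failed,
        mean_false_alarms=mean_fa,
        edr=(n - failed) / n,
        adjusted_mean_false_alarms=adjusted_false_alarms(reports),
    )


def detect_and_classify(
    cohort: Cohort, config: DetectorConfig
) -> list[DetectionResult]:
    """Run the detector on every animal of a cohort and classify the alarms.

    Animals too short to have any evaluable day are kept in the cohort as
    failed detections with zero false alarms (with a logged warning), so set
    sizes stay comparable across configurations.
    """
    results: list[DetectionResult] = []
    for course in cohort:
        ncourse = normalize_course(course)
        try:
            boundaries = compute_boundaries(ncourse, config)
        except NoEvaluableDaysError:
            logger.warning(
                "animal %r: only %d measurements for window %d; counted as a "
                "failed detection with no false alarms",
                course.animal_id, course.n_days, config.window_size,
            )
            results.append(
                DetectionResult(
                    ncourse=ncourse,
                    boundaries=None,
                    report=classify_alarms(frozenset(), course),
                )
            )
            continue
        alarms = detect_alarms(ncourse, boundaries)
        results.append(
            DetectionResult(
                ncourse=ncourse,
                boundaries=boundaries,
                report=classify_alarms(alarms, course),
            )
        )
    return results


def summary_frame(
    summaries: dict[str, EvaluationSummary], order: Sequence[str] = ("regular", "mad", "score")
) -> pd.DataFrame:
    """Tabulate per-mode summaries in the conventional column order."""
    cols = [m for m in order if m in summaries]
    cols += [m for m in summaries if m not in cols]
    return pd.DataFrame({m: summaries[m].to_dict() for m in cols})
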