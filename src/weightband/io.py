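"""Reading and writing the longitudinal cohort CSV and alarm-report CSV.

The cohort file is long-format, comma-separated UTF-8 with a ``.`` decimal
separator and a required header::

    animal_id,day,weight_g,clinical_score,event

``clinical_score`` may be empty (then the whole animal is score-free) and
``event`` is one of ``""``, ``"resection"`` or ``"endpoint"``; an
``endpoint`` row must be the last day of its animal. The alarm report holds
one row per (animal, day) with defined boundaries, carrying the normalized
weight, the decision boundaries, the 0/1 alarm flag and its TP/FP
classification; re-reading it reproduces the alarm sets exactly.
"""

from __future__ import annotations

import logging
from os import PathLike
from typing import Sequence, Union

import pandas as pd

from .datamodel import Cohort, ValidationError, WeightCourse, course_from_records
from .evaluation import DetectionResult

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "write_alarm_report",
    "read_alarm_report",
]

logger = logging.getLogger(__name__)

PathType = Union[str, PathLike]

COHORT_COLUMNS = ["animal_id", "day", "weight_g", "clinical_score", "event"]
REPORT_COLUMNS = [
    "animal_id", "day", "weight_pct", "lower", "upper", "alarm", "classification",
]
_EVENTS = {"", "resection", "endpoint"}


def read_cohort_csv(path: PathType, label: str = "") -> Cohort:
    """Parse a long-format cohort CSV into a :class:`Cohort`.

    Rows are grouped by ``animal_id`` (in order of first appearance) and
    sorted by day. An animal without an ``endpoint`` row keeps its maximum
    day as the endpoint, with a logged warning; duplicate (animal, day)
    pairs, non-positive weights and a non-final ``endpoint`` row are
    rejected.
    """
    df = pd.read_csv(
        path,
        dtype={"animal_id": str, "event": str},
        keep_default_na=False,
        float_precision="round_trip",
    )
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")

    courses: list[WeightCourse] = []
    for animal_id, group in df.groupby("animal_id", sort=False):
        group = group.sort_values("day")
        days = [int(d) for d in group["day"]]
        dupes = {d for d in days if days.count(d) > 1}
        if dupes:
            raise ValidationError(
                f"{path}: duplicate rows for (animal_id, day) = "
                f"({animal_id}, {sorted(dupes)[0]})"
            )
        weights = [float(w) for w in group["weight_g"]]

        raw_scores = ["" if s == "" else s for s in group["clinical_score"].astype(str)]
        blank = [s == "" or s == "nan" for s in raw_scores]
        if all(blank):
            scores = None
        elif any(blank):
            raise ValidationError(
                f"{path}: animal {animal_id!r} has clinical scores on some "
                f"days but not others; scores must be present for every day "
                f"or absent entirely"
            )
        else:
            scores = [int(float(s)) for s in raw_scores]

        events = list(group["event"].fillna(""))
        bad = sorted(set(events) - _EVENTS)
        if bad:
            raise ValidationError(
                f"{path}: animal {animal_id!r} has unknown event value(s) {bad}"
            )
        resection_day = None
        for d, ev in zip(days, events):
            if ev == "resection":
                resection_day = d
        endpoint_rows = [d for d, ev in zip(days, events) if ev == "endpoint"]
        if endpoint_rows and endpoint_rows != [days[-1]]:
            raise ValidationError(
                f"{path}: animal {animal_id!r} has an 'endpoint' event on day "
                f"{endpoint_rows[0]}, which is not its final day {days[-1]}"
            )
        if not endpoint_rows:
            logger.warning(
                "%s: animal %r has no 'endpoint' row; using its last day %d "
                "as the endpoint", path, animal_id, days[-1],
            )
        if any(b - a > 1 for a, b in zip(days, days[1:])):
            logger.warning(
                "%s: animal %r has gaps between measurement days; the "
                "detector window runs over measurements, not calendar days",
                path, animal_id,
            )
        courses.append(
            course_from_records(animal_id, days, weights, scores, resection_day)
        )
    if not courses:
        raise ValidationError(f"{path}: no animals found")
    return Cohort(courses=tuple(courses), label=label)


def write_cohort_csv(cohort: Cohort, path: PathType) -> None:
    """Write a cohort in the long format accepted by :func:`read_cohort_csv`.

    Floats use Python's shortest round-tripping representation, so
    read -> write -> read is an exact identity on cohort content.
    """
    rows = []
    for c in cohort:
        if c.resection_day is not None and c.resection_day not in c.days:
            raise ValidationError(
                f"animal {c.animal_id!r}: resection day {c.resection_day} is "
                f"not a measurement day and cannot be serialized as an event row"
            )
        for i, (d, w) in enumerate(zip(c.days, c.weights)):
            event = ""
            if c.resection_day == d:
                event = "resection"
            if d == c.endpoint_day:
                event = "endpoint"
            rows.append(
                {
                    "animal_id": c.animal_id,
                    "day": d,
                    "weight_g": w,
                    "clinical_score": "" if c.scores is None else c.scores[i],
                    "event": event,
                }
            )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def write_alarm_report(results: Sequence[DetectionResult], path: PathType) -> None:
    """Serialize per-day detector output with TP/FP classification."""
    if not results:
        raise ValidationError("cannot write an empty alarm report")
    rows = []
    for res in results:
        if res.boundaries is None:
            continue
        pct_by_day = dict(zip(res.ncourse.days, res.ncourse.weight_pct))
        for d, lo, up in zip(
            res.boundaries.days, res.boundaries.lower, res.boundaries.upper
        ):
            alarm = d in res.report.alarm_days
            if not alarm:
                classification = ""
            elif d == res.report.endpoint_day:
                classification = "TP"
            else:
                classification = "FP"
            rows.append(
                {
                    "animal_id": res.report.animal_id,
                    "day": d,
                    "weight_pct": pct_by_day[d],
                    "lower": lo,
                    "upper": up,
                    "alarm": int(alarm),
                    "classification": classification,
                }
            )
    try:
        pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write alarm report to {path}: {exc}") from exc


def read_alarm_report(path: PathType) -> dict[str, frozenset[int]]:
    """Recover per-animal alarm-day sets from a written alarm report."""
    df = pd.read_csv(path, dtype={"animal_id": str}, keep_default_na=False)
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    out: dict[str, frozenset[int]] = {}
    for animal_id, group in df.groupby("animal_id", sort=False):
        alarms = group.loc[group["alarm"].astype(int) == 1, "day"]
        out[str(animal_id)] = frozenset(int(d) for d in alarms)
    return out
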