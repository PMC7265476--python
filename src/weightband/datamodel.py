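"""Domain types for longitudinal body-weight monitoring.

The central object is the :class:`WeightCourse`: one animal's daily body-weight
trajectory from the first post-injection measurement (day 0) to the day the
animal reached its humane endpoint. Courses are grouped into a :class:`Cohort`
(e.g. a training or validation set), and a :class:`DetectorConfig` describes one
run of the control-band detector.

Types are plain frozen dataclasses; they do not validate themselves on
construction so that :func:`validate_course` can be exercised on malformed
values. The I/O layer calls :func:`validate_course` and refuses invalid input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

__all__ = [
    "WeightCourse",
    "Cohort",
    "DetectorConfig",
    "Mode",
    "MODES",
    "validate_course",
    "WeightbandError",
    "ValidationError",
    "ConfigurationError",
    "NoEvaluableDaysError",
]

Mode = Literal["regular", "mad", "score"]
MODES: tuple[str, ...] = ("regular", "mad", "score")


class WeightbandError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(WeightbandError):
    """Input data violates a structural invariant."""


class ConfigurationError(WeightbandError):
    """A detector or simulation configuration is unusable for the given data."""


class NoEvaluableDaysError(WeightbandError):
    """The course is too short for the requested lagging window."""


@dataclass(frozen=True)
class WeightCourse:
    """One animal's dated weight/score trajectory ending at a known endpoint.

    Parameters
    ----------
    animal_id
        Opaque label, unique within a cohort.
    days
        Strictly increasing integer measurement days; day 0 is the first
        measurement after tumour-cell injection. Gaps (missed weighings) are
        permitted; the detector's window runs over *measurements*.
    weights
        Body weight in grams, one positive value per day.
    scores
        Optional integer clinical scores (higher = worse), one per day. Either
        present for every day or absent as a whole.
    resection_day
        Day of a second (tumour-resection) surgery, if any; strictly between
        the first day and the endpoint.
    endpoint_day
        The last day of the course — the day the animal reached the endpoint
        criteria or died. Must equal ``max(days)``.
    """

    animal_id: str
    days: tuple[int, ...]
    weights: tuple[float, ...]
    scores: Optional[tuple[int, ...]] = None
    resection_day: Optional[int] = None
    endpoint_day: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.endpoint_day == -1 and self.days:
            object.__setattr__(self, "endpoint_day", max(self.days))

    @property
    def n_days(self) -> int:
        return len(self.days)

    @property
    def has_scores(self) -> bool:
        return self.scores is not None


@dataclass(frozen=True)
class Cohort:
    """An ordered, uniquely labelled collection of weight courses."""

    courses: tuple[WeightCourse, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.courses:
            raise ValidationError("a cohort must contain at least one course")
        ids = [c.animal_id for c in self.courses]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate animal ids in cohort: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.courses)

    def __iter__(self):
        return iter(self.courses)

    def __getitem__(self, animal_id: str) -> WeightCourse:
        for c in self.courses:
            if c.animal_id == animal_id:
                return c
        raise KeyError(animal_id)

    @property
    def animal_ids(self) -> tuple[str, ...]:
        return tuple(c.animal_id for c in self.courses)


@dataclass(frozen=True)
class DetectorConfig:
    """Parameters governing one detector run.

    Parameters
    ----------
    window_size
        Number of preceding measurements entering the moving average (>= 2).
    width_factor
        Multiplier on the window standard deviation setting the half-width of
        the decision boundaries (> 0).
    mode
        ``"regular"`` (no constraint), ``"mad"`` (boundaries locally narrowed
        by the rounded window-mean deficit) or ``"score"`` (narrowed by the
        clinical score).
    score_narrowing_unit
        Percentage points of normalized weight by which the lower boundary is
        raised per clinical-score point; used only in score mode.
    """

    window_size: int = 6
    width_factor: float = 2.5
    mode: str = "regular"
    score_narrowing_unit: float = 1.0

    def __post_init__(self) -> None:
        if int(self.window_size) != self.window_size or self.window_size < 2:
            raise ConfigurationError(
                f"window_size must be an integer >= 2, got {self.window_size!r}"
            )
        if not self.width_factor > 0:
            raise ConfigurationError(
                f"width_factor must be > 0, got {self.width_factor!r}"
            )
        if self.mode not in MODES:
            raise ConfigurationError(
                f"mode must be one of {MODES}, got {self.mode!r}"
            )
        if not self.score_narrowing_unit > 0:
            raise ConfigurationError(
                f"score_narrowing_unit must be > 0, got {self.score_narrowing_unit!r}"
            )


def validate_course(course: WeightCourse) -> list[str]:
    """Check every :class:`WeightCourse` invariant, returning violations.

    Returns an empty list iff the course is well-formed. Each violation names
    the offending field and value; nothing is raised.
    """
    v: list[str] = []
    n = len(course.days)
    if n < 2:
        v.append(f"days: need at least 2 measurements, got {n}")
    if len(course.weights) != n:
        v.append(
            f"weights: length {len(course.weights)} does not match {n} days"
        )
    if course.scores is not None and len(course.scores) != n:
        v.append(f"scores: length {len(course.scores)} does not match {n} days")

    seen: set[int] = set()
    for i, d in enumerate(course.days):
        if d in seen:
            v.append(f"days: duplicate day {d}")
        seen.add(d)
        if i > 0 and d <= course.days[i - 1]:
            v.append(
                f"days: not strictly increasing at position {i} "
                f"({course.days[i - 1]} -> {d})"
            )

    for d, w in zip(course.days, course.weights):
        if not w > 0:
            v.append(f"weights: non-positive weight {w} on day {d}")
    if course.scores is not None:
        for d, s in zip(course.days, course.scores):
            if s < 0 or int(s) != s:
                v.append(f"scores: invalid score {s!r} on day {d}")

    if course.days and course.endpoint_day != max(course.days):
        v.append(
            f"endpoint_day: {course.endpoint_day} is not the last day "
            f"({max(course.days)})"
        )
    if course.resection_day is not None and course.days:
        if not (min(course.days) < course.resection_day < course.endpoint_day):
            v.append(
                f"resection_day: {course.resection_day} not strictly between "
                f"first day {min(course.days)} and endpoint {course.endpoint_day}"
            )
    return v


def course_from_records(
    animal_id: str,
    days: Sequence[int],
    weights: Sequence[float],
    scores: Optional[Sequence[int]] = None,
    resection_day: Optional[int] = None,
) -> WeightCourse:
    """Build and validate a course; raise :class:`ValidationError` if bad."""
    course = WeightCourse(
        animal_id=str(animal_id),
        days=tuple(int(d) for d in days),
        weights=tuple(float(w) for w in weights),
        scores=None if scores is None else tuple(int(s) for s in scores),
        resection_day=None if resection_day is None else int(resection_day),
    )
    problems = validate_course(course)
    if problems:
        raise ValidationError(
            f"invalid course for animal {animal_id!r}: " + "; ".join(problems)
        )
    return course
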