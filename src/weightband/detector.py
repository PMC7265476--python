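"""The control-band detector: normalization, lagging-window statistics,
boundary construction in three modes, and per-day alarm generation.

The algorithm is an individualized control chart on the normalized body-weight
course. For each measurement with a complete *lagging* window of
``window_size`` preceding measurements, the unweighted window mean (moving
average) and sample standard deviation are computed; the current day is
excluded from its own window so that an abrupt drop cannot inflate the SD and
mask itself. Decision boundaries sit ``width_factor`` window-SDs either side
of the moving mean. A measurement strictly below the lower boundary raises an
alarm; the upper boundary never alarms.

Two constrained modes locally narrow the boundaries to raise sensitivity:

* ``mad`` — by the rounded deficit of today's value below the window mean
  (window mean minus observed value, rounded half-up, clamped at zero);
* ``score`` — by ``score_narrowing_unit`` percentage points per
  clinical-score point recorded that day.

Narrowing is applied symmetrically but never crosses the moving mean, so a
constrained lower boundary always lies at or above the regular one — the
mechanism by which the constrained modes trade extra false alarms for a higher
endpoint detection rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import (
    ConfigurationError,
    DetectorConfig,
    NoEvaluableDaysError,
    ValidationError,
    WeightCourse,
)

__all__ = [
    "NormalizedCourse",
    "BoundarySeries",
    "normalize_course",
    "rolling_stats",
    "mad_narrowing",
    "compute_boundaries",
    "detect_alarms",
    "run_detector",
]


@dataclass(frozen=True)
class NormalizedCourse:
    """A weight course expressed in percent of its first measurement."""

    animal_id: str
    days: tuple[int, ...]
    weight_pct: tuple[float, ...]
    scores: Optional[tuple[int, ...]] = None
    resection_day: Optional[int] = None
    endpoint_day: int = -1

    @property
    def n_days(self) -> int:
        return len(self.days)


@dataclass(frozen=True)
class BoundarySeries:
    """Per-day moving statistics and decision boundaries for one animal.

    Defined only for days with a complete preceding window, i.e. never for the
    first ``window_size`` measurements. All values are percent of the starting
    weight. ``narrowing`` is the non-negative local narrowing applied that day
    (always 0 in regular mode).
    """

    animal_id: str
    days: tuple[int, ...]
    moving_mean: tuple[float, ...]
    moving_sd: tuple[float, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]
    narrowing: tuple[float, ...]
    config: DetectorConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.days,
                "moving_mean": self.moving_mean,
                "moving_sd": self.moving_sd,
                "lower": self.lower,
                "upper": self.upper,
                "narrowing": self.narrowing,
            }
        )


def normalize_course(course: WeightCourse) -> NormalizedCourse:
    """Normalize a course to percent of the starting value.

    The first measurement maps to exactly 100%; all other fields are copied
    unchanged.
    """
    if not course.weights or not course.weights[0] > 0:
        raise ValidationError(
            f"animal {course.animal_id!r}: first weight must be positive to "
            f"serve as the 100% baseline"
        )
    w0 = course.weights[0]
    pct = tuple(100.0 * w / w0 for w in course.weights)
    return NormalizedCourse(
        animal_id=course.animal_id,
        days=course.days,
        weight_pct=pct,
        scores=course.scores,
        resection_day=course.resection_day,
        endpoint_day=course.endpoint_day,
    )


def rolling_stats(values, window_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Lagging-window mean and sample SD for each evaluable position.

    For 0-based position ``d >= window_size`` the statistics cover
    ``values[d - window_size : d]`` — the current value is excluded from its
    own window. Returns two arrays aligned with ``values``; positions without
    a complete preceding window hold NaN.

    Raises
    ------
    NoEvaluableDaysError
        If ``len(values) <= window_size`` (no position has a full window).
    """
    if window_size < 2:
        raise ConfigurationError(f"window_size must be >= 2, got {window_size}")
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if arr.size <= window_size:
        raise NoEvaluableDaysError(
            f"course of length {arr.size} has no day with a complete "
            f"preceding window of {window_size}"
        )
    s = pd.Series(arr)
    mean = s.rolling(window_size).mean().shift(1).to_numpy()
    sd = s.rolling(window_size).std(ddof=1).shift(1).to_numpy()
    return mean, sd


def mad_narrowing(window_mean: float, observed: float) -> int:
    """Rounded local deficit used by the ``mad`` mode.

    The raw value is the lagging-window mean minus the observed value; it is
    rounded half-up to the nearest integer percentage point and clamped at
    zero (a weight above the window mean never widens the boundaries).
    """
    raw = window_mean - observed
    return max(0, int(math.floor(raw + 0.5)))


def compute_boundaries(
    ncourse: NormalizedCourse, config: DetectorConfig
) -> BoundarySeries:
    """Decision boundaries for every evaluable day of a normalized course.

    Base boundaries are ``mean ± width_factor * SD`` of the lagging window.
    Mode-specific narrowing raises the lower and lowers the upper boundary by
    the same amount, clamped so that neither crosses the moving mean.
    """
    if config.mode == "score" and ncourse.scores is None:
        raise ConfigurationError(
            f"animal {ncourse.animal_id!r}: score mode requires clinical "
            f"scores, which are absent"
        )
    mean, sd = rolling_stats(ncourse.weight_pct, config.window_size)
    k = config.width_factor

    days: list[int] = []
    means: list[float] = []
    sds: list[float] = []
    lowers: list[float] = []
    uppers: list[float] = []
    narrowings: list[float] = []
    for i in range(config.window_size, ncourse.n_days):
        m, s = float(mean[i]), float(sd[i])
        if config.mode == "regular":
            n_d = 0.0
        elif config.mode == "mad":
            n_d = float(mad_narrowing(m, ncourse.weight_pct[i]))
        else:  # score
            n_d = config.score_narrowing_unit * ncourse.scores[i]
        lower = min(m, m - k * s + n_d)
        upper = max(m, m + k * s - n_d)
        days.append(ncourse.days[i])
        means.append(m)
        sds.append(s)
        lowers.append(lower)
        uppers.append(upper)
        narrowings.append(n_d)

    return BoundarySeries(
        animal_id=ncourse.animal_id,
        days=tuple(days),
        moving_mean=tuple(means),
        moving_sd=tuple(sds),
        lower=tuple(lowers),
        upper=tuple(uppers),
        narrowing=tuple(narrowings),
        config=config,
    )


def detect_alarms(
    ncourse: NormalizedCourse, boundaries: BoundarySeries
) -> frozenset[int]:
    """Alarm days: days whose weight falls strictly below the lower boundary.

    Only the lower boundary triggers; a value exactly on the boundary or any
    upper-boundary crossing is not an alarm, and days without boundaries never
    alarm.
    """
    pct_by_day = dict(zip(ncourse.days, ncourse.weight_pct))
    return frozenset(
        d for d, lo in zip(boundaries.days, boundaries.lower)
        if pct_by_day[d] < lo
    )


def run_detector(
    course: WeightCourse, config: DetectorConfig
) -> tuple[BoundarySeries, frozenset[int]]:
    """Normalize, compute boundaries and detect alarms for one course."""
    ncourse = normalize_course(course)
    boundaries = compute_boundaries(ncourse, config)
    return boundaries, detect_alarms(ncourse, boundaries)
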