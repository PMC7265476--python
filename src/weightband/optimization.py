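"""Grid search over window sizes and width-factors, and parameter selection.

The detector has two tuning knobs: the lagging-window size (how much history
the moving average sees) and the width-factor (how many window-SDs the
boundaries sit from the mean). The grid search evaluates every combination on
a training cohort; :func:`select_parameters` then applies a two-stage rule —
first the window minimizing the false-alarm burden averaged over all widths,
then, at that window, the widest band still achieving the maximum endpoint
detection rate (wider bands mean fewer false alarms at equal sensitivity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import Cohort, DetectorConfig, ValidationError
from .evaluation import EvaluationSummary, detect_and_classify, evaluate_cohort

__all__ = [
    "GridResult",
    "default_windows",
    "default_widths",
    "grid_search",
    "select_parameters",
]

logger = logging.getLogger(__name__)


def default_windows() -> tuple[int, ...]:
    """Window sizes 2-10 days."""
    return tuple(range(2, 11))


def default_widths() -> tuple[float, ...]:
    """Width-factors 0.5-3.0 in steps of 0.25."""
    return tuple(np.round(np.arange(0.5, 3.0 + 1e-9, 0.25), 2))


@dataclass(frozen=True)
class GridResult:
    """Evaluation summaries for every (window, width) grid point of one mode."""

    entries: dict[tuple[int, float, str], EvaluationSummary]
    windows: tuple[int, ...]
    widths: tuple[float, ...]
    mode: str

    def summary(self, window: int, width: float) -> EvaluationSummary:
        return self.entries[(window, width, self.mode)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (one row per grid point) for export/plots."""
        rows = [
            {"window_size": w, "width_factor": k, "mode": m, **s.to_dict()}
            for (w, k, m), s in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)


def grid_search(
    cohort: Cohort,
    windows: Sequence[int] | None = None,
    widths: Sequence[float] | None = None,
    mode: str = "regular",
    score_unit: float = 1.0,
) -> GridResult:
    """Evaluate the detector on every (window_size, width_factor) pair.

    Deterministic for fixed input; animals too short for a given window are
    retained as failed detections (see
    :func:`weightband.evaluation.detect_and_classify`).
    """
    windows = tuple(int(w) for w in (windows if windows is not None else default_windows()))
    widths = tuple(float(k) for k in (widths if widths is not None else default_widths()))
    if not windows or not widths:
        raise ValidationError("grid ranges must be non-empty")

    entries: dict[tuple[int, float, str], EvaluationSummary] = {}
    for w in windows:
        for k in widths:
            config = DetectorConfig(
                window_size=w, width_factor=k, mode=mode,
                score_narrowing_unit=score_unit,
            )
            reports = [r.report for r in detect_and_classify(cohort, config)]
            entries[(w, k, mode)] = evaluate_cohort(reports)
    return GridResult(entries=entries, windows=windows, widths=widths, mode=mode)


def select_parameters(grid: GridResult) -> tuple[int, float]:
    """Two-stage parameter selection on a completed grid.

    Stage 1 picks the window size whose mean false-alarm count, averaged over
    all width-factors, is smallest (ties broken toward the smaller window).
    Stage 2, at that window, picks the largest width-factor achieving the
    maximum endpoint detection rate (ties resolved toward wider bands, i.e.
    fewer false alarms).
    """
    if not grid.entries:
        raise ValidationError("cannot select parameters from an empty grid")

    best_window = None
    best_fa = np.inf
    for w in sorted(grid.windows):
        fa = np.mean([grid.summary(w, k).mean_false_alarms for k in grid.widths])
        if fa < best_fa:  # strict: ties keep the smaller (earlier) window
            best_fa = fa
            best_window = w

    edrs = {k: grid.summary(best_window, k).edr for k in grid.widths}
    max_edr = max(edrs.values())
    best_width = max(k for k, e in edrs.items() if e == max_edr)
    logger.info(
        "selected window=%d (avg false alarms %.3f), width=%.2f (EDR %.3f)",
        best_window, best_fa, best_width, max_edr,
    )
    return best_window, best_width
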