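"""High-level modelling interface: fit the detector on a training cohort,
inspect the fitted parameters, and apply them to new cohorts.

:class:`EndpointDetector` wraps the lower-level modules in the familiar
model/results idiom: the model is constructed from data (a :class:`Cohort`,
a long-format DataFrame or a CSV path), ``fit()`` performs the grid-search
estimation of the window size and width-factor on that cohort, and the
returned :class:`EndpointDetectorResults` carries the fitted parameters, the
full grid, the per-animal detections and a ``summary()`` table, plus
``evaluate()`` for held-out (validation) cohorts and per-animal boundary
plots.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from . import io as wio
from .datamodel import Cohort, DetectorConfig, ValidationError
from .evaluation import (
    DetectionResult,
    EvaluationSummary,
    detect_and_classify,
    evaluate_cohort,
)
from .optimization import GridResult, grid_search, select_parameters

__all__ = ["EndpointDetector", "EndpointDetectorResults"]


class EndpointDetector:
    """Adaptive control-band endpoint detector for a cohort of weight courses.

    Parameters
    ----------
    cohort
        Training data: one weight course per animal.
    mode
        Detector mode used for fitting and evaluation: ``"regular"``,
        ``"mad"`` or ``"score"``.
    score_narrowing_unit
        Lower-boundary narrowing per clinical-score point (percentage points
        of normalized weight); score mode only.

    Examples
    --------
    >>> from weightband import EndpointDetector, simulate_cohort, study_like_config
    >>> train = simulate_cohort(study_like_config("training"))
    >>> res = EndpointDetector(train).fit()
    >>> res.window_size, res.width_factor  # doctest: +SKIP
    (2, 3.0)
    """

    def __init__(
        self,
        cohort: Cohort,
        mode: str = "regular",
        score_narrowing_unit: float = 1.0,
    ) -> None:
        # constructing a throwaway config validates mode/unit early
        DetectorConfig(mode=mode, score_narrowing_unit=score_narrowing_unit)
        self.cohort = cohort
        self.mode = mode
        self.score_narrowing_unit = score_narrowing_unit

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label: str = "", **kwargs
    ) -> "EndpointDetector":
        """Build from a long-format frame with the cohort CSV's columns."""
        import io as _io

        buf = _io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        return cls(wio.read_cohort_csv(buf, label=label), **kwargs)

    @classmethod
    def from_csv(cls, path, label: str = "", **kwargs) -> "EndpointDetector":
        return cls(wio.read_cohort_csv(path, label=label), **kwargs)

    def fit(
        self,
        windows: Optional[Sequence[int]] = None,
        widths: Optional[Sequence[float]] = None,
    ) -> "EndpointDetectorResults":
        """Grid-search the window size and width-factor on the cohort.

        Defaults cover windows 2-10 days and width-factors 0.5-3.0 in steps
        of 0.25.
        """
        grid = grid_search(
            self.cohort,
            windows=windows,
            widths=widths,
            mode=self.mode,
            score_unit=self.score_narrowing_unit,
        )
        window, width = select_parameters(grid)
        return EndpointDetectorResults(self, grid, window, width)

    def run(self, config: DetectorConfig) -> list[DetectionResult]:
        """Run the detector at explicit parameters (no fitting)."""
        return detect_and_classify(self.cohort, config)


class EndpointDetectorResults:
    """Fitted detector parameters plus diagnostics on the training cohort."""

    def __init__(
        self,
        model: EndpointDetector,
        grid: GridResult,
        window_size: int,
        width_factor: float,
    ) -> None:
        self.model = model
        self.grid = grid
        self.window_size = window_size
        self.width_factor = width_factor
        self.config = DetectorConfig(
            window_size=window_size,
            width_factor=width_factor,
            mode=model.mode,
            score_narrowing_unit=model.score_narrowing_unit,
        )
        self.detections: list[DetectionResult] = model.run(self.config)
        self.training_summary: EvaluationSummary = evaluate_cohort(
            [d.report for d in self.detections]
        )

    def evaluate(self, cohort: Cohort) -> EvaluationSummary:
        """Apply the fitted parameters to a held-out cohort."""
        results = detect_and_classify(cohort, self.config)
        return evaluate_cohort([r.report for r in results])

    def grid_frame(self) -> pd.DataFrame:
        return self.grid.to_frame()

    def summary(self) -> str:
        """Plain-text summary in the spirit of a regression results table."""
        s = self.training_summary
        lines = [
            "Endpoint control-band detector",
            "=" * 46,
            f"{'cohort':<28}{self.model.cohort.label or '<unlabelled>':>18}",
            f"{'animals (n)':<28}{s.n:>18d}",
            f"{'mode':<28}{self.model.mode:>18}",
            f"{'window size (days)':<28}{self.window_size:>18d}",
            f"{'width-factor (SD units)':<28}{self.width_factor:>18.2f}",
            "-" * 46,
            f"{'endpoint detection rate':<28}{s.edr:>18.2f}",
            f"{'failed detections':<28}{s.failed_detections:>18d}",
            f"{'mean false alarms':<28}{s.mean_false_alarms:>18.2f}",
            f"{'adjusted false alarms':<28}{s.adjusted_mean_false_alarms:>18.2f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot_course(self, animal_id: str, ax=None):
        """Plot one animal's normalized course, boundaries and alarms."""
        import matplotlib.pyplot as plt

        for det in self.detections:
            if det.report.animal_id == animal_id:
                break
        else:
            raise KeyError(animal_id)
        if det.boundaries is None:
            raise ValidationError(
                f"animal {animal_id!r} has no evaluable days at window "
                f"{self.window_size}"
            )
        if ax is None:
            _, ax = plt.subplots()
        nc, b = det.ncourse, det.boundaries
        ax.plot(nc.days, nc.weight_pct, "o-", color="black", label="weight (%)")
        ax.plot(b.days, b.lower, "--", color="tab:blue", label="boundaries")
        ax.plot(b.days, b.upper, "--", color="tab:blue")
        alarms = sorted(det.report.alarm_days)
        if alarms:
            pct = dict(zip(nc.days, nc.weight_pct))
            ax.plot(
                alarms, [pct[d] for d in alarms], "x", color="tab:pink",
                markersize=10, mew=2, label="alarm",
            )
        ax.set_xlabel("day after injection")
        ax.set_ylabel("body weight (% of start)")
        ax.set_title(f"{animal_id} (window {self.window_size}, width {self.width_factor})")
        ax.legend()
        return ax
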