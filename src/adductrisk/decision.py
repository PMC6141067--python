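"""Decision thresholding: turn risk scores into class labels.

A subject with score ``f >= t`` is called a case.  Rather than fixing
``t = 0.5``, the operating threshold is chosen by scanning the grid
``t = 0.00, 0.01, ..., 1.00`` for the minimum training error rate; when a
whole range ``[t_min, t_max]`` of grid thresholds attains the minimum, the
midpoint ``t_opt = (t_min + t_max) / 2`` is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["THRESHOLD_GRID", "ThresholdScan", "classify", "error_rate", "select_threshold"]

logger = logging.getLogger(__name__)

#: The fixed 101-point scan grid, 0.00 to 1.00 in steps of 0.01.
THRESHOLD_GRID: np.ndarray = np.arange(101) / 100.0
THRESHOLD_GRID.setflags(write=False)


def classify(scores: np.ndarray, t: float) -> np.ndarray:
    """Label scores against a threshold: 1 where ``score >= t``, else 0."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {t}")
    scores = np.asarray(scores, dtype=float)
    return (scores >= t).astype(int)


def error_rate(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Fraction of misclassified subjects."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual labels must have equal length")
    if predicted.size == 0:
        raise ValueError("empty label vectors")
    return float(np.mean(predicted != actual))


@dataclass(frozen=True)
class ThresholdScan:
    """Error rate at every grid threshold plus the selected operating point.

    ``t_min`` / ``t_max`` are the smallest and largest grid thresholds
    attaining ``min_error``; ``t_opt`` is their midpoint.
    """

    grid: np.ndarray
    error_by_t: np.ndarray
    min_error: float
    t_min: float
    t_max: float
    t_opt: float

    def to_table(self) -> str:
        """Two-column ``t<TAB>error`` text plus a summary line."""
        lines = ["t\terror"]
        lines += [f"{t:.2f}\t{e:.6f}" for t, e in zip(self.grid, self.error_by_t)]
        lines.append(
            f"# min_error={self.min_error:.6f} t_min={self.t_min:.2f} "
            f"t_max={self.t_max:.2f} t_opt={self.t_opt:.4f}"
        )
        return "\n".join(lines) + "\n"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_table())


def select_threshold(scores: np.ndarray, actual: np.ndarray) -> ThresholdScan:
    """Scan the 0.01-step grid for the minimum-training-error threshold.

    Both classes must be present in ``actual``.  Ties over a contiguous
    range of thresholds resolve to the range midpoint; if the attaining
    set is non-contiguous the extremes are still reported but the midpoint
    may not attain the minimum, and a warning is logged.
    """
    scores = np.asarray(scores, dtype=float)
    actual = np.asarray(actual)
    if scores.shape != actual.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(actual)) < 2:
        raise ValueError("threshold selection requires both classes")

    predictions = scores[None, :] >= THRESHOLD_GRID[:, None]  # (101, n)
    error_by_t = np.mean(predictions != (actual == 1)[None, :], axis=1)
    min_error = float(error_by_t.min())
    attaining = np.flatnonzero(error_by_t == min_error)
    if not np.array_equal(attaining, np.arange(attaining[0], attaining[-1] + 1)):
        logger.warning(
            "minimum-error thresholds form a non-contiguous set; "
            "the midpoint t_opt may not attain the minimum error"
        )
    t_min = float(THRESHOLD_GRID[attaining[0]])
    t_max = float(THRESHOLD_GRID[attaining[-1]])
    return ThresholdScan(
        grid=THRESHOLD_GRID.copy(),
        error_by_t=error_by_t,
        min_error=min_error,
        t_min=t_min,
        t_max=t_max,
        t_opt=(t_min + t_max) / 2.0,
    )
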