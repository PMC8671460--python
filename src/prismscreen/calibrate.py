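"""Threshold calibration on logFC against a biomarker-defined ground truth.

A cell line is predicted "sensitive" when its logFC is strictly below the
candidate threshold.  Against a binary biomarker label (1 = expected
responder) this yields a confusion matrix per threshold; the calibrated
cutoff maximizes Youden's index J = sensitivity + specificity - 1 over the
threshold grid, with ties broken toward the threshold of smallest absolute
value (the most conservative call rate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CalibrationCurve", "confusion_at_threshold", "youden_scan"]


@dataclass
class CalibrationCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    youden: np.ndarray
    chosen_threshold: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "youden": self.youden,
            }
        )


def _as_arrays(values, labels) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be aligned 1-D sequences")
    if y.min() == y.max():
        raise ValueError("labels contain a single class; sensitivity or specificity undefined")
    return v, y


def confusion_at_threshold(values, labels, t: float) -> tuple[int, int, int, int]:
    """Confusion counts (tp, fp, tn, fn) at threshold ``t``.

    Predicted positive (sensitive) iff value < t — a value exactly equal to
    the threshold is predicted negative.
    """
    v, y = _as_arrays(values, labels)
    pred = v < t
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return tp, fp, tn, fn


def youden_scan(values, labels, grid=None) -> CalibrationCurve:
    """Scan candidate thresholds and choose the Youden-optimal cutoff.

    ``grid`` defaults to the sorted unique observed values plus -1 (the
    conventional single-dose killing cutoff).  Among thresholds tied at the
    maximal J the one of smallest |t| wins (then the smaller t, for
    determinism).
    """
    v, y = _as_arrays(values, labels)
    if grid is None:
        grid = np.unique(np.append(np.unique(v), -1.0))
    grid = np.asarray(sorted(set(float(t) for t in np.asarray(grid, dtype=float))))
    if grid.size == 0:
        raise ValueError("threshold grid is empty")

    sens = np.empty(grid.size)
    spec = np.empty(grid.size)
    for i, t in enumerate(grid):
        tp, fp, tn, fn = confusion_at_threshold(v, y, t)
        sens[i] = tp / (tp + fn)
        spec[i] = tn / (tn + fp)
    youden = sens + spec - 1.0

    best = youden.max()
    tied = np.flatnonzero(np.isclose(youden, best))
    order = sorted(tied, key=lambda i: (abs(grid[i]), grid[i]))
    chosen = float(grid[order[0]])
    return CalibrationCurve(grid, sens, spec, youden, chosen)
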