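"""Discriminant-analysis wrapper: dummy coding and the R²/Q² diagnostics.

PLS-DA regresses a 0/1 dummy variable on X.  Fit quality on the calibration
samples is R²; the same quantity computed from predictions of samples the
model never saw (cross-validation folds or a test set) is Q².  A large gap
R² ≫ Q² is the overfitting signature that makes calibrated score plots
untrustworthy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import UserInputError


@dataclass(frozen=True)
class LabelEncoding:
    """Invertible two-class dummy coding, levels in sorted order -> {0, 1}."""

    levels: tuple[str, str]

    def to_values(self, labels) -> np.ndarray:
        labels = [str(v) for v in labels]
        bad = sorted(set(labels) - set(self.levels))
        if bad:
            raise UserInputError(f"unknown class label(s) {bad}; expected {self.levels}")
        lookup = {self.levels[0]: 0.0, self.levels[1]: 1.0}
        return np.array([lookup[v] for v in labels])


def encode_labels(labels) -> tuple[np.ndarray, LabelEncoding]:
    """Map a two-level label vector to a {0, 1} dummy response.

    Levels are assigned deterministically in sorted order; more or fewer than
    two levels is an error (multi-class DA is out of scope).
    """
    labels = [str(v) for v in np.asarray(labels).ravel()]
    levels = sorted(set(labels))
    if len(levels) != 2:
        raise UserInputError(
            f"need exactly 2 class levels, got {len(levels)}: {levels[:5]}"
        )
    encoding = LabelEncoding(levels=(levels[0], levels[1]))
    return encoding.to_values(labels), encoding


def classify(yhat, encoding: LabelEncoding) -> list[str]:
    """Assign class labels by thresholding at the dummy midpoint (0.5).

    Ties go to the lower-coded class.
    """
    yhat = np.asarray(yhat, dtype=float).ravel()
    return [encoding.levels[1] if v > 0.5 else encoding.levels[0] for v in yhat]


def r_squared(y, yhat) -> float:
    """1 - SS_res/SS_tot with SS_tot around the evaluated set's own mean."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise UserInputError(f"length mismatch: {y.size} vs {yhat.size}")
    if y.size < 2:
        raise UserInputError("need at least 2 values")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise UserInputError("total sum of squares is zero; R2 undefined")
    return 1.0 - float(((y - yhat) ** 2).sum()) / ss_tot


def q_squared(y_held_out, yhat_held_out, y_train_mean: float) -> float:
    """1 - PRESS / SS around the calibration mean.

    For cross-validation, PRESS pools the prediction residuals of all folds
    and ``y_train_mean`` is the full calibration mean (the standard PRESS
    convention); for a test set it is the calibration mean as well.
    """
    y = np.asarray(y_held_out, dtype=float).ravel()
    yhat = np.asarray(yhat_held_out, dtype=float).ravel()
    if y.size != yhat.size:
        raise UserInputError(f"length mismatch: {y.size} vs {yhat.size}")
    if y.size < 2:
        raise UserInputError("need at least 2 held-out values")
    ss = float(((y - y_train_mean) ** 2).sum())
    if ss == 0:
        raise UserInputError("denominator sum of squares is zero; Q2 undefined")
    press = float(((y - yhat) ** 2).sum())
    return 1.0 - press / ss


@dataclass
class FitMetrics:
    """R²/Q² bundle for one fitted model (one repetition of a study)."""

    r2: float
    q2_cv: float | None = None
    q2_test: float | None = None
    per_component_x_variance: np.ndarray = field(default_factory=lambda: np.zeros(0))
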