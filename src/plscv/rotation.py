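"""Cross-validated scores with Procrustes rotation toward the overall model.

Bilinear models are only defined up to a rotation (and sign) of their latent
basis, so scores from different cross-validation segments live in slightly
different, arbitrarily oriented frames.  Comparing or pooling them naively
mixes those frames and makes validated score plots look worse than they are.
The repair: fit one overall model on all calibration samples, rotate every
segment model's loading matrix toward the overall loadings (orthogonal or
oblique Procrustes), and apply the counter-rotation to the segment's scores —
including the scores of the held-out samples.  Pooling the counter-rotated
held-out scores row by row yields a validated score matrix directly
comparable to the calibrated one.

The counter-rotation is T (R')^-1, chosen so that the segment reconstruction
T P' is exactly invariant under the rotation pair; for an orthogonal R this
simplifies to T R.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.model_selection import KFold, StratifiedKFold

from .da import FitMetrics, q_squared, r_squared
from .exceptions import (
    IllConditionedError,
    PlscvError,
    RankDeficiencyError,
    UserInputError,
)
from .pls import as_data_matrix, as_response, fit_pls, predict_response, predict_scores

#: counter-rotation refuses rotation matrices with condition number above this
MAX_ROTATION_COND = 1e8

ROTATION_MODES = ("oblique", "orthogonal", "none")
CV_SCHEMES = ("random_stratified", "contiguous")


# ---------------------------------------------------------------------------
# cross-validation plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CvPlan:
    """Fold assignment: sample i is held out in segment ``assignment[i]``."""

    n_segments: int
    assignment: np.ndarray
    scheme: str
    seed: int

    def __post_init__(self):
        a = np.asarray(self.assignment, dtype=int)
        object.__setattr__(self, "assignment", a)
        if self.n_segments < 2:
            raise UserInputError("need at least 2 cross-validation segments")
        counts = np.bincount(a, minlength=self.n_segments)
        if (counts == 0).any() or a.max() >= self.n_segments:
            raise UserInputError("every segment must hold out at least one sample")
        if counts.max() == a.size:
            raise UserInputError("a segment may not hold out every sample")


def make_cv_plan(y, n_segments: int = 10, scheme: str = "random_stratified",
                 seed: int = 0) -> CvPlan:
    """Assign samples to held-out segments.

    ``random_stratified`` (default) shuffles within class so each fold keeps
    the class ratio within one sample of the global ratio; ``contiguous``
    assigns consecutive blocks in sample order.
    """
    y = np.asarray(y)
    n = y.size
    if scheme not in CV_SCHEMES:
        raise UserInputError(f"unknown CV scheme {scheme!r}; choose from {CV_SCHEMES}")
    if not 2 <= n_segments <= n:
        raise UserInputError(
            f"n_segments={n_segments} outside valid range [2, {n}]"
        )
    assignment = np.empty(n, dtype=int)
    if scheme == "random_stratified":
        splitter = StratifiedKFold(n_splits=n_segments, shuffle=True, random_state=seed)
        groups = y.astype(str)
        if np.bincount(np.unique(groups, return_inverse=True)[1]).min() < n_segments:
            raise UserInputError(
                "stratified plan needs every class to have at least n_segments samples"
            )
        for k, (_, held) in enumerate(splitter.split(np.zeros((n, 1)), groups)):
            assignment[held] = k
    else:
        for k, (_, held) in enumerate(KFold(n_splits=n_segments).split(np.zeros((n, 1)))):
            assignment[held] = k
    return CvPlan(n_segments=n_segments, assignment=assignment, scheme=scheme, seed=seed)


# ---------------------------------------------------------------------------
# Procrustes rotations
# ---------------------------------------------------------------------------

@dataclass
class RotationResult:
    """An F x F rotation linking a segment's loading frame to the target."""

    rotation: np.ndarray
    mode: str
    target_loadings: np.ndarray
    segment_loadings: np.ndarray
    degenerate: bool = False


def _check_pair(P_seg, P_full):
    P_seg = np.asarray(P_seg, dtype=float)
    P_full = np.asarray(P_full, dtype=float)
    if P_seg.ndim != 2 or P_seg.shape != P_full.shape:
        raise UserInputError(
            f"loading matrices must share one J x F shape, got {P_seg.shape} "
            f"and {P_full.shape}"
        )
    return P_seg, P_full


def orthogonal_procrustes(P_seg, P_full) -> RotationResult:
    """Best orthogonal R minimizing ||P_seg R - P_full||_F.

    R = U V' from the SVD of P_seg' P_full.  A zero singular value makes the
    minimizer non-unique; the SVD solution is still returned but flagged
    ``degenerate`` with a warning.
    """
    P_seg, P_full = _check_pair(P_seg, P_full)
    M = P_seg.T @ P_full
    U, s, Vt = scipy.linalg.svd(M)
    degenerate = bool(s[-1] <= s[0] * np.finfo(float).eps * max(M.shape)) or s[0] == 0
    if degenerate:
        warnings.warn(
            "degenerate Procrustes problem (zero singular value); "
            "rotation is non-unique, returning the SVD solution",
            RuntimeWarning,
            stacklevel=2,
        )
    return RotationResult(rotation=U @ Vt, mode="orthogonal",
                          target_loadings=P_full, segment_loadings=P_seg,
                          degenerate=degenerate)


def oblique_procrustes(P_seg, P_full) -> RotationResult:
    """Least-squares R = pinv(P_seg) P_full; the package default mode."""
    P_seg, P_full = _check_pair(P_seg, P_full)
    F = P_seg.shape[1]
    rank = np.linalg.matrix_rank(P_seg)
    if rank < F:
        raise RankDeficiencyError(
            f"segment loadings are rank deficient: {F - rank} of {F} columns "
            "are linearly dependent"
        )
    R, *_ = scipy.linalg.lstsq(P_seg, P_full)
    return RotationResult(rotation=R, mode="oblique",
                          target_loadings=P_full, segment_loadings=P_seg)


def counter_rotate_scores(T, rotation) -> np.ndarray:
    """Apply the score-side counter-rotation T (R')^-1.

    Chosen so that scores-times-loadings is invariant: the counter-rotated
    scores with the rotated loadings reproduce T P_seg' exactly.  For an
    orthogonal R this equals T R.
    """
    R = rotation.rotation if isinstance(rotation, RotationResult) else np.asarray(rotation)
    T = np.atleast_2d(np.asarray(T, dtype=float))
    if T.shape[1] != R.shape[0] or R.shape[0] != R.shape[1]:
        raise UserInputError(
            f"scores with {T.shape[1]} columns incompatible with "
            f"{R.shape[0]}x{R.shape[1]} rotation"
        )
    cond = np.linalg.cond(R)
    if not np.isfinite(cond) or cond > MAX_ROTATION_COND:
        raise IllConditionedError(
            f"rotation matrix is ill-conditioned (condition number {cond:.3g})"
        )
    return T @ np.linalg.inv(R).T


# ---------------------------------------------------------------------------
# the full procedure
# ---------------------------------------------------------------------------

@dataclass
class ValidatedScores:
    """Cross-validated score matrix: row i comes from the fold holding out i."""

    scores: np.ndarray
    fold_of_sample: np.ndarray
    mode: str
    sample_ids: tuple[str, ...] = ()


def cross_validated_scores(X, y, n_components: int, plan: CvPlan | None = None,
                           mode: str = "oblique", preprocessing: str = "center",
                           n_segments: int = 10, seed: int = 0,
                           ) -> tuple[ValidatedScores, FitMetrics]:
    """Rotation-corrected cross-validated scores plus R²/Q²(CV).

    Procedure: (a) fit the overall model on all rows — its loadings are the
    rotation target; (b) per segment, refit on the retained rows only
    (preprocessing re-estimated on those rows, so no information leaks),
    rotate the segment loadings toward the target, project the held-out rows
    to scores and counter-rotate them into the overall frame; (c) pool the
    held-out predictions for Q²(CV) with the full-calibration mean in the
    denominator.

    ``mode="none"`` skips the rotation (R forced to identity) — useful only to
    demonstrate the frame inconsistencies that rotation repairs.
    """
    dm = as_data_matrix(X)
    I = dm.shape[0]
    y = as_response(y, I)
    if mode not in ROTATION_MODES:
        raise UserInputError(f"unknown rotation mode {mode!r}; choose from {ROTATION_MODES}")
    if plan is None:
        plan = make_cv_plan(y, n_segments=n_segments, seed=seed)
    if plan.assignment.size != I:
        raise UserInputError(
            f"plan covers {plan.assignment.size} samples, data has {I}"
        )

    overall = fit_pls(dm, y, n_components, preprocessing)
    F = overall.n_components
    scores = np.full((I, F), np.nan)
    yhat_held_out = np.full(I, np.nan)

    for seg in range(plan.n_segments):
        held = np.flatnonzero(plan.assignment == seg)
        kept = np.flatnonzero(plan.assignment != seg)
        try:
            seg_model = fit_pls(dm.take(kept), y[kept], n_components, preprocessing)
            if mode == "oblique":
                rot = oblique_procrustes(seg_model.loadings, overall.loadings)
            elif mode == "orthogonal":
                rot = orthogonal_procrustes(seg_model.loadings, overall.loadings)
            else:
                rot = RotationResult(np.eye(F), "none", overall.loadings,
                                     seg_model.loadings)
            T_held = predict_scores(seg_model, dm.take(held))
            scores[held] = counter_rotate_scores(T_held, rot)
            yhat_held_out[held] = predict_response(seg_model, dm.take(held))
        except PlscvError as err:
            raise PlscvError(f"cross-validation segment {seg + 1} failed: {err}") from err

    metrics = FitMetrics(
        r2=r_squared(y, predict_response(overall, dm)),
        q2_cv=q_squared(y, yhat_held_out, float(y.mean())),
        per_component_x_variance=overall.x_variance_per_component,
    )
    validated = ValidatedScores(scores=scores, fold_of_sample=plan.assignment.copy(),
                                mode=mode, sample_ids=dm.sample_ids)
    return validated, metrics
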