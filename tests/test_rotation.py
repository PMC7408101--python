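import numpy as np
import pytest
import scipy.linalg
from numpy.testing import assert_allclose

from plscv import (
    IllConditionedError,
    RankDeficiencyError,
    UserInputError,
    counter_rotate_scores,
    cross_validated_scores,
    encode_labels,
    fit_pls,
    make_cv_plan,
    oblique_procrustes,
    orthogonal_procrustes,
)
from plscv.da import q_squared
from plscv.pls import predict_response


# ---------------------------------------------------------------------------
# cross-validation plans
# ---------------------------------------------------------------------------

def test_stratified_plan_balances_classes(rng):
    y = np.array([0, 1] * 20)
    plan = make_cv_plan(y, n_segments=5, seed=3)
    global_ratio = y.mean()
    for seg in range(5):
        held = y[plan.assignment == seg]
        assert abs(held.sum() - global_ratio * held.size) <= 1
    counts = np.bincount(plan.assignment, minlength=5)
    assert counts.sum() == y.size and counts.min() > 0


def test_contiguous_plan_is_blockwise():
    y = np.zeros(12)
    plan = make_cv_plan(y, n_segments=3, scheme="contiguous", seed=0)
    assert_allclose(plan.assignment, np.repeat([0, 1, 2], 4))


def test_plan_validation():
    with pytest.raises(UserInputError):
        make_cv_plan(np.array([0, 1, 0, 1]), n_segments=1)
    with pytest.raises(UserInputError):
        make_cv_plan(np.array([0, 1, 0, 1]), n_segments=3)  # class smaller than K
    with pytest.raises(UserInputError, match="scheme"):
        make_cv_plan(np.zeros(10), n_segments=2, scheme="bogus")


# ---------------------------------------------------------------------------
# Procrustes rotations
# ---------------------------------------------------------------------------

def test_identical_loadings_give_identity_rotation(rng):
    P = rng.normal(size=(6, 3))
    for fn in (orthogonal_procrustes, oblique_procrustes):
        assert_allclose(fn(P, P).rotation, np.eye(3), atol=1e-10)


def test_sign_switch_is_repaired_by_diagonal_rotation(rng):
    P = rng.normal(size=(6, 2))
    P_seg = P * np.array([-1.0, 1.0])
    for fn in (orthogonal_procrustes, oblique_procrustes):
        assert_allclose(fn(P_seg, P).rotation, np.diag([-1.0, 1.0]), atol=1e-10)


def _planar_orthogonal_misfit(P_seg, P_full, n_grid=20000):
    """Brute-force minimum over planar rotations and sign flips (2-D case)."""
    best = np.inf
    for theta in np.linspace(0, 2 * np.pi, n_grid, endpoint=False):
        c, s = np.cos(theta), np.sin(theta)
        for refl in (1.0, -1.0):
            R = np.array([[c, -s * refl], [s, c * refl]])
            best = min(best, np.linalg.norm(P_seg @ R - P_full))
    return best


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_orthogonal_rotation_matches_grid_search_oracle(seed):
    rng = np.random.default_rng(seed)
    P_seg = rng.normal(size=(6, 2))
    P_full = rng.normal(size=(6, 2))
    result = orthogonal_procrustes(P_seg, P_full)
    misfit = np.linalg.norm(P_seg @ result.rotation - P_full)
    assert misfit <= _planar_orthogonal_misfit(P_seg, P_full) + 1e-6
    # and agrees with the reference SVD solver
    R_ref, _ = scipy.linalg.orthogonal_procrustes(P_seg, P_full)
    assert_allclose(result.rotation, R_ref, atol=1e-10)
    assert_allclose(result.rotation.T @ result.rotation, np.eye(2), atol=1e-10)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_oblique_rotation_matches_per_column_regression(seed):
    rng = np.random.default_rng(seed)
    P_seg = rng.normal(size=(8, 3))
    P_full = rng.normal(size=(8, 3))
    result = oblique_procrustes(P_seg, P_full)
    for col in range(3):
        beta, *_ = np.linalg.lstsq(P_seg, P_full[:, col], rcond=None)
        assert_allclose(result.rotation[:, col], beta, atol=1e-10)


def test_square_oblique_solve_is_exact(rng):
    P_seg = rng.normal(size=(3, 3))
    P_full = rng.normal(size=(3, 3))
    R = oblique_procrustes(P_seg, P_full).rotation
    assert_allclose(P_seg @ R, P_full, atol=1e-9)


def test_oblique_rejects_rank_deficient_segment(rng):
    P = rng.normal(size=(6, 3))
    P[:, 2] = P[:, 0] + P[:, 1]
    with pytest.raises(RankDeficiencyError, match="1 of 3"):
        oblique_procrustes(P, rng.normal(size=(6, 3)))


def test_degenerate_orthogonal_problem_warns(rng):
    P_seg = np.zeros((4, 2))
    P_seg[:, 0] = rng.normal(size=4)
    with pytest.warns(RuntimeWarning, match="degenerate"):
        result = orthogonal_procrustes(P_seg, rng.normal(size=(4, 2)))
    assert result.degenerate


# ---------------------------------------------------------------------------
# counter-rotation
# ---------------------------------------------------------------------------

def test_counter_rotation_special_cases(rng):
    T = rng.normal(size=(5, 2))
    assert_allclose(counter_rotate_scores(T, np.eye(2)), T, atol=1e-12)
    flipped = counter_rotate_scores(T, np.diag([-1.0, 1.0]))
    assert_allclose(flipped[:, 0], -T[:, 0], atol=1e-12)
    assert_allclose(flipped[:, 1], T[:, 1], atol=1e-12)


@pytest.mark.parametrize("seed", range(10))
def test_counter_rotation_preserves_reconstruction(seed):
    """Rotated loadings with counter-rotated scores leave T P' unchanged."""
    rng = np.random.default_rng(seed)
    T = rng.normal(size=(7, 3))
    P_seg = rng.normal(size=(9, 3))
    P_full = rng.normal(size=(9, 3))
    for fn in (orthogonal_procrustes, oblique_procrustes):
        result = fn(P_seg, P_full)
        T_rot = counter_rotate_scores(T, result)
        recon = T_rot @ (P_seg @ result.rotation).T
        assert np.linalg.norm(recon - T @ P_seg.T) < 1e-10 * np.linalg.norm(T @ P_seg.T)


def test_counter_rotation_rejects_singular_rotation(rng):
    T = rng.normal(size=(4, 2))
    with pytest.raises(IllConditionedError):
        counter_rotate_scores(T, np.array([[1.0, 1.0], [1.0, 1.0]]))


# ---------------------------------------------------------------------------
# the full cross-validated-score procedure
# ---------------------------------------------------------------------------

def test_leave_one_out_on_noiseless_data_matches_calibrated(cal_xy):
    """Without noise there is nothing to overfit: validated ~= calibrated."""
    X_cal, y, _ = cal_xy
    n = X_cal.shape[0]
    plan = make_cv_plan(y, n_segments=n, scheme="contiguous", seed=0)
    validated, _ = cross_validated_scores(X_cal, y, 2, plan=plan)
    calibrated = fit_pls(X_cal, y, 2).scores
    rel_dev = np.linalg.norm(validated.scores - calibrated) / np.linalg.norm(calibrated)
    assert rel_dev < 0.05


def test_q2_matches_independent_fold_loop(cal_xy):
    """Pooled Q2 equals a hand-rolled CV loop with per-fold refitting."""
    X_cal, y, _ = cal_xy
    plan = make_cv_plan(y, n_segments=5, seed=11)
    _, metrics = cross_validated_scores(X_cal, y, 2, plan=plan)
    yhat = np.empty_like(y)
    for seg in range(5):
        held = np.flatnonzero(plan.assignment == seg)
        kept = np.flatnonzero(plan.assignment != seg)
        model = fit_pls(X_cal.take(kept), y[kept], 2)
        yhat[held] = predict_response(model, X_cal.take(held))
    assert metrics.q2_cv == pytest.approx(q_squared(y, yhat, y.mean()), abs=1e-12)


def test_rotation_repairs_fold_frame_inconsistency(cal_xy):
    """Without rotation at least one fold's scores point the wrong way;
    with oblique rotation every fold agrees with the overall frame."""
    X_cal, y, _ = cal_xy
    plan = make_cv_plan(y, n_segments=10, seed=7)
    calibrated = fit_pls(X_cal, y, 2).scores
    raw, _ = cross_validated_scores(X_cal, y, 2, plan=plan, mode="none")
    rotated, _ = cross_validated_scores(X_cal, y, 2, plan=plan, mode="oblique")

    def fold_correlations(scores):
        out = []
        for seg in range(plan.n_segments):
            rows = np.flatnonzero(plan.assignment == seg)
            for col in range(2):
                out.append(np.corrcoef(scores[rows, col], calibrated[rows, col])[0, 1])
        return np.asarray(out)

    assert fold_correlations(raw.scores).min() < 0
    assert fold_correlations(rotated.scores).min() > 0
    for col in range(2):
        assert np.corrcoef(rotated.scores[:, col], calibrated[:, col])[0, 1] > 0.99


def test_oblique_and_orthogonal_modes_agree(cal_xy):
    """The choice of rotation matters far less than doing a rotation at all."""
    X_cal, y, _ = cal_xy
    plan = make_cv_plan(y, n_segments=10, seed=7)
    oblique, _ = cross_validated_scores(X_cal, y, 2, plan=plan, mode="oblique")
    orthogonal, _ = cross_validated_scores(X_cal, y, 2, plan=plan, mode="orthogonal")
    for col in range(2):
        corr = np.corrcoef(oblique.scores[:, col], orthogonal.scores[:, col])[0, 1]
        assert abs(corr) > 0.9


def test_every_row_filled_once(cal_xy):
    X_cal, y, _ = cal_xy
    validated, _ = cross_validated_scores(X_cal, y, 2, n_segments=8, seed=2)
    assert np.isfinite(validated.scores).all()
    assert validated.scores.shape == (X_cal.shape[0], 2)
    assert set(validated.fold_of_sample) == set(range(8))
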