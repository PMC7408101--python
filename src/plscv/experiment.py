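"""Repeated-resampling study: metrics, separation statistics and figures.

One repetition draws a fresh dataset (or calibration/test split), fits
PLS-DA and OPLS-DA on the calibration samples, computes rotation-corrected
cross-validated scores, and records R², Q²(CV), Q²(test) together with a
class-separation statistic for each of the four score-plot variants
(calibrated PLS, calibrated OPLS, cross-validated PLS, test-set PLS).
Repeating quantifies the spread of those numbers, which single bar charts
hide.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .da import encode_labels, q_squared
from .exceptions import UserInputError
from .opls import fit_opls
from .pls import DataMatrix, as_data_matrix, fit_pls, predict_response, predict_scores
from .rotation import cross_validated_scores, make_cv_plan
from .simulate import SimConfig, generate, split, with_seed

logger = logging.getLogger(__name__)

#: per-repetition seeds: rep k of a study with master seed m uses this rule
SEED_MULTIPLIER = 1_000_003
SEED_MODULUS = 2_147_483_647


def repetition_seed(master_seed: int, repetition: int) -> int:
    return (int(master_seed) * SEED_MULTIPLIER + int(repetition)) % SEED_MODULUS


@dataclass
class RepetitionRecord:
    repetition_id: int
    seed: int
    r2_cal_pls: float
    q2_cv: float
    q2_test: float
    sep_calibrated_pls: float
    sep_calibrated_opls: float
    sep_cross_validated: float
    sep_test: float


def separation_stat(scores, labels) -> float:
    """Between-class over within-class scatter in the plotted score plane.

    Squared distance between the class means divided by the pooled
    within-class variance (total, over the plotted dimensions).  Zero for
    identical class clouds; grows with separation.  Not affine-invariant on
    purpose: it measures what the eye sees in a given score plot.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 1:
        scores = scores.T
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if levels.size != 2:
        raise UserInputError(f"separation statistic needs 2 classes, got {levels.size}")
    a = scores[labels == levels[0]]
    b = scores[labels == levels[1]]
    if min(len(a), len(b)) < 2:
        raise UserInputError("each class needs at least 2 samples")
    d = a.mean(axis=0) - b.mean(axis=0)
    pooled = (((a - a.mean(axis=0)) ** 2).sum() + ((b - b.mean(axis=0)) ** 2).sum()) \
        / (len(a) + len(b) - 2)
    if pooled == 0:
        return float("inf") if d @ d > 0 else 0.0
    return float(d @ d / pooled)


def _plane(scores: np.ndarray) -> np.ndarray:
    """First two columns (or the single column) of a score matrix."""
    scores = np.atleast_2d(scores)
    return scores[:, : min(2, scores.shape[1])]


def _one_repetition(rep: int, seed: int, X_cal: DataMatrix, labels_cal,
                    X_test: DataMatrix, labels_test, n_components: int,
                    n_segments: int, rotation_mode: str,
                    preprocessing: str) -> RepetitionRecord:
    y_cal, encoding = encode_labels(labels_cal)
    y_test = encoding.to_values(labels_test)

    plan = make_cv_plan(y_cal, n_segments=n_segments, seed=seed)
    validated, metrics = cross_validated_scores(
        X_cal, y_cal, n_components, plan=plan, mode=rotation_mode,
        preprocessing=preprocessing,
    )
    pls = fit_pls(X_cal, y_cal, n_components, preprocessing)
    yhat_test = predict_response(pls, X_test)
    q2_test = q_squared(y_test, yhat_test, float(y_cal.mean()))
    T_test = predict_scores(pls, X_test)

    opls = fit_opls(X_cal, y_cal, n_orthogonal=n_components - 1,
                    preprocessing=preprocessing)
    if opls.n_orthogonal:
        opls_plane = np.column_stack([opls.predictive_scores,
                                      opls.orthogonal_scores[:, 0]])
    else:
        opls_plane = opls.predictive_scores[:, None]

    return RepetitionRecord(
        repetition_id=rep, seed=seed,
        r2_cal_pls=metrics.r2, q2_cv=metrics.q2_cv, q2_test=q2_test,
        sep_calibrated_pls=separation_stat(_plane(pls.scores), labels_cal),
        sep_calibrated_opls=separation_stat(opls_plane, labels_cal),
        sep_cross_validated=separation_stat(_plane(validated.scores), labels_cal),
        sep_test=separation_stat(_plane(T_test), labels_test),
    )


def run_simulation_study(config: SimConfig, n_repetitions: int,
                         n_components: int = 2, n_segments: int = 10,
                         rotation_mode: str = "oblique",
                         preprocessing: str = "center") -> list[RepetitionRecord]:
    """Repeat: draw data, split, fit, validate; one record per repetition.

    Deterministic under the master seed in ``config.seed``: repetition k uses
    ``repetition_seed(config.seed, k)`` for both the data draw and the CV
    plan.  A failed repetition is logged and skipped, never silent.
    """
    if n_repetitions < 1:
        raise UserInputError("n_repetitions must be >= 1")
    records: list[RepetitionRecord] = []
    for rep in range(n_repetitions):
        seed = repetition_seed(config.seed, rep)
        try:
            dataset = generate(with_seed(config, seed))
            X_cal, labels_cal, X_test, labels_test = split(dataset)
            records.append(_one_repetition(
                rep, seed, X_cal, labels_cal, X_test, labels_test,
                n_components, n_segments, rotation_mode, preprocessing,
            ))
        except Exception as err:  # noqa: BLE001 - record and continue
            logger.warning("repetition %d failed and was skipped: %s", rep, err)
    if not records:
        raise UserInputError("every repetition failed; see the log")
    return records


def run_external_study(X, labels, n_components: int, n_cal_per_class: int,
                       n_repetitions: int, n_segments: int = 10, seed: int = 0,
                       rotation_mode: str = "oblique",
                       preprocessing: str = "center") -> list[RepetitionRecord]:
    """Repeated balanced calibration/test splits of a user-supplied dataset.

    Each repetition draws ``n_cal_per_class`` samples per class at random for
    calibration; the remainder forms the test set, balanced by discarding a
    random surplus of the larger class.
    """
    dm = as_data_matrix(X)
    labels = np.asarray([str(v) for v in np.asarray(labels).ravel()])
    if labels.size != dm.shape[0]:
        raise UserInputError("label vector length does not match sample count")
    levels = np.unique(labels)
    if levels.size != 2:
        raise UserInputError(f"need exactly 2 classes, got {levels.size}")
    counts = {lv: int((labels == lv).sum()) for lv in levels}
    for lv, c in counts.items():
        if n_cal_per_class >= c:
            raise UserInputError(
                f"n_cal_per_class={n_cal_per_class} leaves no test samples for "
                f"class {lv!r} (size {c})"
            )
    records: list[RepetitionRecord] = []
    for rep in range(n_repetitions):
        rep_seed = repetition_seed(seed, rep)
        rng = np.random.default_rng(rep_seed)
        cal_idx, test_parts = [], []
        for lv in levels:
            members = np.flatnonzero(labels == lv)
            picked = rng.choice(members, size=n_cal_per_class, replace=False)
            cal_idx.append(picked)
            test_parts.append(np.setdiff1d(members, picked))
        keep = min(len(p) for p in test_parts)
        test_idx = np.concatenate([
            rng.choice(p, size=keep, replace=False) for p in test_parts
        ])
        cal = np.sort(np.concatenate(cal_idx))
        test = np.sort(test_idx)
        try:
            records.append(_one_repetition(
                rep, rep_seed, dm.take(cal), labels[cal], dm.take(test),
                labels[test], n_components, n_segments, rotation_mode,
                preprocessing,
            ))
        except Exception as err:  # noqa: BLE001
            logger.warning("repetition %d failed and was skipped: %s", rep, err)
    if not records:
        raise UserInputError("every repetition failed; see the log")
    return records


def records_to_frame(records: list[RepetitionRecord]) -> pd.DataFrame:
    """Tidy table, one row per repetition."""
    return pd.DataFrame([asdict(r) for r in records])


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

CLASS_COLORS = ("#1f77b4", "#d62728")


def _scatter_panel(ax, scores, labels, title, var_explained=None):
    scores = np.atleast_2d(scores)
    if scores.shape[1] == 1:
        scores = np.column_stack([scores[:, 0], np.zeros(len(scores))])
    levels = np.unique(np.asarray(labels))
    for lv, color in zip(levels, CLASS_COLORS):
        mask = np.asarray(labels) == lv
        ax.scatter(scores[mask, 0], scores[mask, 1], s=12, alpha=0.6,
                   color=color, label=str(lv), linewidths=0)
    xlab, ylab = "Component 1", "Component 2"
    if var_explained is not None and len(var_explained) >= 2:
        xlab += f" ({100 * var_explained[0]:.1f}% X-var)"
        ylab += f" ({100 * var_explained[1]:.1f}% X-var)"
    ax.set_xlabel(xlab)
    ax.set_ylabel(ylab)
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)


def render_panels(calibrated_pls, calibrated_opls, validated, test_scores,
                  labels_cal, labels_test, out_path,
                  var_explained=None) -> str:
    """Write the four-panel score-plot figure (2 x 2 grid).

    Panels: calibrated PLS, calibrated OPLS (predictive vs first orthogonal
    score), cross-validated PLS, test-set PLS.  With an empty test set a
    three-panel figure is written instead and a notice logged.
    """
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    have_test = test_scores is not None and len(np.atleast_1d(test_scores)) > 0
    if not have_test:
        logger.info("no test samples: rendering a three-panel figure")
    fig = Figure(figsize=(9, 8) if have_test else (12, 4.2), dpi=110)
    FigureCanvasAgg(fig)
    n_panels = 4 if have_test else 3
    shape = (2, 2) if have_test else (1, 3)
    axes = fig.subplots(*shape).ravel()
    _scatter_panel(axes[0], calibrated_pls, labels_cal,
                   "Calibrated PLS-DA scores", var_explained)
    _scatter_panel(axes[1], calibrated_opls, labels_cal,
                   "Calibrated OPLS-DA scores")
    axes[1].set_xlabel("Predictive component")
    axes[1].set_ylabel("Orthogonal component 1")
    _scatter_panel(axes[2], validated, labels_cal,
                   "Cross-validated PLS-DA scores", var_explained)
    if have_test:
        _scatter_panel(axes[3], test_scores, labels_test,
                       "Test-set PLS-DA scores", var_explained)
    fig.tight_layout()
    fig.savefig(out_path, metadata={"Software": None})
    logger.info("wrote %d-panel score figure to %s", n_panels, out_path)
    return str(out_path)


def render_metric_bars(records: list[RepetitionRecord], out_path) -> str:
    """Bar summary of R², Q²(CV), Q²(test): medians with interquartile bars."""
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    frame = records_to_frame(records)
    cols = ["r2_cal_pls", "q2_cv", "q2_test"]
    names = ["R² (calibration)", "Q² (cross-validation)", "Q² (test)"]
    med = frame[cols].median()
    lo = med - frame[cols].quantile(0.25)
    hi = frame[cols].quantile(0.75) - med

    fig = Figure(figsize=(5.5, 4), dpi=110)
    FigureCanvasAgg(fig)
    ax = fig.subplots()
    ax.bar(names, med, yerr=np.vstack([lo, hi]), capsize=4,
           color=["#555555", "#1f77b4", "#2ca02c"])
    ax.axhline(0, color="black", linewidth=0.8)
    ax.set_ylabel("Fraction of response variance")
    ax.set_title(f"Explained variance over {len(records)} repetitions "
                 "(median, IQR)")
    for tick in ax.get_xticklabels():
        tick.set_fontsize(8)
    fig.tight_layout()
    fig.savefig(out_path, metadata={"Software": None})
    logger.info("wrote metric bar figure to %s", out_path)
    return str(out_path)
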