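"""Single-response OPLS: one predictive component plus orthogonal components.

Orthogonal signal correction splits the systematic X-variation into a part
correlated with y (one predictive component, for a single response) and parts
orthogonal to y.  Each orthogonal round removes from the current X the
direction of its loading that is orthogonal to the predictive weight; the
predictive component is then fitted on the filtered X.  With zero orthogonal
components the model reduces exactly to one-component PLS, and with F-1
orthogonal components its predictions equal those of F-component PLS — the
two models reshuffle the same subspace, which is why the calibrated OPLS
score plot looks cleaner without being more predictive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ComponentNullError, UserInputError
from .pls import (
    NULL_COMPONENT_RTOL,
    Preprocessing,
    as_data_matrix,
    as_response,
    _orient_sign,
)


@dataclass
class OplsModel:
    predictive_scores: np.ndarray     # t_pred, length I
    predictive_loading: np.ndarray    # length J
    predictive_weight: np.ndarray     # length J, unit norm
    orthogonal_scores: np.ndarray     # I x K
    orthogonal_loadings: np.ndarray   # J x K
    orthogonal_weights: np.ndarray    # J x K, unit columns
    inner_regression: float
    preprocessing: Preprocessing
    y_mean: float = 0.0
    x_total_ss: float = 0.0

    @property
    def n_orthogonal(self) -> int:
        return self.orthogonal_scores.shape[1]

    @property
    def x_variance_per_component(self) -> np.ndarray:
        """X-variance fractions, predictive component first."""
        if self.x_total_ss == 0:
            return np.zeros(1 + self.n_orthogonal)
        parts = [(self.predictive_scores @ self.predictive_scores)
                 * (self.predictive_loading @ self.predictive_loading)]
        for k in range(self.n_orthogonal):
            t = self.orthogonal_scores[:, k]
            p = self.orthogonal_loadings[:, k]
            parts.append((t @ t) * (p @ p))
        return np.asarray(parts) / self.x_total_ss


def fit_opls(X, y, n_orthogonal: int, preprocessing: str = "center") -> OplsModel:
    """Fit a single-y OPLS model with ``n_orthogonal`` orthogonal components.

    The predictive weight is w = X'y (normalized); each orthogonal round takes
    w_orth proportional to p - (w'p) w from the current loading p, deflates X
    by the orthogonal component, and the final predictive component is fitted
    on the filtered X.
    """
    dm = as_data_matrix(X)
    I, J = dm.shape
    if I < 2:
        raise UserInputError(f"need at least 2 samples to fit, got {I}")
    y = as_response(y, I)
    n_orthogonal = int(n_orthogonal)
    if n_orthogonal < 0:
        raise UserInputError("n_orthogonal must be non-negative")
    if n_orthogonal > min(I - 2, J - 1):
        raise UserInputError(
            f"n_orthogonal={n_orthogonal} exceeds min(I-2, J-1)={min(I - 2, J - 1)}"
        )

    prep = Preprocessing.fit(dm.values, preprocessing)
    Xp = prep.apply(dm.values)
    y_mean = float(y.mean()) if prep.mode != "none" else 0.0
    yc = y - y_mean
    if np.allclose(yc, yc[0]):
        raise UserInputError("response is constant after centering; cannot fit OPLS")

    x_norm = np.linalg.norm(Xp)
    w = Xp.T @ yc
    w_norm = np.linalg.norm(w)
    if w_norm <= NULL_COMPONENT_RTOL * max(x_norm, 1.0):
        raise ComponentNullError(1, "X carries no covariance with y")
    w = w / w_norm
    w, _ = _orient_sign(w, np.zeros(1))

    Xd = Xp.copy()
    T_orth = np.empty((I, n_orthogonal))
    P_orth = np.empty((J, n_orthogonal))
    W_orth = np.empty((J, n_orthogonal))
    for k in range(n_orthogonal):
        t = Xd @ w
        tt = t @ t
        if tt == 0:
            raise ComponentNullError(k + 1, "predictive score vanished during filtering")
        p = Xd.T @ t / tt
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o <= NULL_COMPONENT_RTOL * max(np.linalg.norm(p), 1.0):
            raise ComponentNullError(
                k + 1, "orthogonal component is numerically null"
            )
        w_o = w_o / n_o
        t_o = Xd @ w_o
        w_o, t_o = _orient_sign(w_o, t_o)
        t_o_ss = t_o @ t_o
        if t_o_ss < (NULL_COMPONENT_RTOL * x_norm) ** 2:
            raise ComponentNullError(k + 1, "orthogonal score norm below tolerance")
        p_o = Xd.T @ t_o / t_o_ss
        Xd = Xd - np.outer(t_o, p_o)
        T_orth[:, k], P_orth[:, k], W_orth[:, k] = t_o, p_o, w_o

    t_pred = Xd @ w
    tt = t_pred @ t_pred
    if tt < (NULL_COMPONENT_RTOL * max(x_norm, 1.0)) ** 2:
        raise ComponentNullError(n_orthogonal + 1, "predictive component is null")
    p_pred = Xd.T @ t_pred / tt
    b = float(t_pred @ yc / tt)

    return OplsModel(
        predictive_scores=t_pred, predictive_loading=p_pred, predictive_weight=w,
        orthogonal_scores=T_orth, orthogonal_loadings=P_orth, orthogonal_weights=W_orth,
        inner_regression=b, preprocessing=prep, y_mean=y_mean,
        x_total_ss=x_norm ** 2,
    )


def predict_opls_scores(model: OplsModel, X_new) -> tuple[np.ndarray, np.ndarray]:
    """(t_pred, T_orth) for new samples, after sequential orthogonal filtering."""
    dm = as_data_matrix(X_new)
    if dm.shape[1] != model.predictive_weight.size:
        raise UserInputError(
            f"new data has {dm.shape[1]} variables, model expects "
            f"{model.predictive_weight.size}"
        )
    Xp = model.preprocessing.apply(dm.values)
    T_orth = np.empty((Xp.shape[0], model.n_orthogonal))
    for k in range(model.n_orthogonal):
        t_o = Xp @ model.orthogonal_weights[:, k]
        Xp = Xp - np.outer(t_o, model.orthogonal_loadings[:, k])
        T_orth[:, k] = t_o
    t_pred = Xp @ model.predictive_weight
    return t_pred, T_orth


def predict_opls_response(model: OplsModel, X_new) -> np.ndarray:
    t_pred, _ = predict_opls_scores(model, X_new)
    return t_pred * model.inner_regression + model.y_mean
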