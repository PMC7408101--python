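"""Single-response PLS regression (NIPALS) with explicit scores and loadings.

The bilinear model is

    X = T P' + E        (I x J data, I x F scores, J x F loadings)
    y = T b + e         (F x 1 inner regression vector)

fitted by NIPALS with X-deflation only, which for a single response converges
in one pass per component.  Preprocessing (column centering or autoscaling) is
estimated from the training rows and stored on the model so it can be
reapplied verbatim to new samples, which is what makes cross-validation
leak-free downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ComponentNullError, IllConditionedError, UserInputError

#: a component is rejected when its score norm falls below this fraction of
#: the preprocessed data norm
NULL_COMPONENT_RTOL = 1e-12

#: condition number above which P'W is treated as singular in projections
MAX_PROJECTION_COND = 1e12

PREPROCESSING_MODES = ("none", "center", "autoscale")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DataMatrix:
    """An I x J numeric matrix with sample and variable identifiers.

    Missing values are rejected: missing-data handling is out of scope.
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    variable_ids: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise UserInputError(f"data matrix must be 2-D, got {values.ndim}-D")
        if not np.isfinite(values).all():
            raise UserInputError("data matrix contains missing or non-finite entries")
        i, j = values.shape
        if i < 1:
            raise UserInputError("need at least 1 sample row")
        if j < 1:
            raise UserInputError("need at least 1 variable")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "variable_ids", tuple(str(v) for v in self.variable_ids))
        if len(self.sample_ids) != i:
            raise UserInputError(
                f"{len(self.sample_ids)} sample ids for {i} rows"
            )
        if len(self.variable_ids) != j:
            raise UserInputError(
                f"{len(self.variable_ids)} variable ids for {j} columns"
            )
        for name, ids in (("sample", self.sample_ids), ("variable", self.variable_ids)):
            if len(set(ids)) != len(ids):
                raise UserInputError(f"duplicate {name} ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def take(self, rows) -> "DataMatrix":
        """Row subset preserving identifiers."""
        rows = np.asarray(rows)
        return DataMatrix(
            self.values[rows],
            tuple(self.sample_ids[i] for i in rows),
            self.variable_ids,
        )

    @classmethod
    def from_dataframe(cls, frame) -> "DataMatrix":
        return cls(frame.to_numpy(dtype=float), tuple(map(str, frame.index)),
                   tuple(map(str, frame.columns)))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.sample_ids),
                            columns=list(self.variable_ids))


def as_data_matrix(X) -> DataMatrix:
    """Coerce an array-like or DataFrame to a :class:`DataMatrix`."""
    if isinstance(X, DataMatrix):
        return X
    if hasattr(X, "columns") and hasattr(X, "index"):
        return DataMatrix.from_dataframe(X)
    values = np.asarray(X, dtype=float)
    if values.ndim != 2:
        raise UserInputError(f"data matrix must be 2-D, got {values.ndim}-D")
    i, j = values.shape
    return DataMatrix(values,
                      tuple(f"s{k + 1}" for k in range(i)),
                      tuple(f"v{k + 1}" for k in range(j)))


def as_response(y, n_rows: int) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if y.size != n_rows:
        raise UserInputError(f"response length {y.size} does not match {n_rows} samples")
    if not np.isfinite(y).all():
        raise UserInputError("response contains missing or non-finite entries")
    return y


@dataclass(frozen=True)
class Preprocessing:
    """Column statistics estimated from training rows only."""

    mode: str
    column_means: np.ndarray | None = None
    column_scales: np.ndarray | None = None

    @classmethod
    def fit(cls, X: np.ndarray, mode: str) -> "Preprocessing":
        if mode not in PREPROCESSING_MODES:
            raise UserInputError(
                f"unknown preprocessing mode {mode!r}; choose from {PREPROCESSING_MODES}"
            )
        if mode == "none":
            return cls("none")
        means = X.mean(axis=0)
        if mode == "center":
            return cls("center", column_means=means)
        scales = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(scales == 0)
        if zero.size:
            raise UserInputError(
                f"autoscaling impossible: column(s) {', '.join(str(c + 1) for c in zero[:5])} "
                "have zero variance"
            )
        return cls("autoscale", column_means=means, column_scales=scales)

    def apply(self, X: np.ndarray) -> np.ndarray:
        if self.mode == "none":
            return np.asarray(X, dtype=float)
        Xp = X - self.column_means
        if self.mode == "autoscale":
            Xp = Xp / self.column_scales
        return Xp


@dataclass
class BilinearModel:
    """A fitted PLS model: X = T P' + E, y = T b + e (on preprocessed data)."""

    n_components: int
    scores: np.ndarray          # T, I x F
    loadings: np.ndarray        # P, J x F
    weights: np.ndarray         # W, J x F, unit columns
    inner_regression: np.ndarray  # b, length F
    response_residuals: np.ndarray  # e, length I
    x_residuals: np.ndarray     # E, I x J
    preprocessing: Preprocessing
    y_mean: float = 0.0
    x_total_ss: float = field(default=0.0, repr=False)
    sample_ids: tuple[str, ...] = ()
    variable_ids: tuple[str, ...] = ()

    @property
    def x_variance_per_component(self) -> np.ndarray:
        """Fraction of preprocessed-X variance captured by each component."""
        if self.x_total_ss == 0:
            return np.zeros(self.n_components)
        t_ss = (self.scores ** 2).sum(axis=0)
        p_ss = (self.loadings ** 2).sum(axis=0)
        return t_ss * p_ss / self.x_total_ss


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _orient_sign(w: np.ndarray, t: np.ndarray):
    """Make each weight vector's largest-magnitude entry positive.

    Deterministic orientation across platforms; flipping w flips t, and the
    loading/inner coefficients computed from the flipped t stay consistent.
    """
    if w[np.argmax(np.abs(w))] < 0:
        return -w, -t
    return w, t


def fit_pls(X, y, n_components: int, preprocessing: str = "center") -> BilinearModel:
    """Fit a single-response PLS model by NIPALS with X-deflation.

    Parameters
    ----------
    X : DataMatrix, DataFrame or 2-D array
    y : 1-D response (a centered dummy variable for DA use)
    n_components : number of latent components F, 1 <= F <= min(I-1, J)
    preprocessing : "none", "center" (default) or "autoscale"; the response is
        mean-centered whenever the mode is not "none"
    """
    dm = as_data_matrix(X)
    I, J = dm.shape
    if I < 2:
        raise UserInputError(f"need at least 2 samples to fit, got {I}")
    y = as_response(y, I)
    n_components = int(n_components)
    if not 1 <= n_components <= min(I - 1, J):
        raise UserInputError(
            f"n_components={n_components} outside valid range [1, {min(I - 1, J)}] "
            f"for a {I}x{J} matrix"
        )

    prep = Preprocessing.fit(dm.values, preprocessing)
    Xp = prep.apply(dm.values)
    y_mean = float(y.mean()) if prep.mode != "none" else 0.0
    yc = y - y_mean
    if np.allclose(yc, yc[0]):
        raise UserInputError("response is constant after centering; cannot fit PLS")

    x_norm = np.linalg.norm(Xp)
    x_total_ss = x_norm ** 2
    Xd = Xp.copy()
    T = np.empty((I, n_components))
    W = np.empty((J, n_components))
    P = np.empty((J, n_components))
    b = np.empty(n_components)

    for f in range(n_components):
        w = Xd.T @ yc
        w_norm = np.linalg.norm(w)
        if w_norm <= NULL_COMPONENT_RTOL * max(x_norm, 1.0):
            raise ComponentNullError(f + 1, "X carries no residual covariance with y")
        w = w / w_norm
        t = Xd @ w
        if np.linalg.norm(t) < NULL_COMPONENT_RTOL * x_norm:
            raise ComponentNullError(f + 1)
        w, t = _orient_sign(w, t)
        tt = t @ t
        p = Xd.T @ t / tt
        b[f] = (t @ yc) / tt
        Xd = Xd - np.outer(t, p)
        T[:, f], W[:, f], P[:, f] = t, w, p

    e = yc - T @ b
    return BilinearModel(
        n_components=n_components,
        scores=T, loadings=P, weights=W, inner_regression=b,
        response_residuals=e, x_residuals=Xd,
        preprocessing=prep, y_mean=y_mean, x_total_ss=x_total_ss,
        sample_ids=dm.sample_ids, variable_ids=dm.variable_ids,
    )


def _projection_matrix(model: BilinearModel) -> np.ndarray:
    """W (P'W)^-1, mapping preprocessed rows to scores."""
    A = model.loadings.T @ model.weights
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > MAX_PROJECTION_COND:
        raise IllConditionedError(
            f"P'W is numerically singular (condition number {cond:.3g}); "
            "scores for new samples are not defined"
        )
    return model.weights @ np.linalg.inv(A)


def predict_scores(model: BilinearModel, X_new) -> np.ndarray:
    """Scores of new samples: T_new = X_pre W (P'W)^-1.

    For the training rows this reproduces the stored score matrix.
    """
    dm = as_data_matrix(X_new)
    if dm.shape[1] != model.loadings.shape[0]:
        raise UserInputError(
            f"new data has {dm.shape[1]} variables, model expects {model.loadings.shape[0]}"
        )
    Xp = model.preprocessing.apply(dm.values)
    return Xp @ _projection_matrix(model)


def predict_response(model: BilinearModel, X_new) -> np.ndarray:
    """Predicted response: y_hat = T_new b, back-transformed through centering."""
    return predict_scores(model, X_new) @ model.inner_regression + model.y_mean
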