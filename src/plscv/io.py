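"""CSV readers/writers, the flat key-value config format, and logging setup.

Matrix CSV convention: first row holds variable ids, first column holds
sample ids, one optional designated label column for class membership, and
everything else strictly numeric.  UTF-8, comma delimiter, period decimal.
Internally everything is 0-based; user-facing messages are 1-based.
"""

from __future__ import annotations

import hashlib
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import UserInputError
from .pls import BilinearModel, DataMatrix, Preprocessing
from .rotation import ValidatedScores

logger = logging.getLogger("plscv")


def configure_logging(level: int = logging.INFO) -> None:
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )


@contextmanager
def log_stage(name: str):
    """Log wall time of a pipeline stage at info level."""
    start = time.perf_counter()
    yield
    logger.info("stage %s finished in %.2f s", name, time.perf_counter() - start)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def read_matrix_csv(path, label_column: str | None = None,
                    ) -> tuple[DataMatrix, np.ndarray | None]:
    """Read a samples x variables CSV; optionally split out a label column.

    Non-numeric cells outside the label column raise with their 1-based
    row/column coordinates; duplicate sample or variable ids raise.
    """
    path = Path(path)
    if not path.exists():
        raise UserInputError(f"no such file: {path}")
    frame = pd.read_csv(path, index_col=0, dtype=str)
    frame.index = frame.index.map(str)
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise UserInputError(f"duplicate sample id {dup!r} in {path}")
    if frame.columns.duplicated().any():
        dup = frame.columns[frame.columns.duplicated()][0]
        raise UserInputError(f"duplicate variable id {dup!r} in {path}")

    labels = None
    if label_column is not None:
        if label_column not in frame.columns:
            raise UserInputError(
                f"label column {label_column!r} not found in {path}; "
                f"available columns: {', '.join(frame.columns[:10])}"
            )
        labels = frame[label_column].to_numpy(dtype=str)
        frame = frame.drop(columns=[label_column])

    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy() & frame.notna().to_numpy()
                      | frame.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise UserInputError(
            f"non-numeric cell at data row {r + 1}, column {c + 1} "
            f"(variable {frame.columns[c]!r}) in {path}"
        )
    return DataMatrix.from_dataframe(numeric), labels


def write_matrix_csv(X: DataMatrix, path, labels=None,
                     label_column: str = "class") -> None:
    frame = X.to_dataframe()
    if labels is not None:
        if label_column in frame.columns:
            raise UserInputError(
                f"label column name {label_column!r} collides with a variable id"
            )
        frame.insert(0, label_column, list(labels))
    frame.index.name = "sample_id"
    frame.to_csv(path)


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def write_scores_csv(scores, path, sample_ids=None, fold_of_sample=None) -> None:
    """Write scores with header ``sample_id,fold,score_1..score_F``.

    Accepts a :class:`ValidatedScores` or a plain score matrix (then ``fold``
    is written as -1 unless given).  Floats round-trip at full precision.
    """
    if isinstance(scores, ValidatedScores):
        matrix = scores.scores
        fold = scores.fold_of_sample
        ids = scores.sample_ids or sample_ids
    else:
        matrix = np.atleast_2d(np.asarray(scores, dtype=float))
        fold = fold_of_sample
        ids = sample_ids
    if matrix.size == 0:
        matrix = matrix.reshape(0, matrix.shape[1] if matrix.ndim == 2 else 0)
    n, f = matrix.shape
    if ids is None:
        ids = [f"s{i + 1}" for i in range(n)]
    if fold is None:
        fold = np.full(n, -1, dtype=int)
    frame = pd.DataFrame(matrix, columns=[f"score_{k + 1}" for k in range(f)])
    frame.insert(0, "fold", np.asarray(fold, dtype=int))
    frame.insert(0, "sample_id", list(ids))
    frame.to_csv(path, index=False)


def read_scores_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    expected = {"sample_id", "fold"}
    if not expected <= set(frame.columns):
        raise UserInputError(f"{path} is not a scores CSV (missing {expected})")
    return frame


# ---------------------------------------------------------------------------
# model bundles
# ---------------------------------------------------------------------------

def save_model_bundle(model: BilinearModel, out_dir) -> None:
    """Export a fitted PLS model as a directory of plain CSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    comp = [f"comp_{k + 1}" for k in range(model.n_components)]
    sample_index = list(model.sample_ids) or None
    var_index = list(model.variable_ids) or None
    pd.DataFrame(model.scores, columns=comp, index=sample_index).to_csv(out / "scores.csv")
    pd.DataFrame(model.loadings, columns=comp, index=var_index).to_csv(out / "loadings.csv")
    pd.DataFrame(model.weights, columns=comp, index=var_index).to_csv(out / "weights.csv")
    pd.DataFrame({"b": model.inner_regression}, index=comp).to_csv(out / "inner_regression.csv")
    prep = model.preprocessing
    stats = pd.DataFrame(index=var_index if var_index else
                         range(model.loadings.shape[0]))
    if prep.column_means is not None:
        stats["mean"] = prep.column_means
    if prep.column_scales is not None:
        stats["scale"] = prep.column_scales
    stats.to_csv(out / "preprocessing.csv")
    meta = pd.Series({
        "n_components": model.n_components,
        "preprocessing_mode": prep.mode,
        "y_mean": repr(float(model.y_mean)),
        "x_total_ss": repr(float(model.x_total_ss)),
    })
    meta.to_csv(out / "meta.csv", header=False)


def load_model_bundle(in_dir) -> BilinearModel:
    src = Path(in_dir)
    if not (src / "meta.csv").exists():
        raise UserInputError(f"{src} is not a model bundle (meta.csv missing)")
    meta = pd.read_csv(src / "meta.csv", header=None, index_col=0)[1]
    scores = pd.read_csv(src / "scores.csv", index_col=0)
    loadings = pd.read_csv(src / "loadings.csv", index_col=0)
    weights = pd.read_csv(src / "weights.csv", index_col=0)
    b = pd.read_csv(src / "inner_regression.csv", index_col=0)["b"].to_numpy()
    stats = pd.read_csv(src / "preprocessing.csv", index_col=0)
    mode = str(meta["preprocessing_mode"])
    prep = Preprocessing(
        mode=mode,
        column_means=stats["mean"].to_numpy() if "mean" in stats else None,
        column_scales=stats["scale"].to_numpy() if "scale" in stats else None,
    )
    T = scores.to_numpy()
    P = loadings.to_numpy()
    y_mean = float(meta["y_mean"])
    return BilinearModel(
        n_components=int(meta["n_components"]),
        scores=T, loadings=P, weights=weights.to_numpy(),
        inner_regression=b,
        response_residuals=np.zeros(T.shape[0]),
        x_residuals=np.zeros((T.shape[0], P.shape[0])),
        preprocessing=prep, y_mean=y_mean,
        x_total_ss=float(meta["x_total_ss"]),
        sample_ids=tuple(map(str, scores.index)),
        variable_ids=tuple(map(str, loadings.index)),
    )


# ---------------------------------------------------------------------------
# flat key-value configuration
# ---------------------------------------------------------------------------

#: every key the config file may set, with its parser
CONFIG_KEYS = {
    "n_samples": int,
    "n_variables": int,
    "n_informative": int,
    "calibration_stride": int,
    "class_sep": float,
    "score_sd1": float,
    "score_sd2": float,
    "seed": int,
    "n_components": int,
    "preprocessing": str,
    "n_segments": int,
    "cv_scheme": str,
    "rotation_mode": str,
    "n_repetitions": int,
    "output_dir": str,
}


@dataclass(frozen=True)
class StudyConfig:
    """Resolved flat configuration (file values overridden by CLI flags)."""

    values: dict

    def __getitem__(self, key):
        return self.values[key]

    def get(self, key, default=None):
        return self.values.get(key, default)

    def digest(self) -> str:
        payload = ";".join(f"{k}={self.values[k]}" for k in sorted(self.values))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def parse_config_file(path) -> dict:
    """Parse ``key = value`` lines; '#' starts a comment; unknown keys reject."""
    path = Path(path)
    if not path.exists():
        raise UserInputError(f"no such config file: {path}")
    values = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise UserInputError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in CONFIG_KEYS:
            raise UserInputError(
                f"{path}:{lineno}: unknown config key {key!r}; "
                f"known keys: {', '.join(sorted(CONFIG_KEYS))}"
            )
        try:
            values[key] = CONFIG_KEYS[key](value)
        except ValueError as err:
            raise UserInputError(f"{path}:{lineno}: bad value for {key}: {err}") from err
    return values


def resolve_config(file_values: dict | None, flag_values: dict) -> StudyConfig:
    """Merge config-file values under explicit CLI flags (flags win)."""
    merged = dict(file_values or {})
    for key, value in flag_values.items():
        if value is not None:
            merged[key] = value
    config = StudyConfig(values=merged)
    logger.info("resolved config (digest %s): %s", config.digest(), merged)
    return config
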