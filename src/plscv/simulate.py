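"""Rank-2 synthetic datasets for the overfitting study.

Each dataset is an exact product of two score vectors and two loading
vectors, X = t1 p1' + t2 p2', with no additive noise.  Score 1 carries the
class information (class-conditional Gaussians with overlapping means);
score 2 is class-independent.  Loading 1 is sparse — only ``n_informative``
of the variables load on the class-informative score, with uniform(0, 1)
entries — while loading 2 has uniform(0, 1) entries on every variable.  Most
of the variance in X is therefore unrelated to class membership, the regime
in which calibrated score plots overstate separation.

Calibration/test splitting picks every ``calibration_stride``-th sample
(positions 1, 1+stride, ... in 1-based terms); at the defaults (2000 samples,
stride 50) this yields a 40 x 360 calibration set and a 1960 x 360 test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import UserInputError
from .pls import DataMatrix


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults define the study conditions."""

    n_samples: int = 2000
    n_variables: int = 360
    n_informative: int = 10
    calibration_stride: int = 50
    #: distance between the class means on score 1 (in score-1 SD units when
    #: score_sd[0] == 1); the default gives clearly overlapping classes
    class_sep: float = 1.0
    score_sd: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 4 or self.n_samples % 2:
            raise UserInputError("n_samples must be an even integer >= 4")
        if self.n_variables < 1:
            raise UserInputError("n_variables must be positive")
        if not 1 <= self.n_informative <= self.n_variables:
            raise UserInputError(
                f"n_informative={self.n_informative} must be in [1, {self.n_variables}]"
            )
        if self.calibration_stride < 1 or self.n_samples % self.calibration_stride:
            raise UserInputError(
                f"calibration_stride={self.calibration_stride} must divide "
                f"n_samples={self.n_samples}"
            )
        if self.class_sep < 0:
            raise UserInputError("class_sep must be non-negative")
        if len(self.score_sd) != 2 or min(self.score_sd) <= 0:
            raise UserInputError("score_sd must be two positive values")


@dataclass
class SimulatedDataset:
    X: DataMatrix
    labels: np.ndarray          # strings, one of the two class names
    true_scores: np.ndarray     # I x 2, the generating t1, t2
    true_loadings: np.ndarray   # J x 2, the generating p1, p2
    calibration_index: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    test_index: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    config: SimConfig | None = None


CLASS_NAMES = ("A", "B")


def generate(config: SimConfig) -> SimulatedDataset:
    """Draw one dataset: X = t1 p1' + t2 p2', exactly rank two.

    Classes are assigned first (balanced 50/50, randomly ordered); t1 is then
    sampled from N(-sep/2, sd1) or N(+sep/2, sd1) by class and t2 from
    N(0, sd2) independently of class.  Same seed, same dataset, bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    n, J = config.n_samples, config.n_variables
    cls = rng.permutation(np.repeat([0, 1], n // 2))
    t1 = rng.normal((cls - 0.5) * config.class_sep, config.score_sd[0])
    t2 = rng.normal(0.0, config.score_sd[1], size=n)

    p1 = np.zeros(J)
    informative = rng.choice(J, size=config.n_informative, replace=False)
    p1[informative] = rng.uniform(0.0, 1.0, size=config.n_informative)
    p2 = rng.uniform(0.0, 1.0, size=J)

    X = np.outer(t1, p1) + np.outer(t2, p2)
    dm = DataMatrix(X,
                    tuple(f"s{i + 1:04d}" for i in range(n)),
                    tuple(f"v{j + 1:03d}" for j in range(J)))
    labels = np.array([CLASS_NAMES[c] for c in cls])
    cal = np.arange(0, n, config.calibration_stride)
    test = np.setdiff1d(np.arange(n), cal)
    return SimulatedDataset(
        X=dm, labels=labels,
        true_scores=np.column_stack([t1, t2]),
        true_loadings=np.column_stack([p1, p2]),
        calibration_index=cal, test_index=test, config=config,
    )


def split(dataset: SimulatedDataset, stride: int | None = None,
          ) -> tuple[DataMatrix, np.ndarray, DataMatrix, np.ndarray]:
    """(X_cal, labels_cal, X_test, labels_test) by the every-stride-th rule.

    With ``stride=None`` the indices stored at generation time are used.
    """
    n = dataset.X.shape[0]
    if stride is None:
        cal, test = dataset.calibration_index, dataset.test_index
    else:
        if stride < 1 or stride > n:
            raise UserInputError(f"stride={stride} outside [1, {n}]")
        if n % stride:
            raise UserInputError(f"stride={stride} does not divide n_samples={n}")
        cal = np.arange(0, n, stride)
        test = np.setdiff1d(np.arange(n), cal)
    if test.size == 0:
        raise UserInputError("test partition is empty (stride selects every sample)")
    return (dataset.X.take(cal), dataset.labels[cal],
            dataset.X.take(test), dataset.labels[test])


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Same study conditions, different random draw."""
    return replace(config, seed=int(seed))
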