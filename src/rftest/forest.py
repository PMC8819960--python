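"""The test statistic: out-of-bag generalization error of a random forest.

For a binary outcome the forest makes probabilistic OOB predictions and
the statistic is the Brier score, mean((p_i - y_i)^2) over samples with
OOB coverage; for a continuous outcome it is the OOB mean squared error.
The statistic is averaged over a small number of independently seeded
forests to stabilize it (its sampling noise would otherwise inflate the
permutation null).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from ._forest_core import forest_oob_predictions
from .features import AugmentedFeatures

__all__ = [
    "ForestConfig",
    "StatisticValue",
    "CoverageError",
    "oob_brier",
    "oob_mse",
    "forest_statistic",
]

#: default minimum node size below which a node is not split, per task —
#: the conventions of probability forests (classification) and
#: regression forests.
DEFAULT_MIN_NODE = {"classification": 10, "regression": 5}


class CoverageError(RuntimeError):
    """No sample received an out-of-bag prediction."""


@dataclass(frozen=True)
class ForestConfig:
    """Hyperparameters of the forest behind the statistic.

    mtry_fraction is applied to the actual (augmented, filtered) feature
    count: mtry = max(1, round(mtry_fraction * n_features)).
    """

    n_trees: int = 500
    mtry_fraction: float = 0.025
    n_repeats: int = 3
    task: str = "classification"
    seed: int | None = None
    min_node_size: int | None = None  # None -> task default (10 / 5)

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0 < self.mtry_fraction <= 1:
            raise ValueError("mtry_fraction must be in (0, 1]")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.min_node_size is not None and self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")

    @property
    def resolved_min_node(self) -> int:
        if self.min_node_size is not None:
            return self.min_node_size
        return DEFAULT_MIN_NODE[self.task]

    def mtry(self, n_features: int) -> int:
        return max(1, round(self.mtry_fraction * n_features))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["min_node_size"] = self.resolved_min_node
        return d


@dataclass(frozen=True)
class StatisticValue:
    """An averaged OOB-error statistic and its per-repeat components."""

    value: float
    per_repeat: tuple[float, ...]
    n_oob_covered: int  # fewest covered samples over the repeats

    def __post_init__(self):
        assert np.isclose(self.value, float(np.mean(self.per_repeat)))


def _covered(pred: np.ndarray) -> np.ndarray:
    return np.isfinite(pred)


def oob_brier(oob_probabilities: np.ndarray, y: np.ndarray) -> float:
    """Brier score over OOB-covered samples.

    ``oob_probabilities`` holds each sample's OOB probability of class 1;
    samples with no OOB coverage are marked NaN and excluded.
    """
    p = np.asarray(oob_probabilities, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probabilities and outcomes have different lengths")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    cov = _covered(p)
    if not cov.any():
        raise CoverageError(
            "no sample has an out-of-bag prediction; grow more trees"
        )
    pc = p[cov]
    if ((pc < 0) | (pc > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((pc - y[cov]) ** 2))


def oob_mse(oob_predictions: np.ndarray, y: np.ndarray) -> float:
    """Mean squared error over OOB-covered samples (NaN = uncovered)."""
    pred = np.asarray(oob_predictions, dtype=float)
    y = np.asarray(y, dtype=float)
    if pred.shape != y.shape:
        raise ValueError("predictions and outcomes have different lengths")
    cov = _covered(pred)
    if not cov.any():
        raise CoverageError(
            "no sample has an out-of-bag prediction; grow more trees"
        )
    return float(np.mean((pred[cov] - y[cov]) ** 2))


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, AugmentedFeatures):
        return features.matrix
    return np.ascontiguousarray(np.asarray(features, dtype=np.float64))


def single_forest_oob(
    X: np.ndarray, y: np.ndarray, config: ForestConfig, seed_seq: np.random.SeedSequence
) -> np.ndarray:
    """OOB predictions of one forest (NaN where a sample is never OOB)."""
    tree_seeds = seed_seq.generate_state(config.n_trees).astype(np.int64)
    pred_sum, pred_cnt = forest_oob_predictions(
        X,
        np.ascontiguousarray(y, dtype=np.float64),
        config.n_trees,
        config.mtry(X.shape[1]),
        config.resolved_min_node,
        tree_seeds,
    )
    with np.errstate(invalid="ignore"):
        pred = np.where(pred_cnt > 0, pred_sum / np.maximum(pred_cnt, 1), np.nan)
    return pred


def forest_statistic(features, y, config: ForestConfig) -> StatisticValue:
    """Average OOB error over ``config.n_repeats`` independent forests.

    Deterministic given (features, y, config.seed): per-repeat seeds are
    spawned from the master seed, and each repeat re-seeds the entire
    forest (bootstrap draws and candidate-feature subsets alike).
    """
    X = _as_matrix(features)
    y = np.asarray(y, dtype=np.float64)
    if X.shape[0] != y.shape[0]:
        raise ValueError(
            f"feature rows ({X.shape[0]}) != outcome length ({y.shape[0]})"
        )
    if config.task == "classification":
        uniq = np.unique(y)
        if len(uniq) < 2:
            raise ValueError(
                "outcome is constant; a classification statistic needs two classes"
            )
        if not set(uniq) <= {0.0, 1.0}:
            raise ValueError("classification outcome must be coded 0/1")
    ss = np.random.SeedSequence(config.seed)
    repeats = ss.spawn(config.n_repeats)
    values = []
    coverage = []
    for child in repeats:
        pred = single_forest_oob(X, y, config, child)
        if config.task == "classification":
            values.append(oob_brier(pred, y))
        else:
            values.append(oob_mse(pred, y))
        coverage.append(int(np.isfinite(pred).sum()))
    return StatisticValue(
        value=float(np.mean(values)),
        per_repeat=tuple(values),
        n_oob_covered=min(coverage),
    )
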