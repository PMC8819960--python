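"""The community-level association test.

The null hypothesis is that the outcome is independent of the community
profile (given covariates). The observed statistic is the forest's OOB
generalization error on the augmented features; under the null the
features carry no information, so the observed error should look like
the error obtained after breaking the feature–outcome link. Replicate
outcomes are produced by

* plain permutation of Y (no covariates),
* permutation of regression residuals (continuous Y with covariates;
  the observed statistic is then computed on the residuals as well), or
* regeneration of a binary Y from the fitted logistic model conditional
  on the observed number of cases (binary Y with covariates).

Small observed errors are evidence against the null, so the p-value
counts replicates with error *at or below* the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .features import PhylogeneticFeatureAugmenter
from .forest import ForestConfig, forest_statistic
from .tree import PhyloTree

__all__ = [
    "CovariateModel",
    "CovariateError",
    "TestResult",
    "pvalue",
    "fit_covariate_model",
    "permute_null_continuous",
    "permute_null_binary",
    "conditional_bernoulli",
    "RandomForestAssociationTest",
    "rftest",
]


def pvalue(t_obs: float, t_perm: Sequence[float]) -> float:
    """Permutation p-value (#{replicates <= observed} + 1) / (B + 1).

    Ties count toward significance's denominator side (<= exactly),
    which keeps the test valid. The attainable range is
    [1/(B+1), 1].
    """
    t_perm = np.asarray(t_perm, dtype=float)
    if t_perm.ndim != 1 or t_perm.size == 0:
        raise ValueError("need at least one permutation statistic")
    b = t_perm.size
    return float((np.sum(t_perm <= t_obs) + 1) / (b + 1))


# ----------------------------------------------------------------------
# covariate adjustment


class CovariateError(ValueError):
    """The covariate regression cannot be fit as specified."""


@dataclass
class CovariateModel:
    """A fitted outcome-on-covariates regression used to build the null.

    For a continuous outcome this is an OLS fit; its residuals are both
    the adjusted outcome and the pool that gets permuted. For a binary
    outcome it is a logistic fit; its fitted probabilities parameterize
    the conditional-Bernoulli null.
    """

    family: str  # "linear" | "logistic"
    params: np.ndarray  # intercept first
    residuals: np.ndarray | None = None
    linear_predictors: np.ndarray | None = None
    fitted_probabilities: np.ndarray | None = None
    column_names: tuple[str, ...] = ()


def _design(Z) -> tuple[np.ndarray, tuple[str, ...]]:
    if Z is None:
        raise ValueError("Z is required; pass n_rows for an intercept-only design")
    if isinstance(Z, pd.DataFrame):
        names = tuple(str(c) for c in Z.columns)
        Zm = Z.to_numpy(dtype=float)
    else:
        Zm = np.asarray(Z, dtype=float)
        if Zm.ndim == 1:
            Zm = Zm[:, None]
        names = tuple(f"z{k}" for k in range(Zm.shape[1]))
    design = np.column_stack([np.ones(Zm.shape[0]), Zm])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # locate offending columns via the QR diagonal
        _, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        bad = [names[k - 1] for k in range(1, design.shape[1]) if diag[k] < 1e-10]
        raise CovariateError(
            f"covariate matrix is rank deficient (collinear columns: {bad or names})"
        )
    return design, names


def fit_covariate_model(y, Z, family: str | None = None) -> CovariateModel:
    """Regress the outcome on covariates (OLS or logistic with intercept).

    ``family`` is inferred from the outcome when not given: exactly two
    distinct values -> logistic, otherwise linear.
    """
    y = np.asarray(y, dtype=float)
    design, names = _design(Z)
    if design.shape[0] != y.shape[0]:
        raise ValueError("outcome and covariates have different lengths")
    if family is None:
        family = "logistic" if len(np.unique(y)) == 2 else "linear"
    if family == "linear":
        fit = sm.OLS(y, design).fit()
        return CovariateModel(
            family="linear",
            params=np.asarray(fit.params),
            residuals=np.asarray(fit.resid),
            column_names=names,
        )
    if family != "logistic":
        raise ValueError(f"unknown family {family!r}")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("logistic family requires a 0/1 outcome")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        try:
            fit = sm.Logit(y, design).fit(disp=0)
        except Exception as exc:
            raise CovariateError(
                "logistic covariate fit failed (possibly perfect separation); "
                f"penalized fits are out of scope: {exc}"
            ) from exc
    eta = design @ np.asarray(fit.params)
    pi = 1.0 / (1.0 + np.exp(-eta))
    if np.any(pi <= 1e-10) or np.any(pi >= 1 - 1e-10):
        raise CovariateError(
            "logistic fit yields degenerate fitted probabilities "
            "(perfect separation?); penalized fits are out of scope"
        )
    return CovariateModel(
        family="logistic",
        params=np.asarray(fit.params),
        linear_predictors=eta,
        fitted_probabilities=pi,
        column_names=names,
    )


def permute_null_continuous(model: CovariateModel, rng: np.random.Generator) -> np.ndarray:
    """One null outcome for the continuous case: permuted residuals."""
    if model.family != "linear" or model.residuals is None:
        raise ValueError("continuous null requires a fitted linear model")
    return rng.permutation(model.residuals)


def _poisson_binomial_tail_table(pi: np.ndarray, k: int) -> np.ndarray:
    """q[i, t] = P(sum of Bernoulli(pi[i:]) equals t), for t = 0..k."""
    n = pi.shape[0]
    q = np.zeros((n + 1, k + 1))
    q[n, 0] = 1.0
    for i in range(n - 1, -1, -1):
        p = pi[i]
        q[i, 0] = (1 - p) * q[i + 1, 0]
        for t in range(1, k + 1):
            q[i, t] = p * q[i + 1, t - 1] + (1 - p) * q[i + 1, t]
    return q


def conditional_bernoulli(
    pi: np.ndarray, n_cases: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw y ~ independent Bernoulli(pi_i) conditioned on sum(y) = n_cases.

    Exact sequential sampler: dynamic programming gives the
    Poisson-binomial tail probabilities q[i, t] = P(sum over i.. = t),
    and each coordinate is drawn with
    P(y_i = 1 | remaining total t) = pi_i * q[i+1, t-1] / q[i, t].
    """
    pi = np.asarray(pi, dtype=float)
    n = pi.shape[0]
    if not (0 <= n_cases <= n):
        raise ValueError(f"n_cases must be in [0, {n}], got {n_cases}")
    if ((pi < 0) | (pi > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    y = np.zeros(n, dtype=np.int64)
    if n_cases == 0:
        return y
    if n_cases == n:
        y[:] = 1
        return y
    q = _poisson_binomial_tail_table(pi, n_cases)
    if q[0, n_cases] <= 0:
        raise ValueError("the requested case count has zero probability")
    t = n_cases
    u = rng.random(n)
    for i in range(n):
        if t == 0:
            break
        if n - i == t:
            y[i:] = 1
            break
        p1 = pi[i] * q[i + 1, t - 1] / q[i, t]
        if u[i] < p1:
            y[i] = 1
            t -= 1
    return y


def permute_null_binary(
    model: CovariateModel, n_cases: int, rng: np.random.Generator
) -> np.ndarray:
    """One null outcome for the binary case: conditional regeneration.

    Draws independent Bernoulli outcomes from the fitted logistic
    probabilities, conditioned on the total equalling the observed
    number of cases.
    """
    if model.family != "logistic" or model.fitted_probabilities is None:
        raise ValueError("binary null requires a fitted logistic model")
    return conditional_bernoulli(model.fitted_probabilities, n_cases, rng)


# ----------------------------------------------------------------------
# the test


@dataclass
class TestResult:
    """Everything needed to report and reproduce one test."""

    statistic: float  # observed OOB error T_obs
    null_statistics: np.ndarray  # T~_1 .. T~_B
    n_permutations: int
    p_value: float
    outcome_type: str  # "binary" | "continuous"
    covariate_mode: str  # "none" | "residual_permutation" | "conditional_regeneration"
    config: dict = field(default_factory=dict)
    seed: int | None = None
    per_repeat_observed: tuple[float, ...] = ()
    n_oob_covered: int = 0

    def to_dict(self) -> dict:
        d = {
            "statistic": self.statistic,
            "null_statistics": [float(v) for v in self.null_statistics],
            "n_permutations": self.n_permutations,
            "p_value": self.p_value,
            "outcome_type": self.outcome_type,
            "covariate_mode": self.covariate_mode,
            "config": self.config,
            "seed": self.seed,
            "per_repeat_observed": list(self.per_repeat_observed),
            "n_oob_covered": self.n_oob_covered,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TestResult":
        d = dict(d)
        d["null_statistics"] = np.asarray(d["null_statistics"], dtype=float)
        d["per_repeat_observed"] = tuple(d.get("per_repeat_observed", ()))
        d.pop("version", None)
        d.pop("timestamp", None)
        return cls(**d)


class RandomForestAssociationTest(BaseEstimator):
    """Permutation test of community–outcome association.

    Fits a random forest of the outcome on taxon abundances augmented
    with phylogenetically accumulated internal-node abundances, uses the
    out-of-bag error (Brier score for binary outcomes, MSE for
    continuous ones, averaged over ``n_repeats`` forests) as the test
    statistic, and calibrates it against ``n_permutations`` replicate
    outcomes generated under the null.

    Parameters
    ----------
    tree : PhyloTree or None
        Rooted tree over the table's taxa; ``None`` tests on the leaf
        features alone.
    n_permutations : int, default 999
        Number of null replicates B; the smallest attainable p-value is
        1/(B+1).
    n_trees, mtry_fraction, n_repeats, min_node_size
        Forest hyperparameters (see :class:`rftest.forest.ForestConfig`).
    max_sparsity : float, default 0.96
        Features zero in more than this fraction of samples are dropped.
    drop_constant : bool, default True
        Drop zero-variance features (e.g. the root column).
    outcome_type : {"auto", "binary", "continuous"}
        "auto" declares the outcome binary iff it takes exactly two
        distinct values.
    random_state : int or None
        Master seed. Forest fits and the permutation stream draw from
        independent spawned streams, so changing B or n_repeats never
        correlates the two sources.

    Attributes (after ``fit``)
    --------------------------
    statistic_, p_value_, null_statistics_, result_, features_
    """

    def __init__(
        self,
        tree: PhyloTree | None = None,
        n_permutations: int = 999,
        n_trees: int = 500,
        mtry_fraction: float = 0.025,
        n_repeats: int = 3,
        min_node_size: int | None = None,
        max_sparsity: float = 0.96,
        drop_constant: bool = True,
        outcome_type: str = "auto",
        random_state: int | None = None,
    ):
        self.tree = tree
        self.n_permutations = n_permutations
        self.n_trees = n_trees
        self.mtry_fraction = mtry_fraction
        self.n_repeats = n_repeats
        self.min_node_size = min_node_size
        self.max_sparsity = max_sparsity
        self.drop_constant = drop_constant
        self.outcome_type = outcome_type
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _resolve_outcome(self, y) -> tuple[np.ndarray, str, dict | None]:
        y_arr = np.asarray(y)
        distinct = pd.unique(pd.Series(y_arr).dropna())
        if len(distinct) < 2:
            raise ValueError("outcome is constant; the test is undefined")
        if self.outcome_type == "binary" or (
            self.outcome_type == "auto" and len(distinct) == 2
        ):
            levels = sorted(distinct.tolist())
            if len(levels) != 2:
                raise ValueError(
                    f"outcome declared binary but has {len(levels)} levels"
                )
            mapping = {levels[0]: 0, levels[1]: 1}
            coded = np.array([mapping[v] for v in y_arr.tolist()], dtype=float)
            return coded, "binary", {str(k): v for k, v in mapping.items()}
        if self.outcome_type not in ("auto", "continuous"):
            raise ValueError(f"unknown outcome_type {self.outcome_type!r}")
        return y_arr.astype(float), "continuous", None

    def fit(self, X, y, covariates=None):
        B = int(self.n_permutations)
        if B < 1:
            raise ValueError("n_permutations must be >= 1")
        if B < 19:
            warnings.warn(
                f"with B={B} permutations the smallest attainable p-value is "
                f"{1/(B+1):.3g} > 0.05; increase n_permutations",
                UserWarning,
                stacklevel=2,
            )
        if isinstance(X, pd.DataFrame) and isinstance(y, pd.Series):
            if set(y.index) == set(X.index):
                y = y.loc[X.index]
        if (
            isinstance(X, pd.DataFrame)
            and isinstance(covariates, (pd.DataFrame, pd.Series))
            and set(covariates.index) == set(X.index)
        ):
            covariates = covariates.loc[X.index]

        augmenter = PhylogeneticFeatureAugmenter(
            tree=self.tree,
            max_sparsity=self.max_sparsity,
            drop_constant=self.drop_constant,
        )
        feats = augmenter.fit_transform_features(
            X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        )
        self.augmenter_ = augmenter
        self.features_ = feats

        y_coded, outcome_type, mapping = self._resolve_outcome(y)
        if y_coded.shape[0] != feats.data.shape[0]:
            raise ValueError("outcome length does not match the table")
        task = "classification" if outcome_type == "binary" else "regression"

        ss = np.random.SeedSequence(self.random_state)
        ss_forest, ss_perm = ss.spawn(2)
        forest_seeds = ss_forest.generate_state(B + 1, dtype=np.uint32)
        perm_rng = np.random.default_rng(ss_perm)

        def config_for(b: int) -> ForestConfig:
            return ForestConfig(
                n_trees=self.n_trees,
                mtry_fraction=self.mtry_fraction,
                n_repeats=self.n_repeats,
                task=task,
                seed=int(forest_seeds[b]),
                min_node_size=self.min_node_size,
            )

        self.covariate_model_ = None
        if covariates is None:
            covariate_mode = "none"
            y_work = y_coded
            draw_null = lambda: perm_rng.permutation(y_work)
        elif outcome_type == "continuous":
            covariate_mode = "residual_permutation"
            model = fit_covariate_model(y_coded, covariates, family="linear")
            self.covariate_model_ = model
            y_work = model.residuals  # the adjusted outcome
            draw_null = lambda: permute_null_continuous(model, perm_rng)
        else:
            covariate_mode = "conditional_regeneration"
            model = fit_covariate_model(y_coded, covariates, family="logistic")
            self.covariate_model_ = model
            y_work = y_coded  # raw outcome; only the null is regenerated
            n_cases = int(round(y_coded.sum()))
            draw_null = lambda: permute_null_binary(model, n_cases, perm_rng)

        obs = forest_statistic(feats, y_work, config_for(0))
        null = np.empty(B)
        for b in range(1, B + 1):
            null[b - 1] = forest_statistic(feats, draw_null(), config_for(b)).value

        p = pvalue(obs.value, null)
        config = config_for(0).to_dict()
        config.pop("seed")
        config.update(
            {
                "n_permutations": B,
                "max_sparsity": self.max_sparsity,
                "drop_constant": self.drop_constant,
                "n_features": feats.n_features,
                "n_leaf_features": len(feats.leaf_columns),
                "n_node_features": len(feats.node_columns),
                "filters": feats.filters,
                "outcome_mapping": mapping,
            }
        )
        self.statistic_ = obs.value
        self.null_statistics_ = null
        self.p_value_ = p
        self.outcome_type_ = outcome_type
        self.result_ = TestResult(
            statistic=obs.value,
            null_statistics=null,
            n_permutations=B,
            p_value=p,
            outcome_type=outcome_type,
            covariate_mode=covariate_mode,
            config=config,
            seed=self.random_state,
            per_repeat_observed=obs.per_repeat,
            n_oob_covered=obs.n_oob_covered,
        )
        return self


def rftest(
    table,
    y,
    tree: PhyloTree | None = None,
    covariates=None,
    n_permutations: int = 999,
    n_trees: int = 500,
    mtry_fraction: float = 0.025,
    n_repeats: int = 3,
    min_node_size: int | None = None,
    max_sparsity: float = 0.96,
    drop_constant: bool = True,
    outcome_type: str = "auto",
    random_state: int | None = None,
) -> TestResult:
    """Run the association test and return its :class:`TestResult`.

    Thin functional wrapper over :class:`RandomForestAssociationTest`.
    """
    est = RandomForestAssociationTest(
        tree=tree,
        n_permutations=n_permutations,
        n_trees=n_trees,
        mtry_fraction=mtry_fraction,
        n_repeats=n_repeats,
        min_node_size=min_node_size,
        max_sparsity=max_sparsity,
        drop_constant=drop_constant,
        outcome_type=outcome_type,
        random_state=random_state,
    )
    est.fit(table, y, covariates=covariates)
    return est.result_
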