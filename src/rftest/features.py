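"""Phylogenetic feature augmentation and sparsity filtering.

Each internal node of the tree contributes one feature: the summed
abundance of its descendant taxa. Concatenating these with the leaf
(taxon) features lets a forest pick up signals that are phylogenetically
clustered — a whole clade shifting together appears as a single strong
column instead of many weak ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .tree import PhyloTree, align

__all__ = [
    "AugmentedFeatures",
    "FilterError",
    "accumulate_node_abundances",
    "sparsity_filter",
    "PhylogeneticFeatureAugmenter",
    "SparsityFilter",
]


class FilterError(ValueError):
    """Filtering removed every feature."""


@dataclass
class AugmentedFeatures:
    """Leaf abundances side by side with internal-node accumulated abundances.

    ``data`` holds the n × (p' + m') matrix; ``leaf_columns`` and
    ``node_columns`` partition its columns. ``filters`` records every
    filtering step applied, in order.
    """

    data: pd.DataFrame
    leaf_columns: tuple[str, ...]
    node_columns: tuple[str, ...]
    filters: list[dict] = field(default_factory=list)

    def __post_init__(self):
        expected = set(self.leaf_columns) | set(self.node_columns)
        if expected != set(self.data.columns):
            raise ValueError("leaf/node column labels do not match the matrix")

    @property
    def matrix(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.float64)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<AugmentedFeatures {self.data.shape[0]} samples, "
            f"{len(self.leaf_columns)} leaf + {len(self.node_columns)} node cols>"
        )


def _validate_table(table: pd.DataFrame) -> None:
    if table.columns.duplicated().any():
        raise ValueError("taxon identifiers are not unique")
    if table.index.duplicated().any():
        raise ValueError("sample identifiers are not unique")
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("abundance table contains non-numeric entries")
    if np.isnan(values).any():
        raise ValueError("abundance table contains missing entries")
    if (values < 0).any():
        raise ValueError("abundance table contains negative entries")


def accumulate_node_abundances(
    table: pd.DataFrame, tree: PhyloTree
) -> AugmentedFeatures:
    """Build the augmented feature matrix [X | W].

    For every internal node l (root included), w_il is the sum of the
    abundances of the taxa descending from l in sample i. Requires the
    table's columns to be exactly the tree's leaves (use
    :func:`rftest.tree.align` first).
    """
    _validate_table(table)
    if set(table.columns) != set(tree.leaves):
        raise ValueError(
            "table and tree are not aligned: taxon sets differ "
            f"({len(set(table.columns) ^ set(tree.leaves))} mismatched ids); "
            "call rftest.tree.align first"
        )
    ordered = table.loc[:, list(tree.leaves)]
    X = ordered.to_numpy(dtype=np.float64)
    leaf_pos = {leaf: j for j, leaf in enumerate(tree.leaves)}

    internal = tree.internal_nodes
    cols: dict[str, np.ndarray] = {}
    # postorder: children are computed before their parent
    for node in reversed(tree.nodes):
        kids = tree.children.get(node)
        if kids is None:
            continue
        acc = np.zeros(X.shape[0])
        for c in kids:
            acc = acc + (X[:, leaf_pos[c]] if c in leaf_pos else cols[c])
        cols[node] = acc
    W = pd.DataFrame({node: cols[node] for node in internal}, index=ordered.index)
    data = pd.concat([ordered.astype(np.float64), W], axis=1)
    return AugmentedFeatures(
        data=data, leaf_columns=tuple(tree.leaves), node_columns=tuple(internal)
    )


def sparsity_filter(
    features: AugmentedFeatures,
    max_sparsity: float = 0.96,
    drop_constant: bool = False,
) -> AugmentedFeatures:
    """Drop features that are zero in too large a fraction of samples.

    A column is removed when its fraction of exactly-zero entries
    exceeds ``max_sparsity`` (so ``max_sparsity=1`` is the identity).
    With ``drop_constant=True`` zero-variance columns are removed as
    well — the root's accumulated abundance, for instance, is constant
    for rarefied data and carries no information.
    """
    if not 0 <= max_sparsity <= 1:
        raise ValueError(f"max_sparsity must be in [0, 1], got {max_sparsity}")
    values = features.data.to_numpy()
    sparsity = (values == 0).mean(axis=0)
    keep = sparsity <= max_sparsity
    removed_constant: list[str] = []
    if drop_constant:
        constant = np.all(values == values[0:1, :], axis=0)
        removed_constant = [
            c for c, k, cst in zip(features.data.columns, keep, constant) if k and cst
        ]
        keep &= ~constant
    if not keep.any():
        raise FilterError(
            f"sparsity filtering at max_sparsity={max_sparsity} removed every "
            "feature; use a looser (larger) threshold"
        )
    kept_cols = [c for c, k in zip(features.data.columns, keep) if k]
    removed = [c for c, k in zip(features.data.columns, keep) if not k]
    record = {
        "max_sparsity": max_sparsity,
        "drop_constant": drop_constant,
        "n_removed": len(removed),
        "removed_constant": removed_constant,
        "n_before": features.n_features,
        "n_after": len(kept_cols),
    }
    kept_set = set(kept_cols)
    return AugmentedFeatures(
        data=features.data.loc[:, kept_cols],
        leaf_columns=tuple(c for c in features.leaf_columns if c in kept_set),
        node_columns=tuple(c for c in features.node_columns if c in kept_set),
        filters=features.filters + [record],
    )


class PhylogeneticFeatureAugmenter(BaseEstimator, TransformerMixin):
    """sklearn transformer: abundance table -> augmented, filtered features.

    Parameters
    ----------
    tree : PhyloTree or None
        Rooted tree over (a superset or subset of) the table's taxa.
        ``None`` skips augmentation and only filters the leaf features.
    max_sparsity : float, default 0.96
        Features zero in more than this fraction of samples are dropped.
    drop_constant : bool, default True
        Also drop zero-variance features (e.g. the root column on
        rarefied data).

    ``fit`` aligns the tree with the training table and learns which
    columns survive filtering; ``transform`` rebuilds the augmented
    matrix for (new) samples over the same taxa and returns the retained
    columns, as a DataFrame.
    """

    def __init__(self, tree: PhyloTree | None = None, max_sparsity: float = 0.96,
                 drop_constant: bool = True):
        self.tree = tree
        self.max_sparsity = max_sparsity
        self.drop_constant = drop_constant

    def _augment(self, X: pd.DataFrame) -> AugmentedFeatures:
        if self.tree is None:
            _validate_table(X)
            return AugmentedFeatures(
                data=X.astype(np.float64),
                leaf_columns=tuple(X.columns),
                node_columns=(),
            )
        aligned = align(self.tree_, X) if hasattr(self, "tree_") else align(self.tree, X)
        return accumulate_node_abundances(aligned.table, aligned.tree)

    def fit(self, X: pd.DataFrame, y=None):
        X = _as_frame(X)
        if self.tree is not None:
            aligned = align(self.tree, X)
            self.tree_ = aligned.tree
            self.dropped_taxa_ = aligned.dropped_taxa
            self.dropped_leaves_ = aligned.dropped_leaves
        else:
            self.dropped_taxa_ = ()
            self.dropped_leaves_ = ()
        full = self._augment(X)
        filtered = sparsity_filter(full, self.max_sparsity, self.drop_constant)
        self.feature_names_ = tuple(filtered.data.columns)
        self.filter_record_ = filtered.filters[-1]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "feature_names_"):
            raise RuntimeError("PhylogeneticFeatureAugmenter is not fitted")
        full = self._augment(_as_frame(X))
        return full.data.loc[:, list(self.feature_names_)]

    def fit_transform_features(self, X: pd.DataFrame) -> AugmentedFeatures:
        """Fit and return the full :class:`AugmentedFeatures` record."""
        self.fit(X)
        full = self._augment(_as_frame(X))
        kept = set(self.feature_names_)
        return AugmentedFeatures(
            data=full.data.loc[:, list(self.feature_names_)],
            leaf_columns=tuple(c for c in full.leaf_columns if c in kept),
            node_columns=tuple(c for c in full.node_columns if c in kept),
            filters=[self.filter_record_],
        )

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)


class SparsityFilter(BaseEstimator, TransformerMixin):
    """sklearn transformer dropping columns with too many exact zeros."""

    def __init__(self, max_sparsity: float = 0.96, drop_constant: bool = False):
        self.max_sparsity = max_sparsity
        self.drop_constant = drop_constant

    def fit(self, X, y=None):
        X = _as_frame(X)
        feats = AugmentedFeatures(
            data=X.astype(np.float64), leaf_columns=tuple(X.columns), node_columns=()
        )
        filtered = sparsity_filter(feats, self.max_sparsity, self.drop_constant)
        self.feature_names_ = tuple(filtered.data.columns)
        self.filter_record_ = filtered.filters[-1]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _as_frame(X)
        return X.loc[:, list(self.feature_names_)]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    return pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])
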