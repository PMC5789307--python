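"""Random-forest Gini-importance feature ranking.

The ranking procedure grows an ensemble of CART-style classification trees
on bootstrap resamples, with Gini-impurity splits over ``mtry`` randomly
chosen features per node (defaults mtry=4, 500 trees, minimum node size 1,
unlimited depth, no pruning).  A feature's importance is the total
node-size-weighted Gini decrease attributed to splits on it, averaged over
trees (mean decrease in Gini).  The top-ranked features feed the
discriminant classifier; ranking ties are broken by the fixed feature-name
order of the feature table.

The ensemble is implemented here rather than delegated, so that seeding is
exact and the importance accounting can be checked for conservation;
established forest implementations serve only as sanity oracles in tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._forest import grow_forest
from .features import FEATURE_NAMES


@dataclass
class RankingConfig:
    """Forest hyperparameters for the importance ranking."""

    ntree: int = 500
    mtry: int = 4
    min_node: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if not 1 <= self.mtry <= len(FEATURE_NAMES):
            raise ValueError(f"mtry must lie in [1, {len(FEATURE_NAMES)}]")
        if self.min_node < 1:
            raise ValueError("min_node must be >= 1")


@dataclass
class RankingResult:
    """Importance map, decreasing-importance feature order, and config echo."""

    importance: dict[str, float]
    order: list[str]
    config: RankingConfig = field(default_factory=RankingConfig)

    def to_json(self) -> str:
        return json.dumps(
            {
                "importance": self.importance,
                "order": self.order,
                "config": {
                    "ntree": self.config.ntree,
                    "mtry": self.config.mtry,
                    "min_node": self.config.min_node,
                    "seed": self.config.seed,
                },
            },
            indent=2,
        )


class GiniImportanceForest:
    """Random forest grown solely to rank features by mean decrease in Gini.

    Parameters
    ----------
    n_trees : int
        Number of bootstrap trees (default 500).
    mtry : int
        Features tried per split (default 4).
    min_node : int
        Minimum samples per node to attempt a split into halves of at least
        this size (default 1).
    random_state : int
        Seed for bootstrap resampling and per-node feature subsampling.

    Attributes
    ----------
    feature_importances_ : ndarray
        Mean decrease in Gini per feature (>= 0).
    ranking_ : ndarray
        Feature indices sorted by decreasing importance, ties broken by
        column order.
    tree_totals_ : ndarray
        Per-tree total Gini decrease (sum of that tree's importance
        contributions) — the conservation ledger.
    classes_ : ndarray
    """

    def __init__(self, n_trees: int = 500, mtry: int = 4, min_node: int = 1,
                 random_state: int = 0):
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_node = min_node
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_trees": self.n_trees,
            "mtry": self.mtry,
            "min_node": self.min_node,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        n, d = X.shape
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 1 <= self.mtry <= d:
            raise ValueError(f"mtry must lie in [1, {d}]")
        classes, y_enc = np.unique(np.asarray(y), return_inverse=True)
        if classes.size < 2:
            raise ValueError("ranking requires at least 2 classes")
        counts = np.bincount(y_enc)
        if np.any(counts < 2):
            small = classes[counts < 2]
            raise ValueError(f"every class needs >= 2 rows; too few for {small}")
        rng = np.random.default_rng(self.random_state)
        boot = rng.integers(0, n, size=(self.n_trees, n), dtype=np.int64)
        tree_seeds = rng.integers(0, 2**31 - 1, size=self.n_trees, dtype=np.int64)
        imp, totals = grow_forest(
            X, y_enc.astype(np.int64), int(classes.size), boot,
            int(self.mtry), int(self.min_node), tree_seeds)
        self.classes_ = classes
        self.tree_importances_ = imp
        self.tree_totals_ = totals
        self.feature_importances_ = imp.mean(axis=0)
        # stable sort: ties keep the fixed column order
        self.ranking_ = np.argsort(-self.feature_importances_, kind="stable")
        return self

    def top_features(self, k: int) -> np.ndarray:
        if not hasattr(self, "ranking_"):
            raise RuntimeError("forest not fitted")
        if not 1 <= k <= self.ranking_.size:
            raise ValueError(f"k must lie in [1, {self.ranking_.size}]")
        return self.ranking_[:k]


def rank_features(matrix: pd.DataFrame, config: RankingConfig | None = None) -> RankingResult:
    """Rank the 14 epoch features of a labelled feature matrix.

    ``matrix`` must carry the feature columns plus a ``behaviour`` label
    column (as built by :func:`lamegait.features.build_feature_matrix`).
    """
    if config is None:
        config = RankingConfig()
    missing = [c for c in FEATURE_NAMES if c not in matrix.columns]
    if missing:
        raise ValueError(f"feature matrix missing columns {missing}")
    if "behaviour" not in matrix.columns:
        raise ValueError("feature matrix missing 'behaviour' label column")
    X = matrix.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = matrix["behaviour"].to_numpy()
    forest = GiniImportanceForest(
        n_trees=config.ntree, mtry=config.mtry, min_node=config.min_node,
        random_state=config.seed).fit(X, y)
    importance = {
        name: float(forest.feature_importances_[i])
        for i, name in enumerate(FEATURE_NAMES)
    }
    order = [FEATURE_NAMES[i] for i in forest.ranking_]
    return RankingResult(importance=importance, order=order, config=config)


def top_k(result: RankingResult, k: int = 3) -> list[str]:
    """First ``k`` feature names of the ranking (ties already resolved)."""
    if not 1 <= k <= len(result.order):
        raise ValueError(f"k must lie in [1, {len(result.order)}]")
    return list(result.order[:k])
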