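"""Random-forest feature selection.

The selection strategy, run independently inside every cross-validation
fold:

1. within each of the six feature sub-categories, rank features by mean
   random-forest Gini importance over repeated forests (default 50
   repetitions with seeds seed+1..seed+n_reps) and keep the top 50;
2. pool the per-sub-category winners (up to 300 features) and re-rank the
   pool the same way;
3. grow prefixes of the pooled ranking one feature at a time, training a
   forest on each prefix and recording its out-of-bag (OOB) error; the
   selected set is the SHORTEST prefix attaining the minimal OOB error.

Forests use scikit-learn's RandomForestClassifier with bootstrap sampling
and sqrt(F) features per split; its normalized mean-decrease-in-impurity
importances order features identically to unnormalized summed Gini
decreases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.ensemble import RandomForestClassifier

from .features import SUBCATEGORIES, FeatureTable

__all__ = [
    "RFConfig",
    "SelectionResult",
    "rf_gini_importance",
    "rank_subcategory",
    "pool_and_rerank",
    "incremental_oob_selection",
    "select_features",
]


@dataclass
class RFConfig:
    """Random-forest hyperparameters for the selection stages."""

    n_trees: int = 500
    n_reps: int = 50
    top_k: int = 50


@dataclass
class SelectionResult:
    """Outcome of one selection run (one cross-validation fold)."""

    pooled_ranking: list[str]
    oob_trace: np.ndarray
    selected: list[str]
    seed: int
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.oob_trace = np.asarray(self.oob_trace, dtype=float)
        if self.selected != self.pooled_ranking[: len(self.selected)]:
            raise ValueError("selected must be a prefix of pooled_ranking")

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "seed": int(self.seed),
                    "pooled_ranking": list(self.pooled_ranking),
                    "oob_trace": [float(v) for v in self.oob_trace],
                    "selected": list(self.selected),
                    "dropped": list(self.dropped),
                },
                fh, sort_keys=False)


def _make_forest(n_trees: int, seed: int, oob: bool = False) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        oob_score=oob,
        random_state=seed,
        n_jobs=1,
    )


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need two classes to estimate feature importance")
    if counts.min() < 2:
        raise ValueError("need at least 2 subjects per class")
    return X, y


def rf_gini_importance(X, y, n_trees: int = 500, seed: int = 0) -> np.ndarray:
    """Per-feature Gini importance from one random forest.

    Nonnegative; a constant feature is never split on and scores 0.
    """
    X, y = _validate_xy(X, y)
    forest = _make_forest(n_trees, seed)
    forest.fit(X, y)
    return forest.feature_importances_


def _mean_importance(X: np.ndarray, y: np.ndarray, n_trees: int,
                     n_reps: int, seed: int) -> np.ndarray:
    """Mean importance over n_reps forests seeded seed+1..seed+n_reps."""
    imp = np.zeros(X.shape[1])
    for rep in range(1, n_reps + 1):
        imp += rf_gini_importance(X, y, n_trees=n_trees, seed=seed + rep)
    return imp / n_reps


def _usable_columns(values: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop features a forest cannot split on: NaN or zero variance."""
    arr = values.to_numpy(dtype=float)
    finite = ~np.isnan(arr).any(axis=0)
    ok = finite.copy()
    ok[finite] = arr[:, finite].std(axis=0) > 0
    dropped = list(values.columns[~ok])
    return values.loc[:, ok], dropped


def rank_subcategory(table: FeatureTable, subcat: str, n_reps: int = 50,
                     top_k: int = 50, n_trees: int = 500,
                     seed: int = 0) -> list[str]:
    """Rank one sub-category's features by mean RF importance; return the top k.

    Zero-variance and NaN features are dropped before ranking. Ties break by
    column order, which is stable across runs.
    """
    names = table.features_of(subcat)
    if not names:
        return []
    sub, _ = _usable_columns(table.values[names])
    if sub.shape[1] == 0:
        return []
    y = table.labels.to_numpy()
    imp = _mean_importance(sub.to_numpy(dtype=float), y, n_trees, n_reps, seed)
    order = np.argsort(-imp, kind="stable")
    return [sub.columns[i] for i in order[: min(top_k, sub.shape[1])]]


def pool_and_rerank(rankings, table: FeatureTable, n_reps: int = 50,
                    n_trees: int = 500, seed: int = 0) -> list[str]:
    """Pool per-sub-category top lists and re-rank the union by mean RF
    importance on the pooled set."""
    pooled: list[str] = []
    for ranking in rankings:
        for name in ranking:
            if name in pooled:
                raise ValueError(f"duplicate feature across rankings: {name}")
            pooled.append(name)
    if not pooled:
        return []
    X = table.values[pooled].to_numpy(dtype=float)
    y = table.labels.to_numpy()
    imp = _mean_importance(X, y, n_trees, n_reps, seed)
    order = np.argsort(-imp, kind="stable")
    return [pooled[i] for i in order]


def _shortest_prefix_argmin(trace: np.ndarray) -> int:
    """1-based length of the shortest prefix attaining the minimal OOB error."""
    trace = np.asarray(trace, dtype=float)
    return int(np.argmin(trace)) + 1


def _oob_error(X: np.ndarray, y: np.ndarray, n_trees: int, seed: int) -> float:
    forest = _make_forest(n_trees, seed, oob=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        forest.fit(X, y)
        score = forest.oob_score_
    return 1.0 - float(score)


def incremental_oob_selection(pooled_ranking, table: FeatureTable,
                              n_trees: int = 500, seed: int = 0) -> SelectionResult:
    """Grow prefixes of the pooled ranking and pick the OOB-error minimiser.

    For prefix sizes 1..len(pooled_ranking) a forest is trained and its OOB
    error recorded; the selected set is the shortest prefix attaining the
    global minimum (ties break toward fewer features).
    """
    pooled_ranking = list(pooled_ranking)
    if not pooled_ranking:
        raise ValueError("pooled ranking is empty")
    y = table.labels.to_numpy()
    X_full = table.values[pooled_ranking].to_numpy(dtype=float)
    trace = np.empty(len(pooled_ranking))
    for m in range(1, len(pooled_ranking) + 1):
        trace[m - 1] = _oob_error(X_full[:, :m], y, n_trees, seed + m)
    n_sel = _shortest_prefix_argmin(trace)
    return SelectionResult(pooled_ranking=pooled_ranking, oob_trace=trace,
                           selected=pooled_ranking[:n_sel], seed=seed)


def select_features(table: FeatureTable, rf: RFConfig | None = None,
                    seed: int = 0) -> SelectionResult:
    """Full selection pipeline on one training table (one fold).

    Runs the per-sub-category ranking, pooling/re-ranking and incremental
    OOB minimisation with disjoint seed streams.
    """
    rf = rf or RFConfig()
    _, dropped = _usable_columns(table.values)
    rankings = [
        rank_subcategory(table, subcat, n_reps=rf.n_reps, top_k=rf.top_k,
                         n_trees=rf.n_trees, seed=seed + 100 * (i + 1))
        for i, subcat in enumerate(SUBCATEGORIES)
    ]
    pooled = pool_and_rerank(rankings, table, n_reps=rf.n_reps,
                             n_trees=rf.n_trees, seed=seed + 700)
    result = incremental_oob_selection(pooled, table, n_trees=rf.n_trees,
                                       seed=seed + 800)
    result.dropped = dropped
    return result
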