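"""Ensemble feature ranking fused by PageRank, with forward-adding selection.

Seven per-feature relevance rankings are computed independently, fused into a
single consensus order by a PageRank walk on an endorsement graph (each
ranking contributes directed edges from every feature to the feature ranked
immediately above it, so stationary mass accumulates on features that many
rankings place high), and the accuracy-optimal prefix of the fused order is
found by forward adding: cross-validated accuracy is evaluated at growing
prefix sizes and the smallest prefix attaining the maximum wins.

Ranking methods (all deterministic given the data):

``anova``     one-way ANOVA F statistic per feature
``mi``        mutual information after equal-width binning (10 bins)
``mrmr``      greedy minimal-redundancy maximal-relevance (F-test relevance,
              mean absolute Pearson correlation redundancy)
``lasso``     |coefficient| of an L1-regularized logistic model on
              standardized features at a fixed regularization strength
``pearson``   point-biserial correlation magnitude
``chi2``      chi-squared statistic on quartile-binned features
``relieff``   ReliefF with k=5 nearest hits/misses, range-normalized diffs

Constant features score 0 under every method and sink to the ranking tail in
canonical column order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import chi2_contingency
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import mutual_info_score
from sklearn.utils.validation import check_is_fitted

from .classify import SvmParams, cross_validate
from .encoders import FeatureMatrix

__all__ = [
    "Ranking",
    "SelectionResult",
    "SelectionConfig",
    "EnsembleRankSelector",
    "RANKING_METHODS",
    "rank_single",
    "fuse_pagerank",
    "forward_select",
    "select_features",
]


@dataclass
class Ranking:
    """An ordered permutation of the feature set, best first, with scores."""

    method_name: str
    features: list[str]
    scores: dict[str, float]
    canonical_order: list[str]

    def __post_init__(self) -> None:
        if sorted(self.features) != sorted(self.canonical_order):
            raise ValueError("ranking must be a permutation of the column set")
        if not all(np.isfinite(v) for v in self.scores.values()):
            raise ValueError("ranking scores must be finite")


@dataclass
class SelectionResult:
    """Fused ranking, chosen prefix, and its CV accuracy profile."""

    fused_ranking: Ranking
    selected_features: list[str]
    accuracy_curve: dict[int, float]
    best_size: int
    best_accuracy: float
    method_rankings: dict[str, Ranking] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fused_ranking": [
                {"rank": i + 1, "feature": f, "weight": self.fused_ranking.scores[f]}
                for i, f in enumerate(self.fused_ranking.features)
            ],
            "selected_features": self.selected_features,
            "accuracy_curve": {str(k): v for k, v in self.accuracy_curve.items()},
            "best_size": self.best_size,
            "best_accuracy": self.best_accuracy,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def ranking_tsv(self, path: str | Path) -> None:
        lines = [
            f"{i + 1}\t{f}" for i, f in enumerate(self.fused_ranking.features)
        ]
        Path(path).write_text("\n".join(lines) + "\n")


# --- individual ranking methods -------------------------------------------


def _score_anova(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    import warnings as _warnings

    with np.errstate(divide="ignore", invalid="ignore"), _warnings.catch_warnings():
        # constant columns are scored 0 and sunk deliberately
        _warnings.filterwarnings("ignore", message="Features .* are constant")
        f_stat, _ = f_classif(X, y)
    # zero within-class variance gives F = inf: a perfect separator, kept
    # as a large finite score so the ranking invariant (finite) holds
    return np.nan_to_num(f_stat, nan=0.0, posinf=1e300)


def _equal_width_bins(col: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = col.min(), col.max()
    if hi == lo:
        return np.zeros(len(col), dtype=int)
    edges = np.linspace(lo, hi, bins + 1)
    return np.clip(np.digitize(col, edges[1:-1]), 0, bins - 1)


def _score_mi(X: np.ndarray, y: np.ndarray, bins: int = 10) -> np.ndarray:
    return np.array(
        [mutual_info_score(y, _equal_width_bins(X[:, j], bins)) for j in range(X.shape[1])]
    )


def _score_pearson(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / denom
    return np.abs(np.nan_to_num(r))


def _score_chi2(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        if col.max() == col.min():
            continue
        # quartile bins; duplicate edges collapse for skewed columns
        edges = np.unique(np.quantile(col, [0.25, 0.5, 0.75]))
        binned = np.digitize(col, edges)
        table = pd.crosstab(binned, y).to_numpy()
        if table.shape[0] < 2:
            continue
        scores[j] = chi2_contingency(table, correction=False).statistic
    return scores


def _score_lasso(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> np.ndarray:
    sd = X.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    Z = (X - X.mean(axis=0)) / safe
    Z[:, sd == 0] = 0.0
    clf = LogisticRegression(
        l1_ratio=1.0, solver="liblinear", C=C, max_iter=1000, random_state=0
    )
    clf.fit(Z, y)
    return np.abs(clf.coef_.ravel())


def _score_relieff(X: np.ndarray, y: np.ndarray, k: int = 5) -> np.ndarray:
    """ReliefF weights: every instance is an anchor; k nearest hits and misses.

    Features are range-normalized so per-feature differences lie in [0, 1];
    weight = mean(miss diffs) - mean(hit diffs).
    """
    n, p = X.shape
    lo, hi = X.min(axis=0), X.max(axis=0)
    rng_ = np.where(hi > lo, hi - lo, 1.0)
    Z = (X - lo) / rng_
    Z[:, hi == lo] = 0.0
    dists = cdist(Z, Z)
    np.fill_diagonal(dists, np.inf)
    weights = np.zeros(p)
    for i in range(n):
        hits = np.flatnonzero(y == y[i])
        misses = np.flatnonzero(y != y[i])
        hits = hits[hits != i]
        kk_h = min(k, len(hits))
        kk_m = min(k, len(misses))
        if kk_h == 0 or kk_m == 0:
            continue
        near_h = hits[np.argsort(dists[i, hits], kind="stable")[:kk_h]]
        near_m = misses[np.argsort(dists[i, misses], kind="stable")[:kk_m]]
        weights += np.abs(Z[near_m] - Z[i]).mean(axis=0)
        weights -= np.abs(Z[near_h] - Z[i]).mean(axis=0)
    return weights / n


def _greedy_mrmr(X: np.ndarray, y: np.ndarray) -> tuple[list[int], np.ndarray]:
    """Greedy mRMR order and the selection-time score of each feature."""
    p = X.shape[1]
    relevance = _score_anova(X, y)
    sd = X.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    Z = (X - X.mean(axis=0)) / safe
    Z[:, sd == 0] = 0.0
    corr = np.abs(Z.T @ Z) / X.shape[0]
    order: list[int] = []
    scores = np.zeros(p)
    remaining = list(range(p))
    first = max(remaining, key=lambda j: (relevance[j], -j))
    order.append(first)
    scores[first] = relevance[first]
    remaining.remove(first)
    while remaining:
        sel = np.array(order)
        best_j, best_val = None, None
        for j in remaining:
            val = relevance[j] - corr[j, sel].mean()
            if best_val is None or val > best_val or (val == best_val and j < best_j):
                best_j, best_val = j, val
        order.append(best_j)
        scores[best_j] = best_val
        remaining.remove(best_j)
    return order, scores


_SCORERS: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "anova": _score_anova,
    "mi": _score_mi,
    "pearson": _score_pearson,
    "chi2": _score_chi2,
    "lasso": _score_lasso,
    "relieff": _score_relieff,
}

RANKING_METHODS: tuple[str, ...] = (
    "anova", "mi", "mrmr", "lasso", "pearson", "chi2", "relieff",
)


def rank_single(data: FeatureMatrix, method: str) -> Ranking:
    """Rank all features by one method; higher score = more discriminative.

    Ties break by canonical column order; constant columns are forced to
    score 0 and ranked after every non-constant column.
    """
    if method not in RANKING_METHODS:
        raise ValueError(
            f"unknown ranking method {method!r}; valid: {', '.join(RANKING_METHODS)}"
        )
    if data.y is None:
        raise ValueError("ranking requires a labeled matrix")
    X = data.X.to_numpy(dtype=float)
    y = data.y.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    columns = data.feature_names
    constant = X.max(axis=0) == X.min(axis=0)

    if method == "mrmr":
        order_idx, scores = _greedy_mrmr(X, y)
        scores = scores.copy()
        scores[constant] = 0.0
        order_idx = [j for j in order_idx if not constant[j]] + [
            j for j in range(len(columns)) if constant[j]
        ]
    else:
        scores = np.asarray(_SCORERS[method](X, y), dtype=float)
        scores[constant] = 0.0
        order_idx = sorted(
            range(len(columns)), key=lambda j: (bool(constant[j]), -scores[j], j)
        )
    return Ranking(
        method_name=method,
        features=[columns[j] for j in order_idx],
        scores={columns[j]: float(scores[j]) for j in range(len(columns))},
        canonical_order=list(columns),
    )


def fuse_pagerank(
    rankings: Sequence[Ranking], damping: float = 0.85
) -> Ranking:
    """Fuse rankings by PageRank on the endorsement graph.

    Each ranking adds a unit-weight directed edge from every feature to
    every feature ranked above it (lower endorses higher — the
    Markov-chain rank-aggregation construction), so the edge weight from
    a to b counts the rankings placing b above a.  Dangling mass is
    redistributed uniformly; the stationary weights sum to 1.  Output
    order: weight descending, ties by canonical column order.
    """
    if not rankings:
        raise ValueError("at least one ranking is required")
    feature_set = set(rankings[0].features)
    for r in rankings[1:]:
        if set(r.features) != feature_set:
            raise ValueError("all rankings must cover the same feature set")
    canonical = rankings[0].canonical_order
    p = len(canonical)
    idx = {f: i for i, f in enumerate(canonical)}
    W = np.zeros((p, p))
    for r in rankings:
        pos_arr = np.empty(p)
        for rank_pos, f in enumerate(r.features):
            pos_arr[idx[f]] = rank_pos
        W += pos_arr[:, None] > pos_arr[None, :]
    G = nx.from_numpy_array(W, create_using=nx.DiGraph)
    weights = nx.pagerank(
        G, alpha=damping, tol=1e-10, max_iter=10000, weight="weight"
    )
    ordered = sorted(range(p), key=lambda i: (-weights[i], i))
    return Ranking(
        method_name="pagerank_fusion",
        features=[canonical[i] for i in ordered],
        scores={canonical[i]: float(weights[i]) for i in range(p)},
        canonical_order=canonical,
    )


def _prefix_sizes(p: int, step: int, dense_limit: int = 200) -> list[int]:
    sizes = list(range(1, min(p, dense_limit) + 1, step))
    if p > dense_limit:
        sizes.extend(range(dense_limit + 5, p, 5))
    if sizes[-1] != p:
        sizes.append(p)
    return sizes


def forward_select(
    data: FeatureMatrix,
    fused: Ranking,
    evaluator: Callable[[FeatureMatrix], float],
    step: int = 1,
) -> SelectionResult:
    """Evaluate growing prefixes of the fused ranking; keep the best.

    Prefix sizes go 1, 1+step, ... up to 200 features, then every 5, always
    including the full set.  ``best_size`` is the smallest evaluated prefix
    attaining the maximum accuracy.
    """
    p = data.shape[1]
    if p == 0:
        raise ValueError("empty feature matrix")
    curve: dict[int, float] = {}
    for size in _prefix_sizes(p, step):
        subset = data.select(fused.features[:size])
        curve[size] = float(evaluator(subset))
    best_accuracy = max(curve.values())
    best_size = min(s for s, a in curve.items() if a == best_accuracy)
    return SelectionResult(
        fused_ranking=fused,
        selected_features=fused.features[:best_size],
        accuracy_curve=curve,
        best_size=best_size,
        best_accuracy=best_accuracy,
    )


@dataclass
class SelectionConfig:
    """Settings for the full rank-fuse-forward-add pipeline."""

    methods: Sequence[str] = RANKING_METHODS
    damping: float = 0.85
    step: int = 1
    cv: int = 5
    seed: int = 0
    svm_C: float = 1.0
    svm_g: float | None = None  # None -> 1 / (p * Var), sklearn 'scale'


def _default_evaluator(config: SelectionConfig) -> Callable[[FeatureMatrix], float]:
    def evaluate_subset(subset: FeatureMatrix) -> float:
        g = config.svm_g
        if g is None:
            A = subset.X.to_numpy(float)
            var = A.var()
            g = 1.0 / (A.shape[1] * var) if var > 0 else 1.0
        report = cross_validate(
            subset, SvmParams(C=config.svm_C, g=g), k=config.cv, seed=config.seed
        )
        return report.ACC

    return evaluate_subset


def select_features(
    data: FeatureMatrix,
    config: SelectionConfig | None = None,
    evaluator: Callable[[FeatureMatrix], float] | None = None,
) -> SelectionResult:
    """Rank by every configured method, fuse with PageRank, forward-add.

    The default prefix evaluator is the classify module's stratified CV
    accuracy with a fixed-seed RBF SVM at C=1 and the variance-scaled gamma.
    """
    config = config or SelectionConfig()
    rankings = {m: rank_single(data, m) for m in config.methods}
    fused = fuse_pagerank(list(rankings.values()), damping=config.damping)
    result = forward_select(
        data, fused, evaluator or _default_evaluator(config), step=config.step
    )
    result.method_rankings = rankings
    return result


class EnsembleRankSelector(SelectorMixin, BaseEstimator):
    """sklearn feature selector: ensemble ranking, PageRank fusion, forward adding.

    Parameters
    ----------
    methods : sequence of str
        Ranking methods to fuse (default: all seven).
    damping : float, default 0.85
        PageRank damping factor.
    step : int, default 1
        Prefix-size step during forward adding (dense up to 200 features,
        every 5 beyond).
    cv : int, default 5
        Fold count of the internal SVM accuracy evaluator.
    random_state : int, default 0
        Seed for the internal CV shuffling.

    Attributes
    ----------
    fused_ranking_ : list of str
        Features best-first after fusion.
    pagerank_weights_ : dict
    accuracy_curve_ : dict  (prefix size -> CV accuracy)
    best_size_, best_accuracy_ : int, float
    support_ : bool mask of the selected columns in input order
    """

    def __init__(
        self,
        methods: Sequence[str] = RANKING_METHODS,
        damping: float = 0.85,
        step: int = 1,
        cv: int = 5,
        random_state: int = 0,
    ) -> None:
        self.methods = methods
        self.damping = damping
        self.step = step
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y) -> "EnsembleRankSelector":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"f{j}" for j in range(X.shape[1])]
        data = FeatureMatrix(X.copy(), pd.Series(np.asarray(y), index=X.index))
        config = SelectionConfig(
            methods=self.methods,
            damping=self.damping,
            step=self.step,
            cv=self.cv,
            seed=self.random_state,
        )
        result = select_features(data, config)
        self.result_ = result
        self.fused_ranking_ = list(result.fused_ranking.features)
        self.pagerank_weights_ = dict(result.fused_ranking.scores)
        self.accuracy_curve_ = dict(result.accuracy_curve)
        self.best_size_ = result.best_size
        self.best_accuracy_ = result.best_accuracy
        selected = set(result.selected_features)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.support_ = np.array([c in selected for c in X.columns])
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_
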