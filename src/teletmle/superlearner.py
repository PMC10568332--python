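"""Cross-validated superlearner with practice-clustered, outcome-stratified
folds and a non-negative least squares (NNLS) metalearner.

The stacking contract: each learner is trained on the complement of every
fold to fill an out-of-fold prediction matrix Z; the metalearner solves

    alpha = argmin_{a >= 0} || y - Z a ||^2,

normalized to sum to one, and the final predictor is the alpha-weighted
combination of full-data refits, clipped away from 0/1 before any logit
transform.  Folds assign whole practices (clusters), so intra-practice
correlation never leaks across the train/validation split; practices are
dealt to folds serpentine-style by outcome prevalence so fold prevalences
track the global prevalence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler

__all__ = [
    "FoldAssignment",
    "LearnerSpec",
    "SuperLearnerFit",
    "make_folds",
    "nnls_meta",
    "cv_fit",
    "learner_library",
    "PROB_CLIP",
]

#: Probability clipping bound applied before any logit transform.
PROB_CLIP = 1e-6


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldAssignment:
    """Fold index per observation; whole clusters share a fold."""

    folds: np.ndarray  # 1..K per observation
    K: int
    seed: int
    cluster_fold: dict  # cluster id -> fold

    def validation_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.folds == k)

    def prevalences(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y)
        return np.array([y[self.folds == k].mean() for k in range(1, self.K + 1)])


def make_folds(cluster_ids, outcomes, K: int = 10, seed: int = 0) -> FoldAssignment:
    """Assign whole clusters (practices) to K folds, stratified by outcome.

    Clusters are sorted by outcome prevalence (seeded shuffle breaks ties)
    and dealt serpentine-style to folds, then size-rebalanced by moving
    clusters from the largest to the smallest fold whenever that does not
    worsen the spread of fold prevalences.  Deterministic given seed.
    """
    cluster_ids = np.asarray(cluster_ids)
    y = np.asarray(outcomes, dtype=float)
    if K < 2:
        raise ValueError("K must be >= 2")
    df = pd.DataFrame({"cluster": cluster_ids, "y": y})
    agg = df.groupby("cluster")["y"].agg(["size", "mean"]).reset_index()
    if len(agg) < K:
        raise ValueError(f"need at least K={K} clusters, got {len(agg)}")
    rng = np.random.default_rng(seed)
    agg = agg.sample(frac=1.0, random_state=np.random.RandomState(seed)).sort_values(
        "mean", kind="stable"
    )
    order = agg.reset_index(drop=True)
    # serpentine deal: 1..K, K..1, 1..K, ...
    fold_of = {}
    sizes = np.zeros(K)
    prev_sum = np.zeros(K)
    seq = list(range(K)) + list(range(K - 1, -1, -1))
    for i, row in enumerate(order.itertuples(index=False)):
        k = seq[i % (2 * K)]
        fold_of[row.cluster] = k
        sizes[k] += row.size
        prev_sum[k] += row.size * row.mean

    def _spread() -> float:
        with np.errstate(invalid="ignore"):
            prevs = np.where(sizes > 0, prev_sum / np.maximum(sizes, 1), np.nan)
        return float(np.nanmax(prevs) - np.nanmin(prevs))

    # size rebalancing passes
    by_cluster = {row.cluster: (row.size, row.mean) for row in order.itertuples(index=False)}
    for _ in range(10 * len(order)):
        big, small = int(np.argmax(sizes)), int(np.argmin(sizes))
        gap = sizes[big] - sizes[small]
        if gap <= max(1, order["size"].min()):
            break
        candidates = [c for c, k in fold_of.items() if k == big]
        rng.shuffle(candidates)
        moved = False
        for c in candidates:
            sz, mu = by_cluster[c]
            if sz >= gap:
                continue
            before = _spread()
            sizes[big] -= sz; sizes[small] += sz
            prev_sum[big] -= sz * mu; prev_sum[small] += sz * mu
            if _spread() <= before + 1e-12 and sizes[big] > 0:
                fold_of[c] = small
                moved = True
                break
            sizes[big] += sz; sizes[small] -= sz
            prev_sum[big] += sz * mu; prev_sum[small] -= sz * mu
        if not moved:
            break

    folds = np.array([fold_of[c] + 1 for c in cluster_ids], dtype=int)
    counts = np.bincount(folds, minlength=K + 1)[1:]
    if np.any(counts == 0):
        raise ValueError("fold construction produced an empty fold")
    return FoldAssignment(folds=folds, K=K, seed=seed, cluster_fold=dict(fold_of))


# ---------------------------------------------------------------------------
# learners
# ---------------------------------------------------------------------------

class SplineLogistic(BaseEstimator, ClassifierMixin):
    """Additive spline logistic regression (generalised-additive surrogate).

    Expands continuous columns (those with more than ``min_unique`` distinct
    values) in a B-spline basis and fits a (optionally L1-penalised)
    logistic regression on the expanded design; with an L1 penalty the
    spline basis is adaptively pruned.
    """

    def __init__(self, n_knots=5, degree=3, penalty=None, C=1.0, min_unique=10,
                 max_iter=300, random_state=None):
        self.n_knots = n_knots
        self.degree = degree
        self.penalty = penalty
        self.C = C
        self.min_unique = min_unique
        self.max_iter = max_iter
        self.random_state = random_state

    def _expand(self, X: np.ndarray, fit: bool) -> np.ndarray:
        if fit:
            nuniq = np.array([len(np.unique(X[:, j])) for j in range(X.shape[1])])
            self.cont_cols_ = np.flatnonzero(nuniq > self.min_unique)
            if len(self.cont_cols_):
                self.spliner_ = SplineTransformer(
                    n_knots=self.n_knots, degree=self.degree, include_bias=False
                ).fit(X[:, self.cont_cols_])
        if len(self.cont_cols_):
            S = self.spliner_.transform(X[:, self.cont_cols_])
            return np.hstack([X, S])
        return X

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        Xe = self._expand(X, fit=True)
        if self.penalty == "l1":
            lr = LogisticRegression(penalty="l1", solver="liblinear", C=self.C,
                                    max_iter=self.max_iter, random_state=self.random_state)
        else:
            lr = LogisticRegression(C=self.C, max_iter=self.max_iter)
        self.model_ = Pipeline([("scale", StandardScaler()), ("lr", lr)]).fit(Xe, y)
        self.classes_ = self.model_.named_steps["lr"].classes_
        return self

    def predict_proba(self, X):
        Xe = self._expand(np.asarray(X, dtype=float), fit=False)
        return self.model_.predict_proba(Xe)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


@dataclass(frozen=True)
class LearnerSpec:
    """Name plus a factory producing a fresh sklearn-style classifier."""

    name: str
    factory: Callable[[int], BaseEstimator]

    def build(self, seed: int) -> BaseEstimator:
        return self.factory(seed)


def _lib_full(seed_base: int = 0) -> list[LearnerSpec]:
    return [
        LearnerSpec("logistic", lambda s: Pipeline(
            [("scale", StandardScaler()),
             ("lr", LogisticRegression(C=1e6, max_iter=1000))])),
        LearnerSpec("gam_splines", lambda s: SplineLogistic(random_state=s)),
        LearnerSpec("random_forest", lambda s: RandomForestClassifier(
            n_estimators=300, min_samples_leaf=20, random_state=s, n_jobs=1)),
        LearnerSpec("gradient_boosting", lambda s: HistGradientBoostingClassifier(
            max_iter=150, max_depth=3, learning_rate=0.1, random_state=s)),
        LearnerSpec("adaptive_splines", lambda s: SplineLogistic(
            penalty="l1", C=0.5, random_state=s)),
        LearnerSpec("lasso", lambda s: Pipeline(
            [("scale", StandardScaler()),
             ("lr", LogisticRegression(penalty="l1", solver="liblinear", C=1.0,
                                       random_state=s))])),
    ]


def _lib_fast(seed_base: int = 0) -> list[LearnerSpec]:
    return [
        LearnerSpec("logistic", lambda s: Pipeline(
            [("scale", StandardScaler()),
             ("lr", LogisticRegression(C=1e6, max_iter=1000))])),
        LearnerSpec("lasso", lambda s: Pipeline(
            [("scale", StandardScaler()),
             ("lr", LogisticRegression(penalty="l1", solver="liblinear", C=1.0,
                                       random_state=s))])),
        LearnerSpec("gradient_boosting", lambda s: HistGradientBoostingClassifier(
            max_iter=40, max_depth=2, learning_rate=0.3, min_samples_leaf=20,
            random_state=s)),
    ]


def learner_library(profile: str = "full") -> list[LearnerSpec]:
    """The default learner libraries.

    ``full``: logistic, additive splines, random forest, gradient boosting,
    L1-pruned adaptive splines, lasso logistic — six families with
    complementary strengths.  ``fast``: logistic + lasso + shallow boosting,
    for simulation studies and quick runs.
    """
    if profile == "full":
        return _lib_full()
    if profile == "fast":
        return _lib_fast()
    raise ValueError(f"unknown learner profile {profile!r}")


# ---------------------------------------------------------------------------
# metalearner and stacking
# ---------------------------------------------------------------------------

def nnls_meta(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Non-negative least squares metalearner weights, normalized to sum 1.

    If the unconstrained-at-zero solution is identically zero the weights
    fall back to uniform with a warning.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    if Z.ndim != 2 or Z.shape[1] == 0:
        raise ValueError("Z must be a nonempty 2-D prediction matrix")
    if not np.any(Z):
        raise ValueError("rank-0 prediction matrix")
    alpha, _ = nnls(Z, y)
    total = alpha.sum()
    if total <= 0:
        warnings.warn("all NNLS weights are zero; falling back to uniform weights")
        return np.full(Z.shape[1], 1.0 / Z.shape[1])
    return alpha / total


def _discrete_meta(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Discrete superlearner: all weight on the single best CV learner."""
    risks = ((Z - y[:, None]) ** 2).mean(axis=0)
    alpha = np.zeros(Z.shape[1])
    alpha[int(np.argmin(risks))] = 1.0
    return alpha


@dataclass
class SuperLearnerFit:
    """Cross-validated stack: fold map, Z matrix, weights, refit learners."""

    learner_names: list[str]
    Z: np.ndarray
    alpha: np.ndarray
    folds: FoldAssignment
    refits: list[BaseEstimator]
    metalearner: str = "nnls"
    dropped: list[str] = field(default_factory=list)
    #: NNLS solution before sum-to-one normalization (optimality holds here)
    alpha_raw: np.ndarray | None = None

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        p = np.zeros(len(X))
        for a, est in zip(self.alpha, self.refits):
            if a > 0:
                p += a * est.predict_proba(X)[:, 1]
        return np.clip(p, PROB_CLIP, 1 - PROB_CLIP)

    def cv_risk(self, y) -> np.ndarray:
        """Per-learner cross-validated squared-error risk."""
        y = np.asarray(y, dtype=float)
        return ((self.Z - y[:, None]) ** 2).mean(axis=0)

    def cv_stack_risk(self, y) -> float:
        y = np.asarray(y, dtype=float)
        return float(((self.Z @ self.alpha - y) ** 2).mean())

    def weights(self) -> dict[str, float]:
        return dict(zip(self.learner_names, (float(a) for a in self.alpha)))


def _proba1(est: BaseEstimator, X: np.ndarray) -> np.ndarray:
    p = est.predict_proba(X)
    if p.shape[1] == 1:  # degenerate single-class fit
        cls = est.classes_[0]
        return np.full(len(X), float(cls))
    return p[:, 1]


def cv_fit(
    X,
    y,
    folds: FoldAssignment,
    learners: Sequence[LearnerSpec] | None = None,
    seed: int = 0,
    metalearner: str = "nnls",
) -> SuperLearnerFit:
    """Fit the superlearner: out-of-fold Z, metalearner weights, full refits.

    A learner that fails on any fold is dropped entirely with a logged
    warning (never silently treated as a zero column).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if learners is None:
        learners = learner_library("full")
    if not set(np.unique(y)).issubset({0.0, 1.0}):
        raise ValueError("y must be binary")
    n, L = len(y), len(learners)
    Z = np.full((n, L), np.nan)
    failed = set()
    for k in range(1, folds.K + 1):
        val = folds.validation_indices(k)
        train = np.flatnonzero(folds.folds != k)
        for j, spec in enumerate(learners):
            if j in failed:
                continue
            try:
                est = spec.build(seed + 1000 * j + k)
                est.fit(X[train], y[train])
                Z[val, j] = _proba1(est, X[val])
            except Exception as exc:  # noqa: BLE001 - contract: drop with warning
                warnings.warn(f"learner {spec.name!r} failed on fold {k}: {exc}; dropping it")
                failed.add(j)
    keep = [j for j in range(L) if j not in failed]
    if not keep:
        raise RuntimeError("every learner failed during cross-validation")
    Z = np.clip(Z[:, keep], PROB_CLIP, 1 - PROB_CLIP)
    kept_specs = [learners[j] for j in keep]

    if metalearner == "nnls":
        alpha_raw, _ = nnls(Z, y)
        alpha = nnls_meta(Z, y)
    elif metalearner == "discrete":
        alpha = _discrete_meta(Z, y)
        alpha_raw = alpha.copy()
    else:
        raise ValueError(f"unknown metalearner {metalearner!r}")

    refits = []
    for j, spec in enumerate(kept_specs):
        est = spec.build(seed + 1000 * keep[j])
        est.fit(X, y)
        refits.append(est)
    return SuperLearnerFit(
        learner_names=[s.name for s in kept_specs],
        Z=Z,
        alpha=alpha,
        folds=folds,
        refits=refits,
        metalearner=metalearner,
        dropped=[learners[j].name for j in sorted(failed)],
        alpha_raw=alpha_raw,
    )
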