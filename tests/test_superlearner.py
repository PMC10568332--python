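"""Superlearner: clustered stratified folds, NNLS metalearner, stacking."""

import warnings

import numpy as np
import pytest
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from teletmle.superlearner import (
    LearnerSpec,
    cv_fit,
    learner_library,
    make_folds,
    nnls_meta,
)


def _clustered_data(rng, n_clusters=20, per=50, beta=1.0):
    cluster = np.repeat(np.arange(n_clusters), per)
    X = rng.normal(size=(n_clusters * per, 4))
    u = rng.normal(0, 0.3, n_clusters)[cluster]
    y = (rng.random(len(cluster)) < expit(beta * X[:, 0] - 0.5 * X[:, 1] + u)).astype(float)
    return cluster, X, y


# -- folds --------------------------------------------------------------------

def test_equal_clusters_give_equal_folds(rng):
    cluster, _, y = _clustered_data(rng, n_clusters=20, per=50)
    fa = make_folds(cluster, y, K=10, seed=0)
    sizes = np.bincount(fa.folds)[1:]
    assert (sizes == 100).all()


def test_no_cluster_ever_split(rng):
    cluster, _, y = _clustered_data(rng, n_clusters=37, per=13)
    fa = make_folds(cluster, y, K=10, seed=3)
    for c in np.unique(cluster):
        assert len(np.unique(fa.folds[cluster == c])) == 1


def test_folds_deterministic_and_nonempty(rng):
    cluster, _, y = _clustered_data(rng)
    a = make_folds(cluster, y, K=10, seed=5)
    b = make_folds(cluster, y, K=10, seed=5)
    assert (a.folds == b.folds).all()
    assert all((a.folds == k).any() for k in range(1, 11))


def test_fewer_clusters_than_folds_is_error():
    with pytest.raises(ValueError):
        make_folds(np.repeat([0, 1, 2], 5), np.zeros(15), K=10, seed=0)


def test_stratified_folds_beat_random_assignment(rng):
    """Fold outcome prevalences track the global prevalence better than
    random cluster-to-fold assignment (averaged over 100 permutations)."""
    n_clusters, per = 30, 30
    cluster = np.repeat(np.arange(n_clusters), per)
    prevs = np.linspace(0.1, 0.9, n_clusters)
    y = (rng.random(len(cluster)) < prevs[cluster]).astype(float)
    fa = make_folds(cluster, y, K=10, seed=1)
    ours = fa.prevalences(y).max() - fa.prevalences(y).min()

    spreads = []
    for _ in range(100):
        perm = rng.integers(0, 10, n_clusters)
        fp = [
            y[np.isin(cluster, np.flatnonzero(perm == k))].mean()
            for k in range(10)
            if (perm == k).any()
        ]
        spreads.append(max(fp) - min(fp))
    assert ours <= np.mean(spreads)


# -- NNLS metalearner ---------------------------------------------------------

def test_nnls_single_column_weight_one(rng):
    Z = rng.uniform(0.1, 0.9, size=(50, 1))
    y = (rng.random(50) < Z[:, 0]).astype(float)
    assert nnls_meta(Z, y) == pytest.approx([1.0])


def test_nnls_recovers_perfect_column_vs_simplex_grid(rng):
    """y equals column 1 exactly, column 2 is noise: NNLS puts all weight on
    column 1, agreeing with a brute-force simplex grid search to 1e-3."""
    n = 400
    y = (rng.random(n) < 0.5).astype(float)
    Z = np.column_stack([y, rng.uniform(0, 1, n)])
    alpha = nnls_meta(Z, y)

    grid = np.linspace(0, 1, 2001)
    risks = [((y - (a * Z[:, 0] + (1 - a) * Z[:, 1])) ** 2).mean() for a in grid]
    best = grid[int(np.argmin(risks))]
    assert alpha[0] == pytest.approx(best, abs=1e-3)
    assert alpha[0] == pytest.approx(1.0, abs=1e-6)


def test_nnls_duplicate_columns_degeneracy(rng):
    n = 300
    p = rng.uniform(0.2, 0.8, n)
    y = (rng.random(n) < p).astype(float)
    alpha1 = nnls_meta(p[:, None], y)
    alpha2 = nnls_meta(np.column_stack([p, p]), y)
    assert alpha2.sum() == pytest.approx(1.0)
    fitted1 = p[:, None] @ alpha1
    fitted2 = np.column_stack([p, p]) @ alpha2
    np.testing.assert_allclose(fitted1, fitted2, atol=1e-8)


def test_nnls_rank_zero_is_error():
    with pytest.raises(ValueError):
        nnls_meta(np.zeros((10, 2)), np.zeros(10))


# -- stacking -----------------------------------------------------------------

def _logistic_spec():
    return LearnerSpec(
        "logistic",
        lambda s: Pipeline([("scale", StandardScaler()),
                            ("lr", LogisticRegression(C=1e6, max_iter=1000))]),
    )


def test_single_learner_stack_equals_refit(rng):
    cluster, X, y = _clustered_data(rng)
    folds = make_folds(cluster, y, K=5, seed=0)
    fit = cv_fit(X, y, folds, [_logistic_spec()], seed=0)
    assert fit.weights() == {"logistic": 1.0}
    direct = _logistic_spec().build(0).fit(X, y).predict_proba(X)[:, 1]
    np.testing.assert_allclose(fit.predict(X), np.clip(direct, 1e-6, 1 - 1e-6), atol=1e-9)


def test_duplicated_learner_leaves_predictions_unchanged(rng):
    cluster, X, y = _clustered_data(rng)
    folds = make_folds(cluster, y, K=5, seed=0)
    single = cv_fit(X, y, folds, [_logistic_spec()], seed=0)
    double = cv_fit(X, y, folds, [_logistic_spec(), _logistic_spec()], seed=0)
    assert double.alpha.sum() == pytest.approx(1.0)
    np.testing.assert_allclose(single.predict(X), double.predict(X), atol=1e-6)


def test_failing_learner_dropped_with_warning(rng):
    class Boom:
        def fit(self, X, y):
            raise RuntimeError("boom")

    cluster, X, y = _clustered_data(rng)
    folds = make_folds(cluster, y, K=5, seed=0)
    specs = [_logistic_spec(), LearnerSpec("boom", lambda s: Boom())]
    with pytest.warns(UserWarning, match="boom"):
        fit = cv_fit(X, y, folds, specs, seed=0)
    assert fit.learner_names == ["logistic"]
    assert fit.dropped == ["boom"]
    assert fit.Z.shape[1] == 1


def test_nnls_stack_optimality_on_training_criterion(rng):
    """The un-normalized NNLS stack never has larger CV squared error than
    the best single learner (each basis vector is feasible)."""
    cluster, X, y = _clustered_data(rng, n_clusters=25, per=40)
    folds = make_folds(cluster, y, K=5, seed=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = cv_fit(X, y, folds, learner_library("fast"), seed=2)
    raw_risk = ((y - fit.Z @ fit.alpha_raw) ** 2).mean()
    single_risks = fit.cv_risk(y)
    assert raw_risk <= single_risks.min() + 1e-10


def test_stack_beats_worst_learner_under_logistic_truth(rng):
    """y from a logistic model in X: the stacked CV risk does not exceed the
    worst library member's CV risk."""
    cluster, X, y = _clustered_data(rng, n_clusters=40, per=50, beta=1.5)
    folds = make_folds(cluster, y, K=5, seed=4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = cv_fit(X, y, folds, learner_library("fast"), seed=4)
    assert fit.cv_stack_risk(y) <= fit.cv_risk(y).max() + 1e-8


def test_out_of_fold_discipline(rng):
    """Z entries for a fold come from models that never saw that fold: a
    learner that memorizes training labels cannot predict its own fold."""

    class Memorizer:
        def fit(self, X, y):
            self.keys = {tuple(row): yy for row, yy in zip(X, y)}
            self.classes_ = np.array([0.0, 1.0])
            return self

        def predict_proba(self, X):
            p = np.array([self.keys.get(tuple(row), 0.5) for row in X])
            return np.column_stack([1 - p, p])

    cluster, X, y = _clustered_data(rng, n_clusters=10, per=20)
    folds = make_folds(cluster, y, K=5, seed=0)
    fit = cv_fit(X, y, folds, [LearnerSpec("memo", lambda s: Memorizer())], seed=0)
    # out-of-fold predictions are the 0.5 fallback, not the memorized labels
    assert np.allclose(fit.Z[:, 0], 0.5)


def test_discrete_metalearner_picks_single_learner(rng):
    cluster, X, y = _clustered_data(rng)
    folds = make_folds(cluster, y, K=5, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = cv_fit(X, y, folds, learner_library("fast"), seed=0, metalearner="discrete")
    assert sorted(fit.alpha) == [0.0, 0.0, 1.0]


def test_full_library_has_six_families():
    names = [s.name for s in learner_library("full")]
    assert names == ["logistic", "gam_splines", "random_forest",
                     "gradient_boosting", "adaptive_splines", "lasso"]
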