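import numpy as np
import pytest

from masegc.ensemble import (
    BaseLearnerSpec,
    FoldPlan,
    LEARNER_KINDS,
    build_meta_features,
    grid_search,
    make_base_learner,
    predict,
    train_stacking,
)
from masegc.errors import ConfigError, DimensionError, FoldPlanError


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(7)
    X = np.vstack([rng.normal(-2, 0.5, (40, 8)), rng.normal(2, 0.5, (40, 8))])
    y = np.array([0] * 40 + [1] * 40)
    return X, y


# -- base learners ---------------------------------------------------------


def test_unknown_kind_rejected():
    with pytest.raises(ConfigError):
        BaseLearnerSpec("perceptron")


@pytest.mark.parametrize("kind", LEARNER_KINDS)
def test_learner_contract(kind, separable):
    X, y = separable
    learner = make_base_learner(BaseLearnerSpec(kind, seed=1))
    if kind == "cnn1d":
        learner.set_params(epochs=20)
    learner.fit(X, y)
    proba = learner.predict_proba(X)
    assert proba.shape == (len(y), 2)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
    assert ((proba >= 0) & (proba <= 1)).all()


def test_decision_tree_shatters_separable(separable):
    X, y = separable
    tree = make_base_learner(BaseLearnerSpec("decision_tree", seed=0))
    tree.fit(X, y)
    assert (tree.predict(X) == y).mean() == 1.0


def test_cnn_learns_separable(separable):
    X, y = separable
    cnn = make_base_learner(BaseLearnerSpec("cnn1d", {"epochs": 30}, seed=2))
    cnn.fit(X, y)
    assert (cnn.predict(X) == y).mean() >= 0.95


# -- grid search -----------------------------------------------------------


def test_grid_size_one_returned(separable):
    X, y = separable
    spec = BaseLearnerSpec("random_forest", grid={"n_estimators": [37]}, seed=0)
    assert grid_search(spec, X, y)["n_estimators"] == 37


def test_svm_grid_evaluates_nine_candidates(separable, monkeypatch):
    X, y = separable
    import masegc.ensemble as ens

    counter = {"n": 0}
    real = ens.make_base_learner

    def spy(spec):
        counter["n"] += 1
        return real(spec)

    monkeypatch.setattr(ens, "make_base_learner", spy)
    spec = BaseLearnerSpec("svm_rbf", seed=0)
    best = ens.grid_search(spec, X, y, n_folds=3)
    assert counter["n"] == 9 * 3  # printed grid: 3 C values x 3 gammas, 3 folds
    assert best["C"] in (0.001, 0.01, 0.1)
    assert best["gamma"] in (1, 10, 100)


def test_grid_tie_keeps_first(separable):
    X, y = separable
    spec = BaseLearnerSpec("decision_tree", grid={"max_depth": [None, None]}, seed=0)
    # identical candidates score identically; the first must win
    assert grid_search(spec, X, y)["max_depth"] is None


def test_empty_grid_returns_fixed_params(separable):
    X, y = separable
    spec = BaseLearnerSpec("decision_tree", params={"max_depth": 3}, seed=0)
    assert grid_search(spec, X, y) == {"max_depth": 3}


# -- fold plans ------------------------------------------------------------


def test_fold_plan_partitions_exactly():
    y = np.array([0, 1] * 20)
    plan = FoldPlan.make(y, 5, seed=3)
    seen = np.concatenate([va for _, va in plan.splits])
    assert sorted(seen.tolist()) == list(range(40))
    for tr, va in plan.splits:
        assert np.intersect1d(tr, va).size == 0


def test_fold_plan_stratification_within_one_sample():
    y = np.array([1] * 30 + [0] * 10)
    plan = FoldPlan.make(y, 5, seed=1)
    for _, va in plan.splits:
        pos = y[va].sum()
        assert abs(pos - 6) <= 1  # 30 positives / 5 folds


def test_fold_plan_small_class_rejected():
    y = np.array([1] * 30 + [0] * 3)
    with pytest.raises(FoldPlanError):
        FoldPlan.make(y, 5, seed=0)


# -- meta features ---------------------------------------------------------


def test_meta_width_matches_learner_count(separable):
    X, y = separable
    specs = [BaseLearnerSpec(k, {"epochs": 10} if k == "cnn1d" else {}, seed=i)
             for i, k in enumerate(LEARNER_KINDS)]
    plan = FoldPlan.make(y, 4, seed=2)
    meta = build_meta_features(specs, plan, X, y)
    assert meta.X_meta.shape == (len(y), 5)
    assert meta.learner_kinds == list(LEARNER_KINDS)


def test_single_learner_meta_tracks_labels(separable):
    X, y = separable
    plan = FoldPlan.make(y, 4, seed=2)
    meta = build_meta_features([BaseLearnerSpec("random_forest", seed=0)], plan, X, y)
    col = meta.X_meta[:, 0]
    # separable data: out-of-fold probabilities order the classes perfectly
    assert ((col > 0.5) == (y == 1)).mean() == 1.0


def test_out_of_fold_discipline_bookkeeping(separable):
    X, y = separable
    plan = FoldPlan.make(y, 4, seed=5)
    meta = build_meta_features([BaseLearnerSpec("decision_tree", seed=0)], plan, X, y)
    for k, (tr, va) in enumerate(plan.splits):
        assert (meta.fold_of_sample[va] == k).all()
        assert np.intersect1d(tr, va).size == 0


def test_leakage_canary_memorizer_stays_at_chance(rng):
    """A decision tree memorizes its training set; on pure-noise labels its
    out-of-fold meta column must stay near chance. Only a leak of the target
    sample into training could push it toward perfect accuracy."""
    X = rng.normal(size=(60, 6))
    y = np.array([0, 1] * 30)
    plan = FoldPlan.make(y, 5, seed=1)
    meta = build_meta_features([BaseLearnerSpec("decision_tree", seed=0)], plan, X, y)
    oof_acc = (((meta.X_meta[:, 0] > 0.5).astype(int)) == y).mean()
    assert oof_acc < 0.8  # in-sample accuracy would be exactly 1.0
    tree = make_base_learner(BaseLearnerSpec("decision_tree", seed=0))
    tree.fit(X, y)
    assert (tree.predict(X) == y).mean() == 1.0  # confirms the memorization


# -- stacking --------------------------------------------------------------


def _fast_specs(seed=0):
    return [
        BaseLearnerSpec("svm_rbf", seed=seed),
        BaseLearnerSpec("decision_tree", seed=seed + 1),
        BaseLearnerSpec("cnn1d", {"epochs": 15}, seed=seed + 2),
    ]


def test_stacking_recovers_separable(separable):
    X, y = separable
    rng = np.random.default_rng(99)
    holdout = rng.choice(len(y), size=20, replace=False)
    train = np.setdiff1d(np.arange(len(y)), holdout)
    model = train_stacking(X[train], y[train], _fast_specs(), inner_folds=4, seed=3)
    labels, proba = predict(model, X[holdout])
    assert (labels == y[holdout]).mean() >= 0.95
    assert ((proba >= 0) & (proba <= 1)).all()


def test_stacking_single_learner_width_one(separable):
    X, y = separable
    model = train_stacking(
        X, y, [BaseLearnerSpec("decision_tree", seed=0)], inner_folds=4, seed=1
    )
    assert model.meta_dataset.X_meta.shape[1] == 1
    labels, _ = predict(model, X)
    assert set(labels) <= {0, 1}


def test_stacking_deterministic(separable):
    X, y = separable
    a = train_stacking(X, y, _fast_specs(), inner_folds=4, seed=11)
    b = train_stacking(X, y, _fast_specs(), inner_folds=4, seed=11)
    la, pa = predict(a, X)
    lb, pb = predict(b, X)
    np.testing.assert_array_equal(la, lb)
    np.testing.assert_array_equal(pa, pb)


def test_predict_row_order_equivariance(separable):
    X, y = separable
    model = train_stacking(X, y, _fast_specs(), inner_folds=4, seed=2)
    perm = np.random.default_rng(0).permutation(len(y))
    l1, p1 = predict(model, X)
    l2, p2 = predict(model, X[perm])
    np.testing.assert_array_equal(l1[perm], l2)
    np.testing.assert_allclose(p1[perm], p2, atol=1e-12)


def test_predict_width_mismatch(separable):
    X, y = separable
    model = train_stacking(X, y, [BaseLearnerSpec("svm_rbf", seed=0)], inner_folds=4, seed=0)
    with pytest.raises(DimensionError):
        predict(model, X[:, :4])


def test_tie_probability_maps_to_positive():
    # direct check of the documented tie rule on the thresholding step
    p = np.array([0.5, 0.49999, 0.50001])
    labels = (p >= 0.5).astype(int)
    np.testing.assert_array_equal(labels, [1, 0, 1])
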