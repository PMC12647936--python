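"""Stacking ensemble: five base learners, out-of-fold meta-features, and a
gradient-boosted-tree meta-classifier.

Base learners (RBF-kernel SVM, random forest, decision tree, AdaBoost, and a
1-D CNN over the fused latent vector) all honor a ``fit`` / ``predict_proba``
contract. For each inner fold the learners are trained on the fold's training
part and emit positive-class probabilities for its validation part; stacking
the folds gives every training sample a meta-row produced by models that
never saw it. The meta-classifier is XGBoost with 50 boosting rounds. After
meta-training the base learners are refit on the full outer-training set for
deployment.

Tumor is the positive class throughout: TP counts tumors, so specificity
measures normal-tissue recognition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from xgboost import XGBClassifier

from ._cnn import Conv1DClassifier
from .errors import ConfigError, DimensionError, FoldPlanError

__all__ = [
    "LEARNER_KINDS",
    "BaseLearnerSpec",
    "FoldPlan",
    "MetaDataset",
    "StackingModel",
    "make_base_learner",
    "make_meta_classifier",
    "grid_search",
    "build_meta_features",
    "train_stacking",
    "predict",
]

LEARNER_KINDS = ("svm_rbf", "random_forest", "decision_tree", "adaboost", "cnn1d")

# the SVM base learner needs per-sample probabilities for the meta-features;
# SVC(probability=True) still provides them on current scikit-learn releases
warnings.filterwarnings(
    "ignore",
    message="The `probability` parameter was deprecated",
    category=FutureWarning,
)

#: hyperparameter grids as printed in the protocol this package follows;
#: the decision tree uses library defaults and the CNN is tuned empirically,
#: so neither carries a default grid
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svm_rbf": {"C": [0.001, 0.01, 0.1], "gamma": [1, 10, 100]},
    "random_forest": {"n_estimators": [200, 500]},
    "decision_tree": {},
    "adaboost": {"n_estimators": [100, 200, 300]},
    "cnn1d": {},
}

#: pinned settings used when grid search is disabled
DEFAULT_PARAMS: dict[str, dict] = {
    "svm_rbf": {"C": 1.0, "gamma": "scale"},
    "random_forest": {"n_estimators": 200},
    "decision_tree": {},
    "adaboost": {"n_estimators": 100},
    "cnn1d": {},
}


@dataclass
class BaseLearnerSpec:
    """One base learner: kind, fixed hyperparameters, optional search grid."""

    kind: str
    params: dict = field(default_factory=dict)
    grid: dict[str, list] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in LEARNER_KINDS:
            raise ConfigError(f"unknown base learner kind {self.kind!r}")

    def with_params(self, params: dict) -> "BaseLearnerSpec":
        return BaseLearnerSpec(self.kind, {**self.params, **params}, self.grid, self.seed)


def make_base_learner(spec: BaseLearnerSpec):
    """Instantiate a fresh, unfitted learner honoring fit/predict_proba."""
    params = {**DEFAULT_PARAMS[spec.kind], **spec.params}
    if spec.kind == "svm_rbf":
        return SVC(kernel="rbf", probability=True, random_state=spec.seed, **params)
    if spec.kind == "random_forest":
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **params)
    if spec.kind == "decision_tree":
        from sklearn.tree import DecisionTreeClassifier

        # library defaults, pinned: Gini impurity, best-split, no depth limit
        return DecisionTreeClassifier(
            criterion=params.pop("criterion", "gini"), random_state=spec.seed, **params
        )
    if spec.kind == "adaboost":
        return AdaBoostClassifier(random_state=spec.seed, **params)
    if spec.kind == "cnn1d":
        return Conv1DClassifier(seed=spec.seed, **params)
    raise ConfigError(f"unknown base learner kind {spec.kind!r}")  # pragma: no cover


def make_meta_classifier(seed: int = 0, n_estimators: int = 50) -> XGBClassifier:
    """Gradient-boosted trees, 50 rounds, depth 3, learning rate 0.1."""
    return XGBClassifier(
        n_estimators=n_estimators,
        max_depth=3,
        learning_rate=0.1,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
    )


@dataclass
class FoldPlan:
    """Stratified splits of one sample set into disjoint validation folds."""

    splits: list[tuple[np.ndarray, np.ndarray]]
    n_samples: int
    stratified: bool
    seed: int

    @classmethod
    def make(cls, y: np.ndarray, n_folds: int, seed: int, stratified: bool = True) -> "FoldPlan":
        y = np.asarray(y, dtype=int)
        if stratified and np.bincount(y, minlength=2).min() < n_folds:
            raise FoldPlanError(
                f"cannot stratify {n_folds} folds: smallest class has "
                f"{np.bincount(y, minlength=2).min()} samples"
            )
        kf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = [(tr.copy(), va.copy()) for tr, va in kf.split(np.zeros_like(y), y)]
        plan = cls(splits, len(y), stratified, seed)
        plan.validate()
        return plan

    def validate(self) -> None:
        seen = np.zeros(self.n_samples, dtype=int)
        for tr, va in self.splits:
            if np.intersect1d(tr, va).size:
                raise FoldPlanError("train and validation parts overlap")
            seen[va] += 1
        if not (seen == 1).all():
            raise FoldPlanError("validation folds must partition the samples exactly")


@dataclass
class MetaDataset:
    """Out-of-fold base-learner probabilities (one column per learner)."""

    X_meta: np.ndarray
    y: np.ndarray
    learner_kinds: list[str]
    fold_of_sample: np.ndarray  # which inner fold produced each meta-row

    def __post_init__(self) -> None:
        if self.X_meta.shape != (len(self.y), len(self.learner_kinds)):
            raise DimensionError("meta matrix shape must be (n_samples, n_learners)")
        if ((self.X_meta < 0) | (self.X_meta > 1)).any():
            raise DimensionError("meta-features are probabilities and must lie in [0,1]")


def _positive_proba(learner, X: np.ndarray) -> np.ndarray:
    proba = learner.predict_proba(X)
    pos = int(np.flatnonzero(np.asarray(learner.classes_) == 1)[0])
    return proba[:, pos]


def grid_search(
    spec: BaseLearnerSpec, X: np.ndarray, y: np.ndarray, n_folds: int = 3, seed: int = 0
) -> dict:
    """Exhaustive search over the spec's grid by stratified CV, F1 selection.

    Candidates are evaluated in cross-product order (first grid key varies
    slowest); ties keep the earliest candidate. An empty grid returns the
    spec's fixed parameters unchanged.
    """
    grid = spec.grid if spec.grid is not None else DEFAULT_GRIDS[spec.kind]
    if not grid:
        return dict(spec.params)
    keys = list(grid)
    plan = FoldPlan.make(y, n_folds, seed)
    best_params, best_score = None, -np.inf
    for combo in product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        scores = []
        for tr, va in plan.splits:
            learner = make_base_learner(spec.with_params(params))
            learner.fit(X[tr], y[tr])
            pred = (_positive_proba(learner, X[va]) >= 0.5).astype(int)
            scores.append(f1_score(y[va], pred, zero_division=0))
        score = float(np.mean(scores))
        if score > best_score:  # strict: ties keep the first candidate
            best_params, best_score = params, score
    return {**spec.params, **best_params}


def build_meta_features(
    specs: Sequence[BaseLearnerSpec], plan: FoldPlan, X: np.ndarray, y: np.ndarray
) -> MetaDataset:
    """One meta-row per sample from models that never saw that sample."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if plan.n_samples != len(y):
        raise FoldPlanError("fold plan covers a different number of samples")
    meta = np.full((len(y), len(specs)), np.nan)
    fold_of = np.full(len(y), -1, dtype=int)
    for k, (tr, va) in enumerate(plan.splits):
        for j, spec in enumerate(specs):
            learner = make_base_learner(spec)
            learner.fit(X[tr], y[tr])
            meta[va, j] = _positive_proba(learner, X[va])
        fold_of[va] = k
    if np.isnan(meta).any():
        raise FoldPlanError("a sample was covered by no validation fold")
    return MetaDataset(meta, y, [s.kind for s in specs], fold_of)


@dataclass
class StackingModel:
    """Fitted base learners (refit on the full training set) + meta-classifier."""

    specs: list[BaseLearnerSpec]
    base_learners: list
    meta: XGBClassifier
    plan: FoldPlan
    seed: int
    meta_dataset: MetaDataset | None = None

    @property
    def learner_kinds(self) -> list[str]:
        return [s.kind for s in self.specs]


def train_stacking(
    Z: np.ndarray,
    y: np.ndarray,
    specs: Sequence[BaseLearnerSpec],
    plan: FoldPlan | None = None,
    seed: int = 0,
    inner_folds: int = 10,
    do_grid_search: bool = False,
    keep_meta_dataset: bool = True,
) -> StackingModel:
    """Fit the stacking ensemble on the fused latent matrix Z.

    When ``do_grid_search`` is set, each learner's grid is searched on the
    training data first (stratified CV inside the fold), and the winning
    hyperparameters are used for both meta-feature construction and the final
    refit.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=int)
    if not specs:
        raise ConfigError("need at least one base learner")
    if plan is None:
        plan = FoldPlan.make(y, inner_folds, seed)
    specs = list(specs)
    if do_grid_search:
        specs = [s.with_params(grid_search(s, Z, y, seed=s.seed)) for s in specs]
    meta_ds = build_meta_features(specs, plan, Z, y)
    meta = make_meta_classifier(seed=seed)
    meta.fit(meta_ds.X_meta, meta_ds.y)
    bases = []
    for spec in specs:
        learner = make_base_learner(spec)
        learner.fit(Z, y)
        bases.append(learner)
    return StackingModel(
        specs, bases, meta, plan, seed, meta_ds if keep_meta_dataset else None
    )


def predict(model: StackingModel, Z_test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and positive-class probabilities for new fused latents.

    A meta-probability of exactly 0.5 maps to the positive (tumor) label.
    """
    Z_test = np.asarray(Z_test, dtype=float)
    expected = model.base_learners[0].n_features_in_ if hasattr(
        model.base_learners[0], "n_features_in_"
    ) else None
    if expected is not None and Z_test.shape[1] != expected:
        raise DimensionError(f"expected {expected} latent features, got {Z_test.shape[1]}")
    meta_rows = np.column_stack(
        [_positive_proba(b, Z_test) for b in model.base_learners]
    )
    proba = model.meta.predict_proba(meta_rows)
    pos = int(np.flatnonzero(model.meta.classes_ == 1)[0])
    p1 = proba[:, pos]
    labels = (p1 >= 0.5).astype(int)
    return labels, p1
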