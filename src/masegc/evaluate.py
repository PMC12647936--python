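"""Binary classification metrics, the cross-validated end-to-end pipeline,
and the ablation harness.

Metrics follow the tumor-positive convention:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 P R / (P + R) = 2 TP / (2 TP + FP + FN)

Zero-denominator cases report 0 with an explicit degenerate flag instead of
raising, so ablation sweeps never abort on a pathological fold.

The cross-validation loop keeps all fitting inside the outer-training fold:
filtering, imputation donors, scaling statistics, the differential screen,
SMOTE-Tomek balancing, autoencoder weights and every learner are derived
from L_f only, and the frozen encoders/models are then applied to Test_f.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autoencoder import LatentBundle, TrainConfig, encode, train_autoencoder
from .balance import smote_tomek
from .config import EXCLUDE_CHOICES, PipelineConfig
from .ensemble import (
    BaseLearnerSpec,
    FoldPlan,
    StackingModel,
    build_meta_features,
    make_meta_classifier,
    predict as stacking_predict,
    train_stacking,
)
from .errors import MasegcError, PipelineError
from .io_core import LabelTable, Modality, MultiOmicsDataset, OmicsMatrix
from .preprocess import (
    apply_minmax,
    filter_low_abundance,
    fit_minmax,
    knn_impute,
    moderated_differential_screen,
)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "AblationSpec",
    "confusion_counts",
    "metrics",
    "cross_validate_pipeline",
    "ablation_run",
    "CrossValResult",
]

#: ablation exclusion -> learner kind (meta handled separately)
_EXCLUDE_TO_KIND = {
    "svm": "svm_rbf",
    "rf": "random_forest",
    "dt": "decision_tree",
    "adaboost": "adaboost",
    "cnn": "cnn1d",
}


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise PipelineError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.TN + other.TN, self.FP + other.FP, self.FN + other.FN
        )


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Counts under tumor = positive (1), normal = negative (0)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise PipelineError("y_true and y_pred must be equal-length 1-D label vectors")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not set(np.unique(arr)).issubset({0, 1}):
            raise PipelineError(f"{name} must be binary 0/1")
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    counts: ConfusionCounts
    degenerate: list[str] = field(default_factory=list)
    rounding: int = 4

    def as_dict(self, rounded: bool = False) -> dict:
        vals = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
        }
        if rounded:
            vals = {k: round(v, self.rounding) for k, v in vals.items()}
        vals["counts"] = {
            "TP": self.counts.TP, "TN": self.counts.TN,
            "FP": self.counts.FP, "FN": self.counts.FN,
        }
        if self.degenerate:
            vals["degenerate"] = list(self.degenerate)
        return vals


def _ratio(num: int, den: int, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """All five metrics from the confusion counts."""
    if counts.total == 0:
        raise PipelineError("cannot compute metrics on zero samples")
    deg: list[str] = []
    accuracy = (counts.TP + counts.TN) / counts.total
    precision = _ratio(counts.TP, counts.TP + counts.FP, "precision", deg)
    recall = _ratio(counts.TP, counts.TP + counts.FN, "recall", deg)
    specificity = _ratio(counts.TN, counts.TN + counts.FP, "specificity", deg)
    f1 = _ratio(2 * counts.TP, 2 * counts.TP + counts.FP + counts.FN, "f1", deg)
    return MetricsReport(accuracy, precision, recall, specificity, f1, counts, deg)


@dataclass
class AblationSpec:
    """Exactly one excluded component per run."""

    excluded: str = "none"

    def __post_init__(self) -> None:
        if self.excluded not in EXCLUDE_CHOICES:
            raise PipelineError(f"excluded must be one of {EXCLUDE_CHOICES}")


# ---------------------------------------------------------------------------
# per-fold pipeline
# ---------------------------------------------------------------------------


def _active_specs(cfg: PipelineConfig, fold_seed: int) -> list[BaseLearnerSpec]:
    kinds = ["svm_rbf", "random_forest", "decision_tree", "adaboost", "cnn1d"]
    excluded_kind = _EXCLUDE_TO_KIND.get(cfg.exclude)
    specs = []
    for i, kind in enumerate(kinds):
        if kind == excluded_kind:
            continue
        params = {"epochs": cfg.cnn_epochs} if kind == "cnn1d" else {}
        specs.append(BaseLearnerSpec(kind, params=params, seed=(fold_seed + i) & 0x7FFFFFFF))
    return specs


def _preprocess_fold(
    train_ds: MultiOmicsDataset,
    test_ds: MultiOmicsDataset | None,
    cfg: PipelineConfig,
    log: dict,
) -> tuple[dict[Modality, np.ndarray], dict[Modality, np.ndarray] | None]:
    """filter -> impute -> scale -> screen, all fit on the training part.

    Returns sample-major (n, p) blocks per modality. If the screen selects
    fewer than ``cfg.min_screen_features`` features, the smallest adjusted
    p-values top it up so the autoencoder always has an input.
    """
    train_blocks: dict[Modality, np.ndarray] = {}
    test_blocks: dict[Modality, np.ndarray] | None = {} if test_ds is not None else None
    for modality in sorted(train_ds.modalities, key=lambda m: m.value):
        mat = train_ds.modalities[modality]
        test_mat = test_ds.modalities[modality] if test_ds is not None else None
        stage_log = {"n_features_in": mat.n_features}

        if modality.is_expression or not cfg.filter_expression_only:
            mat = filter_low_abundance(mat, cfg.zero_fraction_threshold)
            if test_mat is not None:
                test_mat = test_mat.subset_features(mat.feature_ids)
        stage_log["n_after_filter"] = mat.n_features

        if mat.has_missing() or (test_mat is not None and test_mat.has_missing()):
            imputed_train = knn_impute(mat, k=cfg.knn_k)
            if test_mat is not None and test_mat.has_missing():
                test_mat = knn_impute(test_mat, k=cfg.knn_k, reference=mat)
            mat = imputed_train

        stats = fit_minmax(mat)
        mat = apply_minmax(mat, stats)
        if test_mat is not None:
            test_mat = apply_minmax(test_mat, stats)

        screen = moderated_differential_screen(mat, train_ds.labels, alpha=cfg.alpha)
        keep = screen.selected.copy()
        if keep.sum() < cfg.min_screen_features:
            top = np.argsort(screen.adjusted, kind="stable")[: cfg.min_screen_features]
            keep[top] = True
        mat = mat.subset_features(keep)
        if test_mat is not None:
            test_mat = test_mat.subset_features(mat.feature_ids)
        stage_log["n_selected"] = int(screen.selected.sum())
        stage_log["n_kept"] = mat.n_features

        train_blocks[modality] = mat.values.T
        if test_blocks is not None:
            test_blocks[modality] = test_mat.values.T
        log[modality.value] = stage_log
    return train_blocks, test_blocks


def _encode_fold(
    train_blocks: dict[Modality, np.ndarray],
    test_blocks: dict[Modality, np.ndarray] | None,
    cfg: PipelineConfig,
    fold_seed: int,
) -> tuple[np.ndarray, np.ndarray | None, dict]:
    """Train one autoencoder per modality on the training block, freeze it,
    and emit fused latents for train and test."""
    mods = sorted(train_blocks, key=lambda m: m.value)
    weights = (
        np.asarray(cfg.fusion_weights, dtype=float)
        if cfg.fusion_weights is not None
        else np.full(len(mods), 1.0 / len(mods))
    )
    train_latents, test_latents, traces = {}, {}, {}
    for i, modality in enumerate(mods):
        tc = TrainConfig(
            latent_dim=cfg.latent_dim,
            hidden_widths=cfg.ae_hidden_widths,
            epochs=cfg.ae_epochs,
            learning_rate=cfg.ae_learning_rate,
            batch_size=cfg.ae_batch_size,
            seed=(fold_seed + 101 * i) & 0x7FFFFFFF,
            tied=cfg.ae_tied,
        )
        model = train_autoencoder(train_blocks[modality], tc, modality=modality)
        train_latents[modality] = encode(model, train_blocks[modality])
        if test_blocks is not None:
            test_latents[modality] = encode(model, test_blocks[modality])
        traces[modality.value] = [model.loss_trace[0], model.loss_trace[-1]]
    bundle = LatentBundle.build(train_latents, weights)
    Z_test = None
    if test_blocks is not None:
        Z_test = LatentBundle.build(test_latents, weights).fused
    return bundle.fused, Z_test, traces


def _fit_and_predict_fold(
    Z: np.ndarray,
    y: np.ndarray,
    Z_test: np.ndarray,
    cfg: PipelineConfig,
    fold_seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (validation OOF predictions over the training set, their
    labels implicitly = y, test predictions)."""
    plan = FoldPlan.make(y, cfg.inner_folds, (fold_seed + 7) & 0x7FFFFFFF)
    if cfg.exclude == "meta":
        # single boosted-tree classifier on the fused latents, no stacking
        oof = np.empty(len(y), dtype=int)
        for tr, va in plan.splits:
            clf = make_meta_classifier(seed=fold_seed, n_estimators=cfg.meta_rounds)
            clf.fit(Z[tr], y[tr])
            oof[va] = clf.predict(Z[va]).astype(int)
        clf = make_meta_classifier(seed=fold_seed, n_estimators=cfg.meta_rounds)
        clf.fit(Z, y)
        test_pred = clf.predict(Z_test).astype(int)
        return oof, y, test_pred

    specs = _active_specs(cfg, fold_seed)
    model = train_stacking(
        Z, y, specs, plan=plan, seed=fold_seed, do_grid_search=cfg.do_grid_search
    )
    # validation = meta applied to inner out-of-fold base probabilities
    meta_ds = model.meta_dataset
    pos = int(np.flatnonzero(model.meta.classes_ == 1)[0])
    val_proba = model.meta.predict_proba(meta_ds.X_meta)[:, pos]
    val_pred = (val_proba >= 0.5).astype(int)
    test_pred, _ = stacking_predict(model, Z_test)
    return val_pred, y, test_pred


@dataclass
class CrossValResult:
    """Per-fold and pooled metrics for one cross-validated run."""

    fold_validation: list[MetricsReport]
    fold_test: list[MetricsReport]
    validation_pooled: MetricsReport
    test_pooled: MetricsReport
    outer_plan: FoldPlan
    provenance: dict

    def aggregate(self, split: str = "test") -> dict[str, tuple[float, float]]:
        """Mean and sd of each metric across folds."""
        reports = self.fold_test if split == "test" else self.fold_validation
        out = {}
        for m in ("accuracy", "precision", "recall", "specificity", "f1"):
            vals = np.array([getattr(r, m) for r in reports])
            out[m] = (float(vals.mean()), float(vals.std(ddof=1 if len(vals) > 1 else 0)))
        return out

    def as_json(self) -> str:
        payload = {
            "validation_pooled": self.validation_pooled.as_dict(),
            "test_pooled": self.test_pooled.as_dict(),
            "aggregate_test": {k: list(v) for k, v in self.aggregate("test").items()},
            "aggregate_validation": {
                k: list(v) for k, v in self.aggregate("validation").items()
            },
            "fold_test": [r.as_dict() for r in self.fold_test],
            "fold_validation": [r.as_dict() for r in self.fold_validation],
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _balance_fold(
    X: np.ndarray, y: np.ndarray, cfg: PipelineConfig, fold_seed: int, log: dict
) -> tuple[np.ndarray, np.ndarray]:
    if not cfg.balance:
        return X, y
    counts = np.bincount(y, minlength=2)
    if counts.min() / counts.max() >= cfg.target_ratio:
        log["balance"] = {"skipped": "target ratio already met"}
        return X, y
    res = smote_tomek(
        X, y, k=cfg.smote_k, target_ratio=cfg.target_ratio,
        seed=(fold_seed + 13) & 0x7FFFFFFF, removal_policy=cfg.removal_policy,
    )
    log["balance"] = {
        "class_counts": {str(k): v for k, v in res.class_counts().items()},
        "n_synthetic": sum(p == "synthetic" for p in res.provenance),
        "n_removed": len(res.removed),
    }
    return res.X, res.y


def cross_validate_pipeline(
    dataset: MultiOmicsDataset, config: PipelineConfig, seed: int | None = None
) -> CrossValResult:
    """Run preprocess -> balance -> encode -> stack over stratified outer folds.

    All fitting is confined to the outer-training fold (unless
    ``config.paper_mode`` reproduces the global pre-split scaling/balancing
    order). Validation metrics come from inner out-of-fold predictions on the
    (balanced) training set; test metrics from the untouched outer test fold,
    each test sample scored exactly once. A fold that fails is logged and
    skipped; more than 3 failed folds abort the run.
    """
    cfg = config if seed is None else config.replace(seed=seed)
    master = cfg.stage_seed("pipeline")
    y_all = dataset.y
    outer_plan = FoldPlan.make(y_all, cfg.outer_folds, cfg.stage_seed("outer-folds"))
    provenance: dict = {
        "seed": cfg.seed,
        "paper_mode": cfg.paper_mode,
        "exclude": cfg.exclude,
        "n_samples": dataset.n_samples,
        "outer_folds": cfg.outer_folds,
        "inner_folds": cfg.inner_folds,
        "folds": [],
    }

    if cfg.paper_mode:
        # the published order: preprocess and balance the whole dataset first
        log_global: dict = {}
        blocks, _ = _preprocess_fold(dataset, None, cfg, log_global)
        mods = sorted(blocks, key=lambda m: m.value)
        X_all = np.hstack([blocks[m] for m in mods])
        X_bal, y_bal = _balance_fold(X_all, y_all, cfg, master, log_global)
        provenance["global"] = log_global
        widths = [blocks[m].shape[1] for m in mods]
        edges = np.cumsum([0] + widths)
        outer_plan = FoldPlan.make(y_bal, cfg.outer_folds, cfg.stage_seed("outer-folds"))

    fold_val, fold_test = [], []
    val_counts_sum = test_counts_sum = None
    failed = 0
    for f, (tr, te) in enumerate(outer_plan.splits):
        fold_seed = cfg.stage_seed(f"fold-{f}")
        fold_log: dict = {"fold": f, "n_train": len(tr), "n_test": len(te)}
        try:
            if cfg.paper_mode:
                tr_blocks = {m: X_bal[tr][:, edges[i]:edges[i + 1]] for i, m in enumerate(mods)}
                te_blocks = {m: X_bal[te][:, edges[i]:edges[i + 1]] for i, m in enumerate(mods)}
                y_tr, y_te = y_bal[tr], y_bal[te]
            else:
                train_ids = [dataset.sample_ids[i] for i in tr]
                test_ids = [dataset.sample_ids[i] for i in te]
                train_ds = dataset.subset_samples(train_ids)
                test_ds = dataset.subset_samples(test_ids)
                tr_blocks, te_blocks = _preprocess_fold(train_ds, test_ds, cfg, fold_log)
                y_tr, y_te = train_ds.y, test_ds.y
                mods_f = sorted(tr_blocks, key=lambda m: m.value)
                X_tr = np.hstack([tr_blocks[m] for m in mods_f])
                widths_f = [tr_blocks[m].shape[1] for m in mods_f]
                edges_f = np.cumsum([0] + widths_f)
                X_tr, y_tr = _balance_fold(X_tr, y_tr, cfg, fold_seed, fold_log)
                tr_blocks = {
                    m: X_tr[:, edges_f[i]:edges_f[i + 1]] for i, m in enumerate(mods_f)
                }
            Z_tr, Z_te, traces = _encode_fold(tr_blocks, te_blocks, cfg, fold_seed)
            fold_log["ae_loss"] = traces
            val_pred, val_y, test_pred = _fit_and_predict_fold(
                Z_tr, y_tr, Z_te, cfg, fold_seed
            )
            vc = confusion_counts(val_y, val_pred)
            tc = confusion_counts(y_te, test_pred)
            fold_val.append(metrics(vc))
            fold_test.append(metrics(tc))
            val_counts_sum = vc if val_counts_sum is None else val_counts_sum + vc
            test_counts_sum = tc if test_counts_sum is None else test_counts_sum + tc
            fold_log["test"] = fold_test[-1].as_dict(rounded=True)
        except MasegcError as e:
            failed += 1
            fold_log["error"] = str(e)
            if failed > 3:
                raise PipelineError(f"more than 3 folds failed; last error: {e}") from e
        provenance["folds"].append(fold_log)

    if not fold_test:
        raise PipelineError("every fold failed")
    return CrossValResult(
        fold_val, fold_test, metrics(val_counts_sum), metrics(test_counts_sum),
        outer_plan, provenance,
    )


def ablation_run(
    dataset: MultiOmicsDataset,
    config: PipelineConfig,
    specs: Sequence[AblationSpec],
    seed: int | None = None,
) -> dict[str, CrossValResult]:
    """One full cross-validated run per exclusion, under identical folds.

    The master seed is shared across runs, so fold assignments are paired and
    per-fold metric differences between settings are meaningful.
    """
    results: dict[str, CrossValResult] = {}
    for spec in specs:
        cfg = config.replace(exclude=spec.excluded)
        results[spec.excluded] = cross_validate_pipeline(dataset, cfg, seed=seed)
    return results
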