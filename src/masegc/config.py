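"""Pipeline configuration and per-stage seed derivation."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields

from .errors import ConfigError

__all__ = ["PipelineConfig", "derive_seed", "EXCLUDE_CHOICES"]

EXCLUDE_CHOICES = ("none", "svm", "rf", "dt", "adaboost", "cnn", "meta")


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from the master seed."""
    return (zlib.crc32(f"{master_seed}:{stage}".encode()) ^ master_seed) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    """All stage parameters for the end-to-end run.

    Defaults follow the protocol's printed values where they exist (zero
    threshold 0.6, screen alpha 0.001, 10 outer folds, 50 meta boosting
    rounds, the printed hyperparameter grids) and this package's desk-scale
    choices elsewhere (latent dimension 8, 5 inner folds, seeded numpy
    networks).
    """

    # preprocessing
    zero_fraction_threshold: float = 0.6
    filter_expression_only: bool = True
    knn_k: int = 5
    alpha: float = 0.001
    min_screen_features: int = 8

    # balancing
    balance: bool = True
    smote_k: int = 5
    target_ratio: float = 1.0
    removal_policy: str = "both"

    # autoencoder
    latent_dim: int = 8
    ae_epochs: int = 100
    ae_learning_rate: float = 1e-3
    ae_batch_size: int = 32
    ae_hidden_widths: tuple[int, ...] | None = None
    ae_tied: bool = False
    fusion_weights: tuple[float, ...] | None = None  # None = uniform 1/M

    # ensemble
    outer_folds: int = 10
    inner_folds: int = 5
    do_grid_search: bool = False
    cnn_epochs: int = 50
    exclude: str = "none"
    meta_rounds: int = 50

    # global behaviour
    paper_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if not 0 <= self.zero_fraction_threshold < 1:
            problems.append("zero_fraction_threshold must be in [0,1)")
        if not 0 < self.alpha < 1:
            problems.append("alpha must be in (0,1)")
        if self.knn_k < 1 or self.smote_k < 1:
            problems.append("knn_k and smote_k must be >= 1")
        if self.target_ratio <= 0:
            problems.append("target_ratio must be > 0")
        if self.removal_policy not in ("both", "majority_only"):
            problems.append(f"unknown removal_policy {self.removal_policy!r}")
        if self.latent_dim < 1:
            problems.append("latent_dim must be >= 1")
        if self.outer_folds < 2 or self.inner_folds < 2:
            problems.append("outer_folds and inner_folds must be >= 2")
        if self.exclude not in EXCLUDE_CHOICES:
            problems.append(f"exclude must be one of {EXCLUDE_CHOICES}")
        if self.fusion_weights is not None:
            w = list(self.fusion_weights)
            if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
                problems.append("fusion_weights must be non-negative and sum to 1")
        if problems:
            raise ConfigError("; ".join(problems))

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        """Build from a mapping, rejecting unknown keys (all problems listed)."""
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(
                "unknown config key(s): " + ", ".join(repr(k) for k in unknown)
            )
        raw = dict(raw)
        for key in ("ae_hidden_widths", "fusion_weights"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def replace(self, **kwargs) -> "PipelineConfig":
        from dataclasses import asdict

        d = asdict(self)
        d.update(kwargs)
        return PipelineConfig.from_dict(d)
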