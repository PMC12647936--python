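"""Synthetic multi-omics generator with known class structure.

A shared latent-factor model ties the four modalities together: each sample
draws latent factors whose means differ between tumor and normal on the
informative factors, every modality observes ``loadings @ factors`` plus
Gaussian noise through a modality-appropriate link (softplus for expression
layers, logistic squashing for methylation betas), and class imbalance,
zero inflation and missingness are injected at configurable rates.

Because the class signal lives in factors shared across layers, latent fusion
of several modalities genuinely helps downstream classification; per-modality
private factors ensure no single layer carries the whole signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ConfigError
from .io_core import LabelTable, Modality, MultiOmicsDataset, OmicsMatrix

__all__ = ["SimulationConfig", "GroundTruth", "simulate_multiomics", "inject_missingness"]

#: default feature counts per modality — ordered like the real layers
#: (exon > methylation > mRNA > miRNA), scaled to desk size
DEFAULT_FEATURE_DIMS: dict[Modality, int] = {
    Modality.EXON: 300,
    Modality.MRNA: 200,
    Modality.MIRNA: 60,
    Modality.METHYLATION: 150,
}


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror a desk-scale version of a tumor-heavy cohort: a 5:1
    tumor/normal imbalance (200/40), four modalities with heterogeneous
    dimensionality, 30% zero inflation on expression layers and 10%
    missingness on methylation.
    """

    n_samples_per_class: tuple[int, int] = (200, 40)  # (tumor, normal)
    feature_dims: Mapping[Modality | str, int] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_DIMS)
    )
    n_latent_factors: int = 10
    class_effect_size: float = 3.0
    noise_sd: float = 1.0
    zero_inflation_rate: float = 0.3
    missing_rate: float = 0.1
    informative_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        self.feature_dims = {Modality(m): int(d) for m, d in dict(self.feature_dims).items()}
        n_t, n_n = self.n_samples_per_class
        if n_t <= 0 or n_n <= 0:
            raise ConfigError("both classes need at least one sample")
        if not 0 <= self.zero_inflation_rate < 1:
            raise ConfigError("zero_inflation_rate must be in [0,1)")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0,1)")
        if not 0 < self.informative_fraction <= 1:
            raise ConfigError("informative_fraction must be in (0,1]")
        if self.class_effect_size < 0:
            raise ConfigError("class_effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.n_latent_factors < 1:
            raise ConfigError("need at least one latent factor")
        for m, d in self.feature_dims.items():
            if d < self.n_latent_factors:
                raise ConfigError(
                    f"{m.value}: feature dim {d} < n_latent_factors {self.n_latent_factors}"
                )


@dataclass
class GroundTruth:
    """What the generator knows: labels, informative features, loadings."""

    labels: np.ndarray
    informative_features: dict[Modality, list[str]]
    loadings: dict[Modality, np.ndarray]
    informative_factors: np.ndarray  # bool mask over shared factors

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "labels": self.labels.tolist(),
            "informative_features": {
                m.value: ids for m, ids in self.informative_features.items()
            },
            "informative_factors": self.informative_factors.astype(int).tolist(),
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


def _softplus(x: np.ndarray) -> np.ndarray:
    # overflow-safe log(1+exp(x)); non-negative and right-skewed like RPKM
    return np.logaddexp(0.0, x)


def simulate_multiomics(config: SimulationConfig) -> tuple[MultiOmicsDataset, GroundTruth]:
    """Draw one multi-omics dataset from the shared factor model.

    Deterministic given ``config.seed``: the same config always produces
    bitwise-identical values.
    """
    rng = np.random.default_rng(config.seed)
    n_tumor, n_normal = config.n_samples_per_class
    n = n_tumor + n_normal
    y = np.concatenate([np.ones(n_tumor, dtype=int), np.zeros(n_normal, dtype=int)])

    k = config.n_latent_factors
    n_info = max(1, round(config.informative_fraction * k)) if config.class_effect_size > 0 else 0
    info_mask = np.zeros(k, dtype=bool)
    info_mask[:n_info] = True

    # shared factors: informative ones shifted by the effect size for tumors
    factors = rng.normal(size=(n, k))
    factors[:, info_mask] += np.where(y == 1, config.class_effect_size, 0.0)[:, None]

    modalities: dict[Modality, OmicsMatrix] = {}
    informative_features: dict[Modality, list[str]] = {}
    loadings_out: dict[Modality, np.ndarray] = {}
    sample_ids = [f"s{i:04d}" for i in range(n)]

    for modality in sorted(config.feature_dims, key=lambda m: m.value):
        p = config.feature_dims[modality]
        prefix = modality.value
        feature_ids = [f"{prefix}_f{j:05d}" for j in range(p)]

        # sparse-ish loadings: each feature loads on a few shared factors,
        # plus a private per-modality factor so no single layer is sufficient
        loadings = rng.normal(scale=0.7, size=(p, k)) * (rng.random(size=(p, k)) < 0.3)
        empty = ~loadings.any(axis=1)
        if empty.any():  # guarantee every feature sees at least one factor
            cols = rng.integers(0, k, size=int(empty.sum()))
            loadings[np.flatnonzero(empty), cols] = rng.normal(scale=0.7, size=int(empty.sum()))
        private = rng.normal(size=(n, 1))
        private_load = rng.normal(scale=0.5, size=(p, 1))

        signal = factors @ loadings.T + private @ private_load.T  # (n, p)
        noise = rng.normal(scale=config.noise_sd, size=(n, p))
        raw = signal + noise

        if modality is Modality.METHYLATION:
            values = 1.0 / (1.0 + np.exp(-raw))  # beta-like, strictly in (0,1)
            if config.missing_rate > 0:
                mask = rng.random(size=raw.shape) < config.missing_rate
                values = values.copy()
                values[mask] = np.nan
        else:
            values = _softplus(raw)
            if config.zero_inflation_rate > 0:
                zero = rng.random(size=raw.shape) < config.zero_inflation_rate
                values = values.copy()
                values[zero] = 0.0

        # ground-truth informative features: those whose induced class-mean
        # separation is at least one noise SD — features with (near-)cancelling
        # loadings have no mean shift and are undetectable in principle
        shift = config.class_effect_size * np.abs(loadings[:, info_mask].sum(axis=1))
        info_features = [
            feature_ids[j] for j in range(p) if shift[j] >= config.noise_sd
        ]
        modalities[modality] = OmicsMatrix(modality, feature_ids, sample_ids, values.T)
        informative_features[modality] = info_features
        loadings_out[modality] = loadings

    labels = LabelTable(sample_ids, y)
    dataset = MultiOmicsDataset(modalities, labels, list(sample_ids))
    truth = GroundTruth(y, informative_features, loadings_out, info_mask)
    return dataset, truth


def inject_missingness(matrix: OmicsMatrix, rate: float, seed: int) -> OmicsMatrix:
    """Mask each entry independently with probability ``rate`` (NaN)."""
    if not 0 <= rate < 1:
        raise ConfigError("rate must be in [0,1)")
    if matrix.has_missing():
        raise ConfigError("matrix already contains missing entries")
    if rate == 0:
        return OmicsMatrix(
            matrix.modality, list(matrix.feature_ids), list(matrix.sample_ids), matrix.values.copy()
        )
    rng = np.random.default_rng(seed)
    mask = rng.random(size=matrix.values.shape) < rate
    values = matrix.values.copy()
    values[mask] = np.nan
    return OmicsMatrix(matrix.modality, list(matrix.feature_ids), list(matrix.sample_ids), values)
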