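"""Modality-specific autoencoders and weighted latent fusion.

Each modality's autoencoder maps its (min-max scaled) feature vector through
an encoder Z^l = sigma(W^l.T Z^(l-1) + b^l) into a latent code shared in
dimension across modalities, and mirrors it back through a decoder whose
output activation is sigmoid so reconstructions live on the same [0,1] scale
as the inputs. Reconstruction quality is the per-sample squared-error mean

    L_MSE(X, X_rec) = (1/n) sum_i ||x_i - x_rec_i||^2      (sum over features)

and the modality losses combine as a convex weighted sum with weights
lambda_i >= 0, sum lambda_i = 1; the same weights combine the latent codes
into the fused representation Z = sum_i lambda_i Z_i.

Networks are plain numpy with manual backpropagation and Adam, fully seeded,
so training is deterministic and CPU-friendly at package scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._nn import ACTIVATIONS, Adam, act_backward, act_forward, glorot
from .errors import ConfigError, DimensionError, TrainingError
from .io_core import Modality

__all__ = [
    "AutoencoderModel",
    "TrainConfig",
    "LatentBundle",
    "encode",
    "decode",
    "reconstruction_loss",
    "joint_loss",
    "fuse_latents",
    "train_autoencoder",
    "validate_fusion_weights",
]

WEIGHT_SUM_TOL = 1e-9


@dataclass
class TrainConfig:
    """Autoencoder training hyperparameters (all seeded; no defaults are
    inherited from any published protocol — the source gives none)."""

    latent_dim: int = 64
    hidden_widths: tuple[int, ...] | None = None  # default: (4 * latent_dim,)
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0
    hidden_activation: str = "relu"
    latent_activation: str = "linear"
    output_activation: str = "sigmoid"
    tied: bool = False
    per_feature_loss: bool = False  # divide loss by feature count as well

    def __post_init__(self) -> None:
        if self.latent_dim < 1 or self.epochs < 0 or self.batch_size < 1:
            raise ConfigError("latent_dim/batch_size must be positive, epochs >= 0")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        for a in (self.hidden_activation, self.latent_activation, self.output_activation):
            if a not in ACTIVATIONS:
                raise ConfigError(f"unknown activation {a!r}")

    def resolved_hidden(self) -> tuple[int, ...]:
        return self.hidden_widths if self.hidden_widths is not None else (4 * self.latent_dim,)


@dataclass
class AutoencoderModel:
    """Feedforward encoder/decoder pair for one modality.

    ``encoder_weights[l]`` has shape (width_{l-1}, width_l); a layer computes
    ``act(Z @ W + b)`` on sample-major matrices, which is the sample-wise form
    of sigma(W.T z + b). ``tied=True`` reuses transposed encoder weights for
    the decoder (the symmetric-weight reading); decoder biases are always free.
    """

    modality: Modality
    encoder_weights: list[np.ndarray]
    encoder_biases: list[np.ndarray]
    decoder_weights: list[np.ndarray] | None  # None when tied
    decoder_biases: list[np.ndarray]
    encoder_activations: list[str]
    decoder_activations: list[str]
    loss_trace: list[float] = field(default_factory=list)

    @property
    def tied(self) -> bool:
        return self.decoder_weights is None

    @property
    def input_dim(self) -> int:
        return self.encoder_weights[0].shape[0]

    @property
    def latent_dim(self) -> int:
        return self.encoder_weights[-1].shape[1]

    def _decoder_weight(self, layer: int) -> np.ndarray:
        if self.decoder_weights is not None:
            return self.decoder_weights[layer]
        return self.encoder_weights[len(self.encoder_weights) - 1 - layer].T

    def save(self, directory: str | Path) -> Path:
        """Write one whitespace-separated text array per parameter plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        names = {}
        arrays: list[tuple[str, np.ndarray]] = []
        for i, (w, b) in enumerate(zip(self.encoder_weights, self.encoder_biases)):
            arrays += [(f"enc_w{i}", w), (f"enc_b{i}", b)]
        if self.decoder_weights is not None:
            for i, w in enumerate(self.decoder_weights):
                arrays.append((f"dec_w{i}", w))
        for i, b in enumerate(self.decoder_biases):
            arrays.append((f"dec_b{i}", b))
        for name, arr in arrays:
            np.savetxt(directory / f"{name}.txt", np.atleast_2d(arr))
            names[name] = list(arr.shape)
        manifest = {
            "modality": self.modality.value,
            "tied": self.tied,
            "encoder_activations": self.encoder_activations,
            "decoder_activations": self.decoder_activations,
            "shapes": names,
            "loss_trace": self.loss_trace,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "AutoencoderModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())

        def read(name: str) -> np.ndarray:
            arr = np.loadtxt(directory / f"{name}.txt")
            return arr.reshape(manifest["shapes"][name])

        n_enc = len(manifest["encoder_activations"])
        enc_w = [read(f"enc_w{i}") for i in range(n_enc)]
        enc_b = [read(f"enc_b{i}") for i in range(n_enc)]
        n_dec = len(manifest["decoder_activations"])
        dec_b = [read(f"dec_b{i}") for i in range(n_dec)]
        dec_w = None if manifest["tied"] else [read(f"dec_w{i}") for i in range(n_dec)]
        return cls(
            Modality(manifest["modality"]), enc_w, enc_b, dec_w, dec_b,
            manifest["encoder_activations"], manifest["decoder_activations"],
            manifest.get("loss_trace", []),
        )


def _forward(X, weights, biases, activations):
    a = X
    cache = [a]
    for W, b, act in zip(weights, biases, activations):
        a = act_forward(act, a @ W + b)
        cache.append(a)
    return a, cache


def encode(model: AutoencoderModel, X: np.ndarray) -> np.ndarray:
    """Map sample-major data (n, features) to latent codes (n, latent_dim)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.input_dim:
        raise DimensionError(f"expected (n, {model.input_dim}) input, got {X.shape}")
    if not np.isfinite(X).all():
        raise DimensionError("input contains non-finite values")
    z, _ = _forward(X, model.encoder_weights, model.encoder_biases, model.encoder_activations)
    return z


def decode(model: AutoencoderModel, Z: np.ndarray) -> np.ndarray:
    """Map latent codes back to reconstructions (n, features)."""
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[1] != model.latent_dim:
        raise DimensionError(f"expected (n, {model.latent_dim}) latent, got {Z.shape}")
    weights = [model._decoder_weight(i) for i in range(len(model.decoder_biases))]
    x, _ = _forward(Z, weights, model.decoder_biases, model.decoder_activations)
    return x


def reconstruction_loss(X: np.ndarray, X_rec: np.ndarray, per_feature: bool = False) -> float:
    """Mean over samples of the squared residual norm (sum over features).

    ``per_feature=True`` additionally divides by the feature count, giving a
    scale-free per-entry MSE.
    """
    X = np.asarray(X, dtype=float)
    X_rec = np.asarray(X_rec, dtype=float)
    if X.shape != X_rec.shape:
        raise DimensionError(f"shape mismatch {X.shape} vs {X_rec.shape}")
    loss = float(np.mean(np.sum((X - X_rec) ** 2, axis=1)))
    if per_feature:
        loss /= X.shape[1]
    return loss


def validate_fusion_weights(weights, n_modalities: int | None = None) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if n_modalities is not None and w.size != n_modalities:
        raise ConfigError(f"expected {n_modalities} fusion weights, got {w.size}")
    if (w < 0).any():
        raise ConfigError("fusion weights must be non-negative")
    if abs(w.sum() - 1.0) > WEIGHT_SUM_TOL:
        raise ConfigError(f"fusion weights must sum to 1 (got {w.sum()!r})")
    return w


def joint_loss(losses, weights) -> float:
    """Convex combination of per-modality reconstruction losses."""
    losses = np.asarray(losses, dtype=float)
    w = validate_fusion_weights(weights, losses.size)
    return float(np.dot(w, losses))


def fuse_latents(latents: list[np.ndarray], weights) -> np.ndarray:
    """Entrywise weighted sum of equally-shaped latent matrices."""
    if not latents:
        raise DimensionError("need at least one latent matrix")
    mats = [np.asarray(z, dtype=float) for z in latents]
    shape = mats[0].shape
    for z in mats[1:]:
        if z.shape != shape:
            raise DimensionError(f"latent shape mismatch: {z.shape} vs {shape}")
    w = validate_fusion_weights(weights, len(mats))
    return sum(wi * z for wi, z in zip(w, mats))


@dataclass
class LatentBundle:
    """Per-modality latent codes plus their convex fusion."""

    latents: dict[Modality, np.ndarray]
    weights: np.ndarray
    fused: np.ndarray

    @classmethod
    def build(cls, latents: dict[Modality, np.ndarray], weights) -> "LatentBundle":
        mods = list(latents)
        w = validate_fusion_weights(weights, len(mods))
        fused = fuse_latents([latents[m] for m in mods], w)
        return cls(dict(latents), w, fused)


def _init_model(n_features: int, config: TrainConfig, rng: np.random.Generator) -> AutoencoderModel:
    widths = [n_features, *config.resolved_hidden(), config.latent_dim]
    enc_acts = [config.hidden_activation] * (len(widths) - 2) + [config.latent_activation]
    enc_w = [glorot(rng, widths[i], widths[i + 1]) for i in range(len(widths) - 1)]
    enc_b = [np.zeros(widths[i + 1]) for i in range(len(widths) - 1)]
    dec_widths = widths[::-1]
    dec_acts = [config.hidden_activation] * (len(dec_widths) - 2) + [config.output_activation]
    dec_b = [np.zeros(dec_widths[i + 1]) for i in range(len(dec_widths) - 1)]
    dec_w = None
    if not config.tied:
        dec_w = [glorot(rng, dec_widths[i], dec_widths[i + 1]) for i in range(len(dec_widths) - 1)]
    return AutoencoderModel(Modality.FUSED, enc_w, enc_b, dec_w, dec_b, enc_acts, dec_acts)


def train_autoencoder(
    X: np.ndarray, config: TrainConfig, modality: Modality = Modality.FUSED
) -> AutoencoderModel:
    """Fit an autoencoder to sample-major data by minibatch Adam on the
    reconstruction loss; deterministic given ``config.seed``.

    The loss trace holds the full-data loss before training and after every
    epoch (length epochs + 1). Raises :class:`TrainingError` on divergence.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DimensionError("X must be (n_samples, n_features)")
    n, p = X.shape
    rng = np.random.default_rng(config.seed)
    model = _init_model(p, config, rng)
    model.modality = Modality(modality)

    params = list(model.encoder_weights) + list(model.encoder_biases) + list(model.decoder_biases)
    if model.decoder_weights is not None:
        params += list(model.decoder_weights)
    opt = Adam(params, lr=config.learning_rate)

    def full_loss() -> float:
        return reconstruction_loss(X, decode(model, encode(model, X)))

    model.loss_trace = [full_loss()]
    n_enc = len(model.encoder_weights)
    n_dec = len(model.decoder_biases)

    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            xb = X[batch]
            # forward
            z, enc_cache = _forward(
                xb, model.encoder_weights, model.encoder_biases, model.encoder_activations
            )
            dec_weights = [model._decoder_weight(i) for i in range(n_dec)]
            xr, dec_cache = _forward(z, dec_weights, model.decoder_biases, model.decoder_activations)
            # backward: d loss / d xr for loss = mean_i ||x_i - xr_i||^2
            delta = (2.0 / xb.shape[0]) * (xr - xb)
            g_enc_w = [np.zeros_like(w) for w in model.encoder_weights]
            g_enc_b = [np.zeros_like(b) for b in model.encoder_biases]
            g_dec_b = [np.zeros_like(b) for b in model.decoder_biases]
            g_dec_w = [np.zeros_like(w) for w in dec_weights]
            for layer in range(n_dec - 1, -1, -1):
                a = dec_cache[layer + 1]
                dz = delta * act_backward(model.decoder_activations[layer], a)
                g_dec_w[layer] = dec_cache[layer].T @ dz
                g_dec_b[layer] = dz.sum(axis=0)
                delta = dz @ dec_weights[layer].T
            for layer in range(n_enc - 1, -1, -1):
                a = enc_cache[layer + 1]
                dz = delta * act_backward(model.encoder_activations[layer], a)
                g_enc_w[layer] = enc_cache[layer].T @ dz
                g_enc_b[layer] = dz.sum(axis=0)
                delta = dz @ model.encoder_weights[layer].T
            if model.tied:
                # decoder layer i uses enc_w[n_enc-1-i].T: fold its gradient in
                for i in range(n_dec):
                    g_enc_w[n_enc - 1 - i] += g_dec_w[i].T
                grads = g_enc_w + g_enc_b + g_dec_b
            else:
                grads = g_enc_w + g_enc_b + g_dec_b + g_dec_w
            opt.step(grads)
        loss = full_loss()
        if not np.isfinite(loss):
            raise TrainingError("training diverged (non-finite loss)", trace=model.loss_trace)
        model.loss_trace.append(loss)
    return model
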