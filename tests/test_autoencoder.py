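import numpy as np
import pytest

from masegc.autoencoder import (
    AutoencoderModel,
    TrainConfig,
    decode,
    encode,
    fuse_latents,
    joint_loss,
    reconstruction_loss,
    train_autoencoder,
)
from masegc.errors import ConfigError, DimensionError
from masegc.io_core import Modality


def _linear_model(W_enc, W_dec, b_enc=None, b_dec=None):
    d_in, d_lat = W_enc.shape
    return AutoencoderModel(
        Modality.FUSED,
        [W_enc], [np.zeros(d_lat) if b_enc is None else b_enc],
        [W_dec], [np.zeros(d_in) if b_dec is None else b_dec],
        ["linear"], ["linear"],
    )


# -- encode / decode -------------------------------------------------------


def test_encode_identity_network():
    m = _linear_model(np.eye(3), np.eye(3))
    X = np.arange(6, dtype=float).reshape(2, 3)
    np.testing.assert_array_equal(encode(m, X), X)


def test_encode_sigmoid_zero_weights():
    m = AutoencoderModel(
        Modality.FUSED,
        [np.zeros((4, 2))], [np.zeros(2)],
        [np.zeros((2, 4))], [np.zeros(4)],
        ["sigmoid"], ["sigmoid"],
    )
    out = encode(m, np.ones((3, 4)))
    np.testing.assert_allclose(out, 0.5)


def test_encode_two_layer_hand_propagated():
    W1 = np.array([[1.0, -1.0], [0.5, 2.0]])
    W2 = np.array([[2.0, 0.0], [1.0, 1.0]])
    m = AutoencoderModel(
        Modality.FUSED,
        [W1, W2], [np.zeros(2), np.zeros(2)],
        [np.eye(2)], [np.zeros(2)],
        ["relu", "linear"], ["linear"],
    )
    x = np.array([[1.0, 1.0]])
    h = np.maximum(x @ W1, 0)          # [[1.5, 1.0]]
    expected = h @ W2                   # [[4.0, 1.0]]
    np.testing.assert_allclose(encode(m, x), expected)


def test_decode_pseudoinverse_reconstructs_low_rank(rng):
    W = rng.normal(size=(6, 2))
    X = rng.normal(size=(20, 2)) @ W.T  # rank-2 data in 6-D
    enc = np.linalg.pinv(W.T)           # (6, 2)
    m = _linear_model(enc, np.linalg.pinv(enc))
    np.testing.assert_allclose(decode(m, encode(m, X)), X, atol=1e-6)


def test_decode_zero_latent_sigmoid_gives_half():
    m = AutoencoderModel(
        Modality.FUSED,
        [np.zeros((4, 2))], [np.zeros(2)],
        [np.zeros((2, 4))], [np.zeros(4)],
        ["linear"], ["sigmoid"],
    )
    np.testing.assert_allclose(decode(m, np.zeros((5, 2))), 0.5)


def test_decode_encode_shape_contract(rng):
    cfg = TrainConfig(latent_dim=3, hidden_widths=(6,), epochs=0, seed=0)
    m = train_autoencoder(rng.random((7, 10)), cfg)
    X = rng.random((4, 10))
    assert decode(m, encode(m, X)).shape == X.shape


def test_encode_shape_mismatch():
    m = _linear_model(np.eye(3), np.eye(3))
    with pytest.raises(DimensionError):
        encode(m, np.ones((2, 4)))


# -- losses ----------------------------------------------------------------


def test_loss_zero_for_identical():
    X = np.random.default_rng(0).random((5, 4))
    assert reconstruction_loss(X, X) == 0.0


def test_loss_single_sample():
    assert reconstruction_loss([[1.0, 0.0]], [[0.0, 0.0]]) == pytest.approx(1.0)


def test_loss_mean_over_samples():
    X = np.array([[1.0, 0.0], [0.0, 0.0]])
    Xr = np.array([[0.0, 0.0], [np.sqrt(3.0), 0.0]])  # norms^2: 1 and 3
    assert reconstruction_loss(X, Xr) == pytest.approx(2.0)


def test_loss_shape_mismatch():
    with pytest.raises(DimensionError):
        reconstruction_loss(np.ones((2, 2)), np.ones((2, 3)))


def test_joint_loss_single_modality_weight():
    assert joint_loss([3.0, 1.0, 2.0, 5.0], [1, 0, 0, 0]) == pytest.approx(3.0)


def test_joint_loss_equal_losses_any_weights():
    assert joint_loss([2.0, 2.0, 2.0], [0.2, 0.5, 0.3]) == pytest.approx(2.0)


def test_joint_loss_uniform_mean():
    assert joint_loss([1, 2, 3, 4], [0.25] * 4) == pytest.approx(2.5)


def test_joint_loss_weight_sum_violation():
    with pytest.raises(ConfigError):
        joint_loss([1.0, 2.0], [0.5, 0.6])
    with pytest.raises(ConfigError):
        joint_loss([1.0, 2.0], [-0.5, 1.5])


# -- fusion ----------------------------------------------------------------


def test_fuse_single_modality():
    Z = np.array([[1.0, 2.0]])
    np.testing.assert_array_equal(fuse_latents([Z], [1.0]), Z)


def test_fuse_weighted_sum():
    Z1 = np.array([[1.0, 0.0]])
    Z2 = np.array([[0.0, 1.0]])
    np.testing.assert_allclose(
        fuse_latents([Z1, Z2], [0.25, 0.75]), [[0.25, 0.75]]
    )


def test_fuse_identical_modalities_invariant():
    Z = np.random.default_rng(1).random((4, 3))
    for w in ([0.5, 0.5], [0.1, 0.9]):
        np.testing.assert_allclose(fuse_latents([Z, Z.copy()], w), Z)


def test_fuse_is_linear(rng):
    Z = [rng.normal(size=(3, 2)) for _ in range(4)]
    Zp = [rng.normal(size=(3, 2)) for _ in range(4)]
    w = [0.1, 0.2, 0.3, 0.4]
    a, b = 2.0, -0.5
    lhs = fuse_latents([a * z + b * zp for z, zp in zip(Z, Zp)], w)
    rhs = a * fuse_latents(Z, w) + b * fuse_latents(Zp, w)
    np.testing.assert_allclose(lhs, rhs, atol=1e-12)


def test_fuse_uniform_weights_commute(rng):
    Z = [rng.normal(size=(3, 2)) for _ in range(4)]
    w = [0.25] * 4
    perm = [2, 0, 3, 1]
    np.testing.assert_allclose(
        fuse_latents(Z, w), fuse_latents([Z[i] for i in perm], w), atol=1e-12
    )


def test_fuse_shape_mismatch(rng):
    with pytest.raises(DimensionError):
        fuse_latents([np.ones((2, 3)), np.ones((2, 4))], [0.5, 0.5])


# -- training --------------------------------------------------------------


def test_train_recovers_rank_one_signal(rng):
    u = rng.random((80, 1))
    v = rng.random((1, 20))
    X = u @ v
    cfg = TrainConfig(
        latent_dim=1, hidden_widths=(8,), epochs=200, learning_rate=3e-3, seed=1
    )
    m = train_autoencoder(X, cfg)
    assert m.loss_trace[-1] < 0.05 * m.loss_trace[0]


def test_train_zero_epochs_trace_length_one(rng):
    m = train_autoencoder(rng.random((10, 6)), TrainConfig(latent_dim=2, epochs=0, seed=0))
    assert len(m.loss_trace) == 1


def test_train_deterministic(rng):
    X = rng.random((30, 10))
    cfg = TrainConfig(latent_dim=2, epochs=20, seed=42)
    m1 = train_autoencoder(X, cfg)
    m2 = train_autoencoder(X, cfg)
    for w1, w2 in zip(m1.encoder_weights, m2.encoder_weights):
        np.testing.assert_array_equal(w1, w2)
    assert m1.loss_trace == m2.loss_trace


def test_train_loss_trace_monotone_endpoints(rng):
    X = rng.random((40, 15))
    m = train_autoencoder(X, TrainConfig(latent_dim=4, epochs=50, seed=7))
    assert np.isfinite(m.loss_trace).all()
    assert m.loss_trace[-1] <= m.loss_trace[0]


def test_train_tied_weights_share_parameters(rng):
    X = rng.random((20, 8))
    m = train_autoencoder(X, TrainConfig(latent_dim=2, epochs=5, seed=3, tied=True))
    assert m.tied
    assert m.decoder_weights is None
    # decoder layer 0 is the transpose of the last encoder layer
    np.testing.assert_array_equal(m._decoder_weight(0), m.encoder_weights[-1].T)


def test_save_load_round_trip(rng, tmp_path):
    X = rng.random((15, 6))
    m = train_autoencoder(X, TrainConfig(latent_dim=2, epochs=3, seed=5), Modality.MRNA)
    m.save(tmp_path / "ae")
    back = AutoencoderModel.load(tmp_path / "ae")
    assert back.modality is Modality.MRNA
    np.testing.assert_allclose(encode(back, X), encode(m, X), atol=1e-12)
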