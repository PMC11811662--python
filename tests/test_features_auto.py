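"""Autoencoder feature extraction: shape contracts, training sanity,
determinism, and gradient correctness of the layer engine."""

import numpy as np
import pytest

from painpipe import nn
from painpipe.autoencode import (AEConfig, Autoencoder, ParameterError,
                                 closest_power_of_two, extract_auto_features,
                                 load_encoder, normalize_windows, save_encoder,
                                 train_ae)


class TestClosestPowerOfTwo:
    @pytest.mark.parametrize("n,expected", [
        (64, 64),          # already a power of two
        (2750, 2048),      # 5.5 s x 500 Hz
        (5000, 4096),      # 10 s x 500 Hz
        (96, 64),          # exact tie breaks downward
        (3, 2),            # tie |3-2| == |4-3| also breaks downward
        (1, 1),
    ])
    def test_values(self, n, expected):
        assert closest_power_of_two(n) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ParameterError):
            closest_power_of_two(0)


class TestGradients:
    """Finite-difference checks of every layer's backward pass."""

    def _directional_check(self, layer, x, atol=1e-6):
        rng = np.random.default_rng(9)
        y = layer.forward(x)
        dy = rng.normal(size=y.shape)
        for p in layer.params():
            p.grad[...] = 0.0
        dx = layer.backward(dy)
        # input gradient
        dxdir = rng.normal(size=x.shape)
        eps = 1e-7
        lp = np.sum(layer.forward(x + eps * dxdir) * dy)
        lm = np.sum(layer.forward(x - eps * dxdir) * dy)
        assert abs((lp - lm) / (2 * eps) - np.sum(dx * dxdir)) < atol * max(
            1.0, abs(np.sum(dx * dxdir)))
        # parameter gradients
        layer.forward(x)
        for p in layer.params():
            dd = rng.normal(size=p.value.shape)
            ana = np.sum(dd * p.grad)
            p.value += eps * dd
            lp = np.sum(layer.forward(x) * dy)
            p.value -= 2 * eps * dd
            lm = np.sum(layer.forward(x) * dy)
            p.value += eps * dd
            assert abs((lp - lm) / (2 * eps) - ana) < atol * max(1.0, abs(ana))

    def test_dense(self):
        rng = np.random.default_rng(0)
        self._directional_check(nn.Dense(7, 5, rng), rng.normal(size=(3, 7)))

    def test_conv1d(self):
        rng = np.random.default_rng(1)
        self._directional_check(nn.Conv1d(2, 4, rng), rng.normal(size=(3, 2, 16)))

    def test_conv_transpose1d(self):
        rng = np.random.default_rng(2)
        self._directional_check(nn.ConvTranspose1d(4, 2, rng),
                                rng.normal(size=(3, 4, 8)))

    def test_lstm(self):
        rng = np.random.default_rng(3)
        self._directional_check(nn.LSTM(2, 6, rng), rng.normal(size=(4, 5, 2)))


class TestShapeContracts:
    @pytest.mark.parametrize("arch", ["cnn", "lstm"])
    @pytest.mark.parametrize("input_len,latent", [(2750, 32), (55, 32), (40, 6)])
    def test_encode_decode_shapes(self, arch, input_len, latent):
        cfg = AEConfig(input_len=input_len, latent_dim=latent, arch=arch, seed=0)
        ae = Autoencoder(cfg)
        x = np.random.default_rng(0).normal(size=(4, input_len))
        z = ae.encode(x)
        assert z.shape == (4, latent)
        assert ae.forward(x).shape == x.shape

    def test_cp2_upsampled_when_window_small(self):
        # 55-sample window: closest power of two is 64 > latent 32 -> kept
        assert AEConfig(input_len=55, latent_dim=32).cp2 == 64
        # 40-sample window: nominal CP2 is 32 == latent -> upsampled to 64
        assert AEConfig(input_len=40, latent_dim=32).cp2 == 64

    def test_uncompressive_latent_rejected(self):
        with pytest.raises(ParameterError):
            AEConfig(input_len=100, latent_dim=128)


class TestTraining:
    def _windows(self, n=30, L=40, seed=0):
        rng = np.random.default_rng(seed)
        return normalize_windows(rng.normal(size=(n, L)).cumsum(axis=1))

    @pytest.mark.parametrize("arch", ["cnn", "lstm"])
    def test_loss_decreases(self, arch):
        w = self._windows()
        cfg = AEConfig(input_len=40, latent_dim=8, epochs=15, arch=arch, seed=0)
        enc = train_ae(Autoencoder(cfg), w, cfg, "EDA")
        assert len(enc.loss_history) == 15
        assert enc.loss_history[-1] < enc.loss_history[0]

    def test_beats_constant_predictor(self):
        w = self._windows(n=40)
        cfg = AEConfig(input_len=40, latent_dim=8, epochs=40, seed=0)
        enc = train_ae(Autoencoder(cfg), w, cfg)
        recon = enc.model.forward(w)
        assert np.mean((recon - w) ** 2) < w.var()

    def test_deterministic_given_seed(self):
        w = self._windows()
        cfg = AEConfig(input_len=40, latent_dim=8, epochs=5, seed=7)
        e1 = train_ae(Autoencoder(cfg), w, cfg)
        e2 = train_ae(Autoencoder(cfg), w, cfg)
        assert e1.loss_history == e2.loss_history
        np.testing.assert_array_equal(e1.encode(w), e2.encode(w))

    def test_identical_initial_weights_same_seed(self):
        cfg = AEConfig(input_len=40, latent_dim=8, arch="lstm", seed=3)
        a, b = Autoencoder(cfg), Autoencoder(cfg)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_insufficient_windows_rejected(self):
        w = self._windows(n=5)
        cfg = AEConfig(input_len=40, latent_dim=8, epochs=1, batch_size=10)
        with pytest.raises(ParameterError):
            train_ae(Autoencoder(cfg), w, cfg)

    def test_lstm_learns_constant_sequences(self):
        w = np.full((100, 24), 0.5)
        cfg = AEConfig(input_len=24, latent_dim=4, epochs=100, arch="lstm", seed=0)
        enc = train_ae(Autoencoder(cfg), w, cfg)
        assert np.mean((enc.model.forward(w) - w) ** 2) < 1e-3


class TestExtraction:
    def test_latent_feature_windows(self):
        rng = np.random.default_rng(0)
        w = normalize_windows(rng.normal(size=(12, 40)))
        cfg = AEConfig(input_len=40, latent_dim=6, epochs=2, seed=0)
        enc = train_ae(Autoencoder(cfg), w, cfg, "EDA")
        fw = extract_auto_features(enc, w, meta=[
            {"subject_id": "S1", "modality": "EDA", "t_start": 10.0 * i,
             "window_len": 10.0} for i in range(12)])
        assert len(fw) == 12
        assert all(len(f.values) == 6 for f in fw)
        assert all(f.feature_source == "auto_cnn" for f in fw)

    def test_wrong_window_length_rejected(self):
        rng = np.random.default_rng(0)
        w = normalize_windows(rng.normal(size=(12, 40)))
        cfg = AEConfig(input_len=40, latent_dim=6, epochs=1, seed=0)
        enc = train_ae(Autoencoder(cfg), w, cfg)
        with pytest.raises(ValueError):
            enc.encode(rng.normal(size=(3, 50)))

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        w = normalize_windows(rng.normal(size=(12, 40)))
        cfg = AEConfig(input_len=40, latent_dim=6, epochs=2, seed=0)
        enc = train_ae(Autoencoder(cfg), w, cfg, "EDA")
        save_encoder(enc, tmp_path / "enc")
        back = load_encoder(tmp_path / "enc")
        np.testing.assert_array_equal(enc.encode(w), back.encode(w))
        assert back.loss_history == enc.loss_history
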