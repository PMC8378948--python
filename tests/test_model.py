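"""Tests of the CRNN layers, inspectors, and gradients.

Brute-force scalar oracles (explicit loops over the recurrence and
convolution definitions) are implemented inline and compared against the
vectorized layers.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from taskcrnn import nn
from taskcrnn.errors import ConfigError, ShapeError
from taskcrnn.model import (
    CRNN,
    ConvBlockConfig,
    CrnnConfig,
    count_parameters,
    load_checkpoint,
    reduced_config,
    save_checkpoint,
    shape_chain,
)

from conftest import micro_crnn_config


def conv3d_brute_force(frame, W, b, stride):
    """Direct-loop valid 3D convolution of one frame [X,Y,Z,Cin]."""
    cin, kx, ky, kz, cout = W.shape
    ox = (frame.shape[0] - kx) // stride + 1
    oy = (frame.shape[1] - ky) // stride + 1
    oz = (frame.shape[2] - kz) // stride + 1
    out = np.zeros((ox, oy, oz, cout))
    for i in range(ox):
        for j in range(oy):
            for k in range(oz):
                patch = frame[
                    i * stride : i * stride + kx,
                    j * stride : j * stride + ky,
                    k * stride : k * stride + kz,
                    :,
                ]
                for co in range(cout):
                    out[i, j, k, co] = np.sum(patch * W[:, :, :, :, co].transpose(1, 2, 3, 0)) + b[co]
    return out


class TestConvBlock:
    def test_identity_configuration(self, rng):
        conv = nn.TimeDistributedConv3d(1, 1, (1, 1, 1), stride=1, rng=rng)
        conv.params["W"][:] = 1.0
        conv.params["b"][:] = 0.0
        x = rng.uniform(0.1, 2.0, size=(1, 3, 4, 5, 4, 1)).astype(np.float32)
        bn = nn.BatchNorm(1, eps=0.0)  # identity in eval mode: mean 0, var 1
        relu = nn.ReLU()
        out = relu.forward(bn.forward(conv.forward(x)))
        np.testing.assert_allclose(out, x, rtol=1e-6)

    def test_time_distribution_matches_per_frame_conv(self, rng):
        conv = nn.TimeDistributedConv3d(2, 3, (3, 2, 2), stride=2, rng=rng)
        x = rng.normal(size=(1, 4, 7, 6, 5, 2)).astype(np.float32)
        out = conv.forward(x)
        for t in range(4):
            expected = conv3d_brute_force(
                x[0, t].astype(np.float64), conv.params["W"], conv.params["b"], 2
            )
            np.testing.assert_allclose(out[0, t], expected, atol=1e-5)

    def test_permuting_frames_permutes_outputs(self, rng):
        conv = nn.TimeDistributedConv3d(1, 2, (2, 2, 2), stride=1, rng=rng)
        x = rng.normal(size=(1, 5, 4, 4, 4, 1)).astype(np.float32)
        perm = np.array([3, 1, 4, 0, 2])
        np.testing.assert_allclose(
            conv.forward(x[:, perm]), conv.forward(x)[:, perm], atol=1e-6
        )

    def test_kernel_larger_than_input_rejected(self, rng):
        conv = nn.TimeDistributedConv3d(1, 2, (5, 5, 5), rng=rng)
        with pytest.raises(ShapeError):
            conv.forward(np.zeros((1, 2, 4, 4, 4, 1), dtype=np.float32))

    def test_valid_conv_arithmetic_of_default_stack(self):
        # [20,78,93,76,1] -> [20,36,44,35,32] for block 1, etc. (analytic)
        chain = shape_chain(CrnnConfig()).to_dict()
        assert chain["conv1"] == [20, 36, 44, 35, 32]
        assert chain["conv2"] == [20, 17, 21, 17, 64]
        assert chain["conv3"] == [20, 8, 10, 8, 64]
        assert chain["conv4"] == [20, 1, 1, 1, 64]


class TestCnnForward:
    def test_zero_input_zero_biases_gives_zero_features(self):
        cfg = micro_crnn_config(dropout=0.0)
        model = CRNN(cfg, seed=0)
        x = np.zeros((2, *cfg.input_shape), dtype=np.float32)
        feats = model.cnn_forward(x)  # eval-mode BN: mean 0, var 1, beta 0
        assert feats.shape == (2, 20, 8)
        np.testing.assert_allclose(feats, 0.0, atol=1e-6)

    def test_shape_chain_endpoint(self):
        cfg = micro_crnn_config()
        model = CRNN(cfg, seed=0)
        x = np.random.default_rng(0).normal(size=(1, *cfg.input_shape)).astype(np.float32)
        model.cnn_forward(x)
        assert model._pre_squeeze_shape[2:5] == (1, 1, 1)


class TestLstm:
    def test_zero_weights_zero_states(self):
        W = np.zeros((5 + 3, 12), dtype=np.float32)
        b = np.zeros(12, dtype=np.float32)
        h0 = np.zeros((2, 3), dtype=np.float32)
        c0 = np.zeros((2, 3), dtype=np.float32)
        x = np.ones((2, 5), dtype=np.float32)
        h, c, _ = nn.LSTM.step(x, h0, c0, W, b)
        np.testing.assert_array_equal(h, 0.0)  # o*tanh(c)=0.5*tanh(0)
        np.testing.assert_array_equal(c, 0.0)

    def test_saturated_forget_gate_preserves_cell(self):
        h_dim = 3
        W = np.zeros((2 + h_dim, 4 * h_dim), dtype=np.float32)
        b = np.zeros(4 * h_dim, dtype=np.float32)
        b[:h_dim] = 30.0  # forget bias -> sigmoid ~ 1
        b[h_dim : 2 * h_dim] = -30.0  # input gate ~ 0
        c_prev = np.array([[0.3, -0.8, 1.2]], dtype=np.float32)
        _, c, _ = nn.LSTM.step(
            np.ones((1, 2), dtype=np.float32), np.zeros((1, h_dim), np.float32), c_prev, W, b
        )
        np.testing.assert_allclose(c, c_prev, atol=1e-6)

    def test_sequence_matches_scalar_recurrence(self, rng):
        d, h, t = 3, 2, 5
        lstm = nn.LSTM(d, h, rng=rng)
        x = rng.normal(size=(1, t, d)).astype(np.float32)
        out = lstm.forward(x)

        def sig(v):
            return 1.0 / (1.0 + np.exp(-v))

        W = lstm.params["W"].astype(np.float64)
        b = lstm.params["b"].astype(np.float64)
        hs, cs = np.zeros(h), np.zeros(h)
        for step in range(t):
            z = np.concatenate([hs, x[0, step]]) @ W + b
            f, i = sig(z[:h]), sig(z[h : 2 * h])
            g, o = np.tanh(z[2 * h : 3 * h]), sig(z[3 * h :])
            cs = f * cs + i * g
            hs = o * np.tanh(cs)
            np.testing.assert_allclose(out[0, step], hs, atol=1e-6)


class TestBiLstm:
    def test_time_reversal_swaps_and_reverses_halves(self, rng):
        # structural symmetry; requires the two directions to share weights
        bilstm = nn.BiLSTM(4, 3, rng=rng)
        bilstm.params["bwd_W"] = bilstm.params["fwd_W"].copy()
        bilstm.params["bwd_b"] = bilstm.params["fwd_b"].copy()
        x = rng.normal(size=(2, 6, 4)).astype(np.float32)
        out = bilstm.forward(x)
        out_rev = bilstm.forward(x[:, ::-1].copy())
        np.testing.assert_allclose(out_rev[..., :3], out[:, ::-1, 3:], atol=1e-6)
        np.testing.assert_allclose(out_rev[..., 3:], out[:, ::-1, :3], atol=1e-6)

    def test_deterministic_without_dropout(self, rng):
        bilstm = nn.BiLSTM(4, 3, rng=rng)
        x = rng.normal(size=(1, 20, 4)).astype(np.float32)
        np.testing.assert_array_equal(bilstm.forward(x), bilstm.forward(x))
        assert bilstm.forward(x).shape == (1, 20, 6)


class TestAttention:
    def test_identical_rows_give_uniform_weights(self, rng):
        att = nn.AdditiveAttention(4, 3, rng=rng)
        row = rng.normal(size=4).astype(np.float32)
        H = np.tile(row, (1, 20, 1)).astype(np.float32)
        c = att.forward(H)
        np.testing.assert_allclose(att.last_weights, 1.0 / 20, atol=1e-7)
        np.testing.assert_allclose(c[0], row, atol=1e-6)

    def test_dominant_score_selects_one_step(self, rng):
        att = nn.AdditiveAttention(2, 2, rng=rng)
        att.params["W"] = np.eye(2, dtype=np.float32)
        att.params["b"][:] = 0.0
        att.params["u"] = np.array([100.0, 0.0], dtype=np.float32)
        H = np.array([[[-1.0, 0.0], [1.0, 0.5], [-1.0, 0.2]]], dtype=np.float32)
        c = att.forward(H)
        np.testing.assert_allclose(c[0], H[0, 1], atol=1e-4)

    def test_two_step_toy_against_hand_computation(self):
        att = nn.AdditiveAttention(2, 2)
        att.params["W"] = np.array([[0.5, -0.25], [0.1, 0.3]])
        att.params["b"] = np.array([0.05, -0.1])
        att.params["u"] = np.array([0.2, -0.4])
        H = np.array([[[1.0, 2.0], [-0.5, 0.25]]])
        pre = H[0] @ att.params["W"] + att.params["b"]
        scores = np.tanh(pre) @ att.params["u"]
        w = np.exp(scores) / np.exp(scores).sum()
        expected = w[0] * H[0, 0] + w[1] * H[0, 1]
        np.testing.assert_allclose(att.forward(H)[0], expected, atol=1e-8)

    @given(st.integers(0, 2**31 - 1))
    def test_weights_nonnegative_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        att = nn.AdditiveAttention(5, 4, rng=rng)
        H = rng.normal(scale=3.0, size=(2, 20, 5)).astype(np.float32)
        att.forward(H)
        assert np.all(att.last_weights >= 0)
        np.testing.assert_allclose(att.last_weights.sum(axis=1), 1.0, atol=1e-6)

    def test_elementwise_variant_uniform_case(self):
        att = nn.ElementwiseSoftmaxAttention()
        H = np.full((1, 4, 3), 0.7, dtype=np.float32)
        c = att.forward(H)
        np.testing.assert_allclose(c, 0.7, atol=1e-6)
        np.testing.assert_allclose(att.last_weights.sum(axis=1), 1.0, atol=1e-6)


class TestClassifierAndLoss:
    def test_zero_parameters_give_uniform_probabilities(self):
        d1 = nn.Dense(8, 4, relu=True)
        d2 = nn.Dense(4, 7)
        for layer in (d1, d2):
            layer.params["W"][:] = 0
            layer.params["b"][:] = 0
        logits = d2.forward(d1.forward(np.random.default_rng(0).normal(size=(3, 8)).astype(np.float32)))
        probs = nn.softmax(logits)
        np.testing.assert_allclose(probs, 1.0 / 7, atol=1e-7)

    def test_probabilities_sum_to_one_and_shift_invariance(self, rng):
        logits = rng.normal(scale=5, size=(10, 7))
        p = nn.softmax(logits)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(nn.softmax(logits + 13.7), p, atol=1e-6)

    def test_uniform_logits_cross_entropy_is_ln7(self):
        loss, _ = nn.cross_entropy(np.zeros(7), np.array(3))
        assert loss == pytest.approx(np.log(7), abs=1e-9)

    def test_confident_logits_drive_loss_to_zero(self):
        logits = np.full(7, -10.0)
        logits[2] = 30.0
        loss, _ = nn.cross_entropy(logits, np.array(2))
        assert loss < 1e-6

    def test_random_logits_match_direct_formula(self, rng):
        logits = rng.normal(size=(5, 7))
        labels = rng.integers(0, 7, size=5)
        loss, _ = nn.cross_entropy(logits, labels)
        p = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        direct = -np.mean([np.log(p[i, labels[i]]) for i in range(5)])
        assert loss == pytest.approx(direct, abs=1e-8)


class TestInspectors:
    def test_default_parameter_tally(self):
        report = count_parameters(CrnnConfig())
        assert report.trainable == 2_882_055
        assert report.total == 2_882_503
        assert report.non_trainable == 448

    def test_closed_form_pieces(self):
        report = count_parameters(CrnnConfig())
        by_name = {e.name: e for e in report.entries}
        assert by_name["conv1"].trainable == 7**3 * 1 * 32 + 32 == 11_008
        assert by_name["bilstm"].trainable == 2 * 4 * ((64 + 64) * 64 + 64) == 66_048
        assert by_name["attention"].trainable == 128 * 64 + 64 + 64 == 8_320
        assert by_name["dense1"].trainable == 128 * 64 + 64
        assert by_name["dense2"].trainable == 64 * 7 + 7

    def test_elementwise_attention_has_no_parameters(self):
        report = count_parameters(CrnnConfig(attention="elementwise"))
        assert report.trainable == 2_882_055 - 8_320

    def test_report_totals_consistent(self):
        report = count_parameters(CrnnConfig())
        assert report.total == report.trainable + report.non_trainable
        assert report.total == sum(e.total for e in report.entries)

    def test_analytic_count_matches_allocated_model(self):
        cfg = micro_crnn_config()
        model = CRNN(cfg, seed=0)
        trainable, non_trainable = model.n_parameters()
        report = count_parameters(cfg)
        assert trainable == report.trainable
        assert non_trainable == report.non_trainable

    def test_feature_into_classifier_is_128(self):
        assert CrnnConfig().feature_dim == 128

    def test_full_convolution_condition_enforced(self):
        blocks = list(CrnnConfig().conv_blocks)
        blocks[-1] = ConvBlockConfig((7, 10, 8), 64, 1)  # no longer covers [8,10,8]
        with pytest.raises(ConfigError, match="full convolution"):
            shape_chain(CrnnConfig(conv_blocks=tuple(blocks)))

    def test_too_small_input_names_failing_stage(self):
        with pytest.raises(ConfigError, match="conv4"):
            shape_chain(CrnnConfig(input_shape=(20, 40, 50, 40, 1)))


class TestGradientsAndState:
    def test_backprop_matches_finite_differences(self):
        cfg = CrnnConfig(
            conv_blocks=(ConvBlockConfig((2, 2, 2), 3, 2), ConvBlockConfig((2, 2, 2), 4, 1)),
            lstm_units=3,
            attention_dim=3,
            dense_units=4,
            n_classes=3,
            input_shape=(4, 4, 4, 4, 1),
            lstm_dropout=0.0,
        )
        model = CRNN(cfg, seed=1)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 4, 4, 4, 4, 1)).astype(np.float32)
        y = np.array([0, 2])
        model.loss_and_grads(x, y)
        analytic = {name: layer.grads[key].copy() for name, layer, key in model.named_params()}

        def loss():
            return nn.cross_entropy(model.forward(x, training=True), y)[0]

        eps = 1e-3
        pick = np.random.default_rng(1)
        for name, layer, key in model.named_params():
            flat = layer.params[key].reshape(-1)
            for i in pick.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss()
                flat[i] = orig - eps
                lm = loss()
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                ana = analytic[name].reshape(-1)[i]
                assert abs(num - ana) <= 1e-3 + 0.05 * (abs(num) + abs(ana)), (
                    f"{name}[{i}]: numeric {num}, analytic {ana}"
                )

    def test_forward_deterministic_without_dropout(self, rng):
        cfg = micro_crnn_config(dropout=0.0)
        model = CRNN(cfg, seed=3)
        x = rng.normal(size=(2, *cfg.input_shape)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_checkpoint_round_trip(self, tmp_path, rng):
        cfg = micro_crnn_config()
        model = CRNN(cfg, seed=5)
        x = rng.normal(size=(3, *cfg.input_shape)).astype(np.float32)
        before = model.predict_proba(x)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path)
        np.testing.assert_array_equal(restored.predict_proba(x), before)
        assert restored.config == cfg

    def test_reduced_config_is_valid_and_small(self):
        cfg = reduced_config()
        report = count_parameters(cfg)
        assert report.trainable < 200_000
        chain = shape_chain(cfg)
        assert chain.final_cnn_shape[1:4] == (1, 1, 1)
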