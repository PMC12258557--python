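"""Network unit tests: GRU equations vs a scalar oracle, conv-block shapes,
parameter counting, gradient correctness, determinism contracts."""

import math

import numpy as np
import pytest

from drawkin.architecture import (
    BRANCH_NAMES,
    ConvBlockConfig,
    ConvBlock,
    ModelConfig,
    count_parameters,
    init_model,
)
from drawkin.nn import GRUParameters, bigru_forward, gru_step
from drawkin.nn.layers import sigmoid


# ---------------------------------------------------------------------------
# scalar-loop oracle for the gated-recurrent equations
# ---------------------------------------------------------------------------

def _sig(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-v))


def gru_step_oracle(p: GRUParameters, x_t, h_prev):
    """Element-by-element evaluation of the GRU update, no matrix ops."""
    H, C = p.hidden_size, p.input_size
    cat = list(h_prev) + list(x_t)
    z = [_sig(sum(p.W_z[i][j] * cat[j] for j in range(H + C)) + p.b_z[i]) for i in range(H)]
    r = [_sig(sum(p.W_r[i][j] * cat[j] for j in range(H + C)) + p.b_r[i]) for i in range(H)]
    cat_c = [r[i] * h_prev[i] for i in range(H)] + list(x_t)
    g = [
        math.tanh(sum(p.W_h[i][j] * cat_c[j] for j in range(H + C)) + p.b_h[i])
        for i in range(H)
    ]
    return np.array([(1.0 - z[i]) * h_prev[i] + z[i] * g[i] for i in range(H)])


def bigru_oracle(p_fwd, p_bwd, seq):
    T = seq.shape[0]
    H = p_fwd.hidden_size
    out = np.zeros((T, 2 * H))
    h = np.zeros(H)
    for t in range(T):
        h = gru_step_oracle(p_fwd, seq[t], h)
        out[t, :H] = h
    h = np.zeros(H)
    for t in range(T - 1, -1, -1):
        h = gru_step_oracle(p_bwd, seq[t], h)
        out[t, H:] = h
    return out


def _random_params(rng, H, C):
    return GRUParameters(
        W_z=rng.normal(size=(H, H + C)),
        W_r=rng.normal(size=(H, H + C)),
        W_h=rng.normal(size=(H, H + C)),
        b_z=rng.normal(size=H),
        b_r=rng.normal(size=H),
        b_h=rng.normal(size=H),
    )


class TestGRUStep:
    def test_zero_weights_zero_state(self):
        p = GRUParameters(*(np.zeros((1, 2)),) * 3, *(np.zeros(1),) * 3)
        np.testing.assert_allclose(gru_step(p, np.zeros(1), np.zeros(1)), 0.0)

    def test_zero_weights_unit_state_halves(self):
        # z = r = 0.5, candidate tanh(0) = 0 -> h = (1-0.5)*1 + 0.5*0 = 0.5
        p = GRUParameters(*(np.zeros((1, 2)),) * 3, *(np.zeros(1),) * 3)
        np.testing.assert_allclose(gru_step(p, np.zeros(1), np.ones(1)), 0.5)

    def test_scalar_unit_weights(self):
        # H=C=1, weights 1, x=1, h=0: z=r=sigma(1), candidate tanh(1),
        # h = sigma(1)*tanh(1) = 0.7310586*0.7615942 = 0.5567699
        p = GRUParameters(*(np.ones((1, 2)),) * 3, *(np.zeros(1),) * 3)
        h = gru_step(p, np.ones(1), np.zeros(1))
        expected = _sig(1.0) * math.tanh(1.0)
        np.testing.assert_allclose(h, expected, atol=1e-12)
        assert expected == pytest.approx(0.5567699, abs=5e-7)

    def test_matches_scalar_oracle_on_100_random_instances(self):
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(100):
            H = int(rng.integers(1, 5))
            C = int(rng.integers(1, 5))
            p = _random_params(rng, H, C)
            x = rng.normal(size=C)
            h0 = rng.normal(size=H)
            got = gru_step(p, x, h0)
            want = gru_step_oracle(p, x, h0)
            worst = max(worst, float(np.max(np.abs(got - want))))
        assert worst < 1e-6

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        p = _random_params(rng, 2, 3)
        with pytest.raises(ValueError):
            gru_step(p, np.zeros(2), np.zeros(2))


class TestBiGRU:
    def test_single_step_equals_one_gru_step(self):
        rng = np.random.default_rng(1)
        p_f, p_b = _random_params(rng, 3, 2), _random_params(rng, 3, 2)
        seq = rng.normal(size=(1, 2))
        out = bigru_forward(p_f, p_b, seq)
        np.testing.assert_allclose(out[0, :3], gru_step(p_f, seq[0], np.zeros(3)))
        np.testing.assert_allclose(out[0, 3:], gru_step(p_b, seq[0], np.zeros(3)))

    def test_zero_parameters_propagate_zeros(self):
        p = GRUParameters(*(np.zeros((2, 5)),) * 3, *(np.zeros(2),) * 3)
        out = bigru_forward(p, p, np.random.default_rng(0).normal(size=(4, 3)))
        np.testing.assert_array_equal(out, 0.0)

    def test_matches_stepwise_oracle_and_reversal_property(self):
        rng = np.random.default_rng(5)
        p_f, p_b = _random_params(rng, 2, 3), _random_params(rng, 2, 3)
        seq = rng.normal(size=(4, 3))
        out = bigru_forward(p_f, p_b, seq)
        np.testing.assert_allclose(out, bigru_oracle(p_f, p_b, seq), atol=1e-6)
        # backward half = forward recursion of p_b on the reversed sequence, re-reversed
        rev = bigru_oracle(p_b, p_f, seq[::-1])[:, :2][::-1]
        np.testing.assert_allclose(out[:, 2:], rev, atol=1e-10)


class TestConvBlock:
    def test_channel_arithmetic_all_branches(self):
        rng = np.random.default_rng(0)
        block = ConvBlock(8, ConvBlockConfig(filters=8), rng)
        out = block.forward(np.random.default_rng(1).normal(size=(2, 32, 8)))
        assert out.shape == (2, 32, 32)  # 3*8 + 8

    def test_second_block_shape(self):
        rng = np.random.default_rng(0)
        block = ConvBlock(32, ConvBlockConfig(filters=16), rng)
        out = block.forward(np.zeros((1, 32, 32)))
        assert out.shape == (1, 32, 80)  # 3*16 + 32

    def test_pool_branch_passes_constant_through(self):
        rng = np.random.default_rng(0)
        cfg = ConvBlockConfig(filters=4, enabled_branches=frozenset({"conv1", "conv3", "conv5", "maxpool"}))
        block = ConvBlock(2, cfg, rng)
        for conv in block.convs.values():
            conv.params["W"][:] = 0.0
            conv.params["b"][:] = 0.0
        x = np.full((1, 10, 2), -3.5)
        out = block.forward(x)
        np.testing.assert_array_equal(out[:, :, :12], 0.0)  # conv channels
        np.testing.assert_array_equal(out[:, :, 12:], -3.5)  # pool channels

    def test_time_length_preserved_for_odd_lengths(self):
        rng = np.random.default_rng(0)
        block = ConvBlock(3, ConvBlockConfig(filters=2), rng)
        out = block.forward(np.zeros((1, 17, 3)))
        assert out.shape[1] == 17

    def test_all_branches_disabled_rejected(self):
        with pytest.raises(ValueError):
            ConvBlockConfig(filters=4, enabled_branches=frozenset({"residual"}))


class TestModel:
    def test_eval_mode_deterministic(self):
        cfg = ModelConfig.small(n_channels=4, window_samples=16)
        net = init_model(cfg, seed=3)
        x = np.random.default_rng(0).normal(size=(5, 16, 4))
        p1 = net.predict_proba(x)
        p2 = net.predict_proba(x)
        np.testing.assert_array_equal(p1, p2)
        assert np.all((p1 > 0) & (p1 < 1))

    def test_no_conv_blocks_consumes_raw_windows(self):
        cfg = ModelConfig(n_channels=8, window_samples=16, n_conv_blocks=0, hidden_units=4)
        net = init_model(cfg, seed=0)
        p = net.predict_proba(np.random.default_rng(1).normal(size=(3, 16, 8)))
        assert p.shape == (3,) and np.all((p > 0) & (p < 1))

    def test_init_determinism_and_seed_sensitivity(self):
        cfg = ModelConfig.small(n_channels=4)
        w1 = init_model(cfg, seed=7).get_weights()
        w2 = init_model(cfg, seed=7).get_weights()
        w3 = init_model(cfg, seed=8).get_weights()
        for k in w1:
            np.testing.assert_array_equal(w1[k], w2[k])
        assert any(not np.array_equal(w1[k], w3[k]) for k in w1)

    def test_parameter_count_closed_form_and_branch_removal(self):
        cfg = ModelConfig(n_channels=4, window_samples=32)
        net = init_model(cfg, seed=0)
        assert net.n_parameters == count_parameters(cfg)
        smaller = cfg.without_branch(4)  # drop the 1x5 conv
        assert count_parameters(smaller) < count_parameters(cfg)
        assert init_model(smaller, 0).n_parameters == count_parameters(smaller)
        # every branch removal changes the count distinctly
        counts = {count_parameters(cfg.without_branch(i)) for i in BRANCH_NAMES}
        assert len(counts) == len(BRANCH_NAMES)

    @pytest.mark.parametrize("cell", ["rnn", "lstm", "gru"])
    def test_cell_swap_same_interface(self, cell):
        cfg = ModelConfig.small(n_channels=4, window_samples=8, recurrent_cell=cell)
        net = init_model(cfg, seed=1)
        p = net.predict_proba(np.random.default_rng(0).normal(size=(2, 8, 4)))
        assert p.shape == (2,)

    def test_width_mismatch_rejected(self):
        net = init_model(ModelConfig.small(n_channels=4), seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 32, 6)))

    def test_checkpoint_round_trip(self, tmp_path):
        cfg = ModelConfig.small(n_channels=4, window_samples=8)
        net = init_model(cfg, seed=5)
        x = np.random.default_rng(2).normal(size=(3, 8, 4))
        net.save(tmp_path / "ckpt")
        from drawkin.architecture import SegmentClassifierNet

        back = SegmentClassifierNet.load(tmp_path / "ckpt")
        np.testing.assert_array_equal(net.predict_proba(x), back.predict_proba(x))


class TestGradients:
    @pytest.mark.parametrize("cell", ["gru", "lstm", "rnn"])
    def test_backprop_matches_numerical_gradient(self, cell):
        cfg = ModelConfig(
            n_channels=3, window_samples=6, n_conv_blocks=2, block_filters=(2, 3),
            hidden_units=2, dropout_rate=0.0, recurrent_cell=cell,
        )
        net = init_model(cfg, seed=0)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 6, 3))
        y = np.array([1.0, 0.0])

        def loss():
            p = np.clip(sigmoid(net.forward(x)), 1e-12, 1 - 1e-12)
            return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

        for layer in net.layers():
            layer.zero_grad()
        p = sigmoid(net.forward(x))
        net.backward((p - y) / x.shape[0])
        eps = 1e-6
        check_rng = np.random.default_rng(0)
        for layer in net.layers():
            for k, P in layer.params.items():
                flat_idx = check_rng.choice(P.size, size=min(4, P.size), replace=False)
                for i in flat_idx:
                    idx = np.unravel_index(i, P.shape)
                    old = P[idx]
                    P[idx] = old + eps
                    lp = loss()
                    P[idx] = old - eps
                    lm = loss()
                    P[idx] = old
                    num = (lp - lm) / (2 * eps)
                    ana = layer.grads[k][idx]
                    assert abs(num - ana) <= 1e-5 * max(1.0, abs(num))
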