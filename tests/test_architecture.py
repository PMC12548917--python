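"""Architecture contracts: per-stage shapes, receptive field, causality,
attention normalization and brute-force oracle equivalence."""

import numpy as np
import pytest

from midecode import nn
from midecode.errors import ConfigurationError, ShapeError
from midecode.model import (
    ModelConfig,
    MultiBranchSeparableConv,
    MultiHeadSelfAttention,
    MultiScaleAttentionTCN,
    ResidualTCNBlock,
    SpatioTemporalConv,
    TemporalConvNet,
    count_parameters,
    decision_fusion,
    expected_table,
    feature_fusion,
    load_checkpoint,
    receptive_field_size,
    save_checkpoint,
    shape_trace,
)
from midecode.nn import Tensor

RNG = np.random.default_rng(0)


class TestReceptiveField:
    @pytest.mark.parametrize("kt,l,expected", [(4, 2, 19), (1, 1, 1), (1, 5, 1), (3, 3, 29)])
    def test_formula(self, kt, l, expected):
        assert receptive_field_size(kt, l) == expected

    def test_domain_errors(self):
        with pytest.raises(ConfigurationError):
            receptive_field_size(0, 2)
        with pytest.raises(ConfigurationError):
            receptive_field_size(4, 0)


class TestShapeContract:
    def test_default_geometry_matches_layer_table(self):
        cfg = ModelConfig(C=22, T=1000, Nc=4)
        trace = shape_trace(cfg)
        for stage, want in expected_table(cfg).items():
            assert trace[stage] == want, stage
        assert trace["RFS"] == 19
        assert trace["TCN input length"] == 15

    def test_three_channel_preset_collapses_spatial_axis(self):
        cfg = ModelConfig(C=3, T=1000, Nc=2)
        trace = shape_trace(cfg)
        assert trace["Pool1"] == (64, 1, 125)
        assert trace["Pool2"] == (64, 1, 15)

    def test_config_invariant_violations(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(C=3, T=256, Nc=2, F1=3, D=1).validate()  # F2 not /4
        with pytest.raises(ConfigurationError):
            ModelConfig(C=3, T=256, Nc=2, F1=8, D=2, heads=3).validate()
        with pytest.raises(ConfigurationError):
            ModelConfig(C=3, T=128, Nc=2, F1=8, D=2, n_windows=3).validate()
        with pytest.raises(ConfigurationError):
            ModelConfig(C=3, T=1000, Nc=2, Kt=2, L=2).validate()  # RFS 7 <= 13


class TestSpatioTemporalConv:
    def test_zero_input_gives_zero_preactivation(self, tiny_cfg):
        """Both convolutions are bias-free, so zero input stays zero through
        the linear stages."""
        sc = SpatioTemporalConv(tiny_cfg, np.random.default_rng(0),
                                np.random.default_rng(1))
        x = Tensor(np.zeros((2, 3, 256), dtype=np.float32))
        h = sc.temporal(x.reshape(2 * 3, 1, 256))
        assert np.all(h.data == 0.0)

    def test_output_extents(self, tiny_cfg):
        sc = SpatioTemporalConv(tiny_cfg, np.random.default_rng(0),
                                np.random.default_rng(1)).eval()
        out = sc(Tensor(RNG.standard_normal((2, 3, 256)).astype(np.float32)))
        assert out.shape == (2, 16, 32)


class TestMSC:
    def test_depth_conservation(self, tiny_cfg):
        msc = MultiBranchSeparableConv(tiny_cfg, np.random.default_rng(0),
                                       np.random.default_rng(1)).eval()
        out = msc(Tensor(RNG.standard_normal((2, 16, 32)).astype(np.float32)))
        assert out.shape == (2, 16, 4)  # depth F2 = 16/4+16/4+16/2

    def test_single_branch_depth(self):
        cfg = ModelConfig(C=3, T=256, Nc=2, F1=8, D=2, msc_kernels=(16,))
        msc = MultiBranchSeparableConv(cfg, np.random.default_rng(0),
                                       np.random.default_rng(1)).eval()
        out = msc(Tensor(RNG.standard_normal((1, 16, 32)).astype(np.float32)))
        assert out.shape == (1, 16, 4)

    def test_wrong_depth_raises(self, tiny_cfg):
        msc = MultiBranchSeparableConv(tiny_cfg, np.random.default_rng(0),
                                       np.random.default_rng(1))
        with pytest.raises(ShapeError):
            msc(Tensor(np.zeros((1, 8, 32), dtype=np.float32)))


class TestAttention:
    def _msa(self, cfg):
        return MultiHeadSelfAttention(cfg, np.random.default_rng(3),
                                      np.random.default_rng(4)).eval()

    def test_shape_preserved_and_rows_normalized(self, tiny_cfg):
        msa = self._msa(tiny_cfg)
        out = msa(Tensor(RNG.standard_normal((2, 4, 16)).astype(np.float32)))
        assert out.shape == (2, 4, 16)
        rows = msa.last_attention.sum(axis=-1)
        np.testing.assert_allclose(rows, 1.0, atol=1e-6)

    def test_single_position_attention_is_one(self, tiny_cfg):
        msa = self._msa(tiny_cfg)
        msa(Tensor(RNG.standard_normal((1, 1, 16)).astype(np.float32)))
        np.testing.assert_allclose(msa.last_attention, 1.0, atol=1e-7)

    def test_empty_sequence_raises(self, tiny_cfg):
        with pytest.raises(ShapeError):
            self._msa(tiny_cfg)(Tensor(np.zeros((1, 0, 16), dtype=np.float32)))

    def test_matches_brute_force_single_head(self):
        """Hand-evaluated layer-norm -> Q,K,V -> scaled softmax attention ->
        output projection -> ELU on a 2-element sequence."""
        cfg = ModelConfig(C=3, T=256, Nc=2, F1=2, D=2, heads=1)
        msa = self._msa(cfg)
        f2 = cfg.F2  # 4
        rng = np.random.default_rng(11)
        wq, wk, wv, wo = (rng.integers(-2, 3, size=(f2, f2)).astype(np.float64) * 0.5
                          for _ in range(4))
        msa.wq.data, msa.wk.data, msa.wv.data, msa.wo.data = wq, wk, wv, wo
        x = rng.standard_normal((1, 2, f2))
        out = msa(Tensor(x)).data[0]

        # independent brute-force evaluation
        y = np.empty_like(x[0])
        for i in range(2):
            mu, var = x[0, i].mean(), x[0, i].var()
            y[i] = (x[0, i] - mu) / np.sqrt(var + 1e-5)
        q, k, v = y @ wq, y @ wk, y @ wv
        scores = q @ k.T / np.sqrt(f2)
        att = np.exp(scores - scores.max(axis=1, keepdims=True))
        att /= att.sum(axis=1, keepdims=True)
        z = (att @ v) @ wo
        expected = np.where(z > 0, z, np.exp(z) - 1)
        np.testing.assert_allclose(out, expected, atol=1e-5)


class TestTCN:
    def _cfg(self):
        return ModelConfig(C=3, T=256, Nc=2, F1=8, D=2)

    def test_output_is_last_step_vector(self):
        cfg = self._cfg()
        tcn = TemporalConvNet(32, cfg, np.random.default_rng(0),
                              np.random.default_rng(1)).eval()
        out = tcn(Tensor(RNG.standard_normal((2, 32, 13)).astype(np.float32)))
        assert out.shape == (2, 32)

    def test_sequence_longer_than_rfs_rejected(self):
        cfg = self._cfg()
        tcn = TemporalConvNet(8, cfg, np.random.default_rng(0),
                              np.random.default_rng(1))
        with pytest.raises(ConfigurationError):
            tcn(Tensor(np.zeros((1, 8, 25), dtype=np.float32)))  # RFS 19 <= 25

    def test_causality_exact_perturbation(self):
        """Perturbing input position t leaves all activations at earlier
        positions bit-identical, for every t in a length-13 sequence."""
        cfg = self._cfg()
        tcn = TemporalConvNet(16, cfg, np.random.default_rng(5),
                              np.random.default_rng(6)).eval()
        x = RNG.standard_normal((1, 16, 13)).astype(np.float32)

        def activations(arr):
            h = Tensor(arr)
            outs = []
            with nn.no_grad():
                for block in tcn.blocks:
                    h = block(h)
                    outs.append(h.data.copy())
            return outs

        base = activations(x)
        for t in range(13):
            x2 = x.copy()
            x2[0, :, t] += 1.0
            pert = activations(x2)
            for layer_base, layer_pert in zip(base, pert):
                assert np.array_equal(layer_base[..., :t], layer_pert[..., :t]), t

    def test_zeroed_second_conv_reduces_to_identity(self):
        """With the second convolution zeroed, batch-norm at its running
        statistics and dropout off, the residual path is exactly the
        identity, so the block returns its input and the TCN output equals
        the final input element."""
        cfg = ModelConfig(C=3, T=256, Nc=2, F1=8, D=2, L=1)
        tcn = TemporalConvNet(8, cfg, np.random.default_rng(0),
                              np.random.default_rng(1)).eval()
        block = tcn.blocks[0]
        block.conv2.weight.data[:] = 0.0
        block.bn2.gamma.data[:] = 1.0  # BN(0) = 0 at running stats (0, 1)
        x = RNG.standard_normal((1, 8, 5)).astype(np.float32)
        out = tcn(Tensor(x)).data
        np.testing.assert_allclose(out, x[:, :, -1], atol=1e-6)

    def test_residual_block_matches_brute_force(self):
        """One residual block on a 3-element sequence with hand-set weights
        equals an explicit causal-convolution evaluation."""
        block = ResidualTCNBlock(2, 2, kt=2, dilation=1,
                                 rng=np.random.default_rng(0),
                                 drop_rng=np.random.default_rng(1),
                                 p_drop=0.5).eval()
        w1 = np.array([[[0.5, 1.0], [0.0, -1.0]], [[1.0, 0.0], [0.5, 0.5]]])
        w2 = np.array([[[1.0, 0.0], [0.0, 1.0]], [[0.0, 1.0], [1.0, 0.0]]])
        block.conv1.weight.data = w1.astype(np.float32)
        block.conv2.weight.data = w2.astype(np.float32)
        x = RNG.standard_normal((1, 2, 3)).astype(np.float32)

        def causal_conv(inp, w):
            padded = np.pad(inp, ((0, 0), (1, 0)))
            out = np.zeros_like(inp)
            for o in range(2):
                for t in range(inp.shape[1]):
                    out[o, t] = (padded[:, t : t + 2] * w[o]).sum()
            return out

        def bn_eval(h):  # running stats (0, 1)
            return h / np.sqrt(1.0 + 1e-5)

        def elu(h):
            return np.where(h > 0, h, np.exp(np.minimum(h, 0)) - 1)

        h = elu(bn_eval(causal_conv(x[0], w1)))
        h = elu(bn_eval(causal_conv(h, w2)))
        expected = x[0] + h
        np.testing.assert_allclose(block(Tensor(x)).data[0], expected, atol=1e-5)


class TestFusion:
    def test_feature_fusion_concat_semantics(self):
        a = Tensor(RNG.standard_normal((1, 4, 8)).astype(np.float32))
        zero = Tensor(np.zeros((1, 4, 8), dtype=np.float32))
        fused = feature_fusion(a, zero)
        assert fused.shape == (1, 4, 16)
        np.testing.assert_array_equal(fused.data[..., :8], a.data)
        np.testing.assert_array_equal(fused.data[..., 8:], 0.0)

    def test_feature_fusion_time_mismatch(self):
        with pytest.raises(ShapeError):
            feature_fusion(Tensor(np.zeros((1, 4, 8))), Tensor(np.zeros((1, 5, 8))))

    def test_decision_fusion_closed_forms(self):
        zero = Tensor(np.zeros((1, 4)))
        probs = nn.softmax(decision_fusion(zero, zero), axis=1).data
        np.testing.assert_allclose(probs, 0.25)
        logits = Tensor(np.array([[1.0, 0.0]]))
        fused = decision_fusion(logits, logits)
        probs = nn.softmax(fused, axis=1).data[0]
        np.testing.assert_allclose(probs, [0.8808, 0.1192], atol=1e-4)
        # additive identity: zero second branch leaves softmax(logits)
        same = nn.softmax(decision_fusion(logits, Tensor(np.zeros((1, 2)))), axis=1)
        np.testing.assert_allclose(same.data, nn.softmax(logits, axis=1).data)


class TestFullModel:
    def test_probability_simplex_output(self, tiny_cfg):
        model = MultiScaleAttentionTCN(tiny_cfg, seed=0)
        probs = model.predict_proba(RNG.standard_normal((3, 3, 256)).astype(np.float32))
        assert probs.shape == (3, 2)
        assert np.all(probs > 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_eval_mode_is_deterministic(self, tiny_cfg):
        model = MultiScaleAttentionTCN(tiny_cfg, seed=0)
        x = RNG.standard_normal((2, 3, 256)).astype(np.float32)
        np.testing.assert_array_equal(model.predict_proba(x), model.predict_proba(x))

    @pytest.mark.parametrize(
        "removed", ["msc", "msa", "tcn", "feature_fusion", "decision_fusion", "mff"]
    )
    def test_ablated_variants_forward(self, tiny_cfg, removed):
        model = MultiScaleAttentionTCN(tiny_cfg, seed=0, removed_block=removed)
        probs = model.predict_proba(RNG.standard_normal((2, 3, 256)).astype(np.float32))
        assert probs.shape == (2, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_unknown_ablation_rejected(self, tiny_cfg):
        with pytest.raises(ConfigurationError):
            MultiScaleAttentionTCN(tiny_cfg, removed_block="bogus")

    def test_wrong_input_shape_rejected(self, tiny_cfg):
        model = MultiScaleAttentionTCN(tiny_cfg, seed=0)
        with pytest.raises(ShapeError):
            model(np.zeros((1, 5, 256), dtype=np.float32))

    def test_parameter_count_properties(self, tiny_cfg):
        n1 = count_parameters(MultiScaleAttentionTCN(tiny_cfg, seed=0))
        n2 = count_parameters(MultiScaleAttentionTCN(tiny_cfg, seed=9))
        assert n1 == n2  # independent of initialization
        bigger = ModelConfig(C=3, T=256, Nc=2, F1=16, D=2)
        assert count_parameters(MultiScaleAttentionTCN(bigger, seed=0)) > n1
        # shared-weight windows: the window count adds no parameters to the TCN
        one = ModelConfig(C=3, T=256, Nc=2, F1=8, D=2, n_windows=1)
        three = ModelConfig(C=3, T=256, Nc=2, F1=8, D=2, n_windows=3)
        m1 = MultiScaleAttentionTCN(one, seed=0)
        m3 = MultiScaleAttentionTCN(three, seed=0)
        tcn_params = lambda m: sum(p.data.size for _, p in m.tcn.named_parameters())
        assert tcn_params(m1) == tcn_params(m3)

    def test_checkpoint_round_trip(self, tmp_path, tiny_cfg):
        model = MultiScaleAttentionTCN(tiny_cfg, seed=0)
        x = RNG.standard_normal((2, 3, 256)).astype(np.float32)
        before = model.predict_proba(x)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        np.testing.assert_allclose(back.predict_proba(x), before, atol=1e-7)
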