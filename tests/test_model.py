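"""Architecture contracts: SE gating, attention, encoder, variants, gradients."""

import numpy as np
import pytest

import spectramt as sm
from spectramt.model import EncoderLayer, SEBlock, TASK_PERIOD, TASK_VARIETY
from spectramt.nn import Tensor

TINY = sm.ModelConfig(n_bands_in=9, conv_channels=(4, 6), d_model=8, n_heads=2,
                      n_layers=2, ffn_dim=12, dropout=0.0)


def finite_diff_check(params, loss_fn, rng, n_probe=3, h=1e-5, tol=1e-3):
    """Central finite differences against the recorded analytic gradients."""
    loss = loss_fn()
    for p in params:
        p.grad = None
    loss.backward()
    for p in params:
        flat, g = p.data.ravel(), p.grad.ravel()
        for i in rng.choice(flat.size, size=min(n_probe, flat.size), replace=False):
            old = flat[i]
            flat[i] = old + h
            lp = float(loss_fn().data)
            flat[i] = old - h
            lm = float(loss_fn().data)
            flat[i] = old
            num = (lp - lm) / (2 * h)
            ana = g[i]
            assert abs(num - ana) <= tol * max(abs(num), abs(ana), 1e-4), (
                f"grad mismatch: numeric {num}, analytic {ana}")


class TestSEBlock:
    def test_zero_parameters_halve_input(self):
        # all-zero excitation parameters -> every gate sigmoid(0) = 0.5
        rng = np.random.default_rng(0)
        se = SEBlock(rng, channels=6, reduction=2)
        for p in se.params():
            p.data[:] = 0.0
        U = rng.normal(size=(3, 5, 6))
        out = sm.se_block(U, se)
        np.testing.assert_allclose(out.data, U / 2.0)

    def test_initial_gates_open(self):
        # freshly built gate starts near identity (output bias +2)
        rng = np.random.default_rng(4)
        se = SEBlock(rng, channels=8, reduction=4)
        U = rng.normal(size=(2, 5, 8))
        ratio = sm.se_block(U, se).data / U
        assert 0.6 < np.nanmedian(ratio) < 1.0

    def test_zero_input_stays_zero(self):
        rng = np.random.default_rng(1)
        se = SEBlock(rng, channels=4, reduction=4)
        out = sm.se_block(np.zeros((2, 7, 4)), se)
        np.testing.assert_allclose(out.data, 0.0)

    def test_gates_bounded(self):
        rng = np.random.default_rng(2)
        se = SEBlock(rng, channels=8, reduction=4)
        U = Tensor(rng.normal(size=(2, 5, 8)))
        pooled = U.mean(axis=1)
        gates = (pooled.affine(se.W1, se.b1).relu()
                 .affine(se.W2, se.b2)).sigmoid().data
        assert np.all((gates > 0) & (gates < 1))

    def test_gradient_by_finite_differences(self):
        rng = np.random.default_rng(3)
        se = SEBlock(rng, channels=6, reduction=2)
        U = rng.normal(size=(2, 4, 6))
        tgt = rng.normal(size=(2, 4, 6))

        def loss_fn():
            d = sm.se_block(U, se) - Tensor(tgt)
            return (d * d).sum()
        finite_diff_check(se.params(), loss_fn, rng, tol=1e-4)


class TestPositionalEncoding:
    def test_position_zero(self):
        pe = sm.positional_encoding(5, 8)
        np.testing.assert_allclose(pe[0, 0::2], 0.0)
        np.testing.assert_allclose(pe[0, 1::2], 1.0)

    @pytest.mark.parametrize("d_model", [4, 16, 64])
    def test_first_position_first_channel(self, d_model):
        pe = sm.positional_encoding(3, d_model)
        assert pe[1, 0] == pytest.approx(np.sin(1.0))

    def test_bounded(self):
        pe = sm.positional_encoding(50, 32)
        assert np.all(np.abs(pe) <= 1.0)

    def test_odd_width_rejected(self):
        with pytest.raises(ValueError, match="even"):
            sm.positional_encoding(4, 7)


class TestAttention:
    def test_singleton_softmax(self):
        ctx = sm.attention(np.ones((1, 3)), np.ones((1, 3)), np.array([[2.0, 5.0]]))
        np.testing.assert_allclose(ctx.data, [[2.0, 5.0]])

    def test_zero_query_averages_values(self):
        rng = np.random.default_rng(0)
        K = rng.normal(size=(4, 3))
        V = rng.normal(size=(4, 2))
        ctx = sm.attention(np.zeros((1, 3)), K, V)
        np.testing.assert_allclose(ctx.data[0], V.mean(axis=0), atol=1e-12)

    def test_hand_computed_two_tokens(self):
        Q = np.array([[1.0], [0.0]])
        K = np.array([[1.0], [0.0]])
        V = np.array([[1.0], [0.0]])
        ctx, w = sm.attention(Q, K, V, return_weights=True)
        e = np.exp(1.0)
        np.testing.assert_allclose(w.data[0], [e / (e + 1), 1 / (e + 1)])
        np.testing.assert_allclose(ctx.data[0, 0], e / (e + 1))

    def test_rows_normalised(self):
        rng = np.random.default_rng(1)
        Q = rng.normal(size=(2, 3, 6, 4))
        _, w = sm.attention(Q, rng.normal(size=(2, 3, 6, 4)),
                            rng.normal(size=(2, 3, 6, 4)), return_weights=True)
        np.testing.assert_allclose(w.data.sum(axis=-1), 1.0, atol=1e-6)


class TestMultiHead:
    def test_output_shape(self):
        rng = np.random.default_rng(0)
        mha = sm.MultiHeadAttention(rng, d_model=8, n_heads=2)
        X = rng.normal(size=(3, 5, 8))
        assert sm.multi_head(X, mha).shape == (3, 5, 8)

    def test_single_head_equals_plain_attention(self):
        rng = np.random.default_rng(1)
        mha = sm.MultiHeadAttention(rng, d_model=6, n_heads=1)
        mha.wo.W.data = np.eye(6)
        mha.wo.b.data[:] = 0.0
        X = rng.normal(size=(2, 4, 6))
        out = sm.multi_head(X, mha)
        q = Tensor(X).affine(mha.wq.W, mha.wq.b)
        k = Tensor(X).affine(mha.wk.W, mha.wk.b)
        v = Tensor(X).affine(mha.wv.W, mha.wv.b)
        ref = sm.attention(q, k, v)
        np.testing.assert_allclose(out.data, ref.data, atol=1e-12)

    def test_head_permutation_identity(self):
        # swapping head order together with the matching W_O rows is a no-op
        rng = np.random.default_rng(2)
        mha = sm.MultiHeadAttention(rng, d_model=8, n_heads=2)
        X = rng.normal(size=(2, 5, 8))
        base = sm.multi_head(X, mha).data
        d_k = 4
        perm = np.r_[d_k:2 * d_k, 0:d_k]
        for lin in (mha.wq, mha.wk, mha.wv):
            lin.W.data = lin.W.data[:, perm]
            lin.b.data = lin.b.data[perm]
        mha.wo.W.data = mha.wo.W.data[perm, :]
        np.testing.assert_allclose(sm.multi_head(X, mha).data, base, atol=1e-12)


class TestEncoderLayer:
    def test_eval_mode_deterministic_and_shape_preserving(self):
        rng = np.random.default_rng(0)
        layer = EncoderLayer(rng, TINY)
        X = Tensor(rng.normal(size=(2, 9, 8)))
        a = layer(X).data
        b = layer(X).data
        np.testing.assert_array_equal(a, b)
        assert a.shape == (2, 9, 8)

    def test_layernorm_statistics(self):
        rng = np.random.default_rng(1)
        layer = EncoderLayer(rng, TINY)
        out = layer(Tensor(rng.normal(size=(2, 9, 8)))).data
        # output affine params are identity at init, so token stats are normalised
        np.testing.assert_allclose(out.mean(axis=-1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.var(axis=-1), 1.0, atol=1e-3)

    def test_four_layer_stack_preserves_shape(self):
        cfg = sm.ModelConfig(n_bands_in=9, d_model=8, n_heads=2, n_layers=4,
                             ffn_dim=12, dropout=0.0)
        rng = np.random.default_rng(2)
        layers = [EncoderLayer(rng, cfg) for _ in range(cfg.n_layers)]
        assert len(layers) == 4
        x = Tensor(rng.normal(size=(3, 9, 8)))
        for layer in layers:
            x = layer(x)
        assert x.shape == (3, 9, 8)

    def test_gradient_by_finite_differences(self):
        rng = np.random.default_rng(3)
        layer = EncoderLayer(rng, TINY)
        X = rng.normal(size=(2, 5, 8))
        tgt = rng.normal(size=(2, 5, 8))

        def loss_fn():
            d = layer(Tensor(X)) - Tensor(tgt)
            return (d * d).sum()
        finite_diff_check(layer.params(), loss_fn, rng, n_probe=2)


class TestBuildAndForward:
    def test_pure_transformer_has_no_conv_or_se(self):
        net = sm.build(TINY, sm.Variant.MT_TRANSFORMER)
        assert net.convs == [] and net.se is None
        assert len(net.encoder) == TINY.n_layers

    def test_cnn_only_variant_has_no_encoder(self):
        net = sm.build(TINY, sm.Variant.ST_CNN_TASK1)
        assert net.encoder == [] and net.pe is None
        assert len(net.convs) == len(TINY.conv_channels)

    def test_mt_adds_exactly_one_head(self):
        mt = sm.build(TINY, sm.Variant.MT_CTSE, seed=0)
        st = sm.build(TINY, sm.Variant.ST_CTSE_TASK1, seed=0)
        backbone_mt = sum(p.data.size for p in mt.backbone_params())
        backbone_st = sum(p.data.size for p in st.backbone_params())
        assert backbone_mt == backbone_st
        head = TINY.d_model * 3 + 3
        assert mt.n_parameters() - st.n_parameters() == head

    def test_ablations_differ_only_by_named_blocks(self):
        counts = {v: sm.build(TINY, v, seed=0).n_parameters()
                  for v in (sm.Variant.MT_CTSE, sm.Variant.MT_CNN_TRANSFORMER,
                            sm.Variant.MT_TRANSFORMER_SE, sm.Variant.MT_TRANSFORMER)}
        se_params = sum(p.data.size
                        for p in sm.build(TINY, sm.Variant.MT_CTSE).se.params())
        conv_params = sum(p.data.size for blk in
                          sm.build(TINY, sm.Variant.MT_CTSE).convs for p in blk.params())
        # removing SE removes exactly the SE parameters, ditto for the CNN,
        # modulo the lift layer whose input width changes without the CNN
        assert counts[sm.Variant.MT_CTSE] - counts[sm.Variant.MT_CNN_TRANSFORMER] \
            == se_params
        assert counts[sm.Variant.MT_TRANSFORMER_SE] - counts[sm.Variant.MT_TRANSFORMER] \
            == se_params
        lift_delta = (TINY.conv_channels[-1] - 1) * TINY.d_model
        assert counts[sm.Variant.MT_CTSE] - counts[sm.Variant.MT_TRANSFORMER_SE] \
            == conv_params + lift_delta

    def test_forward_probabilities(self):
        rng = np.random.default_rng(0)
        net = sm.build(TINY, sm.Variant.MT_CTSE, seed=1)
        probs = sm.forward(net, rng.normal(size=(5, 9)))
        assert set(probs) == {TASK_VARIETY, TASK_PERIOD}
        for p in probs.values():
            assert p.shape == (5, 3)
            assert np.all(p >= 0)
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_eval_determinism(self):
        rng = np.random.default_rng(1)
        net = sm.build(TINY, sm.Variant.MT_CTSE, seed=2)
        X = rng.normal(size=(3, 9))
        a = sm.forward(net, X)
        b = sm.forward(net, X)
        for t in a:
            np.testing.assert_array_equal(a[t], b[t])

    def test_wrong_input_length_rejected(self):
        net = sm.build(TINY, sm.Variant.MT_CTSE)
        with pytest.raises(ValueError, match="expected"):
            net.predict_proba(np.zeros((2, 11)))

    def test_full_network_gradient(self):
        from spectramt.train import _graph_ce

        rng = np.random.default_rng(4)
        net = sm.build(TINY, sm.Variant.MT_CTSE, seed=5)
        X = rng.normal(size=(4, 9))
        y1 = rng.integers(0, 3, 4)
        y2 = rng.integers(0, 3, 4)

        def loss_fn():
            lg = net.logits(X)
            return (_graph_ce(lg[TASK_VARIETY], y1) * 0.5
                    + _graph_ce(lg[TASK_PERIOD], y2) * 0.5)
        finite_diff_check(net.parameters(), loss_fn, rng, n_probe=2)

    def test_checkpoint_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        net = sm.build(TINY, sm.Variant.MT_CNN_TRANSFORMER, seed=7)
        X = rng.normal(size=(2, 9))
        net.save(tmp_path / "ckpt.npz")
        back = sm.Network.load(tmp_path / "ckpt.npz")
        assert back.variant == net.variant
        a, b = sm.forward(net, X), sm.forward(back, X)
        for t in a:
            np.testing.assert_array_equal(a[t], b[t])
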