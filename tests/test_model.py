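"""The quad-stream network: attention oracle, blocks, cross-exchange, heads."""

import numpy as np
import pytest

import quadnet as q
from quadnet.nn.autograd import Tensor
from quadnet.nn.layers import MultiHeadAttention
from quadnet.nn.model import AttentionBlock
from quadnet.objective import total_loss


def naive_attention_oracle(mha: MultiHeadAttention, x: np.ndarray) -> np.ndarray:
    """Per-head, per-token double loop: the independent reference."""
    B, T, D = x.shape
    H, dk = mha.num_heads, mha.d_k
    proj = lambda lin, z: z @ lin.W.data + lin.b.data
    out = np.zeros((B, T, D))
    for n in range(B):
        qp, kp, vp = (proj(l, x[n]) for l in (mha.wq, mha.wk, mha.wv))
        heads = []
        for h in range(H):
            sl = slice(h * dk, (h + 1) * dk)
            qh, kh, vh = qp[:, sl], kp[:, sl], vp[:, sl]
            mixed = np.zeros((T, dk))
            for t in range(T):
                scores = np.array([qh[t] @ kh[s] / np.sqrt(dk) for s in range(T)])
                w = np.exp(scores - scores.max())
                w /= w.sum()
                mixed[t] = sum(w[s] * vh[s] for s in range(T))
            heads.append(mixed)
        out[n] = np.concatenate(heads, axis=1) @ mha.wo.W.data + mha.wo.b.data
    return out


class TestMultiHeadAttention:
    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(0)
        mha = MultiHeadAttention(token_dim=4, num_heads=2, rng=rng)  # d_k = 2
        x = rng.normal(size=(2, 3, 4))
        t = Tensor(x)
        out = mha(t, t, t).data
        np.testing.assert_allclose(out, naive_attention_oracle(mha, x), atol=1e-6)

    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        mha = MultiHeadAttention(token_dim=8, num_heads=4, rng=rng)
        t = Tensor(rng.normal(size=(3, 5, 8)))
        mha(t, t, t)
        np.testing.assert_allclose(mha.last_weights.sum(axis=-1), 1.0, atol=1e-12)

    def test_sequence_length_one_closed_form(self):
        rng = np.random.default_rng(2)
        mha = MultiHeadAttention(token_dim=6, num_heads=3, rng=rng)
        x = rng.normal(size=(4, 1, 6))
        out = mha(Tensor(x), Tensor(x), Tensor(x)).data
        # softmax over one key is 1, so attention reduces to Wo(Wv x)
        v = x @ mha.wv.W.data + mha.wv.b.data
        expected = v @ mha.wo.W.data + mha.wo.b.data
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_dimension_mismatch_raises(self):
        rng = np.random.default_rng(3)
        mha = MultiHeadAttention(token_dim=4, num_heads=2, rng=rng)
        a, b = Tensor(rng.normal(size=(1, 2, 4))), Tensor(rng.normal(size=(1, 2, 6)))
        with pytest.raises(ValueError):
            mha(a, b, b)


class TestAttentionBlock:
    def test_output_shape(self, tiny_model_cfg):
        rng = np.random.default_rng(0)
        block = AttentionBlock(8, tiny_model_cfg, rng)
        out = block(Tensor(rng.normal(size=(5, 8))))
        assert out.shape == (5, tiny_model_cfg.hidden_dim)

    def test_alpha_zero_makes_attention_inert(self, tiny_model_cfg):
        rng = np.random.default_rng(1)
        block = AttentionBlock(8, tiny_model_cfg, rng)
        x = Tensor(rng.normal(size=(3, 8)))
        assert float(block.alpha.data) == 0.0  # gated identity at init
        baseline = block(x).data.copy()
        # scrambling the self-attention projections must change nothing
        block.attn.wo.W.data = rng.normal(size=block.attn.wo.W.data.shape)
        np.testing.assert_array_equal(block(x).data, baseline)

    def test_batch_rows_independent(self, tiny_model_cfg):
        rng = np.random.default_rng(2)
        block = AttentionBlock(8, tiny_model_cfg, rng)
        row = rng.normal(size=8)
        batch = np.vstack([row, rng.normal(size=8), row])
        out = block(Tensor(batch)).data
        np.testing.assert_array_equal(out[0], out[2])

    def test_shape_mismatch_raises(self, tiny_model_cfg):
        rng = np.random.default_rng(3)
        block = AttentionBlock(8, tiny_model_cfg, rng)
        with pytest.raises(ValueError, match="expected input"):
            block(Tensor(np.ones((2, 9))))


def _tiny_inputs(cfg, batch=4, seed=0):
    rng = np.random.default_rng(seed)
    x1, x2 = rng.normal(size=(batch, cfg.input_dim)), rng.normal(size=(batch, cfg.input_dim))
    return x1, x2, x1 * x2, np.abs(x1 - x2)


class TestCrossExchange:
    def test_zeroed_output_projection_is_identity(self, tiny_model_cfg):
        model = q.QuadNet(tiny_model_cfg).eval_mode()
        for mha in (model.cross_12, model.cross_21, model.cross_id, model.cross_di):
            mha.wo.W.data[:] = 0.0
            mha.wo.b.data[:] = 0.0
        rng = np.random.default_rng(1)
        hs = [Tensor(rng.normal(size=(3, tiny_model_cfg.hidden_dim))) for _ in range(4)]
        outs = model.cross_exchange(*hs)
        for h_in, h_out in zip(hs, outs):
            np.testing.assert_array_equal(h_out.data, h_in.data)

    def test_swap_symmetry_with_tied_weights(self, tiny_model_cfg):
        """Swapping the pair swaps the protein stream states and leaves the
        product/difference stream states unchanged (with shared weights)."""
        model = q.QuadNet(tiny_model_cfg).eval_mode()
        # tie protein streams and the two cross directions
        model.block_p2.load_state_dict(model.block_p1.state_dict())
        model.cross_21.load_state_dict(model.cross_12.state_dict())
        x1, x2, xi, xd = _tiny_inputs(tiny_model_cfg)

        def stream_states(a, b):
            h1 = model.block_p1(Tensor(a))
            h2 = model.block_p2(Tensor(b))
            hi = model.block_int(Tensor(xi))
            hd = model.block_diff(Tensor(xd))
            return [t.data for t in model.cross_exchange(h1, h2, hi, hd)]

        fwd = stream_states(x1, x2)
        swp = stream_states(x2, x1)
        np.testing.assert_allclose(fwd[0], swp[1], atol=1e-10)
        np.testing.assert_allclose(fwd[1], swp[0], atol=1e-10)
        np.testing.assert_allclose(fwd[2], swp[2], atol=1e-10)
        np.testing.assert_allclose(fwd[3], swp[3], atol=1e-10)

    def test_shapes_preserved(self, tiny_model_cfg):
        model = q.QuadNet(tiny_model_cfg).eval_mode()
        rng = np.random.default_rng(2)
        hs = [Tensor(rng.normal(size=(6, tiny_model_cfg.hidden_dim))) for _ in range(4)]
        for out in model.cross_exchange(*hs):
            assert out.shape == (6, tiny_model_cfg.hidden_dim)


class TestFusionAndHeads:
    def test_fused_length(self, tiny_model_cfg):
        model = q.QuadNet(tiny_model_cfg).eval_mode()
        rng = np.random.default_rng(0)
        hs = [Tensor(rng.normal(size=(2, 16))) for _ in range(4)]
        assert model.fuse(*hs).shape == (2, 16)

    def test_zero_streams_give_constant_rows(self, tiny_model_cfg):
        model = q.QuadNet(tiny_model_cfg).eval_mode()
        hs = [Tensor(np.zeros((3, 16))) for _ in range(4)]
        fused = model.fuse(*hs).data
        np.testing.assert_array_equal(fused[0], fused[1])
        np.testing.assert_array_equal(fused[0], fused[2])

    def test_stream_order_matters(self, tiny_model_cfg):
        model = q.QuadNet(tiny_model_cfg).eval_mode()
        rng = np.random.default_rng(1)
        a, b = Tensor(rng.normal(size=(2, 16))), Tensor(rng.normal(size=(2, 16)))
        c, d = Tensor(rng.normal(size=(2, 16))), Tensor(rng.normal(size=(2, 16)))
        assert not np.allclose(model.fuse(a, b, c, d).data, model.fuse(b, a, c, d).data)

    def test_head_ranges_on_random_inputs(self, tiny_model_cfg):
        model = q.QuadNet(tiny_model_cfg).eval_mode()
        out = model(*_tiny_inputs(tiny_model_cfg, batch=32))
        assert ((out.p.data > 0) & (out.p.data < 1)).all()
        assert ((out.u.data >= 0) & (out.u.data <= tiny_model_cfg.u_max)).all()
        assert ((out.s.data > 0) & (out.s.data < 1)).all()
        np.testing.assert_allclose(out.t.data.sum(axis=1), 1.0, atol=1e-6)

    def test_zeroed_heads_analytic_values(self, tiny_model_cfg):
        model = q.QuadNet(tiny_model_cfg).eval_mode()
        for head in (model.head_interact, model.head_uncertainty,
                     model.head_binding, model.head_type):
            head.W.data[:] = 0.0
            head.b.data[:] = 0.0
        out = model(*_tiny_inputs(tiny_model_cfg))
        np.testing.assert_allclose(out.p.data, 0.5)
        np.testing.assert_allclose(out.s.data, 0.5)
        np.testing.assert_allclose(out.u.data, np.log(2), atol=1e-12)
        np.testing.assert_allclose(out.t.data, 1.0 / tiny_model_cfg.n_types)


class TestForward:
    def test_eval_forward_deterministic(self):
        cfg = q.ModelConfig(input_dim=8, hidden_dim=16, num_heads=2, n_tokens=4,
                            dropout=0.3, seed=5)
        model = q.QuadNet(cfg).eval_mode()
        inputs = _tiny_inputs(cfg)
        a, b = model(*inputs), model(*inputs)
        np.testing.assert_array_equal(a.p.data, b.p.data)

    def test_train_forward_uses_dropout(self):
        cfg = q.ModelConfig(input_dim=8, hidden_dim=16, num_heads=2, n_tokens=4,
                            dropout=0.3, seed=5)
        model = q.QuadNet(cfg).train_mode()
        inputs = _tiny_inputs(cfg)
        assert not np.array_equal(model(*inputs).p.data, model(*inputs).p.data)

    def test_singleton_batch_matches_row(self, tiny_model_cfg):
        model = q.QuadNet(tiny_model_cfg).eval_mode()
        x1, x2, xi, xd = _tiny_inputs(tiny_model_cfg, batch=5)
        full = model(x1, x2, xi, xd)
        one = model(x1[2:3], x2[2:3], xi[2:3], xd[2:3])
        np.testing.assert_allclose(one.p.data[0], full.p.data[2], atol=1e-12)

    def test_gradient_reaches_every_parameter_group(self, tiny_model_cfg):
        model = q.QuadNet(tiny_model_cfg).eval_mode()
        # open the self-attention gates so that branch carries gradient too
        for block in (model.block_p1, model.block_p2, model.block_int, model.block_diff):
            block.alpha.data = np.asarray(0.5)
        out = model(*_tiny_inputs(tiny_model_cfg, batch=8))
        loss, _ = total_loss(out.p, out.u, out.s, out.t, np.array([0, 1] * 4))
        loss.backward()
        for name, p in model.named_parameters():
            assert p.grad is not None and np.abs(p.grad).sum() > 0, name

    def test_flat_vector_mode(self):
        cfg = q.ModelConfig(input_dim=8, hidden_dim=16, num_heads=2, n_tokens=1,
                            dropout=0.0, seed=9)
        model = q.QuadNet(cfg).eval_mode()
        out = model(*_tiny_inputs(cfg))
        assert out.p.shape == (4,)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="divisible"):
            q.ModelConfig(input_dim=8, hidden_dim=30, n_tokens=8)
        with pytest.raises(ValueError):
            q.ModelConfig(input_dim=8, hidden_dim=16, n_tokens=4, num_heads=8)


def test_checkpoint_roundtrip(tmp_path, tiny_model_cfg):
    model = q.QuadNet(tiny_model_cfg).eval_mode()
    path = tmp_path / "ckpt.npz"
    q.save_checkpoint(model, path)
    back = q.load_checkpoint(path)
    inputs = _tiny_inputs(tiny_model_cfg)
    np.testing.assert_array_equal(model(*inputs).p.data, back(*inputs).p.data)
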