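import numpy as np
import pytest

from cgcnn import autodiff as ad
from cgcnn.model import (CGCNN, ModelConfig, attn_graph_conv, global_aggregate,
                         l2_normalize_rows, pairwise_attention,
                         temporal_spectral_conv)
from cgcnn.montage import build_graph, build_spectral_operators
from cgcnn.synthetic import grid_montage

from conftest import random_montage


@pytest.fixture
def tiny_ops():
    return build_spectral_operators(build_graph(grid_montage(2, 3)), K=3)


@pytest.fixture
def tiny_model(tiny_ops):
    cfg = ModelConfig(n_nodes=6, n_classes=2, T=12, F=12, c1=4, c2=4, seed=1)
    return CGCNN(cfg, tiny_ops)


def attention_params(rng, N, L, C, zero_bias=False):
    return {
        "W1": rng.standard_normal(C),
        "W2": rng.standard_normal(C),
        "b1": np.zeros((N, L)) if zero_bias else rng.standard_normal((N, L)),
        "b2": np.zeros((L, N)) if zero_bias else rng.standard_normal((L, N)),
    }


class TestPairwiseAttention:
    def test_spatial_shape(self, rng):
        x = rng.standard_normal((5, 7, 3))
        a = pairwise_attention(x, attention_params(rng, 5, 7, 3), "spatial")
        assert a.shape == (5, 5)

    def test_temporal_shape(self, rng):
        x = rng.standard_normal((5, 7, 3))
        a = pairwise_attention(x, attention_params(rng, 5, 7, 3), "temporal")
        assert a.shape == (7, 7)

    def test_zero_input_zero_bias_gives_zero(self, rng):
        x = np.zeros((4, 6, 2))
        p = attention_params(rng, 4, 6, 2, zero_bias=True)
        a = pairwise_attention(x, p, "spatial")
        np.testing.assert_array_equal(a, 0.0)

    def test_scalar_case_hand_oracle(self):
        # N=2, L=1, C=1, unit weights, zero biases:
        # a[i, j] = tanh(x_i) * tanh(x_j)
        x = np.array([[[0.7]], [[-1.2]]])
        p = {"W1": np.ones(1), "W2": np.ones(1),
             "b1": np.zeros((2, 1)), "b2": np.zeros((1, 2))}
        a = pairwise_attention(x, p, "spatial")
        t = np.tanh([0.7, -1.2])
        np.testing.assert_allclose(a, np.outer(t, t), atol=1e-12)

    def test_weight_shape_mismatch_rejected(self, rng):
        x = rng.standard_normal((3, 4, 2))
        p = attention_params(rng, 3, 4, 5)
        with pytest.raises(ValueError):
            pairwise_attention(x, p, "spatial")


class TestL2NormalizeRows:
    def test_three_four_five(self):
        np.testing.assert_array_equal(l2_normalize_rows(np.array([[3.0, 4.0]])),
                                      [[0.6, 0.8]])

    def test_identity_unchanged(self):
        np.testing.assert_array_equal(l2_normalize_rows(np.eye(4)), np.eye(4))

    def test_unit_norm_matrix_unchanged(self, rng):
        a = rng.standard_normal((5, 5))
        a /= np.linalg.norm(a, axis=1, keepdims=True)
        np.testing.assert_allclose(l2_normalize_rows(a), a, atol=1e-12)

    def test_zero_row_passthrough(self):
        a = np.array([[0.0, 0.0], [3.0, 4.0]])
        out = l2_normalize_rows(a)
        np.testing.assert_array_equal(out[0], [0.0, 0.0])
        np.testing.assert_allclose(out[1], [0.6, 0.8])

    def test_rows_have_unit_norm(self, rng):
        out = l2_normalize_rows(rng.standard_normal((8, 8)))
        np.testing.assert_allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            l2_normalize_rows(np.array([[np.inf, 1.0]]))


class TestGraphConv:
    def test_all_ones_attention_is_identity_modulation(self, tiny_ops, rng):
        x = rng.standard_normal((6, 10, 2))
        theta = rng.standard_normal((4, 2, 3))
        with_ones = attn_graph_conv(x, tiny_ops, np.ones((6, 6)), theta)
        without = attn_graph_conv(x, tiny_ops, None, theta)
        np.testing.assert_allclose(with_ones, without, atol=1e-12)

    def test_k0_identity_theta_nonneg_input_is_identity(self, montage_2x3, rng):
        ops = build_spectral_operators(build_graph(montage_2x3), K=0)
        x = np.abs(rng.standard_normal((6, 8, 3)))
        theta = np.eye(3)[None]  # K=0, theta_0 = I
        out = attn_graph_conv(x, ops, np.ones((6, 6)), theta)
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_spectral_domain_oracle(self, tiny_ops, rng):
        # pre-activation output == U (sum_k theta_k T_k(Lambda~)) U^T x
        x = rng.standard_normal((6, 5, 1))
        theta = rng.standard_normal((4, 1, 1))
        out = attn_graph_conv(x, tiny_ops, np.ones((6, 6)), theta,
                              activation=False)
        lam, U = np.linalg.eigh(tiny_ops.laplacian_scaled)
        lam = np.clip(lam, -1.0, 1.0)
        g = sum(theta[k, 0, 0] * np.cos(k * np.arccos(lam)) for k in range(4))
        oracle = U @ np.diag(g) @ U.T @ x[:, :, 0]
        np.testing.assert_allclose(out[:, :, 0], oracle, atol=1e-6)

    def test_k_mismatch_rejected(self, tiny_ops, rng):
        with pytest.raises(ValueError, match="K"):
            attn_graph_conv(rng.standard_normal((6, 5, 1)), tiny_ops,
                            None, rng.standard_normal((3, 1, 1)))

    def test_output_shape(self, tiny_ops, rng):
        out = attn_graph_conv(rng.standard_normal((6, 10, 1)), tiny_ops,
                              np.ones((6, 6)), rng.standard_normal((4, 1, 8)))
        assert out.shape == (6, 10, 8)


class TestTemporalConv:
    def test_valid_padding_output_length(self, rng):
        x1 = rng.standard_normal((9, 100, 4))
        W = rng.standard_normal((5, 4, 64))
        out = temporal_spectral_conv(x1, np.eye(100), W, np.zeros(64))
        assert out.shape == (9, 96, 64)  # (100 - 5)/1 + 1

    def test_identity_attention_equals_plain_conv(self, rng):
        x1 = rng.standard_normal((3, 20, 2))
        W = rng.standard_normal((5, 2, 6))
        b = rng.standard_normal(6)
        with_id = temporal_spectral_conv(x1, np.eye(20), W, b)
        plain = temporal_spectral_conv(x1, None, W, b)
        np.testing.assert_allclose(with_id, plain, atol=1e-12)

    def test_matches_scipy_correlate_oracle(self, rng):
        from scipy.signal import correlate
        x1 = rng.standard_normal((2, 15, 3))
        W = rng.standard_normal((5, 3, 4))
        out = temporal_spectral_conv(x1, None, W, np.zeros(4))
        for n in range(2):
            for c2 in range(4):
                acc = sum(correlate(x1[n, :, c], W[:, c, c2], mode="valid")
                          for c in range(3))
                np.testing.assert_allclose(out[n, :, c2], np.maximum(acc, 0),
                                           atol=1e-10)

    def test_too_short_sequence_rejected(self, rng):
        with pytest.raises(ValueError, match="kernel"):
            temporal_spectral_conv(rng.standard_normal((2, 3, 1)), None,
                                   rng.standard_normal((5, 1, 4)), np.zeros(4))


class TestGlobalAggregate:
    def test_output_shapes(self, rng):
        x2 = rng.standard_normal((7, 30, 8))
        W3 = rng.standard_normal((7 * 8, 8))
        W4 = rng.standard_normal((30 * 8, 8))
        x3, x4 = global_aggregate(x2, W3, np.zeros(8), W4, np.zeros(8))
        assert x3.shape == (1, 30, 8)
        assert x4.shape == (1, 1, 8)

    def test_zero_input_zero_bias_gives_zero(self):
        x3, x4 = global_aggregate(np.zeros((4, 10, 3)),
                                  np.zeros((12, 3)), np.zeros(3),
                                  np.zeros((30, 3)), np.zeros(3))
        np.testing.assert_array_equal(x3, 0.0)
        np.testing.assert_array_equal(x4, 0.0)

    def test_constant_field_unit_sum_weights(self):
        # closed form: conv of a constant with unit-sum weights returns c
        N, L, C = 4, 6, 3
        c = 1.7
        W3 = np.full((N * C, C), 1.0 / (N * C))
        x3, _ = global_aggregate(np.full((N, L, C), c), W3, np.zeros(C),
                                 np.full((L * C, C), 1.0 / (L * C)), np.zeros(C))
        np.testing.assert_allclose(x3, c, atol=1e-12)


class TestForward:
    def test_probabilities_sum_to_one(self, tiny_model, rng):
        probs = tiny_model.predict_proba(rng.standard_normal((5, 6, 12, 1)),
                                         rng.standard_normal((5, 6, 12, 1)))
        assert probs.shape == (5, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_four_class_output(self, tiny_ops, rng):
        cfg = ModelConfig(n_nodes=6, n_classes=4, T=12, F=12, c1=4, c2=4)
        model = CGCNN(cfg, tiny_ops)
        probs = model.predict_proba(rng.standard_normal((2, 6, 12, 1)),
                                    rng.standard_normal((2, 6, 12, 1)))
        assert probs.shape == (2, 4)

    def test_head_permutation_identity(self, tiny_model, rng):
        x_st = rng.standard_normal((3, 6, 12, 1))
        x_ss = rng.standard_normal((3, 6, 12, 1))
        base = tiny_model.predict_proba(x_st, x_ss)
        perm = np.array([1, 0])
        tiny_model.params["fc.W"] = tiny_model.params["fc.W"][:, perm]
        tiny_model.params["fc.b"] = tiny_model.params["fc.b"][perm]
        permuted = tiny_model.predict_proba(x_st, x_ss)
        np.testing.assert_allclose(permuted, base[:, perm], atol=1e-10)

    def test_deterministic(self, tiny_model, rng):
        x_st = rng.standard_normal((2, 6, 12, 1))
        x_ss = rng.standard_normal((2, 6, 12, 1))
        np.testing.assert_array_equal(tiny_model.predict_proba(x_st, x_ss),
                                      tiny_model.predict_proba(x_st, x_ss))

    def test_single_branch_variants(self, tiny_ops, rng):
        x = rng.standard_normal((2, 6, 12, 1))
        for variant, kwargs in (("st", dict(use_ss_branch=False)),
                                ("ss", dict(use_st_branch=False))):
            cfg = ModelConfig(n_nodes=6, n_classes=2, T=12, F=12, c1=4, c2=4,
                              **kwargs)
            model = CGCNN(cfg, tiny_ops)
            probs = model.predict_proba(x_st=x if variant == "st" else None,
                                        x_ss=x if variant == "ss" else None)
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_disabled_branch_input_warns(self, tiny_ops, rng):
        cfg = ModelConfig(n_nodes=6, n_classes=2, T=12, F=12, c1=4, c2=4,
                          use_ss_branch=False)
        model = CGCNN(cfg, tiny_ops)
        x = rng.standard_normal((1, 6, 12, 1))
        with pytest.warns(UserWarning, match="disabled"):
            model.predict_proba(x_st=x, x_ss=x)

    def test_missing_branch_input_rejected(self, tiny_model, rng):
        with pytest.raises(ValueError, match="missing"):
            tiny_model.predict_proba(x_st=rng.standard_normal((1, 6, 12, 1)))

    def test_both_branches_disabled_rejected(self):
        with pytest.raises(ValueError, match="branch"):
            ModelConfig(n_nodes=6, n_classes=2, use_st_branch=False,
                        use_ss_branch=False)

    def test_internal_attention_rows_unit_norm(self, tiny_model, rng):
        # hook into the tape: recompute the attention matrices the forward
        # pass produces and check the row-norm invariant
        from cgcnn.model import _normalize_attention_t, _pairwise_attention_t
        from cgcnn.autodiff import Tensor
        x = rng.standard_normal((3, 6, 12, 1))
        p = {k: Tensor(v) for k, v in tiny_model.params.items()}
        a = _pairwise_attention_t(Tensor(x), p["st.att_s.W1"], p["st.att_s.b1"],
                                  p["st.att_s.W2"], p["st.att_s.b2"], "spatial")
        a = _normalize_attention_t(a, "row")
        norms = np.linalg.norm(a.data, axis=-1)
        mask = norms > 0
        np.testing.assert_allclose(norms[mask], 1.0, atol=1e-6)

    def test_node_permutation_consistency(self, rng):
        # permuting electrodes everywhere leaves class probabilities unchanged
        mont = grid_montage(2, 3)
        ops = build_spectral_operators(build_graph(mont), K=2)
        cfg = ModelConfig(n_nodes=6, n_classes=3, T=10, F=10, c1=3, c2=3,
                          cheb_order=2, seed=7)
        model = CGCNN(cfg, ops)
        x_st = rng.standard_normal((2, 6, 10, 1))
        x_ss = rng.standard_normal((2, 6, 10, 1))
        base = model.predict_proba(x_st, x_ss)

        perm = rng.permutation(6)
        P = np.eye(6)[perm]
        names = [mont.names[i] for i in perm]
        from cgcnn.montage import Montage
        mont_p = Montage.from_table(names, [mont.rows[i] for i in perm],
                                    [mont.cols[i] for i in perm])
        ops_p = build_spectral_operators(build_graph(mont_p), K=2)
        model_p = CGCNN(cfg, ops_p)
        params_p = {k: v.copy() for k, v in model.params.items()}
        for key in params_p:
            if key.endswith(("att_s.b1", "att_t.b1")):
                params_p[key] = params_p[key][perm]
            elif key.endswith(("att_s.b2", "att_t.b2")):
                params_p[key] = params_p[key][:, perm]
            elif key.endswith("agg.W3"):
                C2 = cfg.c2
                blocks = params_p[key].reshape(6, C2, C2)
                params_p[key] = blocks[perm].reshape(6 * C2, C2)
        model_p.params = params_p
        out = model_p.predict_proba(x_st[:, perm], x_ss[:, perm])
        np.testing.assert_allclose(out, base, atol=1e-8)


class TestGradients:
    def test_full_model_finite_difference(self, tiny_model, rng):
        x_st = rng.standard_normal((3, 6, 12, 1))
        x_ss = rng.standard_normal((3, 6, 12, 1))
        y = np.array([0, 1, 0])
        logits = tiny_model.forward_logits(x_st, x_ss)
        loss = ad.softmax_cross_entropy(logits, y)
        loss.backward()
        grads = {k: t.grad.copy() for k, t in tiny_model._tensors.items()}

        def loss_at(params):
            lg = tiny_model.forward_logits(x_st, x_ss, params=params)
            return float(ad.softmax_cross_entropy(lg, y).data)

        eps = 1e-5
        rng_ix = np.random.default_rng(0)
        for name, p in tiny_model.params.items():
            # spot-check a handful of coordinates per parameter
            flat = p.reshape(-1)
            for j in rng_ix.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[j]
                flat[j] = orig + eps
                lp = loss_at(tiny_model.params)
                flat[j] = orig - eps
                lm = loss_at(tiny_model.params)
                flat[j] = orig
                fd = (lp - lm) / (2 * eps)
                g = grads[name].reshape(-1)[j]
                assert abs(fd - g) <= 1e-4 * max(1.0, abs(fd), abs(g)), \
                    f"{name}[{j}]: fd={fd} ad={g}"


class TestConfig:
    def test_variant_construction(self):
        cfg = ModelConfig.for_variant("dual_branch", n_nodes=9, n_classes=2)
        assert not cfg.use_attention and not cfg.use_global_aggregation
        assert cfg.use_st_branch and cfg.use_ss_branch

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            ModelConfig.for_variant("nope", n_nodes=3, n_classes=2)

    def test_roundtrip_dict(self):
        cfg = ModelConfig(n_nodes=9, n_classes=4, c1=16)
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg

    def test_seed_reproducible_init(self, tiny_ops):
        cfg = ModelConfig(n_nodes=6, n_classes=2, T=12, F=12, seed=5)
        a, b = CGCNN(cfg, tiny_ops), CGCNN(cfg, tiny_ops)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])
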