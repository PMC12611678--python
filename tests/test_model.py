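import math

import numpy as np
import pytest
from oracles import attention_oracle, ecc_oracle

from eeggnn.autodiff import Tensor
from eeggnn.errors import MontageError, ValidationError
from eeggnn.graphs import ChannelGraph, GraphConfig, build_graphs
from eeggnn.model import (
    REGION_NAMES, CrossModalGraphClassifier, ModelConfig, RegionFeatures,
    RegionMap, _masked_mean_messages, classify, cross_modal_attention,
    edge_conditioned_conv, forward, gated_fusion, init_bn_state,
    init_parameters, multiscale_encode, project_nodes, region_attention_pool,
)
from eeggnn.preprocess import DEFAULT_CHANNELS, zscore_epochs


def small_cfg(**kw):
    defaults = dict(hidden_width=8, n_heads=2, edge_mlp_hidden=4,
                    classifier_hidden=8, conv_channels=2,
                    kernel_sizes=[10, 5], n_spectral_features=5)
    defaults.update(kw)
    return ModelConfig(**defaults)


def to_float64(model):
    for p in model.params.values():
        p.data = p.data.astype(np.float64)
    for k in model.bn_state:
        model.bn_state[k] = model.bn_state[k].astype(np.float64)
    return model


class TestModelConfig:
    def test_head_divisibility(self):
        with pytest.raises(ValidationError):
            ModelConfig(hidden_width=30, n_heads=4)

    def test_defaults_match_contract(self):
        cfg = ModelConfig()
        assert cfg.kernel_sizes == [100, 50, 25]
        assert cfg.hidden_width == 64
        assert cfg.n_heads == 4
        assert cfg.head_dim == 16
        assert cfg.n_regions == 5
        assert cfg.dropout_rate == 0.5


class TestRegionMap:
    def test_default_covers_montage(self):
        rmap = RegionMap.default()
        indices = rmap.indices(DEFAULT_CHANNELS)
        assert sorted(np.concatenate(list(indices.values())).tolist()) == \
            list(range(16))
        assert set(indices) == set(REGION_NAMES)
        assert len(indices["frontal"]) == 6
        assert len(indices["temporal"]) == 4

    def test_unknown_channel(self):
        with pytest.raises(MontageError):
            RegionMap.default().region_of("XX9")

    def test_empty_region_rejected(self):
        rmap = RegionMap.default()
        with pytest.raises(ValidationError):
            rmap.indices(["FP1", "C3", "P3", "O1"])  # no temporal channel


class TestMultiscaleEncode:
    def test_output_shape(self, rng):
        cfg = small_cfg()
        params = init_parameters(cfg, seed=0)
        out = multiscale_encode(rng.standard_normal((3, 40)), params, cfg)
        assert out.shape == (3, cfg.hidden_width)

    def test_zero_input_zero_output(self):
        cfg = small_cfg()
        params = init_parameters(cfg, seed=0)  # biases start at zero
        out = multiscale_encode(np.zeros((4, 40)), params, cfg,
                                bn_state=init_bn_state(cfg), training=False)
        np.testing.assert_allclose(out, 0.0, atol=1e-7)

    def test_periodic_shift_invariance(self):
        cfg = small_cfg(kernel_sizes=[10, 5])
        params = init_parameters(cfg, seed=0)
        t = np.arange(100)
        x = np.sin(2 * np.pi * t / 10.0)[None, :]  # period 10
        shifted = np.sin(2 * np.pi * (t + 20) / 10.0)[None, :]  # shift = 2 periods
        a = multiscale_encode(x, params, cfg)
        b = multiscale_encode(shifted, params, cfg)
        np.testing.assert_allclose(a, b, atol=1e-5)

    def test_too_short_input(self, rng):
        cfg = small_cfg(kernel_sizes=[50])
        params = init_parameters(cfg, seed=0)
        with pytest.raises(ValidationError):
            multiscale_encode(rng.standard_normal((2, 20)), params, cfg)


class TestProjectNodes:
    def test_identity(self):
        cfg = small_cfg(n_spectral_features=8)
        params = init_parameters(cfg, seed=0)
        params["proj.s.w"].data = np.eye(8, dtype=np.float32)
        x = np.arange(24, dtype=np.float32).reshape(3, 8)
        np.testing.assert_allclose(project_nodes(x, params, "s"), x, atol=1e-6)

    def test_zero_input_bias_broadcast(self, rng):
        cfg = small_cfg()
        params = init_parameters(cfg, seed=0)
        params["proj.s.b"].data = rng.standard_normal(8).astype(np.float32)
        out = project_nodes(np.zeros((3, 5)), params, "s")
        np.testing.assert_allclose(out, np.tile(params["proj.s.b"].data, (3, 1)),
                                   atol=1e-7)

    def test_matches_dense_oracle(self, rng):
        cfg = small_cfg()
        params = init_parameters(cfg, seed=1)
        x = rng.standard_normal((4, 5)).astype(np.float32)
        out = project_nodes(x, params, "s")
        ref = x @ params["proj.s.w"].data + params["proj.s.b"].data
        np.testing.assert_allclose(out, ref, atol=1e-6)

    def test_width_mismatch(self, rng):
        cfg = small_cfg()
        params = init_parameters(cfg, seed=0)
        with pytest.raises(ValidationError):
            project_nodes(rng.standard_normal((4, 7)), params, "s")


class TestEdgeConditionedConv:
    def test_symmetry_identical_inputs(self, rng):
        cfg = small_cfg()
        params = init_parameters(cfg, seed=2)
        nodes = np.tile(rng.standard_normal(8), (4, 1)).astype(np.float32)
        weights = np.full((4, 4), 0.3, dtype=np.float32)
        np.fill_diagonal(weights, 0.0)
        out = edge_conditioned_conv(nodes, weights, params, "t")
        for row in out[1:]:
            np.testing.assert_allclose(row, out[0], atol=1e-6)

    def test_identity_kernel_neighbor_mean(self, rng):
        d = 8
        c = 4
        nodes = Tensor(rng.standard_normal((1, c, d)))
        kernels = Tensor(np.tile(np.eye(d).reshape(1, 1, 1, d, d), (1, c, c, 1, 1)))
        agg = _masked_mean_messages(kernels, nodes).data[0]
        for i in range(c):
            expected = nodes.data[0][[j for j in range(c) if j != i]].mean(axis=0)
            np.testing.assert_allclose(agg[i], expected, atol=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        cfg = small_cfg()
        params = init_parameters(cfg, seed=3)
        nodes = rng.standard_normal((4, 8))
        weights = rng.uniform(-1, 1, (4, 4))
        weights = (weights + weights.T) / 2
        np.fill_diagonal(weights, 0.0)
        out = edge_conditioned_conv(nodes, weights, params, "s")
        ref = ecc_oracle(nodes, weights, params, "s", 8)
        np.testing.assert_allclose(out, ref, atol=1e-5)

    def test_nan_attribute_rejected(self, rng):
        cfg = small_cfg()
        params = init_parameters(cfg, seed=0)
        weights = np.zeros((4, 4))
        weights[0, 1] = np.nan
        with pytest.raises(ValidationError):
            edge_conditioned_conv(rng.standard_normal((4, 8)), weights,
                                  params, "t")


class TestRegionAttentionPool:
    def region_map_for(self, channels):
        return RegionMap.default()

    def test_singleton_region_passthrough(self, rng):
        cfg = small_cfg()
        params = init_parameters(cfg, seed=4)
        # montage with exactly one parietal channel (P3)
        names = ["FP1", "C3", "P3", "O1", "T3"]
        nodes = rng.standard_normal((5, 8))
        rf = region_attention_pool(nodes, RegionMap.default(), params, "t", names)
        np.testing.assert_allclose(
            rf.features[REGION_NAMES.index("parietal")], nodes[2], atol=1e-12)
        np.testing.assert_allclose(rf.attention["parietal"], [1.0], atol=1e-12)

    def test_uniform_scores_uniform_alpha(self, rng):
        cfg = small_cfg()
        params = init_parameters(cfg, seed=5)
        nodes = rng.standard_normal((16, 8))
        # identical embeddings inside the frontal region -> equal scores
        nodes[:6] = nodes[0]
        names = list(DEFAULT_CHANNELS)  # frontal channels are FP1..F8? use map
        rmap = RegionMap.default()
        idx = rmap.indices(names)["frontal"]
        nodes[idx] = nodes[idx[0]]
        rf = region_attention_pool(nodes, rmap, params, "t", names)
        np.testing.assert_allclose(rf.attention["frontal"], 1.0 / len(idx),
                                   atol=1e-7)

    def test_matches_softmax_oracle(self, rng):
        cfg = small_cfg()
        params = init_parameters(cfg, seed=6)
        names = list(DEFAULT_CHANNELS)
        nodes = rng.standard_normal((16, 8))
        rmap = RegionMap.default()
        rf = region_attention_pool(nodes, rmap, params, "t", names)
        indices = rmap.indices(names)
        for r_i, region in enumerate(REGION_NAMES):
            idx = indices[region]
            scores = nodes[idx] @ params[f"pool.t.{region}"].data
            e = np.exp(scores - scores.max())
            alpha = e / e.sum()
            np.testing.assert_allclose(rf.attention[region], alpha, atol=1e-6)
            np.testing.assert_allclose(rf.features[r_i],
                                       alpha @ nodes[idx], atol=1e-6)

    def test_attention_sums_to_one(self, rng):
        cfg = small_cfg()
        params = init_parameters(cfg, seed=7)
        rf = region_attention_pool(rng.standard_normal((16, 8)),
                                   RegionMap.default(), params, "t",
                                   list(DEFAULT_CHANNELS))
        for alpha in rf.attention.values():
            assert np.all(alpha > 0)
            assert abs(alpha.sum() - 1.0) < 1e-6


class TestCrossModalAttention:
    def test_identical_values_give_common_row(self, rng):
        cfg = small_cfg(n_heads=1)
        params = init_parameters(cfg, seed=8)
        for name in ("wq", "wk", "wv", "wo"):
            params[f"att.t.{name}"].data = np.eye(8, dtype=np.float32)
        u_t = rng.standard_normal((5, 8)).astype(np.float32)
        u_s = np.tile(rng.standard_normal(8), (5, 1)).astype(np.float32)
        enh_t, _ = cross_modal_attention(u_t, u_s, params, cfg)
        for row in enh_t:
            np.testing.assert_allclose(row, u_s[0], atol=1e-5)

    def test_matches_per_head_oracle(self, rng):
        cfg = small_cfg(n_heads=2)
        params = init_parameters(cfg, seed=9)
        u_t = rng.standard_normal((5, 8))
        u_s = rng.standard_normal((5, 8))
        enh_t, enh_s = cross_modal_attention(u_t, u_s, params, cfg)
        ref_t = attention_oracle(
            u_t, u_s, params["att.t.wq"].data, params["att.t.wk"].data,
            params["att.t.wv"].data, params["att.t.wo"].data, 2)
        ref_s = attention_oracle(
            u_s, u_t, params["att.s.wq"].data, params["att.s.wk"].data,
            params["att.s.wv"].data, params["att.s.wo"].data, 2)
        np.testing.assert_allclose(enh_t, ref_t, atol=1e-5)
        np.testing.assert_allclose(enh_s, ref_s, atol=1e-5)


class TestGatedFusion:
    def test_gate_zero_limit_returns_raw(self, rng):
        cfg = small_cfg()
        params = init_parameters(cfg, seed=10)
        params["gate.t.w"].data = np.zeros_like(params["gate.t.w"].data)
        params["gate.t.b"].data = np.full(8, -50.0, dtype=np.float32)
        raw = rng.standard_normal((5, 8))
        enh = rng.standard_normal((5, 8))
        np.testing.assert_allclose(gated_fusion(raw, enh, params, "t"), raw,
                                   atol=1e-6)

    def test_gate_one_limit_returns_enhanced(self, rng):
        cfg = small_cfg()
        params = init_parameters(cfg, seed=10)
        params["gate.t.w"].data = np.zeros_like(params["gate.t.w"].data)
        params["gate.t.b"].data = np.full(8, 50.0, dtype=np.float32)
        raw = rng.standard_normal((5, 8))
        enh = rng.standard_normal((5, 8))
        np.testing.assert_allclose(gated_fusion(raw, enh, params, "t"), enh,
                                   atol=1e-6)

    def test_convex_envelope(self, rng):
        cfg = small_cfg()
        params = init_parameters(cfg, seed=11)
        raw = rng.standard_normal((5, 8))
        enh = rng.standard_normal((5, 8))
        out = gated_fusion(raw, enh, params, "s")
        lo = np.minimum(raw, enh) - 1e-7
        hi = np.maximum(raw, enh) + 1e-7
        assert np.all(out >= lo) and np.all(out <= hi)

    def test_shape_mismatch(self, rng):
        cfg = small_cfg()
        params = init_parameters(cfg, seed=0)
        with pytest.raises(ValidationError):
            gated_fusion(rng.standard_normal((5, 8)),
                         rng.standard_normal((4, 8)), params, "t")


class TestClassify:
    def test_zero_weights_half(self, rng):
        cfg = small_cfg()
        params = init_parameters(cfg, seed=12)
        for name in ("clf.w1", "clf.b1", "clf.w2", "clf.b2"):
            params[name].data = np.zeros_like(params[name].data)
        p = classify(rng.standard_normal((5, 8)), rng.standard_normal((5, 8)),
                     params, cfg)
        assert p == 0.5

    def test_open_interval(self, rng):
        cfg = small_cfg()
        params = init_parameters(cfg, seed=13)
        p = classify(rng.standard_normal((5, 8)) * 100,
                     rng.standard_normal((5, 8)) * 100, params, cfg)
        assert 0.0 < p < 1.0

    def test_inference_deterministic(self, rng):
        cfg = small_cfg()
        params = init_parameters(cfg, seed=14)
        ft = rng.standard_normal((5, 8))
        fs_ = rng.standard_normal((5, 8))
        assert classify(ft, fs_, params, cfg) == classify(ft, fs_, params, cfg)

    def test_training_requires_rng(self, rng):
        cfg = small_cfg()
        params = init_parameters(cfg, seed=0)
        with pytest.raises(ValidationError):
            classify(rng.standard_normal((5, 8)), rng.standard_normal((5, 8)),
                     params, cfg, training=True)


class TestForward:
    @pytest.fixture
    def graphs_pair(self, small_graphs):
        esz, temporal, spectral = small_graphs
        return temporal[0], spectral[0]

    def test_probability_range(self, tiny_model, graphs_pair):
        p = forward(graphs_pair[0], graphs_pair[1], tiny_model)
        assert 0.0 < p < 1.0

    def test_channel_mismatch_rejected(self, tiny_model, graphs_pair, rng):
        tg = graphs_pair[0]
        other = ChannelGraph(
            node_features=rng.standard_normal((16, 5)),
            weights=np.zeros((16, 16)), modality="spectral",
            channel_names=[f"X{i}" for i in range(16)],
        )
        with pytest.raises(ValidationError):
            forward(tg, other, tiny_model)

    def test_all_parameter_gradients_finite(self, small_graphs):
        esz, temporal, spectral = small_graphs
        model = CrossModalGraphClassifier(small_cfg(kernel_sizes=[100, 50, 25],
                                                    conv_channels=2), seed=0)
        rng = np.random.default_rng(0)
        logits = model.forward_batch(
            esz.epochs[:2], np.stack([g.weights for g in temporal[:2]]),
            np.stack([g.node_features for g in spectral[:2]]),
            np.stack([g.weights for g in spectral[:2]]),
            training=True, rng=rng,
        )
        logits.sum().backward()
        for name, p in model.params.items():
            assert p.grad is not None, name
            assert np.all(np.isfinite(p.grad)), name

    def test_finite_difference_on_input_channel(self, small_graphs):
        esz, temporal, spectral = small_graphs
        model = to_float64(CrossModalGraphClassifier(
            small_cfg(kernel_sizes=[100, 50], conv_channels=2), seed=1))
        xt = np.asarray(esz.epochs[:1], dtype=np.float64)
        wt = np.asarray(temporal[0].weights[None], dtype=np.float64)
        xs = np.asarray(spectral[0].node_features[None], dtype=np.float64)
        ws = np.asarray(spectral[0].weights[None], dtype=np.float64)
        wt_t, xs_t, ws_t = Tensor(wt), Tensor(xs), Tensor(ws)  # avoid f32 cast
        t = Tensor(xt.copy(), requires_grad=True)
        model.forward_batch(t, wt_t, xs_t, ws_t).sum().backward()
        direction = np.zeros_like(xt)
        direction[0, 3] = 1.0  # perturb one whole input channel
        eps = 1e-6
        f_plus = model.forward_batch(
            Tensor(xt + eps * direction), wt_t, xs_t, ws_t).data.sum()
        f_minus = model.forward_batch(
            Tensor(xt - eps * direction), wt_t, xs_t, ws_t).data.sum()
        fd = (f_plus - f_minus) / (2 * eps)
        ad = (t.grad * direction).sum()
        assert abs(fd - ad) / max(abs(fd), 1e-10) < 1e-3

    def test_permutation_within_region_invariance(self, small_graphs, tiny_model):
        esz, temporal, spectral = small_graphs
        names = esz.channel_names
        idx = tiny_model.region_indices["frontal"]
        perm = np.arange(16)
        perm[idx[0]], perm[idx[1]] = idx[1], idx[0]  # swap two frontal channels

        def features(graph_list, i, permuted):
            g = graph_list[i]
            w = g.weights[np.ix_(perm, perm)] if permuted else g.weights
            f = g.node_features[perm] if permuted else g.node_features
            return f[None].astype(np.float64), w[None].astype(np.float64)

        model = to_float64(CrossModalGraphClassifier(
            small_cfg(kernel_sizes=[50], conv_channels=2), seed=2))
        xt0, wt0 = features(temporal, 0, False)
        xs0, ws0 = features(spectral, 0, False)
        xt1, wt1 = features(temporal, 0, True)
        xs1, ws1 = features(spectral, 0, True)
        p0 = model.forward_batch(xt0, wt0, xs0, ws0).data
        p1 = model.forward_batch(xt1, wt1, xs1, ws1).data
        np.testing.assert_allclose(p0, p1, atol=1e-5)

    def test_checkpoint_round_trip_bitstable(self, small_graphs, tmp_path):
        from eeggnn.io import load_checkpoint, save_checkpoint

        esz, temporal, spectral = small_graphs
        cfg = small_cfg(kernel_sizes=[50], conv_channels=2)
        model = CrossModalGraphClassifier(cfg, seed=5)
        xt = esz.epochs[:3]
        wt = np.stack([g.weights for g in temporal[:3]])
        xs = np.stack([g.node_features for g in spectral[:3]])
        ws = np.stack([g.weights for g in spectral[:3]])
        before = model.predict_proba(xt, wt, xs, ws)
        path = save_checkpoint(tmp_path / "m.ckpt.npz", model.state_dict(),
                               {"model": cfg.to_dict()})
        state, meta = load_checkpoint(path)
        clone = CrossModalGraphClassifier(ModelConfig(**meta["model"]), seed=99)
        clone.load_state_dict(state)
        after = clone.predict_proba(xt, wt, xs, ws)
        np.testing.assert_array_equal(before, after)
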