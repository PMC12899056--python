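"""Network contracts: folding, encoder, spatial LSTM, attention, GRL, heads, loss."""

import numpy as np
import pytest

from neoseiz.model import (
    AttentionPool,
    CICNNEncoder,
    MeanPool,
    ModelConfig,
    SeizureDomainNet,
    SpatialBiLSTM,
    domain_ce_from_logits,
    fold_channels,
    load_checkpoint,
    save_checkpoint,
    unfold_channels,
    weighted_ce_from_logits,
    weighted_ce_loss,
)
from neoseiz.nn import Tensor
from neoseiz.preprocess import NormStats

rng = np.random.default_rng(11)

TINY = dict(base_width=4, lstm_hidden=8, n_domains=3, attention_hidden=8,
            head_hidden=8, dropout_p=0.0)


class TestFolding:
    def test_single_sample_leading_dim(self):
        x = rng.standard_normal((1, 18, 33, 17))
        assert fold_channels(x).shape == (18, 1, 33, 17)

    def test_round_trip_identity(self):
        x = rng.standard_normal((3, 18, 33, 17))
        folded = fold_channels(x)
        enc = folded[:, 0, :, :].reshape(3 * 18, -1)
        restored = unfold_channels(enc, 18)
        np.testing.assert_array_equal(restored.reshape(3, 18, 33, 17),
                                      x.reshape(3, 18, 33, 17))

    def test_index_arithmetic(self):
        # element (n=2, c=5, f, t) lands at folded row 2*18 + 5 = 41
        x = rng.standard_normal((4, 18, 33, 17))
        folded = fold_channels(x)
        np.testing.assert_array_equal(folded[41, 0], x[2, 5])

    def test_wrong_rank_rejected(self):
        with pytest.raises(ValueError):
            fold_channels(rng.standard_normal((18, 33, 17)))


class TestEncoder:
    def test_default_width_gives_1536(self):
        cfg = ModelConfig(n_domains=2)
        assert cfg.cnn_out_dim == 1536

    def test_feature_length_contract(self):
        enc = CICNNEncoder(4, np.random.default_rng(0)).eval()
        out = enc(Tensor(rng.standard_normal((2, 1, 33, 17)).astype(np.float32)))
        assert out.shape == (2, enc.out_dim)
        assert enc.out_dim == 4 * 4 * 6

    def test_weight_sharing_identical_channels_identical_features(self):
        enc = CICNNEncoder(4, np.random.default_rng(0)).eval()
        chan = rng.standard_normal((1, 33, 17)).astype(np.float32)
        batch = np.stack([chan, rng.standard_normal((1, 33, 17)).astype(np.float32),
                          chan])
        out = enc(Tensor(batch)).data
        np.testing.assert_allclose(out[0], out[2], atol=1e-6)
        assert np.abs(out[0] - out[1]).max() > 1e-4

    def test_batch_size_invariance(self):
        enc = CICNNEncoder(4, np.random.default_rng(0)).eval()
        batch = rng.standard_normal((6, 1, 33, 17)).astype(np.float32)
        full = enc(Tensor(batch)).data
        single = enc(Tensor(batch[2:3])).data
        np.testing.assert_allclose(full[2], single[0], atol=1e-5)

    def test_multi_channel_input_rejected(self):
        enc = CICNNEncoder(4, np.random.default_rng(0))
        with pytest.raises(ValueError):
            enc(Tensor(np.zeros((2, 3, 33, 17), dtype=np.float32)))


class TestSpatialBiLSTM:
    def test_output_dim_is_twice_hidden(self):
        mod = SpatialBiLSTM(24, 256, np.random.default_rng(0))
        out = mod(Tensor(rng.standard_normal((2, 18, 24)).astype(np.float32)))
        assert out.shape == (2, 18, 512)

    def test_sequence_order_matters(self):
        mod = SpatialBiLSTM(6, 4, np.random.default_rng(0))
        x = rng.standard_normal((1, 18, 6)).astype(np.float32)
        out_fwd = mod(Tensor(x)).data
        out_rev = mod(Tensor(x[:, ::-1, :].copy())).data
        assert np.abs(out_fwd - out_rev).max() > 1e-4

    def test_wrong_sequence_length_rejected(self):
        mod = SpatialBiLSTM(6, 4, np.random.default_rng(0))
        with pytest.raises(ValueError):
            mod(Tensor(np.zeros((1, 17, 6), dtype=np.float32)))


class TestAttentionPool:
    def test_identical_vectors_give_uniform_weights(self):
        pool = AttentionPool(6, 4, np.random.default_rng(0))
        common = rng.standard_normal(6).astype(np.float32)
        h = Tensor(np.tile(common, (2, 18, 1)))
        z, alpha = pool(h)
        np.testing.assert_allclose(alpha.data, 1.0 / 18, atol=1e-6)
        np.testing.assert_allclose(z.data, np.tile(common, (2, 1)), rtol=1e-5, atol=1e-5)

    def test_rows_sum_to_one(self):
        pool = AttentionPool(6, 4, np.random.default_rng(0))
        _, alpha = pool(Tensor(rng.standard_normal((5, 18, 6)).astype(np.float32)))
        np.testing.assert_allclose(alpha.data.sum(axis=1), 1.0, atol=1e-6)
        assert (alpha.data >= 0).all()

    def test_manual_arithmetic_two_channel_toy(self):
        # oracle: calculator-level evaluation with hand-set parameters
        pool = AttentionPool(3, 2, np.random.default_rng(0))
        W = np.array([[1.0, 0.0, -1.0], [0.5, 0.5, 0.5]], dtype=np.float32)
        b = np.array([0.1, -0.2], dtype=np.float32)
        v = np.array([[2.0, -1.0]], dtype=np.float32)
        pool.proj.weight.data = W
        pool.proj.bias.data = b
        pool.v.weight.data = v
        h = np.array([[[1.0, 2.0, 3.0], [-1.0, 0.5, 0.0]]], dtype=np.float32)
        z, alpha = pool(Tensor(h))
        e = np.array([v[0] @ np.tanh(W @ h[0, i] + b) for i in range(2)])
        exp = np.exp(e - e.max())
        a_exp = exp / exp.sum()
        z_exp = a_exp[0] * h[0, 0] + a_exp[1] * h[0, 1]
        np.testing.assert_allclose(alpha.data[0], a_exp, rtol=1e-5)
        np.testing.assert_allclose(z.data[0], z_exp, rtol=1e-5)

    def test_mean_pool_is_unweighted_average(self):
        h = rng.standard_normal((3, 18, 6)).astype(np.float32)
        z, alpha = MeanPool()(Tensor(h))
        np.testing.assert_allclose(z.data, h.mean(axis=1), atol=1e-6)
        np.testing.assert_allclose(alpha.data, 1.0 / 18)


class TestHeadsAndForward:
    def test_full_shape_chain(self):
        cfg = ModelConfig(**TINY)
        net = SeizureDomainNet(cfg, seed=0)
        x = rng.standard_normal((4, 18, 33, 17)).astype(np.float32)
        out = net.forward(x, lam=0.5)
        assert out.seizure_prob.shape == (4,)
        assert out.domain_logits.shape == (4, 3)
        assert out.attention.shape == (4, 18)
        assert out.pooled.shape == (4, cfg.pooled_dim)
        assert np.isfinite(out.seizure_prob).all()
        assert np.isfinite(out.domain_logits).all()

    def test_probabilities_in_unit_interval(self):
        net = SeizureDomainNet(ModelConfig(**TINY), seed=1)
        out = net.forward(rng.standard_normal((8, 18, 33, 17)).astype(np.float32))
        assert ((out.seizure_prob >= 0) & (out.seizure_prob <= 1)).all()

    def test_eval_mode_deterministic(self):
        net = SeizureDomainNet(ModelConfig(base_width=4, lstm_hidden=8, n_domains=2,
                                           attention_hidden=8, head_hidden=8,
                                           dropout_p=0.5), seed=0)
        net.eval()
        x = rng.standard_normal((3, 18, 33, 17)).astype(np.float32)
        p1 = net.forward(x).seizure_prob
        p2 = net.forward(x).seizure_prob
        np.testing.assert_array_equal(p1, p2)

    def test_train_mode_dropout_stochastic(self):
        net = SeizureDomainNet(ModelConfig(base_width=4, lstm_hidden=8, n_domains=2,
                                           attention_hidden=8, head_hidden=8,
                                           dropout_p=0.5), seed=0)
        net.train()
        x = rng.standard_normal((3, 18, 33, 17)).astype(np.float32)
        p1 = net.forward(x).seizure_prob
        p2 = net.forward(x).seizure_prob
        assert np.abs(p1 - p2).max() > 0

    def test_zero_weights_give_half_probability(self):
        net = SeizureDomainNet(ModelConfig(**TINY), seed=0)
        net.eval()
        for p in net.label_head.parameters():
            p.data = np.zeros_like(p.data)
        out = net.forward(rng.standard_normal((5, 18, 33, 17)).astype(np.float32))
        np.testing.assert_allclose(out.seizure_prob, 0.5, atol=1e-7)

    def test_n_domains_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(base_width=4, n_domains=1)

    def test_pooled_dim_invariant(self):
        cfg = ModelConfig(n_domains=2, lstm_hidden=256)
        assert cfg.pooled_dim == 512


class TestGRLInNetwork:
    def test_lambda_zero_blocks_backbone_gradient_from_domain_loss(self):
        net = SeizureDomainNet(ModelConfig(**TINY), seed=0)
        net.eval()
        x = rng.standard_normal((3, 18, 33, 17)).astype(np.float32)
        out = net.forward(x, lam=0.0)
        loss = domain_ce_from_logits(out.domain_logits_t, np.array([0, 1, 2]))
        net.zero_grad()
        loss.backward()
        for name, p in net.named_parameters():
            if "domain_head" in name:
                assert p.grad is not None and np.abs(p.grad).max() > 0
            else:
                assert p.grad is None or np.abs(p.grad).max() == 0, name

    def test_domain_gradient_scales_with_minus_lambda(self):
        # finite-difference oracle: d(L_d)/dtheta_f with GRL == -lam * true gradient
        from conftest import numgrad

        net = SeizureDomainNet(ModelConfig(**TINY), seed=0)
        net.eval()
        for p in net.parameters():
            p.data = p.data.astype(np.float64)
        x = rng.standard_normal((2, 18, 33, 17))
        d = np.array([0, 2])
        lam = 0.37

        def loss_val():
            out = net.forward(x, lam=lam)
            return float(domain_ce_from_logits(out.domain_logits_t, d).data)

        out = net.forward(x, lam=lam)
        net.zero_grad()
        domain_ce_from_logits(out.domain_logits_t, d).backward()
        checked = 0
        for name, p in net.named_parameters():
            if any(k in name for k in ("stem_conv.weight", "w_ih", "proj.weight")):
                ng = numgrad(loss_val, p.data, idxs=[0, 1], eps=1e-6)
                np.testing.assert_allclose(p.grad.ravel()[:2], -lam * ng,
                                           rtol=1e-3, atol=1e-8)
                checked += 1
        assert checked >= 3


class TestMinMaxToy:
    """Adversarial min-max on a linear toy with a spurious domain feature."""

    @staticmethod
    def _run(seed, lam):
        from neoseiz import nn
        from neoseiz.nn import grad_reverse

        gen = np.random.default_rng(seed)
        n = 256
        label = gen.integers(0, 2, n)
        domain = gen.integers(0, 2, n)
        x = np.stack([
            label * 2.0 - 1.0 + 0.3 * gen.standard_normal(n),   # informative
            domain * 2.0 - 1.0 + 0.3 * gen.standard_normal(n),  # spurious
        ], axis=1).astype(np.float32)
        feat = nn.Linear(2, 2, gen)
        label_head = nn.Linear(2, 2, gen)
        domain_head = nn.Linear(2, 2, gen)
        opt = nn.AdamW(feat.parameters() + label_head.parameters()
                       + domain_head.parameters(), lr=0.05, weight_decay=0.0)
        for _ in range(200):
            z = feat(Tensor(x))
            loss = weighted_ce_from_logits(label_head(z), label, w_pos=1.0) \
                + domain_ce_from_logits(domain_head(grad_reverse(z, lam)), domain)
            opt.zero_grad()
            loss.backward()
            opt.step()
        z = feat(Tensor(x))
        label_acc = float((label_head(z).data.argmax(1) == label).mean())
        dom_acc = float((domain_head(z).data.argmax(1) == domain).mean())
        return label_acc, dom_acc

    def test_adversarial_training_suppresses_domain_feature(self):
        passes = 0
        for seed in range(5):
            label_acc, dom_acc = self._run(seed, lam=1.0)
            if label_acc >= 0.9 and dom_acc <= 0.75:
                passes += 1
        assert passes >= 3, f"only {passes}/5 seeds reached the min-max equilibrium"

    def test_lambda_zero_control_keeps_domain_decodable(self):
        label_acc, dom_acc = self._run(0, lam=0.0)
        assert label_acc >= 0.9
        assert dom_acc >= 0.9


class TestWeightedCELoss:
    def test_unit_weight_equals_plain_cross_entropy(self):
        probs = np.array([0.9, 0.2, 0.7])
        labels = np.array([1, 0, 1])
        expected = -(np.log(0.9) + np.log(0.8) + np.log(0.7))
        assert weighted_ce_loss(probs, labels, w_pos=1.0) == pytest.approx(expected)

    def test_single_positive_half_probability(self):
        # w_pos * ln 2 for y=1, p=0.5, w_pos=2.5
        assert weighted_ce_loss(np.array([0.5]), np.array([1]), w_pos=2.5) == \
            pytest.approx(2.5 * np.log(2.0))

    def test_perfect_predictions_near_zero(self):
        loss = weighted_ce_loss(np.array([1.0, 0.0]), np.array([1, 0]), w_pos=2.5)
        assert loss < 1e-5

    def test_mean_reduction(self):
        probs = np.array([0.5, 0.5])
        labels = np.array([1, 0])
        total = weighted_ce_loss(probs, labels, w_pos=2.5, reduction="sum")
        mean = weighted_ce_loss(probs, labels, w_pos=2.5, reduction="mean")
        assert mean == pytest.approx(total / 2)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            weighted_ce_loss(np.array([]), np.array([]))

    def test_logits_form_matches_probability_form(self):
        logits = rng.standard_normal((6, 2)).astype(np.float64)
        labels = np.array([1, 0, 1, 1, 0, 0])
        t = weighted_ce_from_logits(Tensor(logits), labels, w_pos=2.5)
        probs = np.exp(logits[:, 1]) / np.exp(logits).sum(axis=1)
        expected = weighted_ce_loss(probs, labels, w_pos=2.5, reduction="mean")
        assert float(t.data) == pytest.approx(expected, rel=1e-6)


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path):
        cfg = ModelConfig(**TINY)
        net = SeizureDomainNet(cfg, seed=0)
        net.eval()
        stats = NormStats(mean=1.5, std=2.0, fitted_subject_ids=("a", "b"))
        save_checkpoint(str(tmp_path / "ck"), net, stats, {"a": 0, "b": 1})
        model2, sidecar = load_checkpoint(str(tmp_path / "ck"))
        x = rng.standard_normal((2, 18, 33, 17)).astype(np.float32)
        np.testing.assert_array_equal(net.forward(x).seizure_prob,
                                      model2.forward(x).seizure_prob)
        assert sidecar["norm_stats"]["mean"] == 1.5
        assert sidecar["domain_map"] == {"a": 0, "b": 1}
        assert len(sidecar["montage_order"]) == 18

    def test_mean_pool_checkpoint_has_no_attention_parameters(self, tmp_path):
        cfg = ModelConfig(base_width=4, lstm_hidden=8, n_domains=2,
                          attention_hidden=8, head_hidden=8, use_attention=False)
        net = SeizureDomainNet(cfg, seed=0)
        assert not any("pool" in k for k in net.state_dict())
        save_checkpoint(str(tmp_path / "ck"), net, None, None)
        model2, _ = load_checkpoint(str(tmp_path / "ck"))
        assert isinstance(model2.pool, MeanPool)
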