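"""Model contracts: encoder determinism, decoder causality, loss closed forms
and the analytic backward pass."""

import numpy as np
import pytest

from moltrans import seq2seq
from moltrans.seq2seq import ModelConfig, init_params


@pytest.fixture(scope="module")
def tiny_setup():
    rng = np.random.default_rng(0)
    cfg = ModelConfig(vocab_in_size=5, vocab_out_size=4,
                      encoder_layers=(6, 5), latent_dim=3,
                      decoder_layers=(7, 6), classifier_hidden=(4, 3))
    return cfg, init_params(cfg, rng), rng


class TestEncode:
    def test_deterministic(self, tiny_setup):
        cfg, params, rng = tiny_setup
        toks = rng.integers(0, 5, size=(3, 8))
        mask = np.ones((3, 8))
        z1 = seq2seq.encode(params, cfg, toks, mask)
        z2 = seq2seq.encode(params, cfg, toks, mask)
        np.testing.assert_array_equal(z1, z2)

    def test_fixed_dimension_across_lengths(self, tiny_setup):
        cfg, params, rng = tiny_setup
        for t in (2, 5, 11):
            toks = rng.integers(0, 5, size=(2, t))
            z = seq2seq.encode(params, cfg, toks, np.ones((2, t)))
            assert z.shape == (2, cfg.latent_dim)

    def test_bounded_bottleneck_range(self, tiny_setup):
        cfg, params, rng = tiny_setup
        toks = rng.integers(0, 5, size=(4, 6))
        z = seq2seq.encode(params, cfg, toks, np.ones((4, 6)))
        assert np.all(np.abs(z) <= 1.0)

    def test_padding_is_ignored(self, tiny_setup):
        # the latent of a sequence must not depend on what pads carry
        cfg, params, rng = tiny_setup
        toks = rng.integers(0, 5, size=(1, 6))
        mask = np.ones((1, 6)); mask[0, 4:] = 0
        z1 = seq2seq.encode(params, cfg, toks, mask)
        toks2 = toks.copy(); toks2[0, 4:] = (toks[0, 4:] + 1) % 5
        z2 = seq2seq.encode(params, cfg, toks2, mask)
        np.testing.assert_array_equal(z1, z2)


class TestDecoderInit:
    def test_one_state_per_layer(self, tiny_setup):
        cfg, params, rng = tiny_setup
        z = rng.normal(size=(2, cfg.latent_dim))
        hs, cs = seq2seq.decoder_initial_states(params, cfg, z)
        assert len(hs) == len(cfg.decoder_layers) == len(cs)
        for h, c, size in zip(hs, cs, cfg.decoder_layers):
            assert h.shape == (2, size) and c.shape == (2, size)

    def test_distinct_latents_give_distinct_states(self, tiny_setup):
        cfg, params, rng = tiny_setup
        z = rng.normal(size=(2, cfg.latent_dim))
        hs, cs = seq2seq.decoder_initial_states(params, cfg, z)
        assert not np.allclose(cs[0][0], cs[0][1])

    def test_zero_latent_zero_bias_gives_zero_states(self, tiny_setup):
        cfg, params, rng = tiny_setup
        p = {k: v.copy() for k, v in params.items()}
        for l in range(len(cfg.decoder_layers)):
            p[f"dini{l}_b"][:] = 0.0
        hs, cs = seq2seq.decoder_initial_states(
            p, cfg, np.zeros((1, cfg.latent_dim)))
        for h, c in zip(hs, cs):
            np.testing.assert_array_equal(h, 0.0)
            np.testing.assert_array_equal(c, 0.0)


class TestTeacherForcing:
    def test_output_shape_and_normalization(self, tiny_setup):
        cfg, params, rng = tiny_setup
        z = rng.normal(size=(2, cfg.latent_dim))
        tgt = rng.integers(0, 4, size=(2, 7))
        probs = seq2seq.decode_teacher_forced(params, cfg, z, tgt, 0)
        assert probs.shape == (2, 7, 4)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_causality(self, tiny_setup):
        # perturbing target token k leaves distributions at positions <= k
        # unchanged: step t is conditioned on true tokens < t only
        cfg, params, rng = tiny_setup
        z = rng.normal(size=(1, cfg.latent_dim))
        tgt = rng.integers(0, 4, size=(1, 7))
        probs = seq2seq.decode_teacher_forced(params, cfg, z, tgt, 0)
        k = 3
        tgt2 = tgt.copy(); tgt2[0, k] = (tgt[0, k] + 1) % 4
        probs2 = seq2seq.decode_teacher_forced(params, cfg, z, tgt2, 0)
        np.testing.assert_array_equal(probs[:, : k + 1], probs2[:, : k + 1])
        assert not np.allclose(probs[:, k + 1:], probs2[:, k + 1:])


class TestClassifier:
    def test_output_dimension_and_determinism(self, tiny_setup):
        cfg, params, rng = tiny_setup
        z = rng.normal(size=(3, cfg.latent_dim))
        p1 = seq2seq.classify_properties(params, cfg, z)
        p2 = seq2seq.classify_properties(params, cfg, z)
        assert p1.shape == (3, 9)
        np.testing.assert_array_equal(p1, p2)

    def test_zero_hidden_weights_give_constant_bias_output(self, tiny_setup):
        cfg, params, rng = tiny_setup
        p = {k: v.copy() for k, v in params.items()}
        p["cls_W1"][:] = 0; p["cls_W2"][:] = 0; p["cls_W3"][:] = 0
        p["cls_b3"][:] = np.arange(9.0)
        z = rng.normal(size=(4, cfg.latent_dim))
        out = seq2seq.classify_properties(p, cfg, z)
        np.testing.assert_array_equal(out, np.tile(np.arange(9.0), (4, 1)))


class TestJointLoss:
    def test_closed_form_half_probability(self):
        probs = np.array([[[0.5, 0.25, 0.25]]])
        tgt = np.array([[0]])
        prop = np.zeros((1, 9))
        loss = seq2seq.joint_loss(probs, tgt, prop, prop, np.ones((1, 1)), 1.0)
        assert abs(loss - (-np.log(0.5))) < 1e-9

    def test_uniform_distributions_give_log_n(self):
        n = 7
        probs = np.full((2, 3, n), 1.0 / n)
        tgt = np.zeros((2, 3), dtype=int)
        prop = np.zeros((2, 9))
        loss = seq2seq.joint_loss(probs, tgt, prop, prop, np.ones((2, 3)), 1.0)
        assert abs(loss - np.log(n)) < 1e-9

    def test_zero_at_optimum(self):
        probs = np.zeros((1, 2, 3)); probs[:, :, 1] = 1.0
        tgt = np.ones((1, 2), dtype=int)
        prop = np.ones((1, 9))
        loss = seq2seq.joint_loss(probs, tgt, prop, prop, np.ones((1, 2)), 1.0)
        assert loss == 0.0

    def test_all_masked_is_an_error(self):
        probs = np.full((1, 2, 3), 1 / 3)
        with pytest.raises(ValueError):
            seq2seq.joint_loss(probs, np.zeros((1, 2), dtype=int),
                               np.zeros((1, 9)), np.zeros((1, 9)),
                               np.zeros((1, 2)))


def test_analytic_gradients_match_finite_differences():
    """Spot-check every parameter tensor of a small model against central
    finite differences at 1e-4 relative tolerance."""
    rng = np.random.default_rng(12)
    cfg = ModelConfig(vocab_in_size=4, vocab_out_size=2,
                      encoder_layers=(5,), latent_dim=3,
                      decoder_layers=(4,), classifier_hidden=(3, 3))
    params = init_params(cfg, rng, dtype=np.float64)
    enc = rng.integers(0, 4, size=(2, 5))
    enc_mask = np.ones((2, 5)); enc_mask[1, 3:] = 0
    tgt = rng.integers(0, 2, size=(2, 4))
    tmask = np.ones((2, 4)); tmask[0, 3:] = 0
    prop = rng.normal(size=(2, 9))
    _, _, grads, _ = seq2seq.loss_and_grads(params, cfg, enc, enc_mask, tgt,
                                            tmask, prop, start_index=0)
    eps = 1e-6
    for k, arr in params.items():
        flat = arr.ravel()
        for i in rng.choice(flat.size, size=min(5, flat.size), replace=False):
            old = flat[i]
            flat[i] = old + eps
            lp, *_ = seq2seq.loss_and_grads(params, cfg, enc, enc_mask, tgt,
                                            tmask, prop, 0)
            flat[i] = old - eps
            lm, *_ = seq2seq.loss_and_grads(params, cfg, enc, enc_mask, tgt,
                                            tmask, prop, 0)
            flat[i] = old
            num = (lp - lm) / (2 * eps)
            ana = grads[k].ravel()[i]
            assert abs(num - ana) <= 1e-4 * max(1.0, abs(num)), (k, i)
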