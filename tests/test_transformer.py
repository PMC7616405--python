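"""Tests for the autoregressive prior and its token-masking contract."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iltm import transformer as tr
from iltm.exceptions import ContextLengthError, DegenerateTrainingError


def tiny_config(**kw):
    base = dict(vocab=6, context=10, d_model=16, n_heads=2, n_layers=2,
                d_ff=32, epochs=0)
    base.update(kw)
    return tr.TransformerConfig(**base)


def tiny_model(seed=0, **kw):
    cfg = tiny_config(**kw)
    params = tr.init_params(cfg, seed)
    r = np.random.default_rng(seed + 1)
    params["Wout"] = 0.3 * r.standard_normal(params["Wout"].shape)
    return tr.TransformerModel(params=params, config=cfg)


class TestRasterize:
    def test_row_major_definition(self):
        grid = np.array([[1, 2], [3, 4]])
        seq = tr.rasterize(grid)
        assert seq.s.tolist() == [1, 2, 3, 4]
        assert seq.shape == (2, 2)

    @settings(deadline=None, max_examples=20)
    @given(st.integers(1, 6), st.integers(1, 6), st.integers(0, 99))
    def test_roundtrip_identity(self, h, w, seed):
        grid = np.random.default_rng(seed).integers(0, 9, size=(h, w))
        assert np.array_equal(tr.derasterize(tr.rasterize(grid)), grid)

    def test_8x8_grid_gives_64_tokens(self):
        seq = tr.rasterize(np.zeros((8, 8), dtype=int))
        assert len(seq) == 64


class TestMaskingContract:
    def test_substitution_at_masked_positions_changes_nothing(self):
        """Core contract: outputs at unmasked positions are bit-for-bit
        invariant to arbitrary token substitution at masked positions."""
        model = tiny_model()
        r = np.random.default_rng(3)
        s = r.integers(0, 6, size=8)
        mask = np.array([0, 1, 0, 0, 1, 0, 1, 0], dtype=bool)
        base = tr.token_likelihoods(model, tr.TokenSequence(s, (2, 4)), mask)
        for _ in range(5):
            s2 = s.copy()
            s2[mask] = r.integers(0, 6, size=mask.sum())
            out = tr.token_likelihoods(model, tr.TokenSequence(s2, (2, 4)),
                                       mask)
            assert np.array_equal(base.dists, out.dists)
            assert np.array_equal(base.p[~mask], out.p[~mask])

    def test_causality(self):
        """Distribution at position i ignores tokens at positions >= i."""
        model = tiny_model()
        r = np.random.default_rng(4)
        s = r.integers(0, 6, size=8)
        base = tr.token_likelihoods(model, tr.TokenSequence(s, (2, 4)))
        j = 5
        s2 = s.copy()
        s2[j:] = (s2[j:] + 1) % 6
        out = tr.token_likelihoods(model, tr.TokenSequence(s2, (2, 4)))
        assert np.array_equal(base.dists[:j + 1], out.dists[:j + 1])

    def test_empty_mask_equals_no_mask(self):
        model = tiny_model()
        s = tr.TokenSequence(np.arange(8) % 6, (2, 4))
        a = tr.token_likelihoods(model, s)
        b = tr.token_likelihoods(model, s, np.zeros(8, bool))
        assert np.array_equal(a.p, b.p)
        assert np.array_equal(a.dists, b.dists)

    def test_untrained_uniform_head_gives_uniform_likelihoods(self):
        cfg = tiny_config()
        model = tr.TransformerModel(params=tr.init_params(cfg, 0), config=cfg)
        out = tr.token_likelihoods(model, tr.TokenSequence(np.zeros(8, int),
                                                           (2, 4)))
        assert np.allclose(out.p, 1 / 6, atol=1e-12)

    def test_distributions_normalized(self, trained_prior, token_sequences):
        lik = tr.token_likelihoods(
            trained_prior,
            tr.TokenSequence(token_sequences[0], (8, 8)))
        assert np.allclose(lik.dists.sum(axis=-1), 1.0, atol=1e-6)
        idx = token_sequences[0]
        assert np.allclose(lik.p,
                           lik.dists[np.arange(64), idx], atol=1e-12)


class TestNextTokenDistribution:
    def test_matches_full_forward_pass(self):
        model = tiny_model()
        r = np.random.default_rng(5)
        s = r.integers(0, 6, size=8)
        lik = tr.token_likelihoods(model, tr.TokenSequence(s, (2, 4)))
        for i in range(8):
            d = tr.next_token_distribution(model, s[:i])
            assert np.allclose(d, lik.dists[i], atol=1e-12)

    def test_sums_to_one(self, trained_prior, token_sequences):
        d = tr.next_token_distribution(trained_prior, token_sequences[0][:10])
        assert d.min() >= 0
        assert abs(d.sum() - 1.0) < 1e-6

    def test_masked_prefix_content_irrelevant(self):
        model = tiny_model()
        prefix = np.array([1, 2, 3, 4])
        mask = np.array([0, 1, 0, 1], bool)
        d1 = tr.next_token_distribution(model, prefix, mask)
        prefix2 = np.array([1, 5, 3, 0])
        d2 = tr.next_token_distribution(model, prefix2, mask)
        assert np.array_equal(d1, d2)

    def test_context_overflow(self):
        model = tiny_model()
        with pytest.raises(ContextLengthError):
            tr.next_token_distribution(model, np.zeros(10, int))


class TestLoss:
    def test_zero_masks_reduce_to_plain_cross_entropy(self):
        """With no masks the training loss equals the negative mean log
        of per-position likelihoods (independent oracle)."""
        model = tiny_model(seed=6)
        r = np.random.default_rng(7)
        S = r.integers(0, 6, size=(3, 8))
        loss = tr.masked_cross_entropy(model, S=S)
        oracle = -np.mean([
            np.log(tr.token_likelihoods(model,
                                        tr.TokenSequence(s, (2, 4))).p)
            for s in S])
        assert abs(loss - oracle) < 1e-9

    def test_single_masked_position_hand_oracle(self):
        """Masked loss on a 4-token sequence equals the cross-entropy
        averaged over the remaining positions, computed by hand."""
        model = tiny_model(seed=8)
        s = np.array([2, 0, 5, 1])
        mask = np.array([0, 0, 1, 0], bool)
        lik = tr.token_likelihoods(model, tr.TokenSequence(s, (2, 2)), mask)
        oracle = -(np.log(lik.p[0]) + np.log(lik.p[1]) + np.log(lik.p[3])) / 3
        loss = tr.masked_cross_entropy(model, S=s[None], M=mask[None])
        assert abs(loss - oracle) < 1e-9

    def test_likelihood_consistency(self):
        """Product of unmasked p_i equals exp(-loss * n_unmasked)."""
        model = tiny_model(seed=9)
        s = np.random.default_rng(10).integers(0, 6, size=8)
        mask = np.array([0, 1, 0, 0, 0, 1, 0, 0], bool)
        lik = tr.token_likelihoods(model, tr.TokenSequence(s, (2, 4)), mask)
        loss = tr.masked_cross_entropy(model, S=s[None], M=mask[None])
        prod = np.prod(lik.p[~mask])
        assert np.isclose(prod, np.exp(-loss * (~mask).sum()), rtol=1e-8)

    def test_all_masked_degenerate(self):
        model = tiny_model()
        with pytest.raises(DegenerateTrainingError):
            tr.masked_cross_entropy(model, S=np.zeros((2, 8), int),
                                    M=np.ones((2, 8), bool))


class TestTraining:
    def test_loss_decreases(self, trained_prior):
        assert trained_prior.loss_log[-1] < trained_prior.loss_log[0]

    def test_seeded_determinism(self):
        cfg = tiny_config(epochs=3, batch_size=4, lr=1e-3)
        S = np.random.default_rng(11).integers(0, 6, size=(8, 8))
        a = tr.train_transformer(S, None, cfg, seed=2)
        b = tr.train_transformer(S, None, cfg, seed=2)
        assert a.loss_log == b.loss_log
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)

    def test_mask_alignment_enforced(self):
        cfg = tiny_config(epochs=1)
        S = np.zeros((4, 8), int)
        with pytest.raises(ValueError):
            tr.train_transformer(S, np.zeros((3, 8), bool), cfg, 0)

    def test_all_masked_rejected(self):
        cfg = tiny_config(epochs=1)
        with pytest.raises(DegenerateTrainingError):
            tr.train_transformer(np.zeros((4, 8), int),
                                 np.ones((4, 8), bool), cfg, 0)

    def test_checkpoint_roundtrip(self, trained_prior, tmp_path):
        p = tmp_path / "prior.npz"
        tr.save_transformer(trained_prior, p)
        back = tr.load_transformer(p)
        assert back.config == trained_prior.config
        assert all(np.array_equal(back.params[k], trained_prior.params[k])
                   for k in trained_prior.params)


class TestGradients:
    def test_backward_matches_finite_differences(self):
        cfg = tiny_config()
        params = tr.init_params(cfg, 0)
        r = np.random.default_rng(1)
        params["Wout"] = 0.1 * r.standard_normal(params["Wout"].shape)
        S = r.integers(0, 6, size=(3, 8))
        M = np.zeros_like(S, bool)
        M[0, 2] = M[1, 5] = True
        _, grads = tr.masked_cross_entropy(params, cfg, S, M, with_grads=True)
        eps = 1e-6
        for name in ["Wtok", "Wpos", "Wq_0", "Wk_1", "Wv_0", "Wo_1", "W1_0",
                     "W2_1", "g1_0", "b2_1", "g_f", "Wout", "bq_0"]:
            g = grads[name]
            for _ in range(2):
                ix = tuple(r.integers(0, dim) for dim in g.shape)
                orig = params[name][ix]
                params[name][ix] = orig + eps
                lp = tr.masked_cross_entropy(params, cfg, S, M)
                params[name][ix] = orig - eps
                lm = tr.masked_cross_entropy(params, cfg, S, M)
                params[name][ix] = orig
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - g[ix]) < 1e-4 * max(1.0, abs(fd)), name
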