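"""Tests for resample masks, sequence healing and KDE anomaly maps."""

import numpy as np
import pytest
import sympy
from scipy import stats

from iltm import healing_kde as hk
from iltm import transformer as tr
from iltm import vqvae as vq


class TestResampleMask:
    def test_threshold_definition(self):
        m = hk.compute_resample_mask(np.array([0.9, 0.004, 0.5]), 0.005)
        assert m.flags.tolist() == [False, True, False]

    def test_no_flags_when_all_above(self):
        m = hk.compute_resample_mask(np.full(10, 0.1), 0.005)
        assert not m.flags.any()

    def test_matches_elementwise_oracle(self, rng):
        for _ in range(20):
            p = rng.random(32)
            t = rng.uniform(0.01, 0.99)
            m = hk.compute_resample_mask(p, t)
            assert m.flags.tolist() == [pi < t for pi in p]

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            hk.compute_resample_mask(np.array([0.5]), 0.0)


class TestHealSequence:
    def test_empty_mask_returns_copies(self, trained_prior, token_sequences):
        seq = tr.TokenSequence(token_sequences[0], (8, 8))
        mask = hk.ResampleMask(np.zeros(64, bool), 0.005)
        healed = hk.heal_sequence(trained_prior, seq, mask, 4, seed=0)
        assert len(healed) == 4
        assert all(np.array_equal(h.s, seq.s) for h in healed)

    def test_only_flagged_positions_change(self, trained_prior,
                                           token_sequences):
        seq = tr.TokenSequence(token_sequences[1], (8, 8))
        flags = np.zeros(64, bool)
        flags[[3, 17, 40]] = True
        healed = hk.heal_sequence(trained_prior, seq,
                                  hk.ResampleMask(flags, 0.005), 8, seed=1)
        for h in healed:
            assert np.array_equal(h.s[~flags], seq.s[~flags])

    def test_seeded_determinism(self, trained_prior, token_sequences):
        seq = tr.TokenSequence(token_sequences[2], (8, 8))
        flags = np.zeros(64, bool)
        flags[[10, 30]] = True
        mask = hk.ResampleMask(flags, 0.005)
        a = hk.heal_sequence(trained_prior, seq, mask, 5, seed=3)
        b = hk.heal_sequence(trained_prior, seq, mask, 5, seed=3)
        assert all(np.array_equal(x.s, y.s) for x, y in zip(a, b))

    def test_draws_follow_model_distribution(self, trained_prior,
                                             token_sequences):
        """Chi-square goodness of fit of 10,000 healed draws at one flagged
        position against the prior's next-token distribution."""
        seq = tr.TokenSequence(token_sequences[3], (8, 8))
        pos = 20
        flags = np.zeros(64, bool)
        flags[pos] = True
        healed = hk.heal_sequence(trained_prior, seq,
                                  hk.ResampleMask(flags, 0.005),
                                  10_000, seed=4)
        draws = np.array([h.s[pos] for h in healed])
        expected = tr.next_token_distribution(trained_prior, seq.s[:pos])
        K = trained_prior.config.vocab
        counts = np.bincount(draws, minlength=K).astype(float)
        exp_counts = expected * 10_000
        # merge bins with tiny expectation into one for a valid test
        big = exp_counts >= 5
        obs, exp = counts[big], exp_counts[big]
        tail_exp = exp_counts[~big].sum()
        if tail_exp >= 1.0:
            obs = np.append(obs, counts[~big].sum())
            exp = np.append(exp, tail_exp)
        else:
            # negligible tail mass: a draw there would itself refute fit
            assert counts[~big].sum() <= 2
        stat, pval = stats.chisquare(obs, exp * obs.sum() / exp.sum())
        assert pval > 0.01


class TestReconstructionStack:
    def test_stack_size_conservation(self, trained_vqvae, trained_prior,
                                     token_sequences):
        seq = tr.TokenSequence(token_sequences[4], (8, 8))
        flags = np.zeros(64, bool)
        flags[5] = True
        healed = hk.heal_sequence(trained_prior, seq,
                                  hk.ResampleMask(flags, 0.005), 3, seed=5)
        stack = hk.build_reconstruction_stack(trained_vqvae, healed, 2, seed=6)
        assert stack.n == 6
        assert stack.images.shape == (6, 32, 32)
        assert stack.provenance["n_resamples"] == 3

    def test_deterministic_single_decode_equals_decoder(self, trained_vqvae,
                                                        token_sequences):
        seq = tr.TokenSequence(token_sequences[5], (8, 8))
        stack = hk.build_reconstruction_stack(trained_vqvae, [seq], 1,
                                              seed=0, stochastic=False)
        direct = vq.decode(trained_vqvae,
                           vq.embed(trained_vqvae.codebook,
                                    tr.derasterize(seq)), stochastic=False)
        assert np.array_equal(stack.images[0], direct)

    def test_same_seed_same_stack(self, trained_vqvae, token_sequences):
        seq = tr.TokenSequence(token_sequences[6], (8, 8))
        a = hk.build_reconstruction_stack(trained_vqvae, [seq, seq], 3, seed=9)
        b = hk.build_reconstruction_stack(trained_vqvae, [seq, seq], 3, seed=9)
        assert np.array_equal(a.images, b.images)


class TestSilverman:
    def test_constant_values_give_epsilon(self):
        assert hk.silverman_bandwidth(np.full(300, 0.7), eps=0.05) == 0.05

    def test_closed_form_sigma_one(self):
        r = np.random.default_rng(0)
        # construct a sample with sample std exactly scaled to 1
        v = r.normal(size=300)
        v = (v - v.mean()) / v.std(ddof=1)
        h = hk.silverman_bandwidth(v, eps=0.0)
        expected = float(sympy.N(sympy.Rational(4, 900) ** sympy.Rational(1, 5), 30))
        assert abs(h - expected) < 1e-12

    def test_matches_high_precision_oracle(self, rng):
        for n in (2, 10, 300):
            v = rng.normal(loc=3.0, scale=2.0, size=n)
            eps = float(rng.uniform(0, 0.1))
            sigma = float(np.std(v, ddof=1))
            expected = float(sympy.N(
                (4 * sympy.Float(sigma, 30) ** 5 / (3 * n))
                ** sympy.Rational(1, 5) + sympy.Float(eps, 30), 30))
            assert abs(hk.silverman_bandwidth(v, eps) - expected) < 1e-12

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            hk.silverman_bandwidth(np.array([]))
        with pytest.raises(ValueError):
            hk.silverman_bandwidth(np.array([1.0]), eps=-0.1)


class TestKdeScore:
    def test_zero_spread_closed_form(self):
        h = 0.05
        L = hk.kde_log_score(np.full(20, 0.3), 0.3, h)
        assert np.isclose(L, np.log(1 / (h * np.sqrt(2 * np.pi))), atol=1e-12)

    def test_matches_textbook_oracle(self, rng):
        for _ in range(20):
            v = rng.random(25)
            x0 = float(rng.random())
            h = float(rng.uniform(0.01, 0.5))
            L = hk.kde_log_score(v, x0, h)
            oracle = np.log(np.mean(stats.norm.pdf(x0, loc=v, scale=h)))
            assert abs(L - oracle) < 1e-10

    def test_literal_sum_differs_by_log_n(self, rng):
        v = rng.random(30)
        a = hk.kde_log_score(v, 0.5, 0.1)
        b = hk.kde_log_score(v, 0.5, 0.1, literal_sum=True)
        assert np.isclose(b - a, np.log(30), atol=1e-12)

    def test_monotone_decay_far_from_samples(self):
        v = np.random.default_rng(1).normal(0.5, 0.01, size=50)
        h = 0.05
        scores = [hk.kde_log_score(v, 0.5 + d, h) for d in (0.2, 0.4, 0.8)]
        assert scores[0] > scores[1] > scores[2]

    def test_invalid_bandwidth(self):
        with pytest.raises(ValueError):
            hk.kde_log_score(np.array([0.5]), 0.5, 0.0)

    def test_density_normalizes_to_one(self, rng):
        """Numerical quadrature of the per-pixel density equals 1."""
        v = rng.random(40)
        h = hk.silverman_bandwidth(v, eps=0.05)
        grid = np.linspace(-5, 6, 20_001)
        dens = np.exp([hk.kde_log_score(v, float(x), h) for x in grid])
        assert abs(np.trapezoid(dens, grid) - 1.0) < 1e-3


class TestAnomalyMap:
    def test_decomposes_into_scalar_operations(self, rng):
        stack = hk.ReconstructionStack(images=rng.random((12, 6, 6)))
        original = rng.random((6, 6))
        amap = hk.anomaly_map(stack, original, eps=0.05)
        for i in range(6):
            for j in range(6):
                h = hk.silverman_bandwidth(stack.images[:, i, j], eps=0.05)
                L = hk.kde_log_score(stack.images[:, i, j], original[i, j], h)
                assert abs(amap.bandwidth[i, j] - h) < 1e-12
                assert abs(amap.L[i, j] - L) < 1e-10

    def test_identical_stack_gives_constant_map(self):
        original = np.random.default_rng(2).random((8, 8))
        stack = hk.ReconstructionStack(images=np.repeat(original[None], 5,
                                                        axis=0))
        amap = hk.anomaly_map(stack, original, eps=0.05)
        expected = np.log(1 / (0.05 * np.sqrt(2 * np.pi)))
        assert np.allclose(amap.L, expected, atol=1e-10)

    def test_outlier_pixel_scores_lower(self, rng):
        stack = hk.ReconstructionStack(
            images=0.5 + 0.01 * rng.standard_normal((30, 4, 4)))
        original = np.full((4, 4), 0.5)
        original[2, 2] = 0.95  # far outside the reconstruction cloud
        amap = hk.anomaly_map(stack, original, eps=0.01)
        assert amap.L[2, 2] < amap.L[0, 0]
        assert amap.L[2, 2] == amap.L.min()

    def test_shape_mismatch(self, rng):
        stack = hk.ReconstructionStack(images=rng.random((3, 4, 4)))
        with pytest.raises(ValueError):
            hk.anomaly_map(stack, rng.random((5, 5)))


class TestSegment:
    def test_extreme_thresholds(self, rng):
        stack = hk.ReconstructionStack(images=rng.random((10, 5, 5)))
        amap = hk.anomaly_map(stack, rng.random((5, 5)), eps=0.05)
        assert not hk.segment(amap, np.exp(amap.L.min()) * 0.5).any()
        assert hk.segment(amap, np.exp(amap.L.max()) * 2.0).all()

    def test_elementwise_oracle(self, rng):
        stack = hk.ReconstructionStack(images=rng.random((10, 5, 5)))
        amap = hk.anomaly_map(stack, rng.random((5, 5)), eps=0.05)
        thr = 0.005
        seg = hk.segment(amap, thr)
        assert np.array_equal(seg, amap.L < np.log(thr))


class TestScoreImage:
    def test_end_to_end_determinism(self, trained_vqvae, trained_prior,
                                    small_dataset):
        img = small_dataset.images[0]
        params = hk.ScoreParams(n_resamples=3, n_decodes=2)
        a = hk.score_image(trained_vqvae, trained_prior, img, params, seed=5)
        b = hk.score_image(trained_vqvae, trained_prior, img, params, seed=5)
        assert np.array_equal(a.L, b.L)

    def test_batch_matches_single(self, trained_vqvae, trained_prior,
                                  small_dataset):
        imgs = small_dataset.images[:3]
        params = hk.ScoreParams(n_resamples=2, n_decodes=2)
        batch = hk.score_images(trained_vqvae, trained_prior, imgs, params,
                                seed=8)
        ss = np.random.SeedSequence(8)
        singles = [hk.score_image(trained_vqvae, trained_prior, img, params,
                                  child)
                   for img, child in zip(imgs, ss.spawn(3))]
        for m_batch, m_single in zip(batch, singles):
            assert np.array_equal(m_batch.L, m_single.L)
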