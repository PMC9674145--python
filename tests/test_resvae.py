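"""Skeleton VAE: KL closed forms, reparameterization, loss arithmetic,
training contracts and the generative decode path."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from l2l.errors import ParameterError
from l2l.resvae import (
    LatentDistribution,
    ResidualVAE,
    ResidualVAEResults,
    VaeConfig,
    kl_divergence,
    sample_latent,
    vae_loss,
)


class TestKlDivergence:
    def test_standard_normal_is_zero(self):
        d = LatentDistribution(np.zeros(32), np.ones(32))
        assert kl_divergence(d) == pytest.approx(0.0, abs=1e-12)

    def test_unit_mean_closed_form(self):
        assert kl_divergence(LatentDistribution([1.0], [1.0])) == pytest.approx(0.5)

    def test_wide_sigma_closed_form(self):
        expected = 0.5 * (4.0 - 1.0 - np.log(4.0))
        assert kl_divergence(LatentDistribution([0.0], [2.0])) == pytest.approx(expected)
        assert expected == pytest.approx(0.8069, abs=1e-4)

    def test_matches_numerical_integration_1d(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            mu, sigma = rng.uniform(-2, 2), rng.uniform(0.2, 3.0)

            def integrand(x):
                p = norm.pdf(x, mu, sigma)
                return p * (norm.logpdf(x, mu, sigma) - norm.logpdf(x, 0, 1)) if p > 0 else 0.0

            numeric, _ = quad(integrand, mu - 12 * sigma, mu + 12 * sigma, limit=200)
            assert kl_divergence(LatentDistribution([mu], [sigma])) == \
                pytest.approx(numeric, abs=1e-4)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ParameterError):
            LatentDistribution([0.0], [0.0])


class TestSampleLatent:
    def test_tiny_sigma_returns_mu(self):
        d = LatentDistribution(np.arange(4.0), np.full(4, 1e-12))
        z = sample_latent(d, np.random.default_rng(0))
        assert np.allclose(z, d.mu, atol=1e-10)

    def test_monte_carlo_mean_matches_mu(self):
        rng = np.random.default_rng(1)
        d = LatentDistribution(np.array([0.5, -1.0, 2.0]), np.array([0.3, 1.0, 0.1]))
        draws = np.stack([sample_latent(d, rng) for _ in range(10_000)])
        tol = 3 * d.sigma / np.sqrt(10_000)
        assert np.all(np.abs(draws.mean(axis=0) - d.mu) < tol)

    def test_reproducible_under_seed(self):
        d = LatentDistribution(np.zeros(8), np.ones(8))
        a = sample_latent(d, np.random.default_rng(7))
        b = sample_latent(d, np.random.default_rng(7))
        assert np.array_equal(a, b)


class TestVaeLoss:
    def test_perfect_reconstruction_standard_posterior(self):
        x = np.zeros((4, 4))
        d = LatentDistribution(np.zeros(8), np.ones(8))
        assert vae_loss(x, x, d, beta=1.0).total == 0.0

    def test_beta_zero_drops_kl(self):
        x = np.zeros((4, 4))
        x_hat = x.copy()
        x_hat[0, 0] = 0.3
        d = LatentDistribution([2.0], [1.0])
        parts = vae_loss(x, x_hat, d, beta=0.0)
        assert parts.total == parts.reconstruction

    def test_hand_arithmetic(self):
        x = np.zeros((4, 4))
        x_hat = x.copy()
        x_hat[0, :4] = 0.5                   # 4 pixels differ by 0.5
        mu = np.array([1.0])                 # kl = 0.5
        parts = vae_loss(x, x_hat, LatentDistribution(mu, [1.0]), beta=1.0)
        assert parts.reconstruction == pytest.approx(1.0)
        assert parts.kl == pytest.approx(0.5)
        assert parts.total == pytest.approx(1.5)

    def test_shape_mismatch_rejected(self):
        d = LatentDistribution([0.0], [1.0])
        with pytest.raises(ParameterError):
            vae_loss(np.zeros((2, 2)), np.zeros((3, 3)), d, 1.0)


class TestDefaultArchitectureContract:
    """Default config: 256×256 skeletons ↔ latent vectors of length 32."""

    @pytest.fixture(scope="class")
    def results(self):
        rng = np.random.default_rng(0)
        sk = (rng.random((2, 256, 256)) < 0.05).astype(float)
        return ResidualVAE(list(sk), VaeConfig()).fit(epochs=0)

    def test_encode_gives_32_latent(self, results):
        rng = np.random.default_rng(1)
        x = (rng.random((256, 256)) < 0.05).astype(float)
        dist = results.encode(x)
        assert dist.dim == 32
        assert np.all(dist.sigma > 0)

    def test_encode_deterministic(self, results):
        x = np.zeros((256, 256))
        x[100:150, 100:150] = 1.0
        a, b = results.encode(x), results.encode(x)
        assert np.array_equal(a.mu, b.mu) and np.array_equal(a.sigma, b.sigma)

    def test_decode_returns_256_grid_in_unit_range(self, results):
        out = results.decode(np.random.default_rng(2).standard_normal(32))
        assert out.shape == (256, 256)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_wrong_latent_length_rejected(self, results):
        with pytest.raises(ParameterError):
            results.decode(np.zeros(16))


class TestTraining:
    def _skeletons(self, n, side=16, seed=0):
        rng = np.random.default_rng(seed)
        return list((rng.random((n, side, side)) < 0.2).astype(float))

    def test_epochs_zero_returns_initialization(self, tiny_vae_config):
        res = ResidualVAE(self._skeletons(4), tiny_vae_config).fit(epochs=0)
        assert res.history == []

    def test_same_seed_identical_histories(self, tiny_vae_config):
        data = self._skeletons(8)
        a = ResidualVAE(data, tiny_vae_config).fit()
        b = ResidualVAE(data, tiny_vae_config).fit()
        assert a.history == b.history
        assert len(a.history) == tiny_vae_config.epochs

    def test_loss_parts_consistent(self, tiny_vae_config):
        res = ResidualVAE(self._skeletons(8), tiny_vae_config).fit()
        for h in res.history:
            assert h.total == pytest.approx(
                h.reconstruction + tiny_vae_config.beta * h.kl, rel=1e-9)

    def test_empty_dataset_rejected(self, tiny_vae_config):
        with pytest.raises(ParameterError):
            ResidualVAE([], tiny_vae_config)

    def test_sampling_path_stays_in_unit_range(self, tiny_vae_config):
        res = ResidualVAE(self._skeletons(4), tiny_vae_config).fit(epochs=1)
        rng = np.random.default_rng(3)
        for _ in range(100):
            out = res.decode(rng.standard_normal(tiny_vae_config.latent_dim))
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_checkpoint_roundtrip(self, tiny_vae_config, tmp_path):
        res = ResidualVAE(self._skeletons(4), tiny_vae_config).fit(epochs=1)
        path = tmp_path / "vae.npz"
        res.save(path)
        loaded = ResidualVAEResults.load(path)
        z = np.random.default_rng(4).standard_normal(tiny_vae_config.latent_dim)
        assert np.array_equal(res.decode(z), loaded.decode(z))
        assert loaded.history == res.history


class TestSmokeTraining:
    """Training dynamics on the shared 64-leaf, 30-epoch session run."""

    def test_loss_decreases(self, vae_smoke):
        assert vae_smoke.history[-1].total < vae_smoke.history[0].total

    def test_reconstruction_beats_random_latent(self, vae_smoke, preprocessed):
        x = preprocessed[0].skeleton.as_float()
        rec_err = np.sum((x - vae_smoke.reconstruct(preprocessed[0].skeleton)) ** 2)
        rnd = vae_smoke.decode(np.random.default_rng(5).standard_normal(32))
        rnd_err = np.sum((x - rnd) ** 2)
        assert rec_err < rnd_err

    def test_summary_mentions_training(self, vae_smoke):
        s = vae_smoke.summary()
        assert "latent dim" in s and "32" in s and "epochs trained" in s
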