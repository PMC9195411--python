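"""Network forward passes against hand calculations, loss closed forms,
a Monte-Carlo KL oracle, the finite-difference gradient check and
checkpoint serialization."""

import numpy as np
import pytest

import methylnet as mn
from methylnet.model import (
    EPS, LatentPosterior, NetworkState, classifier_loss, loss_and_grads,
)


def zero_state(cfg: mn.ModelConfig) -> NetworkState:
    state = mn.init_state(cfg)
    return NetworkState({k: np.zeros_like(v) for k, v in state.params.items()})


TOY = mn.ModelConfig(n_features=2, hidden_size=3, latent_size=2, n_classes=4,
                     classifier_hidden=3, seed=0)


class TestEncode:
    def test_all_zero_network_maps_to_standard_posterior(self):
        post = mn.encode(zero_state(TOY), np.array([0.3, 0.7]))
        np.testing.assert_array_equal(post.mu, [0.0, 0.0])
        np.testing.assert_array_equal(post.logvar, [0.0, 0.0])

    def test_deterministic_given_state(self):
        state = mn.init_state(TOY)
        x = np.array([0.2, 0.9])
        a, b = mn.encode(state, x), mn.encode(state, x)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.logvar, b.logvar)

    def test_hand_computed_affine_relu_affine(self):
        cfg = mn.ModelConfig(n_features=1, hidden_size=2, latent_size=1,
                             n_classes=2, classifier_hidden=1)
        state = zero_state(cfg)
        state.params["enc_w1"] = np.array([[2.0, -1.0]])   # h = relu([2x, -x])
        state.params["enc_b1"] = np.array([0.5, 0.0])
        state.params["enc_wmu"] = np.array([[1.0], [1.0]])
        state.params["enc_bmu"] = np.array([0.25])
        # x=1: h = relu([2.5, -1]) = [2.5, 0]; mu = 2.5 + 0.25
        post = mn.encode(state, np.array([1.0]))
        assert post.mu[0] == pytest.approx(2.75)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="features"):
            mn.encode(mn.init_state(TOY), np.zeros(5))


class TestSampleLatent:
    def test_zero_variance_limit_returns_mu(self):
        post = LatentPosterior(np.array([1.5, -2.0]), np.array([-1e10, -1e10]))
        z = mn.sample_latent(post, np.random.default_rng(0))
        np.testing.assert_allclose(z, post.mu)

    def test_standard_posterior_moments(self):
        post = LatentPosterior(np.zeros(1), np.zeros(1))
        rng = np.random.default_rng(42)
        draws = np.array([mn.sample_latent(post, rng)[0] for _ in range(10_000)])
        se_mean = 1 / np.sqrt(len(draws))
        assert abs(draws.mean()) < 3 * se_mean
        se_var = np.sqrt(2 / (len(draws) - 1))
        assert abs(draws.var(ddof=1) - 1) < 3 * se_var

    def test_same_seed_identical_draw(self):
        post = LatentPosterior(np.array([0.5]), np.array([0.2]))
        z1 = mn.sample_latent(post, np.random.default_rng(7))
        z2 = mn.sample_latent(post, np.random.default_rng(7))
        np.testing.assert_array_equal(z1, z2)


class TestDecodeClassify:
    def test_zero_network_decodes_to_half(self):
        xhat = mn.decode(zero_state(TOY), np.zeros(2))
        np.testing.assert_allclose(xhat, [0.5, 0.5])

    def test_hand_computed_decoder(self):
        cfg = mn.ModelConfig(n_features=2, hidden_size=1, latent_size=1,
                             n_classes=2, classifier_hidden=1)
        state = zero_state(cfg)
        state.params["dec_w1"] = np.array([[3.0]])
        state.params["dec_w2"] = np.array([[1.0, -1.0]])
        # z=0.5: h = relu(1.5); out = sigmoid([1.5, -1.5])
        xhat = mn.decode(state, np.array([0.5]))
        np.testing.assert_allclose(xhat, [1 / (1 + np.exp(-1.5)), 1 / (1 + np.exp(1.5))])

    def test_decoder_outputs_strictly_inside_unit_interval(self):
        state = mn.init_state(TOY)
        for z in np.random.default_rng(1).normal(size=(20, 2)) * 50:
            xhat = mn.decode(state, z)
            assert np.all((xhat > 0) & (xhat < 1))

    def test_zero_network_classifies_uniformly(self):
        probs = mn.classify(zero_state(TOY), np.zeros(2))
        np.testing.assert_allclose(probs, [0.25] * 4)

    def test_probabilities_sum_to_one(self):
        state = mn.init_state(TOY)
        for z in np.random.default_rng(2).normal(size=(20, 2)) * 10:
            probs = mn.classify(state, z)
            assert probs.sum() == pytest.approx(1.0, abs=1e-6)
            assert np.all(probs >= 0)

    def test_two_class_closed_form_softmax(self):
        cfg = mn.ModelConfig(n_features=1, hidden_size=1, latent_size=1,
                             n_classes=2, classifier_hidden=1)
        state = zero_state(cfg)
        state.params["clf_w1"] = np.array([[1.0]])
        state.params["clf_w2"] = np.array([[1.0, 0.0]])
        # z=1: hc = 1; logits (1, 0) -> (e/(e+1), 1/(e+1))
        probs = mn.classify(state, np.array([1.0]))
        e = np.e
        np.testing.assert_allclose(probs, [e / (e + 1), 1 / (e + 1)])


class TestLosses:
    def test_kl_zero_at_standard_normal(self):
        assert mn.kl_divergence(LatentPosterior(np.zeros(3), np.zeros(3))) == 0.0

    def test_kl_closed_form_unit_mean(self):
        assert mn.kl_divergence(LatentPosterior(np.array([1.0]), np.array([0.0]))) == \
            pytest.approx(0.5)

    def test_kl_nonnegative_random_posteriors(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            post = LatentPosterior(rng.normal(size=4), rng.normal(size=4))
            assert mn.kl_divergence(post) >= 0

    def test_kl_matches_monte_carlo_within_one_percent(self):
        # MC estimate of E_q[log q(z) - log p(z)] at 1e6 draws
        rng = np.random.default_rng(12)
        mu, logvar = np.array([0.7, -0.4]), np.array([0.3, -0.5])
        sd = np.exp(logvar / 2)
        z = mu + sd * rng.standard_normal((1_000_000, 2))
        log_q = -0.5 * (((z - mu) / sd) ** 2 + logvar + np.log(2 * np.pi))
        log_p = -0.5 * (z**2 + np.log(2 * np.pi))
        mc = float(np.mean((log_q - log_p).sum(axis=1)))
        exact = mn.kl_divergence(LatentPosterior(mu, logvar))
        assert mc == pytest.approx(exact, rel=0.01)

    def test_reconstruction_closed_forms(self):
        assert mn.reconstruction_loss(np.array([0.5, 0.5]), np.array([0.5, 0.5])) == \
            pytest.approx(2 * np.log(2))
        assert mn.reconstruction_loss(np.array([1.0]), np.array([0.5])) == \
            pytest.approx(np.log(2))

    def test_reconstruction_minimized_at_truth(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0.05, 0.95, size=5)
        at_truth = mn.reconstruction_loss(x, x)
        for _ in range(50):
            other = np.clip(x + rng.normal(0, 0.1, size=5), 0.01, 0.99)
            assert mn.reconstruction_loss(x, other) >= at_truth - 1e-12

    def test_reconstruction_guards_exact_zero_one(self):
        loss = mn.reconstruction_loss(np.array([1.0]), np.array([1.0]))
        assert np.isfinite(loss) and loss == pytest.approx(-np.log(1 - EPS), abs=1e-6)

    def test_total_loss_arithmetic(self):
        cfg = mn.ModelConfig(n_features=1)
        assert mn.total_loss(10.0, 2.0, 1.0, cfg) == pytest.approx(1.12)

    def test_total_loss_degenerate_weights(self):
        pure_clf = mn.ModelConfig(n_features=1, vae_weight=0.0)
        assert mn.total_loss(10.0, 2.0, 1.0, pure_clf) == 1.0
        pure_vae = mn.ModelConfig(n_features=1, clf_weight=0.0)
        assert mn.total_loss(10.0, 2.0, 1.0, pure_vae) == pytest.approx(0.12)


class TestGradients:
    @pytest.mark.parametrize("reduction,with_noise", [
        ("sum", True), ("sum", False), ("mean", True),
    ])
    def test_analytic_matches_central_finite_differences(self, reduction, with_noise):
        """Joint-loss gradients on a 6-feature / 2-latent / 3-class toy net."""
        cfg = mn.ModelConfig(n_features=6, hidden_size=5, latent_size=2,
                             n_classes=3, classifier_hidden=4, seed=3,
                             recon_reduction=reduction)
        rng = np.random.default_rng(10)
        state = mn.init_state(cfg, rng)
        x = rng.uniform(0.05, 0.95, size=(4, 6))
        y = np.eye(3)[rng.integers(0, 3, size=4)]
        eps_noise = rng.standard_normal((4, 2)) if with_noise else None

        _, grads = loss_and_grads(state, x, y, cfg, eps_noise)

        h = 1e-5
        for name, w in state.params.items():
            flat = w.ravel()
            idx = rng.choice(flat.size, size=min(10, flat.size), replace=False)
            for k in idx:
                orig = flat[k]
                flat[k] = orig + h
                up, _ = loss_and_grads(state, x, y, cfg, eps_noise)
                flat[k] = orig - h
                dn, _ = loss_and_grads(state, x, y, cfg, eps_noise)
                flat[k] = orig
                fd = (up["total"] - dn["total"]) / (2 * h)
                an = grads[name].ravel()[k]
                denom = max(abs(fd), abs(an), 1e-8)
                assert abs(fd - an) / denom <= 1e-4, (name, k, fd, an)


class TestSerialization:
    def test_checkpoint_round_trip_preserves_outputs_bitwise(self, tmp_path):
        cfg = mn.ModelConfig(n_features=8, hidden_size=6, latent_size=3,
                             n_classes=4, classifier_hidden=5, seed=2)
        state = mn.init_state(cfg)
        path = tmp_path / "model.ckpt"
        mn.save_checkpoint(state, cfg, path)
        loaded, cfg2 = mn.load_checkpoint(path)
        assert cfg2 == cfg
        for k, v in state.params.items():
            np.testing.assert_array_equal(v, loaded.params[k])
        x = np.random.default_rng(0).uniform(size=8)
        np.testing.assert_array_equal(mn.predict_proba(state, x),
                                      mn.predict_proba(loaded, x))


class TestClassifierLoss:
    def test_one_hot_cross_entropy(self):
        y = np.array([1.0, 0.0])
        probs = np.array([0.25, 0.75])
        assert classifier_loss(y, probs) == pytest.approx(-np.log(0.25))
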