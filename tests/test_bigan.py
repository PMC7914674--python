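"""Model core: losses against brute-force oracles, the adaptive prior,
shape/normalisation contracts, and gradient correctness of the objectives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nirgan import (
    LatentPrior,
    TrainConfig,
    build_model,
    classify,
    discriminate,
    encode,
    generate,
    loss_classification,
    loss_discriminator,
    loss_generator,
    pretrain_classifier,
    sample_latent,
    update_prior,
)
from nirgan.nn import MLP, Dense, ReLU, Sigmoid, sigmoid, softmax


# ---------------------------------------------------------------------------
# independent scalar-by-scalar oracles


def oracle_classification(c, c_hat, eps=1e-7):
    total = 0.0
    for ci, pi in zip(np.ravel(c), np.ravel(c_hat)):
        pi = min(max(pi, eps), 1.0)
        total -= ci * math.log(pi)
    return total


def oracle_discriminator(y, y_hat, cls_loss, eps=1e-7):
    total = 0.0
    for yi, pi in zip(np.ravel(y), np.ravel(y_hat)):
        pi = min(max(pi, eps), 1.0 - eps)
        total -= yi * math.log(pi) + (1.0 - yi) * math.log(1.0 - pi)
    return total + cls_loss


def oracle_generator(y_hat, cls_loss, eps=1e-7):
    total = 0.0
    for pi in np.ravel(y_hat):
        total -= math.log(min(max(pi, eps), 1.0))
    return total + cls_loss


class TestLossHandValues:
    def test_classification_perfect_prediction_is_zero(self):
        c = np.zeros(5)
        c[2] = 1.0
        c_hat = np.zeros(5)
        c_hat[2] = 1.0
        assert loss_classification(c, c_hat) == pytest.approx(0.0, abs=1e-12)

    def test_classification_uniform_over_29(self):
        c = np.zeros(29)
        c[0] = 1.0
        assert loss_classification(c, np.full(29, 1 / 29)) == pytest.approx(
            math.log(29), abs=1e-9)

    def test_classification_two_class_hand_value(self):
        assert loss_classification([1, 0], [0.8, 0.2]) == pytest.approx(
            -math.log(0.8), abs=1e-12)

    def test_discriminator_perfect_is_zero(self):
        y = np.array([1.0, 0.0])
        # exact match is clipped away from 0/1 by eps; tolerance reflects it
        assert loss_discriminator(y, y, 0.0) == pytest.approx(0.0, abs=1e-5)

    def test_discriminator_coin_flip(self):
        val = loss_discriminator([1, 0], [0.5, 0.5], 0.0)
        assert val == pytest.approx(2 * math.log(2), abs=1e-12)

    def test_discriminator_additive_cls_term(self):
        base = loss_discriminator([1, 0], [0.5, 0.5], 0.0)
        assert loss_discriminator([1, 0], [0.5, 0.5], 0.5) == pytest.approx(
            base + 0.5, abs=1e-12)

    def test_generator_confident_is_zero(self):
        assert loss_generator([1.0], 0.0) == pytest.approx(0.0, abs=1e-5)

    def test_generator_coin_flip(self):
        assert loss_generator([0.5, 0.5], 0.0) == pytest.approx(
            2 * math.log(2), abs=1e-12)

    def test_generator_monotone_in_confidence(self):
        lo = loss_generator([0.9, 0.9], 0.0)
        hi = loss_generator([0.4, 0.4], 0.0)
        assert hi > lo

    def test_empty_batches_rejected(self):
        with pytest.raises(ValueError):
            loss_discriminator([], [], 0.0)
        with pytest.raises(ValueError):
            loss_generator([], 0.0)
        with pytest.raises(ValueError):
            loss_classification([1, 0], [1.0])


@settings(max_examples=250, deadline=None, derandomize=True)
@given(data=st.data())
def test_losses_match_bruteforce_oracles(data):
    """All three losses agree with scalar-by-scalar oracles to 1e-10."""
    n = data.draw(st.integers(1, 8))
    probs = st.floats(1e-6, 1 - 1e-6)
    y_hat = np.array(data.draw(st.lists(probs, min_size=n, max_size=n)))
    y = np.array(data.draw(st.lists(st.sampled_from([0.0, 1.0]),
                                    min_size=n, max_size=n)))
    cls = data.draw(st.floats(0, 10))
    k = data.draw(st.integers(2, 6))
    raw = np.array(data.draw(st.lists(st.floats(1e-6, 1), min_size=k, max_size=k)))
    c_hat = raw / raw.sum()
    c = np.zeros(k)
    c[data.draw(st.integers(0, k - 1))] = 1.0
    assert loss_classification(c, c_hat) == pytest.approx(
        oracle_classification(c, c_hat), abs=1e-10)
    assert loss_discriminator(y, y_hat, cls) == pytest.approx(
        oracle_discriminator(y, y_hat, cls), abs=1e-10)
    assert loss_generator(y_hat, cls) == pytest.approx(
        oracle_generator(y_hat, cls), abs=1e-10)


# ---------------------------------------------------------------------------
# gradient checks of the three objectives through tiny networks


def _fd_check(loss_fn, net, rtol=1e-4):
    """Compare net's analytic parameter gradients of loss_fn against
    central finite differences."""
    analytic = [(o, g, getattr(o, g).copy()) for o, _, g in net.params()]
    for (owner, pname, gname), (_, _, ga) in zip(net.params(), analytic):
        p = getattr(owner, pname)
        num = np.zeros_like(p)
        it = np.nditer(p, flags=["multi_index"])
        while not it.finished:
            i = it.multi_index
            old = p[i]
            p[i] = old + 1e-6
            fp = loss_fn()
            p[i] = old - 1e-6
            fm = loss_fn()
            p[i] = old
            num[i] = (fp - fm) / 2e-6
            it.iternext()
        denom = np.maximum(np.abs(ga) + np.abs(num), 1e-6)
        assert np.max(np.abs(ga - num) / denom) < rtol, pname


def test_classification_gradient_through_tiny_network():
    rng = np.random.default_rng(0)
    net = MLP([Dense(4, 3, rng), Sigmoid(), Dense(3, 2, rng)])
    x = rng.normal(size=(5, 4))
    y = np.zeros((5, 2))
    y[np.arange(5), rng.integers(0, 2, 5)] = 1.0

    def loss():
        return loss_classification(y, softmax(net.forward(x, train=True)))

    p = softmax(net.forward(x, train=True))
    net.backward(p - y)           # analytic softmax cross-entropy gradient
    _fd_check(loss, net)


def test_discriminator_gradient_through_tiny_network():
    rng = np.random.default_rng(1)
    net = MLP([Dense(4, 3, rng), ReLU(), Dense(3, 1, rng)])
    x = rng.normal(size=(6, 4))
    y = np.array([1.0, 0, 1, 0, 1, 0])

    def loss():
        p = sigmoid(net.forward(x, train=True)[:, 0])
        return loss_discriminator(y, p, 0.0)

    p = sigmoid(net.forward(x, train=True)[:, 0])
    net.backward((p - y)[:, None])
    _fd_check(loss, net)


def test_generator_gradient_through_tiny_network():
    rng = np.random.default_rng(2)
    net = MLP([Dense(4, 3, rng), ReLU(), Dense(3, 1, rng)])
    x = rng.normal(size=(6, 4))

    def loss():
        p = sigmoid(net.forward(x, train=True)[:, 0])
        return loss_generator(p, 0.0)

    p = sigmoid(net.forward(x, train=True)[:, 0])
    net.backward((p - 1.0)[:, None])
    _fd_check(loss, net)


# ---------------------------------------------------------------------------
# adaptive prior


class TestUpdatePrior:
    def _prior(self, dim=1, floor=1e-6):
        return LatentPrior(mu=np.zeros(dim), sigma=np.ones(dim), sigma_floor=floor)

    def test_sigma_one_before_five_records(self):
        p = self._prior(dim=3)
        for i in range(4):
            p = update_prior(p, np.full(3, float(i)))
            np.testing.assert_array_equal(p.sigma, np.ones(3))

    def test_hand_computed_sqrt5(self):
        """History of five zeros, new mean 2: sigma = sqrt(5*4/4) = sqrt(5)."""
        p = self._prior()
        for _ in range(5):
            p = update_prior(p, np.array([0.0]))
        p = update_prior(p, np.array([2.0]))
        assert p.sigma[0] == pytest.approx(math.sqrt(5.0), abs=1e-9)

    def test_degenerate_history_floors(self):
        p = self._prior(floor=1e-6)
        for _ in range(6):
            p = update_prior(p, np.array([3.0]))
        assert p.sigma[0] == pytest.approx(1e-6)

    def test_history_capped_at_five(self):
        p = self._prior()
        for i in range(12):
            p = update_prior(p, np.array([float(i)]))
        assert len(p.history) == 5
        assert p.history[-1][0] == 11.0

    def test_mu_tracks_latest_encoding(self):
        p = self._prior(dim=2)
        p = update_prior(p, np.array([1.0, -1.0]))
        np.testing.assert_array_equal(p.mu, [1.0, -1.0])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            update_prior(self._prior(dim=2), np.zeros(3))


class TestSampleLatent:
    def test_floor_sigma_returns_mu(self):
        p = LatentPrior(mu=np.arange(4.0), sigma=np.full(4, 1e-12))
        z = sample_latent(p, np.random.default_rng(0))
        np.testing.assert_allclose(z, p.mu, atol=1e-9)

    def test_moments_match_prior(self):
        mu = np.array([1.0, -2.0])
        sg = np.array([0.5, 2.0])
        p = LatentPrior(mu=mu, sigma=sg)
        rng = np.random.default_rng(1)
        draws = np.stack([sample_latent(p, rng) for _ in range(10_000)])
        se = sg / np.sqrt(10_000)
        assert np.all(np.abs(draws.mean(0) - mu) < 4 * se)
        assert np.all(np.abs(draws.std(0) - sg) / sg < 0.10)


# ---------------------------------------------------------------------------
# model contracts on a small build


@pytest.fixture(scope="module")
def small_model(tiny_dataset):
    cfg = TrainConfig(n_channels=tiny_dataset.n_channels, epochs=2,
                      pretrain_epochs=5, warmup_epochs=5, n_per_class=8,
                      batch_size=16, rng_seed=0)
    return build_model(tiny_dataset.catalog, cfg)


class TestModelContracts:
    def test_classifier_output_width_equals_class_count(self, small_model):
        p = classify(small_model, np.zeros(small_model.config.n_channels))
        assert p.shape == (small_model.k,)

    def test_encode_shape_and_determinism(self, small_model):
        x = np.linspace(0, 1, small_model.config.n_channels)
        z1, z2 = encode(small_model, x), encode(small_model, x)
        assert z1.shape == (30,)
        assert np.all(np.isfinite(z1))
        np.testing.assert_array_equal(z1, z2)

    def test_generate_shape(self, small_model):
        x = generate(small_model, np.zeros(30))
        assert x.shape == (small_model.config.n_channels,)
        assert np.all(np.isfinite(x))

    def test_discriminate_in_unit_interval(self, small_model):
        rng = np.random.default_rng(0)
        for _ in range(10):
            p = discriminate(small_model,
                             rng.normal(size=small_model.config.n_channels),
                             rng.normal(size=30))
            assert 0.0 < p < 1.0

    def test_classify_normalises(self, small_model):
        rng = np.random.default_rng(1)
        p = classify(small_model, rng.normal(size=(7, small_model.config.n_channels)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_same_initial_parameters(self, tiny_dataset):
        cfg = TrainConfig(n_channels=tiny_dataset.n_channels, rng_seed=42)
        m1 = build_model(tiny_dataset.catalog, cfg)
        m2 = build_model(tiny_dataset.catalog, cfg)
        for a, b in zip(m1.E.state_arrays().values(), m2.E.state_arrays().values()):
            np.testing.assert_array_equal(a, b)

    def test_latent_dimensions_enforced(self, small_model):
        with pytest.raises(ValueError):
            generate(small_model, np.zeros(31))
        with pytest.raises(ValueError):
            encode(small_model, np.zeros(small_model.config.n_channels + 1))

    def test_non_finite_input_rejected(self, small_model):
        x = np.zeros(small_model.config.n_channels)
        x[0] = np.nan
        with pytest.raises(ValueError):
            classify(small_model, x)


class TestPretrainClassifier:
    def test_zero_epochs_leaves_parameters(self, tiny_dataset, tiny_split):
        cfg = TrainConfig(n_channels=tiny_dataset.n_channels, rng_seed=1,
                          n_per_class=8, batch_size=16)
        model = build_model(tiny_dataset.catalog, cfg)
        before = {k: v.copy() for k, v in model.C.state_arrays().items()}
        pretrain_classifier(model, tiny_dataset, tiny_split, epochs=0)
        for k, v in model.C.state_arrays().items():
            np.testing.assert_array_equal(before[k], v)

    def test_loss_decreases_and_is_deterministic(self, tiny_dataset, tiny_split):
        def run():
            cfg = TrainConfig(n_channels=tiny_dataset.n_channels, rng_seed=2,
                              n_per_class=16, batch_size=16)
            model = build_model(tiny_dataset.catalog, cfg)
            return pretrain_classifier(model, tiny_dataset, tiny_split, epochs=15)

        t1, t2 = run(), run()
        assert t1 == t2
        assert t1[-1] < t1[0]
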