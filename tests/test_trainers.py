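import numpy as np
import pytest

from activeclean import (
    CoTeachingConfig,
    MixtureSpec,
    NoiseConfig,
    SoftmaxClassifier,
    SSLLinearConfig,
    coteaching_select,
    ensemble_posterior,
    finetune_on_corrected,
    forget_rate_schedule,
    generate_mixture_dataset,
    make_noisy_benchmark,
    score_table,
    squash_logits,
    train_coteaching,
    train_ssl_linear,
    train_vanilla,
)


def _separable(n=200, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.standard_normal((n, 2)) + 6.0 * np.stack([y, 1 - y], axis=1)
    return X, y


class TestSquash:
    def test_values(self):
        assert squash_logits(0.0, 4.0) == pytest.approx(0.0)
        assert squash_logits(5.0, 4.0) == pytest.approx(3.3931346, abs=1e-6)  # 4 tanh(1.25)
        assert squash_logits(1e6, 4.0) == pytest.approx(4.0, abs=1e-6)

    def test_odd_increasing_bounded(self):
        z = np.linspace(-20, 20, 101)
        g = squash_logits(z, 3.0)
        assert np.allclose(squash_logits(-z, 3.0), -g)
        assert np.all(np.diff(g) > 0)
        assert np.all(np.abs(g) < 3.0)

    def test_rejects_nonpositive_alpha(self):
        with pytest.raises(ValueError):
            squash_logits(1.0, 0.0)


class TestCoteachingSelect:
    def test_small_loss_half(self):
        kept = coteaching_select([0.1, 0.2, 5.0, 6.0], 0.5)
        assert kept.tolist() == [0, 1]

    def test_zero_forget_keeps_all(self):
        assert coteaching_select([3.0, 1.0, 2.0], 0.0).tolist() == [0, 1, 2]

    def test_ties_resolve_to_lowest_index(self):
        assert coteaching_select([1.0, 1.0, 1.0, 1.0], 0.25).tolist() == [0, 1, 2]

    def test_kept_size_is_ceil(self):
        for R in (0.0, 0.3, 0.5, 0.9):
            kept = coteaching_select(np.arange(7, dtype=float), R)
            assert kept.size == int(np.ceil((1 - R) * 7))

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            coteaching_select([1.0], 1.0)
        with pytest.raises(ValueError):
            coteaching_select([np.inf], 0.1)


def test_forget_rate_schedule():
    assert forget_rate_schedule(0, 10, 0.4) == 0.0
    assert forget_rate_schedule(10, 10, 0.4) == pytest.approx(0.4)
    assert forget_rate_schedule(25, 10, 0.4) == pytest.approx(0.4)
    assert forget_rate_schedule(5, 10, 0.4) == pytest.approx(0.2)


class TestVanilla:
    def test_separable_data_high_accuracy(self):
        X, y = _separable()
        model = train_vanilla(None, X, y, seed=0)
        acc = np.mean(np.argmax(model.predict_posterior(X), axis=1) == y)
        assert acc >= 0.99

    def test_deterministic_per_seed(self):
        X, y = _separable()
        p1 = train_vanilla(None, X, y, seed=3).predict_posterior(X)
        p2 = train_vanilla(None, X, y, seed=3).predict_posterior(X)
        assert np.allclose(p1, p2, atol=1e-9)

    def test_constant_features_recover_class_priors(self):
        rng = np.random.default_rng(0)
        y = (rng.random(600) < 0.3).astype(int)  # ~30% class 1
        X = np.ones((600, 2))
        model = train_vanilla(None, X, y, seed=0)
        posts = model.predict_posterior(X)
        assert np.allclose(posts, posts[0], atol=1e-6)
        assert posts[0, 1] == pytest.approx(np.mean(y), abs=0.02)

    def test_posteriors_are_simplices(self):
        X, y = _separable()
        posts = train_vanilla(None, X, y).predict_posterior(X)
        assert np.all(posts >= 0)
        assert np.allclose(posts.sum(axis=1), 1.0)


class TestCoTeaching:
    def test_deterministic_seeds(self):
        X, y = _separable()
        cfg = CoTeachingConfig(eta_hat=0.2, steps=50, seeds=(1, 2))
        pair_a = train_coteaching(SoftmaxClassifier(2, 2), SoftmaxClassifier(2, 2), X, y, cfg)
        pair_b = train_coteaching(SoftmaxClassifier(2, 2), SoftmaxClassifier(2, 2), X, y, cfg)
        assert np.allclose(ensemble_posterior(pair_a, X), ensemble_posterior(pair_b, X))

    def test_rank_separation_under_symmetric_noise(self):
        # the ensemble posterior should give mislabelled samples higher phi
        # than correct ones (AUC > 0.5) across seeds
        for seed in range(5):
            base = generate_mixture_dataset(MixtureSpec(n=400, C=2, separation=5.0, seed=seed))
            noisy, _ = make_noisy_benchmark(base, NoiseConfig("symmetric", eta=0.3, seed=seed + 50))
            labels = np.argmax(noisy.counts, axis=1)
            cfg = CoTeachingConfig(eta_hat=0.3, steps=200, seeds=(seed, seed + 1))
            pair = train_coteaching(SoftmaxClassifier(2, 2), SoftmaxClassifier(2, 2),
                                    noisy.features, labels, cfg)
            posts = ensemble_posterior(pair, noisy.features)
            phi = score_table(noisy.counts, posts)["phi"]
            mis = labels != noisy.true_classes
            # rank-separation AUC via the Mann-Whitney statistic
            from scipy.stats import rankdata

            ranks = rankdata(phi)
            auc = (ranks[mis].sum() - mis.sum() * (mis.sum() + 1) / 2) / (
                mis.sum() * (~mis).sum())
            assert auc > 0.5

    def test_eta_zero_degenerates_to_full_batches(self):
        X, y = _separable(80)
        cfg = CoTeachingConfig(eta_hat=0.0, steps=40, seeds=(0, 1))
        b1, b2 = train_coteaching(SoftmaxClassifier(2, 2), SoftmaxClassifier(2, 2), X, y, cfg)
        acc1 = np.mean(np.argmax(b1.predict_posterior(X), axis=1) == y)
        assert acc1 > 0.9

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CoTeachingConfig(eta_hat=1.0)
        with pytest.raises(ValueError):
            CoTeachingConfig(eta_hat=0.2, T_k=0)
        with pytest.raises(ValueError):
            CoTeachingConfig(eta_hat=0.2, seeds=(3, 3))


def test_ensemble_posterior_means():
    X, y = _separable(100)
    m = train_vanilla(None, X, y, seed=0)
    same = ensemble_posterior((m, m), X)
    assert np.allclose(same, m.predict_posterior(X))
    m2 = train_vanilla(None, X, 1 - y, seed=1)
    mixed = ensemble_posterior((m, m2), X)
    assert np.allclose(mixed, 0.5 * (m.predict_posterior(X) + m2.predict_posterior(X)))


class TestSSLLinear:
    def test_limit_case_matches_reference_logistic_fit(self):
        # eps=0 and alpha=inf reduce to a plain multinomial logistic fit; with
        # 3+ classes the reference solver minimises the same softmax objective
        # with the same L2 penalty on the full coefficient matrix
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(4)
        y = rng.integers(0, 3, 150)
        X = rng.standard_normal((150, 3)) + 3.0 * np.eye(3)[y]
        head = SoftmaxClassifier(3, 3, alpha=None, smoothing=0.0, l2=1.0, seed=0)
        head.fit(X, y, maxiter=3000)
        ref = sklearn.LogisticRegression(C=1.0, tol=1e-10, max_iter=5000).fit(X, y)
        assert np.max(np.abs(head.predict_posterior(X) - ref.predict_proba(X))) < 1e-3

    def test_squash_bounds_confidence(self):
        X, y = _separable(150)
        cfg = SSLLinearConfig(alpha=2.0, smoothing=0.0, seed=0)
        posts = train_ssl_linear(X, y, cfg).predict_posterior(X)
        from scipy.special import softmax

        bound = softmax([2.0, -2.0])[0]
        assert posts.max() <= bound + 1e-9

    def test_deterministic(self):
        X, y = _separable(100)
        cfg = SSLLinearConfig(alpha=10.0, smoothing=0.1, seed=2)
        p1 = train_ssl_linear(X, y, cfg).predict_posterior(X)
        p2 = train_ssl_linear(X, y, cfg).predict_posterior(X)
        assert np.allclose(p1, p2)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SSLLinearConfig(alpha=-1.0)
        with pytest.raises(ValueError):
            SSLLinearConfig(smoothing=1.0)


class TestFinetune:
    def test_zero_epochs_is_noop(self):
        base = generate_mixture_dataset(MixtureSpec(n=100, C=2, separation=5.0, seed=0))
        noisy, _ = make_noisy_benchmark(base, NoiseConfig("symmetric", eta=0.3, seed=1))
        labels = np.argmax(noisy.counts, axis=1)
        model = train_vanilla(None, noisy.features, labels, seed=0)
        W = model.W.copy()
        finetune_on_corrected(model, noisy, epochs=0)
        assert np.array_equal(model.W, W)

    def test_corrected_labels_improve_training_accuracy(self):
        for seed in range(5):
            base = generate_mixture_dataset(MixtureSpec(n=300, C=2, separation=5.0, seed=seed))
            noisy, _ = make_noisy_benchmark(base, NoiseConfig("symmetric", eta=0.3, seed=seed + 9))
            labels = np.argmax(noisy.counts, axis=1)
            model = train_vanilla(None, noisy.features, labels, seed=seed)
            acc_before = np.mean(
                np.argmax(model.predict_posterior(noisy.features), axis=1) == noisy.true_classes)
            corrected = noisy.copy()
            corrected.counts = np.eye(2, dtype=int)[corrected.true_classes] * 3
            finetune_on_corrected(model, corrected, epochs=300)
            acc_after = np.mean(
                np.argmax(model.predict_posterior(noisy.features), axis=1) == noisy.true_classes)
            assert acc_after >= acc_before - 1e-9

    def test_requires_fitted_backend(self):
        model = SoftmaxClassifier(2, 2)
        with pytest.raises(ValueError):
            finetune_on_corrected(model, None, epochs=10)


def test_rank_separation_for_all_trainers():
    # mean phi of mislabelled samples exceeds that of correct samples for
    # vanilla, co-teaching, and the SSL-linear head (5 seeds each)
    for seed in range(5):
        base = generate_mixture_dataset(MixtureSpec(n=300, C=3, separation=5.0, seed=seed))
        noisy, _ = make_noisy_benchmark(base, NoiseConfig("symmetric", eta=0.25, seed=seed + 77))
        labels = np.argmax(noisy.counts, axis=1)
        mis = labels != noisy.true_classes
        X = noisy.features

        posteriors = {}
        posteriors["vanilla"] = train_vanilla(None, X, labels, seed=seed).predict_posterior(X)
        cfg = CoTeachingConfig(eta_hat=0.25, steps=200, seeds=(seed, seed + 1))
        pair = train_coteaching(SoftmaxClassifier(X.shape[1], 3),
                                SoftmaxClassifier(X.shape[1], 3), X, labels, cfg)
        posteriors["coteaching"] = ensemble_posterior(pair, X)
        posteriors["ssl_linear"] = train_ssl_linear(
            X, labels, SSLLinearConfig(seed=seed)).predict_posterior(X)

        for name, posts in posteriors.items():
            phi = score_table(noisy.counts, posts)["phi"]
            assert phi[mis].mean() > phi[~mis].mean(), name
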