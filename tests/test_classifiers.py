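import numpy as np
import pytest
from scipy import stats

from habitatmap.classifiers import (
    classify_volume,
    fit_classifier,
    fit_gaussian_nb,
    silverman_bandwidth,
)
from habitatmap.parameter_maps import normalize_features
from habitatmap.volumes_io import MaskVolume


def brute_force_posteriors(X, means, variances, priors):
    """Independent Bayes-rule oracle: explicit per-feature density products.

    Deliberately long-hand (scipy normal pdf per feature, plain product,
    plain normalization) so it shares no code path with the model.
    """
    X = np.atleast_2d(X)
    n, C = X.shape[0], means.shape[0]
    post = np.zeros((n, C))
    for i in range(n):
        for c in range(C):
            density = priors[c]
            for d in range(X.shape[1]):
                density *= stats.norm.pdf(X[i, d], loc=means[c, d],
                                          scale=np.sqrt(variances[c, d]))
            post[i, c] = density
        post[i] /= post[i].sum()
    return post


def cluster_data(rng, means, n_per_class=100, sd=0.03):
    xs, ys = [], []
    for c, mu in means.items():
        xs.append(rng.normal(mu, sd, size=(n_per_class, 3)))
        ys.append(np.full(n_per_class, c))
    return np.clip(np.vstack(xs), 0, 1), np.concatenate(ys)


class TestGaussianNBFit:
    def test_recovers_means_at_large_n(self):
        rng = np.random.default_rng(0)
        X, y = cluster_data(rng, {1: [0.1, 0.5, 0.5], 2: [0.9, 0.5, 0.5]},
                            n_per_class=500, sd=0.003)
        model = fit_gaussian_nb((X, y))
        assert abs(model.means[0, 0] - 0.1) < 1e-3
        assert abs(model.means[1, 0] - 0.9) < 1e-3

    def test_constant_feature_gets_floor_not_zero(self):
        X = np.column_stack([np.full(20, 0.4), np.linspace(0, 1, 20),
                             np.linspace(0, 1, 20)])
        y = np.array([1] * 10 + [2] * 10)
        model = fit_gaussian_nb((X, y))
        assert model.variances[:, 0].min() == pytest.approx(model.var_floor)
        assert model.var_floor > 0

    def test_empirical_priors(self):
        rng = np.random.default_rng(1)
        X = rng.random((400, 3))
        y = np.array([1] * 100 + [2] * 300)
        model = fit_gaussian_nb((X, y))
        np.testing.assert_allclose(model.priors, [0.25, 0.75])

    def test_single_sample_class_rejected(self):
        X = np.random.default_rng(2).random((3, 3))
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_gaussian_nb((X, np.array([1, 1, 2])))

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        X, y = cluster_data(rng, {1: [0.2, 0.2, 0.2], 3: [0.8, 0.8, 0.8]})
        model = fit_gaussian_nb((X, y))
        from habitatmap.classifiers import GaussianNBModel
        back = GaussianNBModel.from_json(model.to_json(tmp_path / "m.json"))
        np.testing.assert_array_equal(back.class_ids, model.class_ids)
        np.testing.assert_allclose(back.means, model.means)
        np.testing.assert_allclose(back.variances, model.variances)


class TestNBPosteriors:
    def test_matches_brute_force_oracle_to_1e9(self):
        rng = np.random.default_rng(42)
        X, y = cluster_data(rng, {c: rng.random(3) for c in range(1, 6)},
                            n_per_class=60, sd=0.08)
        model = fit_gaussian_nb((X, y))
        queries = rng.random((200, 3))
        expected = brute_force_posteriors(queries, model.means, model.variances,
                                          model.priors)
        got = model.predict_proba(queries)
        assert np.abs(got - expected).max() < 1e-9

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(5)
        X, y = cluster_data(rng, {1: [0.2] * 3, 2: [0.5] * 3, 4: [0.8] * 3})
        model = fit_gaussian_nb((X, y))
        probs = model.predict_proba(rng.random((500, 3)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_midpoint_of_mirrored_classes_is_half_half(self):
        # symmetric classes, equal priors -> exact (0.5, 0.5) at the midpoint
        rng = np.random.default_rng(6)
        a = rng.normal(0, 0.05, size=(100, 3))
        X = np.vstack([0.3 + a, 0.7 - a])  # mirrored samples, equal variance
        y = np.array([1] * 100 + [2] * 100)
        model = fit_gaussian_nb((X, y))
        probs = model.predict_proba(np.array([[0.5, 0.5, 0.5]]))
        np.testing.assert_allclose(probs, [[0.5, 0.5]], atol=1e-12)

    def test_posterior_invariant_to_consistent_feature_reordering(self):
        rng = np.random.default_rng(7)
        X, y = cluster_data(rng, {1: [0.1, 0.5, 0.9], 2: [0.9, 0.1, 0.5]})
        perm = [2, 0, 1]
        queries = rng.random((50, 3))
        p1 = fit_gaussian_nb((X, y)).predict_proba(queries)
        p2 = fit_gaussian_nb((X[:, perm], y)).predict_proba(queries[:, perm])
        np.testing.assert_allclose(p1, p2, atol=1e-12)


class TestSilvermanBandwidth:
    def test_direct_arithmetic(self):
        # d=3, n=1000, sigma=0.2 -> h = 0.2 * (4/(5*1000))**(1/7)
        rng = np.random.default_rng(8)
        X = rng.normal(0.5, 0.2, size=(1000, 3))
        sigma = X.std(axis=0, ddof=1).mean()
        expected = sigma * (4.0 / (5.0 * 1000.0)) ** (1.0 / 7.0)
        assert silverman_bandwidth(X) == pytest.approx(expected, rel=1e-12)

    def test_doubling_n_shrinks_by_known_factor(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, size=(400, 3))
        h1 = silverman_bandwidth(X)
        X2 = np.vstack([X, X])  # same sigma-hat (up to ddof), doubled n
        h2 = silverman_bandwidth(X2)
        sigma1 = X.std(axis=0, ddof=1).mean()
        sigma2 = X2.std(axis=0, ddof=1).mean()
        assert h2 / h1 == pytest.approx((sigma2 / sigma1) * 2 ** (-1.0 / 7.0), rel=1e-9)

    def test_zero_variance_floors(self):
        X = np.full((50, 3), 0.3)
        assert silverman_bandwidth(X) == pytest.approx(1e-4)


class TestFamilyContracts:
    @pytest.fixture(scope="class")
    def separable(self):
        rng = np.random.default_rng(10)
        return cluster_data(rng, {1: [0.15, 0.2, 0.2], 2: [0.5, 0.8, 0.2],
                                  3: [0.85, 0.2, 0.8]}, n_per_class=80, sd=0.03)

    @pytest.mark.parametrize("family,hp", [
        ("LR", 1e3), ("SVM", 10.0), ("NN", 1e-4), ("NB", None),
        ("RF", 30), ("kNN", 15), ("KDE", 0.05), ("aKDE", None),
    ])
    def test_probability_simplex_and_separable_accuracy(self, separable, family, hp):
        X, y = separable
        model = fit_classifier(family, hp, (X, y), seed=0)
        probs = model.predict_proba(X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert (model.predict(X) == y).mean() > 0.95

    def test_knn_vote_fraction(self):
        # prediction equals the vote fraction of the N nearest samples
        rng = np.random.default_rng(11)
        X = rng.random((60, 3))
        y = np.array([1] * 20 + [2] * 40)
        model = fit_classifier("kNN", 10, (X, y), seed=0)
        q = rng.random((1, 3))
        d = np.linalg.norm(X - q, axis=1)
        votes = y[np.argsort(d)[:10]]
        expected = [(votes == 1).mean(), (votes == 2).mean()]
        np.testing.assert_allclose(model.predict_proba(q)[0], expected, atol=1e-12)

    def test_knn_with_full_training_set_predicts_frequencies(self):
        rng = np.random.default_rng(12)
        X = rng.random((50, 3))
        y = np.array([1] * 10 + [2] * 40)
        model = fit_classifier("kNN", 50, (X, y), seed=0)
        probs = model.predict_proba(rng.random((20, 3)))
        np.testing.assert_allclose(probs, np.tile([0.2, 0.8], (20, 1)), atol=1e-12)

    def test_kde_bandwidth_is_kernel_sd(self):
        # single training point: class density is one Gaussian of SD = bandwidth
        X = np.array([[0.5, 0.5, 0.5], [0.5, 0.5, 0.5],
                      [0.2, 0.2, 0.2], [0.2, 0.2, 0.2]])
        y = np.array([1, 1, 2, 2])
        h = 0.75
        model = fit_classifier("KDE", h, (X, y), seed=0)
        q = np.array([[0.4, 0.4, 0.4]])
        dens = []
        for c in (1, 2):
            Xc = X[y == c]
            k = np.exp(-np.sum((q - Xc) ** 2, axis=1) / (2 * h * h))
            dens.append(k.mean() / (2 * np.pi * h * h) ** 1.5)
        expected = np.array(dens) / sum(dens)  # equal priors
        np.testing.assert_allclose(model.predict_proba(q)[0], expected, atol=1e-9)

    def test_hyperparameter_contract_violations(self, separable):
        X, y = separable
        with pytest.raises(ValueError, match="no hyperparameter"):
            fit_classifier("NB", 3.0, (X, y))
        with pytest.raises(ValueError, match="outside range"):
            fit_classifier("kNN", 5, (X, y))
        with pytest.raises(ValueError, match="unknown family"):
            fit_classifier("GBM", 1.0, (X, y))

    @pytest.mark.parametrize("family", ["RF", "NN"])
    def test_stochastic_families_honor_seed(self, separable, family):
        X, y = separable
        hp = 30 if family == "RF" else 1e-4
        q = np.random.default_rng(13).random((30, 3))
        p1 = fit_classifier(family, hp, (X, y), seed=5).predict_proba(q)
        p2 = fit_classifier(family, hp, (X, y), seed=5).predict_proba(q)
        np.testing.assert_array_equal(p1, p2)


class TestClassifyVolume:
    def _model_and_features(self, phantom, training):
        model = fit_classifier("NB", None, training, seed=0)
        features = normalize_features(phantom.adc, phantom.ef, phantom.ff)
        return model, features

    def test_high_agreement_away_from_boundaries(self):
        # compact, well-separated classes (every between-class gap >= 6 SDs,
        # high in-class density): interior voxels classify almost perfectly
        # even with the uniform novelty class competing
        from scipy import ndimage
        from habitatmap.phantom import (ClassParams, PhantomSpec,
                                        generate_phantom, place_training_rois)
        from habitatmap.training_data import (assemble_training_set,
                                              synthesize_novelty_rois)
        params = {
            1: ClassParams(0.9e-3, 0.05e-3, 60.0, 4.0, 5.0, 2.0),
            2: ClassParams(1.0e-3, 0.05e-3, 5.0, 4.0, 5.0, 2.0),
            3: ClassParams(2.4e-3, 0.05e-3, 5.0, 4.0, 5.0, 2.0),
            4: ClassParams(1.5e-3, 0.05e-3, 0.0, 4.0, 85.0, 2.0),
        }
        phantom = generate_phantom(PhantomSpec(seed=17, class_params=params))
        rois = place_training_rois(phantom, n_per_class=2, seed=17)
        training, _ = assemble_training_set(rois, synthesize_novelty_rois(seed=17), [])
        model, features = self._model_and_features(phantom, training)
        _, habitat = classify_volume(model, features, phantom.voi)
        truth = phantom.truth.labels
        # interior = voxels whose 3x3x3 neighborhood is label-homogeneous
        interior = np.ones_like(truth, dtype=bool)
        for c in (1, 2, 3, 4):
            region = truth == c
            eroded = ndimage.binary_erosion(region, np.ones((3, 3, 3)))
            interior &= ~region | eroded
        sel = phantom.voi.membership & interior
        agreement = (habitat.labels[sel] == truth[sel]).mean()
        assert agreement >= 0.99

    def test_single_voxel_voi(self, default_phantom, phantom_training):
        model, features = self._model_and_features(default_phantom, phantom_training)
        member = np.zeros(default_phantom.grid.shape, dtype=bool)
        member[32, 32, 8] = True
        probs, habitat = classify_volume(
            model, features, MaskVolume(grid=default_phantom.grid, membership=member))
        assert habitat.valid.sum() == 1
        assert habitat.labels[32, 32, 8] in (1, 2, 3, 4, 5)

    def test_empty_voi_rejected(self, default_phantom, phantom_training):
        model, features = self._model_and_features(default_phantom, phantom_training)
        empty = MaskVolume(grid=default_phantom.grid,
                           membership=np.zeros(default_phantom.grid.shape, bool))
        with pytest.raises(ValueError, match="empty"):
            classify_volume(model, features, empty)

    def test_all_invalid_features_rejected(self, default_phantom, phantom_training):
        model, features = self._model_and_features(default_phantom, phantom_training)
        member = np.zeros(default_phantom.grid.shape, dtype=bool)
        member[0:2, 0:2, 0] = True
        features.valid[0:2, 0:2, 0] = False
        with pytest.raises(ValueError, match="no valid"):
            classify_volume(model, features,
                            MaskVolume(grid=default_phantom.grid, membership=member))

    def test_single_class_model_is_certain_everywhere(self):
        X = np.random.default_rng(14).random((30, 3))
        y = np.full(30, 3)
        model = fit_gaussian_nb((X, y))
        probs = model.predict_proba(np.random.default_rng(15).random((10, 3)))
        np.testing.assert_allclose(probs, 1.0)
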