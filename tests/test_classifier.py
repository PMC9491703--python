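"""Embedding + marginal-density-product classifier and its evaluation."""

import numpy as np
import pytest

from meibomaps import DensityProductClassifier, evaluate


def make_gaussian_classes(rng, means, cov_scale=1.0, n=60, dim=6):
    X, y = [], []
    for label, mu in means.items():
        pts = rng.normal(size=(n, dim)) * cov_scale + np.asarray(mu)
        X.append(pts)
        y.extend([label] * n)
    return np.vstack(X), np.asarray(y, dtype=object)


@pytest.fixture(scope="module")
def three_class_data():
    rng = np.random.default_rng(0)
    means = {
        "healthy": np.r_[np.zeros(6)],
        "intermediate": np.r_[4.0, 4.0, np.zeros(4)],
        "unhealthy": np.r_[8.0, 8.0, np.zeros(4)],
    }
    return make_gaussian_classes(rng, means)


class TestEmbedding:
    def test_pca_loadings_orthonormal(self, three_class_data):
        X, y = three_class_data
        clf = DensityProductClassifier(method="pca").fit(X, y)
        W = clf.embedding_.components_
        assert np.allclose(W @ W.T, np.eye(2), atol=1e-10)

    def test_pca_first_loading_tracks_dominant_direction(self):
        """Power-iteration oracle on the standardized covariance."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 8))
        X[:, 2] += 5.0 * rng.normal(size=200)  # dominant variance direction
        y = np.asarray(["a"] * 100 + ["b"] * 100, dtype=object)
        clf = DensityProductClassifier(method="pca").fit(X, y)
        Z = clf.scaler_.transform(X)
        C = Z.T @ Z / len(Z)
        v = np.ones(8)
        for _ in range(500):
            v = C @ v
            v /= np.linalg.norm(v)
        w1 = clf.embedding_.components_[0]
        assert abs(np.dot(w1, v)) > 0.99

    def test_lda_separates_linearly_separable_classes(self):
        rng = np.random.default_rng(2)
        X, y = make_gaussian_classes(
            rng, {"a": [0] * 6, "b": [10, 0, 0, 0, 0, 0]}, cov_scale=0.5)
        clf = DensityProductClassifier(method="lda").fit(X, y)
        P = clf.embedding_.transform(clf.scaler_.transform(X))
        pa, pb = P[y == "a"][:, 0], P[y == "b"][:, 0]
        # a strict margin exists between the projected classes
        assert pa.max() < pb.min() or pb.max() < pa.min()


class TestClassify:
    def test_training_cluster_interior_point(self, three_class_data):
        X, y = three_class_data
        clf = DensityProductClassifier(method="lda").fit(X, y)
        probe = np.r_[8.0, 8.0, np.zeros(4)][None, :]
        assert clf.predict(probe)[0] == "unhealthy"

    def test_tie_breaks_toward_more_severe_class(self):
        """Exact midpoint between two mirror-symmetric class densities:
        the scores tie bit-for-bit and the severe class must win."""
        x = np.linspace(-6.0, 6.0, 121)
        pdf_lo = np.exp(-0.5 * (x + 3.0) ** 2)
        pdf_hi = pdf_lo[::-1].copy()  # exact mirror: equal mass at x = 0
        shared = np.exp(-0.5 * x ** 2)
        model = {
            "method": "pca", "density": "kde",
            "severity_order": ["healthy", "intermediate", "unhealthy"],
            "classes": ["healthy", "unhealthy"], "n_components": 2,
            "feature_means": [0.0, 0.0], "feature_scales": [1.0, 1.0],
            "loadings": [[1.0, 0.0], [0.0, 1.0]], "offset": [0.0, 0.0],
            "densities": {
                "healthy": [{"x": x.tolist(), "pdf": pdf_lo.tolist()},
                            {"x": x.tolist(), "pdf": shared.tolist()}],
                "unhealthy": [{"x": x.tolist(), "pdf": pdf_hi.tolist()},
                              {"x": x.tolist(), "pdf": shared.tolist()}],
            },
        }
        clf = DensityProductClassifier.from_json_dict(model)
        mid = np.zeros((1, 2))
        scores = clf.score_samples(mid)[0]
        assert scores[0] == scores[1]
        assert clf.predict(mid)[0] == "unhealthy"

    def test_agreement_with_bayes_rule_on_known_mixture(self):
        """On equal-weight Gaussian classes with shared spherical
        covariance the Bayes rule is computable in closed form; the
        density-product classifier must agree on >= 95% of a dense grid."""
        from scipy.stats import norm

        rng = np.random.default_rng(4)
        means = {"healthy": (-4.0, 0.0), "intermediate": (0.0, 0.0),
                 "unhealthy": (4.0, 0.0)}
        X, y = make_gaussian_classes(rng, {k: list(v) for k, v in means.items()},
                                     n=4000, dim=2)
        clf = DensityProductClassifier(method="pca", density="normal").fit(X, y)
        gx, gy = np.meshgrid(np.linspace(-7, 7, 100), np.linspace(-2.5, 2.5, 100))
        grid = np.c_[gx.ravel(), gy.ravel()]
        pred = clf.predict(grid)
        labels = np.asarray(list(means))
        dens = np.stack([norm.pdf(grid[:, 0], means[c][0]) * norm.pdf(grid[:, 1], means[c][1])
                         for c in labels], axis=1)
        bayes = labels[np.argmax(dens, axis=1)]
        assert (pred == bayes).mean() >= 0.95

    def test_zero_density_everywhere_is_unclassifiable(self, three_class_data):
        X, y = three_class_data
        clf = DensityProductClassifier(method="lda", density="kde").fit(X, y)
        far = np.full((1, 6), 1e6)
        assert clf.predict(far)[0] == "unclassifiable"

    def test_deterministic_given_fitted_model(self, three_class_data):
        X, y = three_class_data
        clf = DensityProductClassifier(method="lda").fit(X, y)
        assert (clf.predict(X) == clf.predict(X)).all()

    def test_single_feature_rescaling_invariance(self, three_class_data):
        """Standardization makes predictions invariant to an affine map
        of any one feature."""
        X, y = three_class_data
        base = DensityProductClassifier(method="lda").fit(X, y).predict(X)
        X2 = X.copy()
        X2[:, 3] = 100.0 * X2[:, 3] - 7.0
        scaled = DensityProductClassifier(method="lda").fit(X2, y).predict(X2)
        assert (base == scaled).all()


class TestSklearnProtocol:
    def test_get_set_params_roundtrip(self):
        clf = DensityProductClassifier(method="pca")
        params = clf.get_params()
        assert params["method"] == "pca"
        clf.set_params(method="lda")
        assert clf.method == "lda"

    def test_clone_and_pipeline_compose(self, three_class_data):
        from sklearn.base import clone
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import MinMaxScaler

        X, y = three_class_data
        pipe = make_pipeline(MinMaxScaler(), DensityProductClassifier(method="lda"))
        pipe.fit(X, y)
        assert pipe.predict(X[:3]).shape == (3,)
        clone(pipe)


class TestJsonRoundTrip:
    @pytest.mark.parametrize("method", ["pca", "lda"])
    def test_serialized_model_predicts_identically(self, three_class_data, method):
        X, y = three_class_data
        clf = DensityProductClassifier(method=method).fit(X, y)
        restored = DensityProductClassifier.from_json_dict(clf.to_json_dict())
        assert (restored.predict(X) == clf.predict(X)).all()


class TestEvaluate:
    def test_perfect_classifier_full_marks(self, three_class_data):
        X, y = three_class_data
        rep = evaluate(DensityProductClassifier(method="lda"), X, y,
                       scheme="resubstitution", seed=0)
        for c, stats in rep["per_class"].items():
            assert stats["efficiency"] == 100.0
            assert stats["ci95"] == (100.0, 100.0)

    def test_random_labels_near_chance(self):
        """Uninformative features + random balanced labels: held-out
        accuracy sits at the 1/3 chance level (binomial 3-sigma band).
        Individual per-class recalls are not asserted: on pure noise the
        density-product rule settles near-ties systematically toward
        whichever class density came out widest, so the per-class rates
        anti-correlate while their average stays at chance."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(300, 5))
        y = rng.choice(np.asarray(["a", "b", "c"], dtype=object), size=300)
        rep = evaluate(DensityProductClassifier(method="pca", density="kde"),
                       X, y, scheme="loocv", seed=0)
        se = 100 * np.sqrt((1 / 3) * (2 / 3) / 300)
        assert rep["overall"] == pytest.approx(100 / 3, abs=3 * se)

    def test_ci_reproducible_under_seed(self, three_class_data):
        X, y = three_class_data
        a = evaluate(DensityProductClassifier(), X, y, scheme="resubstitution", seed=3)
        b = evaluate(DensityProductClassifier(), X, y, scheme="resubstitution", seed=3)
        assert a == b

    def test_single_class_raises(self):
        X = np.zeros((10, 3))
        y = np.asarray(["a"] * 10, dtype=object)
        with pytest.raises(ValueError):
            evaluate(DensityProductClassifier(), X, y)
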