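"""Scikit-learn style estimators: featurization, embedding and the
marginal-density-product classifier.

``DensityProductClassifier`` implements the classification rule used for
gland grading: standardize the 30 features, project them onto the first
two components of PCA or LDA, estimate for every class a 1D density of
each component over the training projections, and assign a query to the
class maximizing the product ``p_c(comp1) * p_c(comp2)``.  Treating the
two components as independent is what makes the classifier a simple,
inspectable thresholding device rather than a full 2D density model.

Both estimators follow the scikit-learn protocol (``fit``/``predict`` or
``transform``, ``get_params``/``set_params``, trailing-underscore fitted
attributes) and compose with sklearn pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gaussian_kde, norm
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .features import FEATURE_NAMES, extract_features
from .maps import build_maps
from .stft import WindowSpec

__all__ = [
    "MorphometricFeaturizer",
    "DensityProductClassifier",
    "evaluate",
    "SEVERITY_ORDER",
]

SEVERITY_ORDER = ("healthy", "intermediate", "unhealthy")


class MorphometricFeaturizer(TransformerMixin, BaseEstimator):
    """Stateless transformer: (image, mask) pairs -> (n, 30) feature matrix.

    Each sample is a ``(image, mask)`` tuple accepted by
    :func:`meibomaps.maps.build_maps`.  ``fit`` only validates parameters;
    all the work happens in ``transform``.
    """

    def __init__(self, sigma_r: float = 8.0, support_radius: int = 24,
                 stride: int = 10, n_q: int = 64, n_theta: int = 90,
                 dc_exclusion_bins: int = 2, n_bins: int = 64):
        self.sigma_r = sigma_r
        self.support_radius = support_radius
        self.stride = stride
        self.n_q = n_q
        self.n_theta = n_theta
        self.dc_exclusion_bins = dc_exclusion_bins
        self.n_bins = n_bins

    def _window_spec(self) -> WindowSpec:
        return WindowSpec(sigma_r=self.sigma_r, support_radius=self.support_radius,
                          stride=self.stride)

    def fit(self, X=None, y=None):
        self._window_spec()  # parameter validation
        self.n_features_out_ = len(FEATURE_NAMES)
        return self

    def transform(self, X) -> np.ndarray:
        spec = self._window_spec()
        rows = []
        for img, mask in X:
            maps = build_maps(img, mask, spec, n_q=self.n_q, n_theta=self.n_theta,
                              dc_exclusion_bins=self.dc_exclusion_bins)
            rows.append(extract_features(maps, n_bins=self.n_bins).values)
        return np.asarray(rows)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)


class _Density1D:
    """1D density: Gaussian KDE (Silverman), normal fit, or interpolated knots."""

    def __init__(self, kind: str, samples: np.ndarray | None = None,
                 knots: tuple[np.ndarray, np.ndarray] | None = None):
        self.kind = kind
        if kind == "kde":
            s = np.asarray(samples, dtype=float)
            if s.size < 3 or s.std() <= 1e-12:
                # KDE degenerates; fall back to a narrow normal
                self.kind = "normal"
                self._loc, self._scale = float(s.mean()), max(float(s.std()), 1e-6)
            else:
                self._kde = gaussian_kde(s, bw_method="silverman")
        elif kind == "normal":
            s = np.asarray(samples, dtype=float)
            self._loc, self._scale = float(s.mean()), max(float(s.std()), 1e-6)
        elif kind == "knots":
            x, y = knots
            self._kx = np.asarray(x, dtype=float)
            self._ky = np.clip(np.asarray(y, dtype=float), 0.0, None)
        else:
            raise ValueError(f"unknown density kind {kind!r}")

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "kde":
            return self._kde(np.atleast_1d(x))
        if self.kind == "normal":
            return norm.pdf(x, self._loc, self._scale)
        return np.interp(x, self._kx, self._ky, left=0.0, right=0.0)

    def knots(self, n: int = 256) -> tuple[np.ndarray, np.ndarray]:
        if self.kind == "knots":
            return self._kx, self._ky
        if self.kind == "kde":
            data = self._kde.dataset.ravel()
            pad = 4.0 * float(np.sqrt(self._kde.covariance[0, 0]))
            lo, hi = data.min() - pad, data.max() + pad
        else:
            lo, hi = self._loc - 6 * self._scale, self._loc + 6 * self._scale
        x = np.linspace(lo, hi, n)
        return x, self(x)


class DensityProductClassifier(ClassifierMixin, BaseEstimator):
    """PCA/LDA embedding to 2 components + per-class marginal-density product.

    Parameters
    ----------
    method : {'lda', 'pca'}
        Supervised (LDA) or unsupervised (PCA) 2-component embedding of
        the standardized features.
    density : {'kde', 'normal'}
        Per-class, per-component 1D density estimate: Gaussian KDE with
        Silverman bandwidth, or a plain normal fit.
    severity_order : sequence of labels
        Tie-breaking order: among equal scores the more severe class
        (later in this sequence) wins, so borderline cases are never
        under-called.  Samples with zero density under every class are
        labeled ``'unclassifiable'``.
    """

    def __init__(self, method: str = "lda", density: str = "kde",
                 severity_order: tuple = SEVERITY_ORDER):
        self.method = method
        self.density = density
        self.severity_order = severity_order

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = np.unique(y)
        if self.method not in ("lda", "pca"):
            raise ValueError(f"unknown method {self.method!r}")
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        self.scaler_ = StandardScaler().fit(X)
        Z = self.scaler_.transform(X)
        n_comp = min(2, X.shape[1], len(self.classes_) - 1 if self.method == "lda" else 2)
        if self.method == "pca":
            self.embedding_ = PCA(n_components=n_comp, svd_solver="full").fit(Z)
        else:
            self.embedding_ = LinearDiscriminantAnalysis(n_components=n_comp).fit(Z, y)
        P = self.embedding_.transform(Z)
        self.n_components_ = P.shape[1]
        self.densities_ = {
            c: [_Density1D(self.density, samples=P[y == c][:, j])
                for j in range(self.n_components_)]
            for c in self.classes_
        }
        return self

    def _severity_rank(self, label) -> int:
        order = list(self.severity_order)
        return order.index(label) if label in order else -1

    def score_samples(self, X) -> np.ndarray:
        """Per-class density products, shape (n_samples, n_classes)."""
        check_is_fitted(self, "densities_")
        X = check_array(X, dtype=float)
        P = self.embedding_.transform(self.scaler_.transform(X))
        scores = np.empty((len(P), len(self.classes_)))
        for k, c in enumerate(self.classes_):
            s = np.ones(len(P))
            for j in range(self.n_components_):
                s *= self.densities_[c][j](P[:, j])
            scores[:, k] = s
        return scores

    def predict(self, X) -> np.ndarray:
        scores = self.score_samples(X)
        labels = []
        for row in scores:
            m = row.max()
            if m <= 0.0:
                labels.append("unclassifiable")
                continue
            tied = [self.classes_[k] for k in np.flatnonzero(row == m)]
            labels.append(max(tied, key=self._severity_rank))
        return np.asarray(labels, dtype=object)

    # --- JSON round-trip -------------------------------------------------
    def to_json_dict(self) -> dict:
        check_is_fitted(self, "densities_")
        dens = {}
        for c in self.classes_:
            comp = []
            for d in self.densities_[c]:
                x, y = d.knots()
                comp.append({"x": x.tolist(), "pdf": y.tolist()})
            dens[str(c)] = comp
        if self.method == "pca":
            loadings = self.embedding_.components_
            offset = -self.embedding_.mean_ @ loadings.T
        else:
            loadings = self.embedding_.scalings_[:, :self.n_components_].T
            offset = -self.embedding_.xbar_ @ loadings.T
        return {
            "method": self.method,
            "density": self.density,
            "severity_order": list(self.severity_order),
            "classes": [str(c) for c in self.classes_],
            "n_components": int(self.n_components_),
            "feature_means": self.scaler_.mean_.tolist(),
            "feature_scales": self.scaler_.scale_.tolist(),
            "loadings": loadings.tolist(),
            "offset": np.asarray(offset).tolist(),
            "densities": dens,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "DensityProductClassifier":
        clf = cls(method=d["method"], density=d["density"],
                  severity_order=tuple(d["severity_order"]))
        clf.classes_ = np.asarray(d["classes"], dtype=object)
        clf.n_components_ = int(d["n_components"])
        clf.scaler_ = StandardScaler()
        clf.scaler_.mean_ = np.asarray(d["feature_means"])
        clf.scaler_.scale_ = np.asarray(d["feature_scales"])
        clf.scaler_.var_ = clf.scaler_.scale_ ** 2
        clf.scaler_.n_features_in_ = len(clf.scaler_.mean_)
        clf.scaler_.with_mean = clf.scaler_.with_std = True

        class _LinearEmbedding:
            def __init__(self, W, b):
                self.W, self.b = np.asarray(W), np.asarray(b)

            def transform(self, Z):
                return Z @ self.W.T + self.b

        clf.embedding_ = _LinearEmbedding(d["loadings"], d["offset"])
        clf.densities_ = {
            c: [_Density1D("knots", knots=(np.asarray(k["x"]), np.asarray(k["pdf"])))
                for k in d["densities"][str(c)]]
            for c in clf.classes_
        }
        return clf


def evaluate(clf: DensityProductClassifier, X, y, scheme: str = "loocv",
             n_bootstrap: int = 2000, seed: int = 0) -> dict:
    """Per-class efficiency (recall, %) with 95% bootstrap CIs.

    ``resubstitution`` scores the training data under the given fitted
    (or freshly fitted) model; ``loocv`` refits with each image held out
    in turn, the honest protocol for small cohorts.  The CI resamples
    each class's per-image correctness indicators (2000 draws, seeded).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to evaluate")
    if scheme == "resubstitution":
        model = clone(clf).fit(X, y)
        pred = model.predict(X)
    elif scheme == "loocv":
        pred = np.empty_like(y)
        idx = np.arange(len(y))
        for i in idx:
            tr = idx != i
            model = clone(clf).fit(X[tr], y[tr])
            pred[i] = model.predict(X[i:i + 1])[0]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    rng = np.random.default_rng(seed)
    out: dict = {"scheme": scheme, "per_class": {}}
    for c in np.unique(y):
        hits = (pred[y == c] == c).astype(float)
        eff = 100.0 * float(hits.mean())
        if hits.size:
            boots = rng.choice(hits, size=(int(n_bootstrap), hits.size), replace=True).mean(axis=1)
            lo, hi = (100.0 * float(v) for v in np.percentile(boots, [2.5, 97.5]))
        else:
            lo = hi = float("nan")
        out["per_class"][str(c)] = {"efficiency": eff, "ci95": (lo, hi), "n": int(hits.size)}
    out["overall"] = 100.0 * float((pred == y).mean())
    return out
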