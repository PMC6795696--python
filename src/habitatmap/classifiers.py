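"""Voxel classifiers producing per-class probabilities.

Gaussian naive Bayes is the reference classifier and is implemented natively
(diagonal class-conditional Gaussians, empirical class priors, floored
variances): the MRF de-noising stage and the correctness oracle both consume
its posteriors, so it must not hide behind a library black box. The seven
comparison families (logistic regression, RBF support-vector machine, a small
fully-connected neural network, random forest, k-nearest-neighbor, kernel
density estimation with fixed or Silverman-selected bandwidth) are thin
wrappers over scikit-learn estimators behind one common contract: a fitted
model exposes ``predict_proba`` rows that sum to one over its classes.

Hyperparameter ranges for each family (the comparison-study search space):

    LR    C         1e-3 .. 1e10   inverse regularization strength
    SVM   C         1e-3 .. 1e5    RBF penalty parameter
    NN    alpha     1e-8 .. 1e5    L2 regularization
    RF    trees     10   .. 1000   number of trees
    kNN   N         10   .. 1000   neighbors (Euclidean)
    KDE   bandwidth 1e-4 .. 10     Gaussian kernel SD
    NB, aKDE        (none)
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KernelDensity, KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .parameter_maps import FeatureField
from .volumes_io import MaskVolume, VoxelGrid

__all__ = [
    "FAMILIES",
    "HYPERPARAMETER_RANGES",
    "GaussianNBModel",
    "ClassifierModel",
    "ProbabilityVolume",
    "HabitatMap",
    "fit_gaussian_nb",
    "fit_classifier",
    "silverman_bandwidth",
    "classify_volume",
]

log = logging.getLogger(__name__)

FAMILIES = ("LR", "SVM", "NN", "NB", "RF", "kNN", "KDE", "aKDE")

#: (low, high) inclusive bounds of the tunable scalar per family; None = no
#: hyperparameter.
HYPERPARAMETER_RANGES: dict[str, tuple[float, float] | None] = {
    "LR": (1e-3, 1e10),
    "SVM": (1e-3, 1e5),
    "NN": (1e-8, 1e5),
    "NB": None,
    "RF": (10, 1000),
    "kNN": (10, 1000),
    "KDE": (1e-4, 1e1),
    "aKDE": None,
}

VARIANCE_FLOOR_FACTOR = 1e-9
BANDWIDTH_FLOOR = 1e-4  # lower bound of the KDE bandwidth search range


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ValueError(f"feature rows must be 2-D, got shape {X.shape}")
    return X


@dataclass
class GaussianNBModel:
    """Diagonal-covariance Gaussian naive Bayes over habitat classes.

    For class ``c`` and feature ``d`` the model stores the sample mean
    ``mu[c, d]`` and variance ``var[c, d]`` (floored away from zero) plus the
    prior ``prior[c]``; the posterior at a feature row ``x`` is

        P(c | x)  proportional to  prior[c] * prod_d N(x_d; mu[c,d], var[c,d])
    """

    class_ids: np.ndarray   # (C,) sorted int labels
    means: np.ndarray       # (C, D)
    variances: np.ndarray   # (C, D), >= var_floor
    priors: np.ndarray      # (C,), sums to 1
    var_floor: float
    n_per_class: dict = field(default_factory=dict)

    def __post_init__(self):
        self.class_ids = np.asarray(self.class_ids, dtype=int)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("class priors must sum to 1")
        if (self.variances <= 0).any():
            raise ValueError("variances must be positive (floored)")

    def joint_log_likelihood(self, X) -> np.ndarray:
        X = _as_matrix(X)
        # log prior + sum_d log N(x_d; mu, var), vectorized over (n, C, D)
        diff = X[:, None, :] - self.means[None, :, :]
        log_pdf = -0.5 * (np.log(2.0 * np.pi * self.variances)[None, :, :]
                          + diff ** 2 / self.variances[None, :, :])
        return np.log(self.priors)[None, :] + log_pdf.sum(axis=2)

    def predict_proba(self, X) -> np.ndarray:
        jll = self.joint_log_likelihood(X)
        return np.exp(jll - logsumexp(jll, axis=1, keepdims=True))

    def predict(self, X) -> np.ndarray:
        return self.class_ids[np.argmax(self.joint_log_likelihood(X), axis=1)]

    def to_json(self, path=None) -> str:
        payload = {
            "model": "gaussian_naive_bayes",
            "class_ids": self.class_ids.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "priors": self.priors.tolist(),
            "var_floor": self.var_floor,
            "n_per_class": {str(k): int(v) for k, v in self.n_per_class.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "GaussianNBModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        payload = json.loads(text)
        return cls(class_ids=np.array(payload["class_ids"]),
                   means=np.array(payload["means"]),
                   variances=np.array(payload["variances"]),
                   priors=np.array(payload["priors"]),
                   var_floor=float(payload["var_floor"]),
                   n_per_class={int(k): v for k, v in payload["n_per_class"].items()})


def fit_gaussian_nb(train, uniform_priors: bool = False) -> GaussianNBModel:
    """Fit the native Gaussian NB model.

    ``train`` is a :class:`~habitatmap.training_data.TrainingSet` or an
    ``(X, y)`` pair. Per-class variances are floored at
    ``1e-9 x (largest per-feature total variance)`` so a constant feature
    cannot produce a degenerate density. Priors default to empirical class
    frequencies; ``uniform_priors=True`` switches to 1/C.
    """
    if isinstance(train, tuple):
        X, y = train
    else:
        X, y = train.matrices()
    X, y = _as_matrix(X), np.asarray(y, dtype=int)
    class_ids = np.unique(y)
    counts = np.array([(y == c).sum() for c in class_ids])
    if (counts < 2).any():
        bad = class_ids[counts < 2].tolist()
        raise ValueError(f"classes {bad} have fewer than 2 samples")
    total_var = X.var(axis=0).max()
    floor = VARIANCE_FLOOR_FACTOR * total_var if total_var > 0 else VARIANCE_FLOOR_FACTOR
    means = np.stack([X[y == c].mean(axis=0) for c in class_ids])
    variances = np.maximum(np.stack([X[y == c].var(axis=0) for c in class_ids]), floor)
    priors = (np.full(len(class_ids), 1.0 / len(class_ids)) if uniform_priors
              else counts / counts.sum())
    return GaussianNBModel(class_ids=class_ids, means=means, variances=variances,
                           priors=priors, var_floor=floor,
                           n_per_class=dict(zip(class_ids.tolist(), counts.tolist())))


def silverman_bandwidth(samples, d: int | None = None) -> float:
    """Silverman's rule-of-thumb bandwidth for a d-dimensional Gaussian KDE.

        h = sigma_hat * (4 / ((d + 2) n)) ** (1 / (d + 4))

    with ``sigma_hat`` the mean of the per-dimension sample standard
    deviations. Degenerate (zero-variance) samples floor at 1e-4, the lower
    bound of the bandwidth search range.
    """
    X = _as_matrix(samples)
    n = X.shape[0]
    if n < 2:
        raise ValueError("Silverman bandwidth needs at least 2 samples")
    if d is None:
        d = X.shape[1]
    sigma = float(X.std(axis=0, ddof=1).mean())
    if sigma <= 0:
        return BANDWIDTH_FLOOR
    return max(sigma * (4.0 / ((d + 2) * n)) ** (1.0 / (d + 4)), BANDWIDTH_FLOOR)


class _KDEClassifier:
    """Class-conditional Gaussian KDE Bayes classifier.

    ``bandwidth=None`` selects each class's bandwidth with Silverman's rule
    from that class's own samples (the 'automatic' variant).
    """

    def __init__(self, bandwidth: float | None):
        self.bandwidth = bandwidth
        self._kdes: dict[int, KernelDensity] = {}
        self._bandwidths: dict[int, float] = {}
        self._log_priors: np.ndarray | None = None
        self.classes_: np.ndarray | None = None

    def fit(self, X, y):
        X, y = _as_matrix(X), np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        counts = []
        for c in self.classes_:
            Xc = X[y == c]
            h = self.bandwidth if self.bandwidth is not None else silverman_bandwidth(Xc)
            kde = KernelDensity(kernel="gaussian", bandwidth=h).fit(Xc)
            self._kdes[int(c)] = kde
            self._bandwidths[int(c)] = float(h)
            counts.append(len(Xc))
        counts = np.asarray(counts, dtype=float)
        self._log_priors = np.log(counts / counts.sum())
        return self

    def predict_proba(self, X):
        X = _as_matrix(X)
        log_post = np.stack(
            [self._kdes[int(c)].score_samples(X) for c in self.classes_], axis=1
        ) + self._log_priors[None, :]
        return np.exp(log_post - logsumexp(log_post, axis=1, keepdims=True))


@dataclass
class ClassifierModel:
    """A fitted classifier of any family under the common probability contract."""

    family: str
    hyperparameter: float | None
    impl: object
    class_ids: np.ndarray
    seed: int | None = None
    n_per_class: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, X) -> np.ndarray:
        X = _as_matrix(X)
        out_of_range = ((X < 0) | (X > 1)).any(axis=1).sum()
        if out_of_range:
            log.warning("%s: %d query rows outside the unit cube were still scored",
                        self.family, int(out_of_range))
        probs = self.impl.predict_proba(X)
        return probs / probs.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        # argmax with ties toward the lowest class id (np.argmax keeps the
        # first maximal index and class_ids are sorted)
        return self.class_ids[np.argmax(self.predict_proba(X), axis=1)]


def _check_hyperparameter(family: str, hyperparameter):
    bounds = HYPERPARAMETER_RANGES[family]
    if bounds is None:
        if hyperparameter is not None:
            raise ValueError(f"{family} takes no hyperparameter, got {hyperparameter}")
        return None
    if hyperparameter is None:
        raise ValueError(f"{family} requires a hyperparameter in {bounds}")
    hp = float(hyperparameter)
    lo, hi = bounds
    if not (lo <= hp <= hi):
        raise ValueError(f"{family} hyperparameter {hp} outside range [{lo}, {hi}]")
    return hp


def fit_classifier(family: str, hyperparameter, train, seed: int = 0) -> ClassifierModel:
    """Fit one of the eight comparison families on a training set.

    Stochastic families (RF, NN) honor ``seed``; the rest are deterministic.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    hp = _check_hyperparameter(family, hyperparameter)
    if isinstance(train, tuple):
        X, y = train
    else:
        X, y = train.matrices()
    X, y = _as_matrix(X), np.asarray(y, dtype=int)
    metadata = {}

    if family == "NB":
        impl = fit_gaussian_nb((X, y))
        class_ids = impl.class_ids
    elif family == "LR":
        impl = LogisticRegression(C=hp, max_iter=2000).fit(X, y)
        class_ids = impl.classes_
    elif family == "SVM":
        # SVC decision values are not probabilities; Platt sigmoid calibration
        # (probability=True) maps them onto the simplex.
        impl = SVC(C=hp, kernel="rbf", probability=True, random_state=seed).fit(X, y)
        class_ids = impl.classes_
        metadata["probability_calibration"] = "platt"
    elif family == "NN":
        # one fully-connected hidden layer of 20 nodes, ReLU, quasi-Newton
        impl = MLPClassifier(hidden_layer_sizes=(20,), alpha=hp, activation="relu",
                             solver="lbfgs", max_iter=2000, random_state=seed).fit(X, y)
        class_ids = impl.classes_
        metadata["architecture"] = "fully-connected, 1 hidden layer x 20 nodes"
    elif family == "RF":
        impl = RandomForestClassifier(n_estimators=int(round(hp)),
                                      random_state=seed).fit(X, y)
        class_ids = impl.classes_
    elif family == "kNN":
        n_neighbors = int(round(hp))
        if n_neighbors > len(y):
            raise ValueError(f"kNN N={n_neighbors} exceeds training size {len(y)}")
        impl = KNeighborsClassifier(n_neighbors=n_neighbors, metric="euclidean").fit(X, y)
        class_ids = impl.classes_
    elif family == "KDE":
        impl = _KDEClassifier(bandwidth=hp).fit(X, y)
        class_ids = impl.classes_
    else:  # aKDE
        impl = _KDEClassifier(bandwidth=None).fit(X, y)
        class_ids = impl.classes_
        metadata["bandwidths"] = impl._bandwidths

    counts = {int(c): int((y == c).sum()) for c in class_ids}
    return ClassifierModel(family=family, hyperparameter=hp, impl=impl,
                           class_ids=np.asarray(class_ids, dtype=int), seed=seed,
                           n_per_class=counts, metadata=metadata)


@dataclass
class ProbabilityVolume:
    """Per-voxel class probabilities on a grid, valid inside the scored VOI."""

    grid: VoxelGrid
    probs: np.ndarray       # (nx, ny, nz, C)
    class_ids: np.ndarray   # (C,)
    valid: np.ndarray       # (nx, ny, nz) bool

    def __post_init__(self):
        self.class_ids = np.asarray(self.class_ids, dtype=int)
        self.probs = np.asarray(self.probs, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        sums = self.probs[self.valid].sum(axis=1)
        if sums.size and not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("per-voxel probabilities must sum to 1")


@dataclass
class HabitatMap:
    """Per-voxel habitat labels (1-5) inside a VOI; 0 marks unlabeled voxels."""

    grid: VoxelGrid
    labels: np.ndarray      # (nx, ny, nz) int, 0 outside the VOI
    valid: np.ndarray       # (nx, ny, nz) bool

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.valid = np.asarray(self.valid, dtype=bool)
        inside = self.labels[self.valid]
        if inside.size and ((inside < 1) | (inside > 5)).any():
            raise ValueError("labels inside the VOI must be in 1..5")


def classify_volume(model, features: FeatureField,
                    voi: MaskVolume) -> tuple[ProbabilityVolume, HabitatMap]:
    """Score every valid VOI voxel, returning probabilities and argmax labels.

    Ties in the argmax break toward the lowest class id. The raw label map is
    the input to MRF de-noising, not the final habitat map.
    """
    if voi.size == 0:
        raise ValueError("VOI mask is empty")
    X, coords = features.samples(voi)
    if X.shape[0] == 0:
        raise ValueError("no valid feature voxels inside the VOI")
    probs_rows = model.predict_proba(X)
    class_ids = np.asarray(model.class_ids, dtype=int)

    shape = features.grid.shape
    probs = np.zeros(shape + (len(class_ids),), dtype=float)
    labels = np.zeros(shape, dtype=int)
    valid = np.zeros(shape, dtype=bool)
    ix, iy, iz = coords.T
    probs[ix, iy, iz] = probs_rows
    labels[ix, iy, iz] = class_ids[np.argmax(probs_rows, axis=1)]
    valid[ix, iy, iz] = True
    return (
        ProbabilityVolume(grid=features.grid, probs=probs, class_ids=class_ids,
                          valid=valid),
        HabitatMap(grid=features.grid, labels=labels, valid=valid),
    )
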