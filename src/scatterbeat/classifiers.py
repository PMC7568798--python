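"""The three beat classifiers: KNN (k=4), PNN (spread 0.01), feedforward NN.

Each classifier exposes a ``*_predict`` function returning predicted labels
plus a per-query confidence used downstream for majority-vote tie breaking:
the class posterior for PNN and the NN, the negative mean neighbor distance
for KNN.

The probabilistic neural network is a Parzen-window classifier: each class
score is the mean Gaussian kernel value between the query and that class's
pattern units; the Bayesian decision picks the class with the largest
normalized score.  The feedforward network (75-70-60-45-30-20-10-4, ReLU
hidden layers, softmax output, Adam, categorical cross-entropy, 50 epochs)
is backed by scikit-learn's multilayer perceptron.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.exceptions import ConvergenceWarning
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier

DEFAULT_HIDDEN = (70, 60, 45, 30, 20, 10)


# ---------------------------------------------------------------------------
# KNN
# ---------------------------------------------------------------------------

@dataclass
class KnnModel:
    training_features: np.ndarray
    training_labels: np.ndarray
    k: int = 4
    _index: NearestNeighbors = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.training_features = np.asarray(self.training_features, dtype=float)
        self.training_labels = np.asarray(self.training_labels)
        if len(self.training_features) == 0:
            raise ValueError("empty training set")
        if not 1 <= self.k <= len(self.training_features):
            raise ValueError("k must be in [1, n_training]")
        self._index = NearestNeighbors(n_neighbors=self.k).fit(
            self.training_features)


def knn_fit(features, labels, k: int = 4) -> KnnModel:
    return KnnModel(features, labels, k)


def knn_predict(model: KnnModel, queries) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean k-nearest-neighbor vote.

    Ties between classes with equal vote counts are broken by the class of
    the single nearest neighbor among the tied classes.  Returns predicted
    labels and the negative mean neighbor distance as confidence.
    """
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    if queries.shape[1] != model.training_features.shape[1]:
        raise ValueError("query dimensionality does not match training data")
    dist, idx = model._index.kneighbors(queries)
    neigh_labels = model.training_labels[idx]          # (n, k), sorted by dist
    out = np.empty(len(queries), dtype=model.training_labels.dtype)
    for i in range(len(queries)):
        labs, counts = np.unique(neigh_labels[i], return_counts=True)
        tied = labs[counts == counts.max()]
        if len(tied) == 1:
            out[i] = tied[0]
        else:
            # neighbors are distance-ordered: first occurrence of a tied class wins
            out[i] = next(l for l in neigh_labels[i] if l in tied)
    return out, -dist.mean(axis=1)


# ---------------------------------------------------------------------------
# PNN
# ---------------------------------------------------------------------------

@dataclass
class PnnModel:
    pattern_units: np.ndarray      # all training vectors
    pattern_labels: np.ndarray
    spread: float = 0.01
    classes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.pattern_units = np.asarray(self.pattern_units, dtype=float)
        self.pattern_labels = np.asarray(self.pattern_labels)
        if self.spread <= 0:
            raise ValueError("spread must be positive")
        if len(self.pattern_units) == 0:
            raise ValueError("empty training set")
        self.classes = np.unique(self.pattern_labels)

    @property
    def layer_sizes(self) -> tuple[int, int, int, int]:
        """input / pattern / summation / output neuron counts."""
        return (self.pattern_units.shape[1], len(self.pattern_units),
                len(self.classes), 1)


def pnn_fit(features, labels, spread: float = 0.01) -> PnnModel:
    return PnnModel(features, labels, spread)


def pnn_predict(model: PnnModel, queries, chunk_size: int = 2048
                ) -> tuple[np.ndarray, np.ndarray]:
    """Parzen-window classification with a Gaussian kernel.

    Class score = mean over the class's pattern units of
    exp(-||x - x_i||^2 / (2 sigma^2)); the label is the argmax and the
    posteriors are the scores normalized to sum to one.  Queries whose
    scores all underflow to zero fall back to the nearest pattern unit's
    class (with a warning), which is the sigma -> 0 limit.
    """
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    if queries.shape[1] != model.pattern_units.shape[1]:
        raise ValueError("query dimensionality does not match pattern units")
    classes = model.classes
    masks = [model.pattern_labels == c for c in classes]
    labels = np.empty(len(queries), dtype=model.pattern_labels.dtype)
    posteriors = np.zeros((len(queries), len(classes)))
    n_fallback = 0
    for lo in range(0, len(queries), chunk_size):
        q = queries[lo:lo + chunk_size]
        d2 = cdist(q, model.pattern_units, metric="sqeuclidean")
        kern = np.exp(-d2 / (2.0 * model.spread**2))
        scores = np.column_stack([kern[:, m].mean(axis=1) for m in masks])
        tot = scores.sum(axis=1)
        dead = tot <= 0.0
        if dead.any():
            n_fallback += int(dead.sum())
            nearest = d2[dead].argmin(axis=1)
            fallback_cls = model.pattern_labels[nearest]
            for j, c in enumerate(classes):
                scores[dead, j] = (fallback_cls == c)
            tot = scores.sum(axis=1)
        posteriors[lo:lo + len(q)] = scores / tot[:, None]
        labels[lo:lo + len(q)] = classes[scores.argmax(axis=1)]
    if n_fallback:
        warnings.warn(
            f"PNN kernel underflow for {n_fallback} queries; "
            "fell back to the nearest pattern unit")
    return labels, posteriors


# ---------------------------------------------------------------------------
# Feedforward NN
# ---------------------------------------------------------------------------

@dataclass
class MlpModel:
    net: MLPClassifier
    layer_sizes: tuple[int, ...]

    @property
    def classes(self) -> np.ndarray:
        return self.net.classes_

    @property
    def n_parameters(self) -> int:
        return sum(w.size for w in self.net.coefs_) + \
            sum(b.size for b in self.net.intercepts_)


def mlp_train(features, labels, seed: int = 0, batch_size: int = 256,
              learning_rate: float = 1e-3, epochs: int = 50,
              hidden_layers: tuple[int, ...] = DEFAULT_HIDDEN) -> MlpModel:
    """Train the feedforward softmax network with Adam.

    Categorical cross-entropy over softmax outputs, minibatch Adam
    (beta1=0.9, beta2=0.999, eps=1e-8) for a fixed number of epochs;
    reproducible given ``seed``.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    net = MLPClassifier(
        hidden_layer_sizes=hidden_layers,
        activation="relu",
        solver="adam",
        alpha=0.0,
        batch_size=min(batch_size, len(features)),
        learning_rate_init=learning_rate,
        max_iter=epochs,
        shuffle=True,
        random_state=seed,
        tol=0.0,
        n_iter_no_change=epochs + 1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(features, labels)
    if not np.isfinite(net.loss_):
        raise RuntimeError(f"training diverged: loss = {net.loss_}")
    sizes = (features.shape[1], *hidden_layers, len(net.classes_))
    return MlpModel(net, sizes)


def mlp_predict(model: MlpModel, features) -> tuple[np.ndarray, np.ndarray]:
    """Softmax argmax prediction; returns labels and class posteriors."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[1] != model.layer_sizes[0]:
        raise ValueError("feature dimensionality does not match the model")
    posteriors = model.net.predict_proba(features)
    labels = model.classes[posteriors.argmax(axis=1)]
    return labels, posteriors


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis."""
    z = np.asarray(logits, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Uniform front-end used by the evaluation driver
# ---------------------------------------------------------------------------

def fit_classifier(name: str, features, labels, seed: int = 0, **hyper):
    """Fit one of {'knn', 'pnn', 'nn'} and return (model, predict_fn).

    ``predict_fn(model, X)`` returns (labels, confidence) where confidence
    is the posterior of the predicted class (PNN/NN) or the negative mean
    neighbor distance (KNN).
    """
    name = name.lower()
    if name == "knn":
        model = knn_fit(features, labels, k=int(hyper.get("k", 4)))
        return model, knn_predict
    if name == "pnn":
        model = pnn_fit(features, labels, spread=float(hyper.get("spread", 0.01)))

        def predict(m, x):
            labs, post = pnn_predict(m, x)
            return labs, post.max(axis=1)
        return model, predict
    if name == "nn":
        model = mlp_train(features, labels, seed=seed,
                          batch_size=int(hyper.get("batch_size", 256)),
                          learning_rate=float(hyper.get("learning_rate", 1e-3)),
                          epochs=int(hyper.get("epochs", 50)))

        def predict(m, x):
            labs, post = mlp_predict(m, x)
            return labs, post.max(axis=1)
        return model, predict
    raise ValueError(f"unknown classifier {name!r} (expected knn, pnn or nn)")
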