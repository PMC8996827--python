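"""Downstream harnesses: 5-NN and MLP classification, GBM yield regression.

The three model classes are sklearn-style estimators over binary
fingerprint matrices:

* :class:`KnnReactionClassifier` — exact nearest-neighbour search under
  Hamming distance (equivalent in ranking to squared Euclidean on 0/1
  vectors) with a deterministic majority vote, k = 5 by default.
* :class:`MlpReactionClassifier` — one tanh hidden layer of 1664 units,
  softmax output trained with cross-entropy by Adam for 10 epochs at
  batch size 64.
* :class:`GradientBoostingYieldRegressor` — XGBoost with a fixed
  hyperparameter set (learning_rate 0.01, max_depth 15,
  min_child_weight 8, colsample_bytree 0.2125, subsample 1) and early
  stopping on a seeded 10% validation split, patience 20 rounds.

Evaluation: accuracy, multiclass Matthews correlation (MCC) and
confusion entropy (CEN) for classification; R-squared for regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted
import xgboost as xgb

from .errors import (
    ConstantTruth,
    EmptyTrainingSet,
    LabelEncodingError,
    LengthMismatch,
    TooFewRows,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GbmHyperparams",
    "MlpSpec",
    "KnnReactionClassifier",
    "MlpReactionClassifier",
    "GradientBoostingYieldRegressor",
    "confusion_matrix",
    "matthews_corrcoef_multiclass",
    "confusion_entropy",
    "evaluate_classification",
    "evaluate_regression",
    "knn_fit",
    "knn_predict",
    "mlp_fit",
    "gbm_fit",
]


@dataclass(frozen=True)
class GbmHyperparams:
    """Gradient-boosting settings used for every yield-regression run."""

    n_estimators: int = 999_999
    learning_rate: float = 0.01
    max_depth: int = 15
    min_child_weight: int = 8
    colsample_bytree: float = 0.2125
    subsample: float = 1.0
    early_stopping_rounds: int = 20
    validation_fraction: float = 0.10


@dataclass(frozen=True)
class MlpSpec:
    """Fixed multilayer-perceptron architecture for classification."""

    hidden_width: int = 1664
    hidden_activation: str = "tanh"
    output_activation: str = "softmax"
    loss: str = "sparse_categorical_crossentropy"
    optimizer: str = "adam"
    learning_rate: float = 0.001
    epochs: int = 10
    batch_size: int = 64


# ---------------------------------------------------------------------------
# k-nearest-neighbour classification


class KnnReactionClassifier(ClassifierMixin, BaseEstimator):
    """Exact k-NN over binary fingerprints with a deterministic vote.

    Distance is the Hamming count of differing bits. Prediction takes a
    majority vote among the k nearest training rows; a tied vote goes to
    the tied class with the smaller summed neighbour distance, and any
    remaining tie to the class seen first in the neighbour list.

    Parameters
    ----------
    n_neighbors : int, default 5

    Attributes
    ----------
    classes_ : ndarray of unique training labels.
    n_samples_fit_ : number of training rows.
    """

    def __init__(self, n_neighbors: int = 5):
        self.n_neighbors = n_neighbors

    def fit(self, X, y) -> "KnnReactionClassifier":
        X = np.asarray(X, dtype=np.uint8)
        y = np.asarray(y)
        if X.shape[0] == 0:
            raise EmptyTrainingSet("cannot fit k-NN on zero rows")
        if X.shape[0] != y.shape[0]:
            raise LengthMismatch(f"{X.shape[0]} rows vs {y.shape[0]} labels")
        self.classes_ = np.unique(y)
        self._y = y
        self._nn = NearestNeighbors(algorithm="brute", metric="hamming").fit(X)
        self._n_bits = X.shape[1]
        self.n_samples_fit_ = X.shape[0]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "_nn")
        X = np.asarray(X, dtype=np.uint8)
        k = self.n_neighbors
        if k > self.n_samples_fit_:
            logger.warning(
                "k=%d exceeds training size %d; clipping", k, self.n_samples_fit_
            )
            k = self.n_samples_fit_
        # sklearn's hamming is a fraction of differing bits; counts are
        # the fraction times the bit width (monotone-identical ranking).
        dist, idx = self._nn.kneighbors(X, n_neighbors=k)
        dist = dist * self._n_bits
        out = []
        for drow, irow in zip(dist, idx):
            out.append(self._vote(self._y[irow], drow))
        return np.asarray(out)

    @staticmethod
    def _vote(labels: np.ndarray, distances: np.ndarray):
        counts: dict = {}
        sums: dict = {}
        order: dict = {}
        for pos, (lab, d) in enumerate(zip(labels, distances)):
            key = lab.item() if hasattr(lab, "item") else lab
            counts[key] = counts.get(key, 0) + 1
            sums[key] = sums.get(key, 0.0) + float(d)
            order.setdefault(key, pos)
        # most votes, then smallest summed distance, then first seen
        return min(counts, key=lambda c: (-counts[c], sums[c], order[c]))

    def kneighbors(self, X, n_neighbors: int | None = None):
        check_is_fitted(self, "_nn")
        k = min(n_neighbors or self.n_neighbors, self.n_samples_fit_)
        dist, idx = self._nn.kneighbors(np.asarray(X, dtype=np.uint8), n_neighbors=k)
        return dist * self._n_bits, idx


# ---------------------------------------------------------------------------
# multilayer perceptron classification


class MlpReactionClassifier(ClassifierMixin, BaseEstimator):
    """Single-hidden-layer MLP classifier over fingerprint bits.

    Architecture: input d -> dense tanh layer (1664 units) -> softmax
    output, trained with cross-entropy by Adam (lr 0.001) for exactly
    ``epochs`` passes at batch size 64. All stochastic elements (weight
    init, minibatch shuffling) derive from ``random_state``.
    """

    def __init__(self, spec: MlpSpec | None = None, random_state: int = 0):
        self.spec = spec
        self.random_state = random_state

    def fit(self, X, y) -> "MlpReactionClassifier":
        spec = self.spec or MlpSpec()
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.shape[0] < 2:
            raise LabelEncodingError(
                f"need >= 2 classes for a softmax output, got {classes.shape[0]}"
            )
        self._mlp = MLPClassifier(
            hidden_layer_sizes=(spec.hidden_width,),
            activation=spec.hidden_activation,
            solver=spec.optimizer,
            learning_rate_init=spec.learning_rate,
            batch_size=spec.batch_size,
            max_iter=spec.epochs,
            shuffle=True,
            random_state=self.random_state,
            early_stopping=False,
            n_iter_no_change=spec.epochs + 1,  # never stop on plateau
        )
        import warnings

        with warnings.catch_warnings():
            # the fixed-epoch protocol intentionally stops at `epochs`
            warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
            self._mlp.fit(np.asarray(X, dtype=np.float32), y)
        self.classes_ = self._mlp.classes_
        self.n_epochs_ = self._mlp.n_iter_
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "_mlp")
        return self._mlp.predict(np.asarray(X, dtype=np.float32))

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "_mlp")
        return self._mlp.predict_proba(np.asarray(X, dtype=np.float32))


# ---------------------------------------------------------------------------
# gradient-boosting yield regression


class GradientBoostingYieldRegressor(RegressorMixin, BaseEstimator):
    """XGBoost regressor for reaction yields with seeded early stopping.

    A ``validation_fraction`` share of the training rows (seeded,
    disjoint from the boosting rows) is held out; boosting stops after
    ``early_stopping_rounds`` rounds without validation improvement and
    the model at the best round is kept.

    Attributes
    ----------
    best_iteration_ : round index of the best validation score.
    validation_indices_ : row indices held out for early stopping.
    """

    def __init__(
        self,
        hyperparams: GbmHyperparams | None = None,
        random_state: int = 0,
    ):
        self.hyperparams = hyperparams
        self.random_state = random_state

    def fit(self, X, y) -> "GradientBoostingYieldRegressor":
        hp = self.hyperparams or GbmHyperparams()
        X = np.asarray(X)
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise LengthMismatch(f"{X.shape[0]} rows vs {y.shape[0]} labels")
        n = X.shape[0]
        n_val = int(round(n * hp.validation_fraction))
        if n == 0 or n_val == 0 or n_val >= n:
            raise TooFewRows(
                f"cannot carve a {hp.validation_fraction:.0%} validation split from {n} rows"
            )
        rng = np.random.default_rng(self.random_state)
        val_idx = rng.choice(n, size=n_val, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[val_idx] = True
        self.validation_indices_ = np.sort(val_idx)
        self._model = xgb.XGBRegressor(
            n_estimators=hp.n_estimators,
            learning_rate=hp.learning_rate,
            max_depth=hp.max_depth,
            min_child_weight=hp.min_child_weight,
            colsample_bytree=hp.colsample_bytree,
            subsample=hp.subsample,
            early_stopping_rounds=hp.early_stopping_rounds,
            tree_method="hist",
            n_jobs=1,
            random_state=self.random_state,
            verbosity=0,
        )
        self._model.fit(
            X[~mask], y[~mask], eval_set=[(X[mask], y[mask])], verbose=False
        )
        self.best_iteration_ = int(self._model.best_iteration)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "_model")
        return self._model.predict(np.asarray(X))


# ---------------------------------------------------------------------------
# evaluation metrics


def confusion_matrix(truth, predicted, labels=None) -> tuple[np.ndarray, np.ndarray]:
    """Confusion matrix C with rows = truth, columns = prediction."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape[0] != predicted.shape[0]:
        raise LengthMismatch(f"{truth.shape[0]} vs {predicted.shape[0]} labels")
    if labels is None:
        labels = np.unique(np.concatenate([truth, predicted]))
    labels = np.asarray(labels)
    index = {lab: i for i, lab in enumerate(labels.tolist())}
    C = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(truth.tolist(), predicted.tolist()):
        C[index[t], index[p]] += 1
    return C, labels


def matthews_corrcoef_multiclass(C: np.ndarray) -> float:
    """Multiclass Matthews correlation from a confusion matrix.

    Gorodkin's generalisation: with s = total, c = trace, t_k = row sums
    and p_k = column sums,
    MCC = (c s - t.p) / sqrt((s^2 - p.p)(s^2 - t.t)); 0 when undefined.
    """
    C = np.asarray(C, dtype=float)
    s = C.sum()
    c = np.trace(C)
    t = C.sum(axis=1)
    p = C.sum(axis=0)
    denom = np.sqrt(s * s - p @ p) * np.sqrt(s * s - t @ t)
    if denom == 0:
        return 0.0
    # guard against float round-off pushing past the [-1, 1] range
    return float(np.clip((c * s - t @ p) / denom, -1.0, 1.0))


def confusion_entropy(C: np.ndarray) -> float:
    """Confusion entropy (CEN) of a confusion matrix; 0 means perfect.

    Each class j gets a misclassification entropy over the probabilities
    of confusing j with every other class (both directions), with
    logarithm base 2(N-1); the per-class entropies are combined with
    weights P_j proportional to class involvement. Degenerate cases
    (single class, empty matrix) return 0.
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    total = C.sum()
    if n < 2 or total == 0:
        return 0.0
    base = 2.0 * (n - 1)
    row = C.sum(axis=1)
    col = C.sum(axis=0)

    def _h(p: float) -> float:
        return 0.0 if p <= 0 else -p * np.log(p) / np.log(base)

    cen = 0.0
    for j in range(n):
        denom_j = row[j] + col[j]
        P_j = denom_j / (2.0 * total)
        if denom_j == 0:
            continue
        cen_j = 0.0
        for k in range(n):
            if k == j:
                continue
            cen_j += _h(C[j, k] / denom_j)  # j mistaken for k
            cen_j += _h(C[k, j] / denom_j)  # k mistaken for j
        cen += P_j * cen_j
    return float(cen)


def evaluate_classification(truth, predicted, labels=None) -> dict:
    """Accuracy, multiclass MCC, CEN and the confusion matrix."""
    C, labs = confusion_matrix(truth, predicted, labels)
    total = C.sum()
    return {
        "accuracy": float(np.trace(C) / total) if total else 0.0,
        "mcc": matthews_corrcoef_multiclass(C),
        "cen": confusion_entropy(C),
        "confusion_matrix": C,
        "labels": labs,
    }


def evaluate_regression(truth, predicted) -> dict:
    """Coefficient of determination R^2 = 1 - SS_res / SS_tot."""
    truth = np.asarray(truth, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if truth.shape[0] != predicted.shape[0]:
        raise LengthMismatch(f"{truth.shape[0]} vs {predicted.shape[0]} values")
    ss_tot = float(((truth - truth.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ConstantTruth("R^2 undefined for constant truth")
    ss_res = float(((truth - predicted) ** 2).sum())
    return {"r2": 1.0 - ss_res / ss_tot}


# ---------------------------------------------------------------------------
# thin functional wrappers


def knn_fit(X, y, n_neighbors: int = 5) -> KnnReactionClassifier:
    return KnnReactionClassifier(n_neighbors=n_neighbors).fit(X, y)


def knn_predict(index: KnnReactionClassifier, X, k: int | None = None) -> np.ndarray:
    if k is not None and k != index.n_neighbors:
        index = KnnReactionClassifier(n_neighbors=k).fit(
            index._nn._fit_X.astype(np.uint8), index._y
        )
    return index.predict(X)


def mlp_fit(X, y, spec: MlpSpec | None = None, seed: int = 0) -> MlpReactionClassifier:
    return MlpReactionClassifier(spec=spec, random_state=seed).fit(X, y)


def gbm_fit(
    X, y, hyperparams: GbmHyperparams | None = None, seed: int = 0
) -> GradientBoostingYieldRegressor:
    return GradientBoostingYieldRegressor(
        hyperparams=hyperparams, random_state=seed
    ).fit(X, y)
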