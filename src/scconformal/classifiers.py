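"""Softmax-scoring classifiers behind a single pluggable contract.

The conformal annotator only requires a model that maps a cell to a point on
the K-simplex (one softmax score per reference cell type).  Any such model —
including wrappers around external annotators — can be used; this module
ships a feed-forward MLP trained with explicit validation-set early stopping,
plus two fast baselines (multinomial logistic regression and a
nearest-centroid softmax) that honor the same contract.

Conformal coverage guarantees are classifier-agnostic: a weak model yields
larger prediction sets, never invalid ones.
"""

from __future__ import annotations

import copy
import pickle
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.neural_network import MLPClassifier

from .datamodel import CellDataset

__all__ = ["TrainingConfig", "SoftmaxModel", "fit_mlp", "fit_baseline",
           "predict_proba", "save_model", "load_model"]


@dataclass
class TrainingConfig:
    """MLP hyperparameters.  Defaults: two hidden layers (256, 64), ReLU,
    Adam lr 1e-3, batch 256, at most 200 epochs with patience 10 on the
    validation cross-entropy, L2 weight decay 1e-4."""

    hidden_layer_sizes: Tuple[int, ...] = (256, 64)
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 200
    patience: int = 10
    l2: float = 1e-4
    seed: int = 0


@dataclass
class SoftmaxModel:
    """A fitted classifier returning one softmax score per reference class.

    ``label_space`` is the sorted list of class names; every probability
    matrix produced by :func:`predict_proba` carries its columns in this
    order.
    """

    label_space: List[str]
    gene_ids: np.ndarray
    backend: object
    kind: str
    config: Optional[TrainingConfig] = None
    # optional per-gene standardization fitted on training data
    feat_mean: Optional[np.ndarray] = None
    feat_sd: Optional[np.ndarray] = None
    fitted: bool = True
    history: dict = field(default_factory=dict)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self.feat_mean is None:
            return X
        return (X - self.feat_mean) / self.feat_sd

    @property
    def n_classes(self) -> int:
        return len(self.label_space)


def _check_labelled(train: CellDataset) -> List[str]:
    if train.labels is None:
        raise ValueError("training set must carry labels")
    classes = sorted(set(train.labels))
    if len(classes) < 2:
        raise ValueError(f"training set has a single class {classes}; need K >= 2")
    return classes


def fit_mlp(train: CellDataset, val: CellDataset,
            config: TrainingConfig = TrainingConfig()) -> SoftmaxModel:
    """Train the feed-forward MLP with early stopping on validation loss.

    One epoch = one shuffled pass of minibatch gradient updates; training
    stops after ``config.max_epochs`` or when the validation cross-entropy
    has not improved for ``config.patience`` consecutive epochs, restoring
    the best weights.  Deterministic given ``config.seed``.
    """
    classes = _check_labelled(train)
    if list(train.gene_ids) != list(val.gene_ids):
        raise ValueError("train and validation gene spaces differ")
    if val.labels is None:
        raise ValueError("validation set must carry labels")

    net = MLPClassifier(
        hidden_layer_sizes=config.hidden_layer_sizes,
        activation="relu",
        solver="adam",
        alpha=config.l2,
        learning_rate_init=config.learning_rate,
        batch_size=config.batch_size,
        random_state=config.seed,
        max_iter=1,  # epochs are driven manually via partial_fit
    )
    rng = np.random.default_rng(config.seed)
    mean = train.matrix.mean(axis=0)
    sd = train.matrix.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    X, y = (train.matrix - mean) / sd, np.asarray(train.labels, dtype=object)
    Xval = (val.matrix - mean) / sd
    n = len(y)
    best_loss, best_state, since_best = np.inf, None, 0
    hist = {"train_loss": [], "val_loss": []}
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            net.batch_size = len(sel)
            net.partial_fit(X[sel], y[sel], classes=classes)
        val_probs = net.predict_proba(Xval)
        v = log_loss(val.labels, val_probs, labels=classes)
        hist["train_loss"].append(float(net.loss_))
        hist["val_loss"].append(float(v))
        if v < best_loss - 1e-8:
            best_loss, since_best = v, 0
            best_state = (copy.deepcopy(net.coefs_), copy.deepcopy(net.intercepts_))
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_state is not None:
        net.coefs_, net.intercepts_ = best_state
    return SoftmaxModel(label_space=classes, gene_ids=train.gene_ids,
                        backend=net, kind="mlp", config=config,
                        feat_mean=mean, feat_sd=sd, history=hist)


class _CentroidSoftmax:
    """Nearest-centroid scorer: softmax of negative squared distances to the
    class centroids, temperature-scaled by the mean within-class variance."""

    def __init__(self, centroids: np.ndarray, temperature: float, classes: List[str]):
        self.centroids = centroids
        self.temperature = temperature
        self.classes_ = classes

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        logits = -d2 / max(self.temperature, 1e-12)
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)


def fit_baseline(train: CellDataset, kind: str = "multinomial_logistic") -> SoftmaxModel:
    """Fit a fast softmax baseline honoring the :class:`SoftmaxModel` contract.

    ``multinomial_logistic`` wraps scikit-learn's LogisticRegression;
    ``nearest_centroid_softmax`` scores by softmax over negative squared
    distances to per-class centroids.
    """
    classes = _check_labelled(train)
    y = np.asarray(train.labels, dtype=object)
    if kind == "multinomial_logistic":
        clf = LogisticRegression(max_iter=2000, C=1.0)
        clf.fit(train.matrix, y)
        backend = clf
    elif kind == "nearest_centroid_softmax":
        centroids = np.vstack([train.matrix[y == c].mean(axis=0) for c in classes])
        within = float(np.mean([train.matrix[y == c].var(axis=0).sum()
                                for c in classes]))
        backend = _CentroidSoftmax(centroids, max(within, 1e-6), classes)
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    return SoftmaxModel(label_space=classes, gene_ids=train.gene_ids,
                        backend=backend, kind=kind)


def predict_proba(model: SoftmaxModel, cells: CellDataset) -> np.ndarray:
    """Softmax scores for each cell, columns in ``model.label_space`` order.

    Rows lie on the K-simplex; a 0-cell input yields a (0, K) matrix.
    """
    if not model.fitted:
        raise ValueError("model is not fitted")
    if list(cells.gene_ids) != list(model.gene_ids):
        extra = set(cells.gene_ids) - set(model.gene_ids)
        missing = set(model.gene_ids) - set(cells.gene_ids)
        raise ValueError(
            f"gene space mismatch: {len(missing)} training genes absent "
            f"(e.g. {sorted(missing)[:5]}), {len(extra)} unseen genes "
            f"(e.g. {sorted(extra)[:5]})"
        )
    K = model.n_classes
    if cells.n_cells == 0:
        return np.zeros((0, K))
    probs = model.backend.predict_proba(model._transform(cells.matrix))
    backend_order = list(model.backend.classes_)
    if backend_order != model.label_space:
        probs = probs[:, [backend_order.index(c) for c in model.label_space]]
    return probs


def save_model(model: SoftmaxModel, path: str) -> None:
    """Persist weights, config and label space to a single file."""
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path: str) -> SoftmaxModel:
    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if not isinstance(model, SoftmaxModel):
        raise ValueError(f"{path} does not contain a SoftmaxModel")
    return model
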