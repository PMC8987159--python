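"""Supervised comparison path: waveform classifier and SVM layer probes.

The comparison model shares the auto-encoder's encoder block structure
(conv + switch max-pool, first conv linear, ReLU elsewhere); a global
average pooling (GAP) over time at the deepest pooling output feeds a
fully connected softmax head. It is trained with cross-entropy, Adam,
batch 32 and early stopping on a held-out split.

``probe_layers`` measures how separably each layer represents the
stimulus categories: an RBF-kernel SVM is scored by stratified k-fold
cross-validation on the temporally averaged features of each layer.
"""

from __future__ import annotations

import copy

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._nn import (
    AdamW,
    conv1d_backward,
    conv1d_forward,
    glorot_uniform,
    max_pool,
    max_pool_backward,
    relu,
    relu_backward,
)


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class WaveformClassifier(ClassifierMixin, BaseEstimator):
    """Encoder + GAP + softmax audio-category classifier (numpy, CPU).

    Architecture parameters mirror :class:`~audenc.dcae.ConvAutoencoder`
    so the two models accept identical inputs and produce identically
    shaped pooling outputs. Early stopping monitors cross-entropy on a
    held-out fraction of the training windows and restores the best
    epoch's weights; ``patience=0`` stops at the first epoch without
    improvement.
    """

    def __init__(
        self,
        filters=(32, 64, 128, 256),
        filter_lengths=(64, 32, 16, 8),
        pool_factors=(1, 2, 2, 2),
        learning_rate=2e-4,
        beta_1=0.5,
        beta_2=0.999,
        epsilon=1e-8,
        weight_decay=0.0,
        batch_size=32,
        max_epochs=200,
        validation_fraction=0.1,
        patience=10,
        warm_start=False,
        random_state=None,
        verbose=0,
    ):
        self.filters = filters
        self.filter_lengths = filter_lengths
        self.pool_factors = pool_factors
        self.learning_rate = learning_rate
        self.beta_1 = beta_1
        self.beta_2 = beta_2
        self.epsilon = epsilon
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.warm_start = warm_start
        self.random_state = random_state
        self.verbose = verbose

    @property
    def n_layers_(self):
        return len(self.filters)

    def initialize(self, n_classes, random_state=None):
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        rng = np.random.default_rng(
            self.random_state if random_state is None else random_state
        )
        chans = (1,) + tuple(self.filters)
        self.encoder_weights_, self.encoder_biases_ = [], []
        for i in range(self.n_layers_):
            k = self.filter_lengths[i]
            self.encoder_weights_.append(
                glorot_uniform(
                    (k, chans[i], chans[i + 1]), k * chans[i], k * chans[i + 1], rng
                )
            )
            self.encoder_biases_.append(np.zeros(chans[i + 1]))
        cL = self.filters[-1]
        self.head_weights_ = glorot_uniform((cL, n_classes), cL, n_classes, rng)
        self.head_bias_ = np.zeros(n_classes)
        self.loss_curve_ = []
        self.validation_curve_ = []
        return self

    def set_encoder_weights(self, weights, biases):
        """Warm-start the encoder (e.g. from a trained auto-encoder)."""
        self.encoder_weights_ = [w.copy() for w in weights]
        self.encoder_biases_ = [b.copy() for b in biases]
        return self

    # -- forward -------------------------------------------------------

    def _truncate(self, X):
        P = int(np.prod(self.pool_factors))
        t = (X.shape[1] // P) * P
        return X[:, :t]

    def _encoder_forward(self, x3, need_grads):
        h = x3
        cache = []
        pooled_maps = []
        for i in range(self.n_layers_):
            y, cols = conv1d_forward(
                h,
                self.encoder_weights_[i],
                self.encoder_biases_[i],
                return_cols=need_grads,
            )
            a = y if i == 0 else relu(y)
            p, sw = max_pool(a, self.pool_factors[i])
            cache.append((h.shape, cols, a, sw))
            pooled_maps.append(p)
            h = p
        return h, pooled_maps, cache

    def _forward(self, x3, need_grads=False):
        h, pooled_maps, cache = self._encoder_forward(x3, need_grads)
        gap = h.mean(axis=1)  # (n, c_L)
        logits = gap @ self.head_weights_ + self.head_bias_
        return _softmax(logits), gap, h.shape[1], cache

    def _backward(self, dlogits, gap, tL, cache):
        gWh = gap.T @ dlogits
        gbh = dlogits.sum(axis=0)
        dgap = dlogits @ self.head_weights_.T
        dg = np.repeat(dgap[:, None, :], tL, axis=1) / tL
        gWe = [None] * self.n_layers_
        gbe = [None] * self.n_layers_
        for i in range(self.n_layers_ - 1, -1, -1):
            h_shape, cols, act, sw = cache[i]
            dg = max_pool_backward(dg, sw, self.pool_factors[i])
            if i > 0:
                dg = relu_backward(dg, act)
            dg, gWe[i], gbe[i] = conv1d_backward(
                dg, cols, self.encoder_weights_[i], h_shape
            )
        return gWe, gbe, gWh, gbh

    # -- estimator API -------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("training data contains a single class")
        yi = np.searchsorted(self.classes_, y)
        K = self.classes_.size
        already = self.warm_start and hasattr(self, "head_weights_")
        if not already:
            self.initialize(K)
        elif self.head_weights_.shape[1] != K:
            raise ValueError("class count changed between warm-started fits")
        self.n_features_in_ = X.shape[1]
        X = self._truncate(X)
        rng = np.random.default_rng(self.random_state)
        n = X.shape[0]
        n_val = max(1, int(round(self.validation_fraction * n))) if n > 2 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if tr_idx.size == 0:
            tr_idx, val_idx = perm, perm[:0]
        opt = AdamW(
            lr=self.learning_rate,
            beta_1=self.beta_1,
            beta_2=self.beta_2,
            eps=self.epsilon,
            weight_decay=self.weight_decay,
        )
        L = self.n_layers_
        decay = [True] * L + [False] * L + [True, False]
        best_val = np.inf
        best_state = None
        stall = 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(tr_idx)
            losses = []
            for s in range(0, order.size, self.batch_size):
                idx = order[s : s + self.batch_size]
                xb = X[idx][:, :, None]
                probs, gap, tL, cache = self._forward(xb, need_grads=True)
                onehot = np.eye(K)[yi[idx]]
                eps = 1e-12
                losses.append(-np.mean(np.log(probs[np.arange(idx.size), yi[idx]] + eps)))
                dlogits = (probs - onehot) / idx.size
                gWe, gbe, gWh, gbh = self._backward(dlogits, gap, tL, cache)
                opt.step(
                    self.encoder_weights_
                    + self.encoder_biases_
                    + [self.head_weights_, self.head_bias_],
                    gWe + gbe + [gWh, gbh],
                    decay,
                )
            self.loss_curve_.append(float(np.mean(losses)))
            if val_idx.size:
                probs, *_ = self._forward(X[val_idx][:, :, None])
                val_loss = float(
                    -np.mean(np.log(probs[np.arange(val_idx.size), yi[val_idx]] + 1e-12))
                )
            else:
                val_loss = self.loss_curve_[-1]
            self.validation_curve_.append(val_loss)
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_state = copy.deepcopy(
                    (
                        self.encoder_weights_,
                        self.encoder_biases_,
                        self.head_weights_,
                        self.head_bias_,
                    )
                )
                stall = 0
            else:
                stall += 1
                if stall > self.patience:
                    break
        if best_state is not None:  # restore the best epoch's weights
            (
                self.encoder_weights_,
                self.encoder_biases_,
                self.head_weights_,
                self.head_bias_,
            ) = best_state
        self.n_iter_ = len(self.loss_curve_)
        return self

    def predict_proba(self, X):
        X = self._truncate(np.asarray(X, dtype=float))
        probs, *_ = self._forward(X[:, :, None])
        return probs

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def encode(self, X):
        """Pooled feature maps per layer, as in the auto-encoder."""
        X = self._truncate(np.asarray(X, dtype=float))
        _, pooled_maps, _ = self._encoder_forward(X[:, :, None], need_grads=False)
        return pooled_maps


def median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF bandwidth by the median pairwise-distance heuristic.

    gamma = 1 / (2 * median(d)^2) over Euclidean pairwise distances
    (subsampled to 500 points for large inputs).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] > 500:
        X = X[np.random.default_rng(0).choice(X.shape[0], 500, replace=False)]
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    med = np.sqrt(np.median(d2[np.triu_indices_from(d2, k=1)]))
    return 1.0 / (2.0 * med**2) if med > 0 else 1.0


def probe_layers(
    layer_features,
    labels,
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> pd.DataFrame:
    """RBF-SVM probe of category separability at each layer.

    ``layer_features[i]`` holds the temporally averaged features of layer
    i+1, one row per window; ``labels`` the window categories. Features
    are z-scored inside each fold's pipeline; the kernel bandwidth uses
    the median heuristic (recorded in the report). Returns a tidy frame
    with one row per layer: mean/sd accuracy over stratified folds.
    """
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if np.any(counts < folds):
        raise ValueError(
            f"every class needs >= {folds} samples for {folds}-fold CV"
        )
    rows = []
    for i, feats in enumerate(layer_features, start=1):
        feats = np.asarray(feats, dtype=float)
        gamma = median_heuristic_gamma(StandardScaler().fit_transform(feats))
        clf = make_pipeline(StandardScaler(), SVC(C=C, kernel="rbf", gamma=gamma))
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        acc = cross_val_score(clf, feats, labels, cv=cv)
        rows.append(
            {
                "layer": i,
                "mean_accuracy": float(acc.mean()),
                "sd_accuracy": float(acc.std()),
                "folds": folds,
                "kernel": "rbf",
                "C": C,
                "gamma": gamma,
            }
        )
    return pd.DataFrame(rows)
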