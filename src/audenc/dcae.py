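"""Unsupervised 1-D deep convolutional auto-encoder over raw waveforms.

The encoder stacks conv + max-pool blocks; the decoder mirrors it with
switch-based un-pooling + deconv blocks, so each pooled maximum is
returned to its exact pre-pooling position during reconstruction. The
first encoder convolution and the last decoder deconvolution are linear;
every other layer uses ReLU. The training objective is

    L(W) = MSE(x, x_hat) + kappa * sum(W^2)

minimized with Adam (decoupled weight decay), mirroring the published
hyper-parameters: filters 32/64/128/256 of lengths 64/32/16/8, pooled
temporal lengths 24k/12k/6k/3k for a 24,000-sample (1.5 s at 16 kHz)
input window, kappa = 0.001, Adam(0.5, 0.999, 1e-8), lr 2e-4, weight
decay 1e-3, batch 32.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._nn import (
    AdamW,
    conv1d_backward,
    conv1d_forward,
    glorot_uniform,
    max_pool,
    max_pool_backward,
    max_unpool,
    max_unpool_backward,
    relu,
    relu_backward,
)
from .metrics import pearson_rows

_COL_BYTES_BUDGET = 512 * 2**20  # cap on the im2col scratch per conv call


def dcae_objective(x, x_hat, weights, kappa):
    """Reconstruction MSE plus kappa * sum of squared weights."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    mse = float(np.mean((x - x_hat) ** 2))
    reg = kappa * float(sum(np.sum(w * w) for w in weights))
    return mse + reg


class ConvAutoencoder(TransformerMixin, BaseEstimator):
    """Switch-unpooling 1-D convolutional auto-encoder (numpy, CPU).

    Parameters default to the published full-scale architecture; desk-scale
    work passes smaller ``filters`` / ``filter_lengths``. ``transform``
    returns the deepest pooling layer's temporally averaged features;
    ``encode`` exposes every layer's pooled feature map.

    Parameters
    ----------
    filters : tuple of int
        Channel count of each encoder conv layer.
    filter_lengths : tuple of int
        Kernel length of each encoder conv layer (decoder mirrors them).
    pool_factors : tuple of int
        Temporal reduction of each max-pooling stage; a factor of 1 keeps
        full resolution.
    l2_weight : float
        kappa of the L2 penalty on conv weights in the loss.
    weight_decay : float
        Decoupled (optimizer-side) weight decay, distinct from l2_weight.
    tol, patience : float, int
        Stop when the relative improvement of the best epoch loss stays
        below ``tol`` for ``patience`` consecutive epochs.
    warm_start : bool
        If True, ``fit`` continues from existing weights (fine-tuning
        after pre-training on a different corpus).

    Attributes
    ----------
    encoder_weights_, encoder_biases_ : list of ndarray
    decoder_weights_, decoder_biases_ : list of ndarray
    loss_curve_ : list of float
        Per-epoch mean objective on the training data.
    n_iter_ : int
    """

    def __init__(
        self,
        filters=(32, 64, 128, 256),
        filter_lengths=(64, 32, 16, 8),
        pool_factors=(1, 2, 2, 2),
        l2_weight=1e-3,
        learning_rate=2e-4,
        beta_1=0.5,
        beta_2=0.999,
        epsilon=1e-8,
        weight_decay=1e-3,
        batch_size=32,
        max_epochs=500,
        tol=1e-5,
        patience=50,
        warm_start=False,
        compute_dtype="float64",
        random_state=None,
        verbose=0,
    ):
        self.filters = filters
        self.filter_lengths = filter_lengths
        self.pool_factors = pool_factors
        self.l2_weight = l2_weight
        self.learning_rate = learning_rate
        self.beta_1 = beta_1
        self.beta_2 = beta_2
        self.epsilon = epsilon
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.tol = tol
        self.patience = patience
        self.warm_start = warm_start
        self.compute_dtype = compute_dtype
        self.random_state = random_state
        self.verbose = verbose

    # -- construction -------------------------------------------------

    @property
    def n_layers_(self) -> int:
        return len(self.filters)

    def _validate_arch(self):
        if not (
            len(self.filters) == len(self.filter_lengths) == len(self.pool_factors)
        ):
            raise ValueError(
                "filters, filter_lengths and pool_factors must have equal length"
            )
        if any(f < 1 for f in self.pool_factors):
            raise ValueError("pool factors must be >= 1")

    def initialize(self, random_state=None):
        """Build seeded Glorot-uniform weights without training."""
        self._validate_arch()
        rng = np.random.default_rng(
            self.random_state if random_state is None else random_state
        )
        L = self.n_layers_
        chans = (1,) + tuple(self.filters)
        self.encoder_weights_, self.encoder_biases_ = [], []
        self.decoder_weights_, self.decoder_biases_ = [], []
        for i in range(L):
            k = self.filter_lengths[i]
            self.encoder_weights_.append(
                glorot_uniform(
                    (k, chans[i], chans[i + 1]), k * chans[i], k * chans[i + 1], rng
                )
            )
            self.encoder_biases_.append(np.zeros(chans[i + 1]))
        for j in range(L - 1, -1, -1):  # mirrored: deepest stage first
            k = self.filter_lengths[j]
            self.decoder_weights_.append(
                glorot_uniform(
                    (k, chans[j + 1], chans[j]), k * chans[j + 1], k * chans[j], rng
                )
            )
            self.decoder_biases_.append(np.zeros(chans[j]))
        self.loss_curve_ = []
        self.n_iter_ = 0
        return self

    def _all_weights(self):
        return self.encoder_weights_ + self.decoder_weights_

    @property
    def pooled_lengths_(self):
        """Temporal length of each pooling output for the fitted input length."""
        t = self.n_features_in_
        out = []
        for f in self.pool_factors:
            t //= f
            out.append(t)
        return out

    # -- forward / backward -------------------------------------------

    def _truncate(self, X):
        P = math.prod(self.pool_factors)
        t = (X.shape[1] // P) * P
        if t < 1:
            raise ValueError("input windows shorter than total pooling factor")
        return X[:, :t]

    def _encoder_pass(self, x3, need_grads, cache):
        """Encoder half: conv -> activation -> switch max-pool per layer."""
        h = x3
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
            cache["enc"].append((h.shape, cols, a))
            cache["switches"].append(sw)
            pooled_maps.append(p)
            h = p
        return h, pooled_maps

    def _forward(self, x3, need_grads):
        """Full autoencoder pass. Returns (x_hat, pooled_maps, cache)."""
        L = self.n_layers_
        cache = {"enc": [], "switches": [], "dec": []}
        g, pooled_maps = self._encoder_pass(x3, need_grads, cache)
        for d, j in enumerate(range(L - 1, -1, -1)):
            u = max_unpool(g, cache["switches"][j], self.pool_factors[j])
            y, cols = conv1d_forward(
                u,
                self.decoder_weights_[d],
                self.decoder_biases_[d],
                return_cols=need_grads,
            )
            g = relu(y) if j > 0 else y
            cache["dec"].append((u.shape, cols, g))
        return g, pooled_maps, cache

    def _backward(self, dg, cache):
        """Backprop from d(loss)/d(x_hat); returns aligned gradient lists."""
        L = self.n_layers_
        gWd = [None] * L
        gbd = [None] * L
        for d in range(L - 1, -1, -1):
            j = L - 1 - d
            u_shape, cols, out = cache["dec"][d]
            if j > 0:
                dg = relu_backward(dg, out)
            dg, gWd[d], gbd[d] = conv1d_backward(
                dg, cols, self.decoder_weights_[d], u_shape
            )
            dg = max_unpool_backward(dg, cache["switches"][j], self.pool_factors[j])
        gWe = [None] * L
        gbe = [None] * L
        for i in range(L - 1, -1, -1):
            h_shape, cols, act = cache["enc"][i]
            dg = max_pool_backward(dg, cache["switches"][i], self.pool_factors[i])
            if i > 0:
                dg = relu_backward(dg, act)
            dg, gWe[i], gbe[i] = conv1d_backward(
                dg, cols, self.encoder_weights_[i], h_shape
            )
        return gWe, gbe, gWd, gbd

    # -- estimator API -------------------------------------------------

    def fit(self, X, y=None):
        """Train on a stack of waveform windows, shape (n_windows, t)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_windows, window_length)")
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        self._validate_arch()
        already = self.warm_start and hasattr(self, "encoder_weights_")
        if not already:
            self.initialize()
        self.n_features_in_ = X.shape[1]
        X = self._truncate(X)
        rng = np.random.default_rng(self.random_state)
        opt = AdamW(
            lr=self.learning_rate,
            beta_1=self.beta_1,
            beta_2=self.beta_2,
            eps=self.epsilon,
            weight_decay=self.weight_decay,
        )
        params = (
            self.encoder_weights_
            + self.encoder_biases_
            + self.decoder_weights_
            + self.decoder_biases_
        )
        L = self.n_layers_
        decay = [True] * L + [False] * L + [True] * L + [False] * L
        n = X.shape[0]
        best = np.inf
        stall = 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb = X[idx][:, :, None]
                x_hat, _, cache = self._forward(xb, need_grads=True)
                resid = x_hat - xb
                mse = float(np.mean(resid**2))
                reg = self.l2_weight * float(
                    sum(np.sum(w * w) for w in self._all_weights())
                )
                losses.append(mse + reg)
                dg = 2.0 * resid / resid.size
                gWe, gbe, gWd, gbd = self._backward(dg, cache)
                for gw, w in zip(gWe + gWd, self.encoder_weights_ + self.decoder_weights_):
                    gw += 2.0 * self.l2_weight * w
                opt.step(params, gWe + gbe + gWd + gbd, decay)
            epoch_loss = float(np.mean(losses))
            self.loss_curve_.append(epoch_loss)
            self.n_iter_ = epoch + 1
            if self.verbose and epoch % max(1, self.max_epochs // 20) == 0:
                print(f"epoch {epoch}: loss {epoch_loss:.6f}")
            if best - epoch_loss > self.tol * max(best, 1e-12):
                best = epoch_loss
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        return self

    def _chunk_size(self, t):
        # bound the im2col scratch of the widest conv layer
        worst = max(
            k * c for k, c in zip(self.filter_lengths, (1,) + tuple(self.filters))
        )
        return max(1, int(_COL_BYTES_BUDGET / (t * worst * 8)))

    def encode(self, X):
        """Pooled feature maps per layer: list of (n, t_i, c_i) arrays.

        Inference-only passes honor ``compute_dtype`` (float32 roughly
        halves memory and speeds the large matmuls); training always
        runs in float64.
        """
        self._check_fitted()
        X = self._truncate(np.asarray(X, dtype=self.compute_dtype))
        n, t = X.shape
        chunk = self._chunk_size(t)
        per_layer = None
        with self._cast_weights():
            for s in range(0, n, chunk):
                _, maps = self._encoder_pass(
                    X[s : s + chunk][:, :, None],
                    need_grads=False,
                    cache={"enc": [], "switches": []},
                )
                if per_layer is None:
                    per_layer = [[m] for m in maps]
                else:
                    for acc, m in zip(per_layer, maps):
                        acc.append(m)
        return [np.concatenate(acc, axis=0).astype(float) for acc in per_layer]

    def _cast_weights(self):
        """Temporarily view weights in compute_dtype for inference passes."""
        import contextlib

        @contextlib.contextmanager
        def _ctx():
            if np.dtype(self.compute_dtype) == np.float64:
                yield
                return
            saved = (
                self.encoder_weights_,
                self.encoder_biases_,
                self.decoder_weights_,
                self.decoder_biases_,
            )
            try:
                dt = self.compute_dtype
                self.encoder_weights_ = [w.astype(dt) for w in saved[0]]
                self.encoder_biases_ = [b.astype(dt) for b in saved[1]]
                self.decoder_weights_ = [w.astype(dt) for w in saved[2]]
                self.decoder_biases_ = [b.astype(dt) for b in saved[3]]
                yield
            finally:
                (
                    self.encoder_weights_,
                    self.encoder_biases_,
                    self.decoder_weights_,
                    self.decoder_biases_,
                ) = saved

        return _ctx()

    def reconstruct(self, X):
        """Decoder output, shape (n, t_truncated)."""
        self._check_fitted()
        X = self._truncate(np.asarray(X, dtype=float))
        n, t = X.shape
        chunk = self._chunk_size(t)
        outs = []
        for s in range(0, n, chunk):
            x_hat, _, _ = self._forward(X[s : s + chunk][:, :, None], need_grads=False)
            outs.append(x_hat[:, :, 0])
        return np.concatenate(outs, axis=0)

    def transform(self, X):
        """Deepest-layer pooled map, temporally averaged: (n, c_last)."""
        return self.encode(X)[-1].mean(axis=1)

    def score(self, X, y=None):
        """Mean reconstruction PCC across windows (NaNs excluded)."""
        mean, _, _ = reconstruction_pcc(self, X)
        return mean

    def objective(self, X):
        """Full training objective (MSE + kappa L2) on X."""
        X = self._truncate(np.asarray(X, dtype=float))
        return dcae_objective(
            X, self.reconstruct(X), self._all_weights(), self.l2_weight
        )

    def _check_fitted(self):
        if not hasattr(self, "encoder_weights_"):
            raise RuntimeError("model is not initialized; call fit() or initialize()")
        if not hasattr(self, "n_features_in_"):
            self.n_features_in_ = None  # initialized-but-unfitted is allowed

    # -- persistence ---------------------------------------------------

    def save(self, path):
        """Checkpoint weights (npz) with a YAML sidecar of the parameters."""
        import yaml

        path = str(path)
        arrays = {}
        for i, (w, b) in enumerate(zip(self.encoder_weights_, self.encoder_biases_)):
            arrays[f"enc_W{i}"], arrays[f"enc_b{i}"] = w, b
        for i, (w, b) in enumerate(zip(self.decoder_weights_, self.decoder_biases_)):
            arrays[f"dec_W{i}"], arrays[f"dec_b{i}"] = w, b
        np.savez_compressed(path, **arrays)
        sidecar = path[: -len(".npz")] if path.endswith(".npz") else path
        with open(sidecar + ".yaml", "w") as fh:
            yaml.safe_dump(self.get_params(), fh)

    @classmethod
    def load(cls, path):
        import yaml

        path = str(path)
        sidecar = path[: -len(".npz")] if path.endswith(".npz") else path
        with open(sidecar + ".yaml") as fh:
            params = yaml.safe_load(fh)
        for key in ("filters", "filter_lengths", "pool_factors"):
            params[key] = tuple(params[key])
        model = cls(**params)
        data = np.load(path)
        L = model.n_layers_
        model.encoder_weights_ = [data[f"enc_W{i}"] for i in range(L)]
        model.encoder_biases_ = [data[f"enc_b{i}"] for i in range(L)]
        model.decoder_weights_ = [data[f"dec_W{i}"] for i in range(L)]
        model.decoder_biases_ = [data[f"dec_b{i}"] for i in range(L)]
        model.loss_curve_ = []
        model.n_iter_ = 0
        return model


def reconstruction_pcc(model, windows):
    """Per-window PCC between inputs and reconstructions.

    Returns (mean, sd, per_window). Windows with zero variance have
    undefined correlation; they are reported as NaN and excluded from
    the mean and SD.
    """
    X = model._truncate(np.asarray(windows, dtype=float))
    r = pearson_rows(X, model.reconstruct(X))
    valid = r[~np.isnan(r)]
    if valid.size == 0:
        return np.nan, np.nan, r
    return float(valid.mean()), float(valid.std()), r


def filter_spectrum_order(model, layer, sample_rate=16_000, n_fft=2048):
    """Sort a layer's filters by the frequency of their spectral peak.

    Each filter's power spectrum is the squared rFFT magnitude of its
    impulse response summed over input channels, on the frequency axis of
    that layer's input rate (the audio rate divided by the upstream
    pooling product). Returns (order, peak_frequencies); an all-zero
    filter gets NaN and sorts last.
    """
    model._check_fitted()
    if not 1 <= layer <= model.n_layers_:
        raise ValueError(f"layer must be in 1..{model.n_layers_}")
    W = model.encoder_weights_[layer - 1]  # (k, c_in, c_out)
    rate = sample_rate / math.prod(model.pool_factors[: layer - 1])
    spec = np.abs(np.fft.rfft(W, n=n_fft, axis=0)) ** 2
    power = spec.sum(axis=1)  # (n_fft//2+1, c_out)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    peaks = freqs[np.argmax(power, axis=0)]
    peaks = np.where(power.sum(axis=0) == 0, np.nan, peaks)
    order = np.argsort(peaks, kind="stable")  # NaNs sort last
    return order, peaks
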