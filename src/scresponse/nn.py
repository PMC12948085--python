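"""A compact numpy neural-network core for the pipeline's convolutional models.

Implements exactly the layers the classifier architectures need — dense,
1-D/2-D convolution (channels-last), batch normalization, max pooling,
global max pooling, dropout — with manual backpropagation, the Adam
optimizer, binary cross-entropy on logits, early stopping and best-weight
checkpointing. Because the backward pass is explicit, class-score gradients
with respect to any intermediate feature map are available, which is what
Grad-CAM needs.

Everything is deterministic given the seeds passed to the builders and to
``fit``; there is no hidden global state.

Conventions: 1-D inputs are ``(N, L, C)``, 2-D inputs ``(N, H, W, C)``;
the final layer emits logits ``(N, 1)``.
"""

from __future__ import annotations

import copy
import warnings
from typing import Sequence

import numpy as np

from .errors import ArchitectureError, ValidationError


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits and its gradient d loss / d z."""
    z = z.reshape(-1)
    y = y.reshape(-1)
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    dz = ((sigmoid(z) - y) / z.size).reshape(-1, 1)
    return loss, dz


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, *, he: bool = True, dtype=np.float64):
        super().__init__()
        std = np.sqrt(2.0 / n_in) if he else np.sqrt(1.0 / n_in)
        self.params = {
            "W": rng.normal(0.0, std, size=(n_in, n_out)).astype(dtype),
            "b": np.zeros(n_out, dtype=dtype),
        }

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g):
        self.grads["W"] = self._x.T @ g
        self.grads["b"] = g.sum(axis=0)
        return g @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Dropout(Layer):
    def __init__(self, rate: float):
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValidationError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if train and self.rate > 0.0:
            if rng is None:
                raise ValidationError("Dropout in training mode requires an rng")
            self._mask = ((rng.random(x.shape) >= self.rate) / (1.0 - self.rate)).astype(x.dtype)
            return x * self._mask
        self._mask = None
        return x

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class BatchNorm(Layer):
    """Per-channel batch normalization over all non-channel axes."""

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float64):
        super().__init__()
        self.params = {"gamma": np.ones(n_channels, dtype=dtype), "beta": np.zeros(n_channels, dtype=dtype)}
        self.running_mean = np.zeros(n_channels, dtype=dtype)
        self.running_var = np.ones(n_channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            self._train_mode = True
        else:
            mu, var = self.running_mean, self.running_var
            self._train_mode = False
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._istd
        self._m = x.size // x.shape[-1]
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, g):
        axes = tuple(range(g.ndim - 1))
        self.grads["gamma"] = (g * self._xhat).sum(axis=axes)
        self.grads["beta"] = g.sum(axis=axes)
        gamma = self.params["gamma"]
        if not self._train_mode:
            return g * gamma * self._istd
        m = self._m
        sum_g = g.sum(axis=axes)
        sum_gx = (g * self._xhat).sum(axis=axes)
        return (gamma * self._istd / m) * (m * g - sum_g - self._xhat * sum_gx)


def _pad_amounts(k: int) -> tuple[int, int]:
    return (k - 1) // 2, k // 2


class Conv1D(Layer):
    def __init__(self, in_channels: int, filters: int, kernel: int, rng: np.random.Generator, padding: str = "same", dtype=np.float64):
        super().__init__()
        if padding not in ("same", "valid"):
            raise ValidationError(f"padding must be 'same' or 'valid', got {padding!r}")
        std = np.sqrt(2.0 / (kernel * in_channels))
        self.params = {
            "W": rng.normal(0.0, std, size=(kernel, in_channels, filters)).astype(dtype),
            "b": np.zeros(filters, dtype=dtype),
        }
        self.kernel = kernel
        self.padding = padding

    def forward(self, x, train=False, rng=None):
        k = self.kernel
        if self.padding == "same":
            pl, pr = _pad_amounts(k)
            xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        else:
            if x.shape[1] < k:
                raise ArchitectureError(
                    f"input length {x.shape[1]} shorter than kernel {k} (valid padding)"
                )
            xp = x
        L_out = xp.shape[1] - k + 1
        self._xp = xp
        self._in_len = x.shape[1]
        y = np.tile(self.params["b"], (x.shape[0], L_out, 1))
        W = self.params["W"]
        for i in range(k):
            y += xp[:, i : i + L_out, :] @ W[i]
        return y

    def backward(self, g):
        k = self.kernel
        xp, W = self._xp, self.params["W"]
        L_out = g.shape[1]
        dW = np.empty_like(W)
        dxp = np.zeros_like(xp)
        for i in range(k):
            dW[i] = np.tensordot(xp[:, i : i + L_out, :], g, axes=([0, 1], [0, 1]))
            dxp[:, i : i + L_out, :] += g @ W[i].T
        self.grads["W"] = dW
        self.grads["b"] = g.sum(axis=(0, 1))
        if self.padding == "same":
            pl, _ = _pad_amounts(k)
            return dxp[:, pl : pl + self._in_len, :]
        return dxp


class Conv2D(Layer):
    def __init__(
        self,
        in_channels: int,
        filters: int,
        kernel: tuple[int, int] = (3, 3),
        rng: np.random.Generator | None = None,
        padding: str = "same",
        dtype=np.float64,
    ):
        super().__init__()
        if padding not in ("same", "valid"):
            raise ValidationError(f"padding must be 'same' or 'valid', got {padding!r}")
        kh, kw = kernel
        std = np.sqrt(2.0 / (kh * kw * in_channels))
        self.params = {
            "W": rng.normal(0.0, std, size=(kh, kw, in_channels, filters)).astype(dtype),
            "b": np.zeros(filters, dtype=dtype),
        }
        self.kernel = (kh, kw)
        self.padding = padding

    def forward(self, x, train=False, rng=None):
        kh, kw = self.kernel
        if self.padding == "same":
            pt, pb = _pad_amounts(kh)
            pl, pr = _pad_amounts(kw)
            xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        else:
            if x.shape[1] < kh or x.shape[2] < kw:
                raise ArchitectureError(
                    f"input {x.shape[1]}x{x.shape[2]} smaller than kernel {kh}x{kw} (valid padding)"
                )
            xp = x
        H_out = xp.shape[1] - kh + 1
        W_out = xp.shape[2] - kw + 1
        self._xp = xp
        self._in_hw = (x.shape[1], x.shape[2])
        y = np.tile(self.params["b"], (x.shape[0], H_out, W_out, 1))
        W = self.params["W"]
        for i in range(kh):
            for j in range(kw):
                y += xp[:, i : i + H_out, j : j + W_out, :] @ W[i, j]
        return y

    def backward(self, g):
        kh, kw = self.kernel
        xp, W = self._xp, self.params["W"]
        H_out, W_out = g.shape[1], g.shape[2]
        dW = np.empty_like(W)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, i : i + H_out, j : j + W_out, :]
                dW[i, j] = np.tensordot(patch, g, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, i : i + H_out, j : j + W_out, :] += g @ W[i, j].T
        self.grads["W"] = dW
        self.grads["b"] = g.sum(axis=(0, 1, 2))
        if self.padding == "same":
            pt, _ = _pad_amounts(kh)
            pl, _ = _pad_amounts(kw)
            h, w = self._in_hw
            return dxp[:, pt : pt + h, pl : pl + w, :]
        return dxp


class MaxPool1D(Layer):
    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, train=False, rng=None):
        p = self.pool
        L2 = x.shape[1] // p
        if L2 < 1:
            raise ArchitectureError(f"input length {x.shape[1]} too short for pool size {p}")
        xt = x[:, : L2 * p, :].reshape(x.shape[0], L2, p, x.shape[2])
        self._arg = xt.argmax(axis=2)
        self._shape = x.shape
        return xt.max(axis=2)

    def backward(self, g):
        n, L2, c = g.shape
        p = self.pool
        d = np.zeros((n, L2, p, c), dtype=g.dtype)
        np.put_along_axis(d, self._arg[:, :, None, :], g[:, :, None, :], axis=2)
        out = np.zeros(self._shape, dtype=g.dtype)
        out[:, : L2 * p, :] = d.reshape(n, L2 * p, c)
        return out


class MaxPool2D(Layer):
    def __init__(self, pool: tuple[int, int] = (2, 2)):
        super().__init__()
        self.pool = pool

    def forward(self, x, train=False, rng=None):
        ph, pw = self.pool
        n, h, w, c = x.shape
        H2, W2 = h // ph, w // pw
        if H2 < 1 or W2 < 1:
            raise ArchitectureError(f"input {h}x{w} too small for pool {ph}x{pw}")
        xt = (
            x[:, : H2 * ph, : W2 * pw, :]
            .reshape(n, H2, ph, W2, pw, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, H2, W2, ph * pw, c)
        )
        self._arg = xt.argmax(axis=3)
        self._shape = x.shape
        return xt.max(axis=3)

    def backward(self, g):
        ph, pw = self.pool
        n, H2, W2, c = g.shape
        d = np.zeros((n, H2, W2, ph * pw, c), dtype=g.dtype)
        np.put_along_axis(d, self._arg[:, :, :, None, :], g[:, :, :, None, :], axis=3)
        d = d.reshape(n, H2, W2, ph, pw, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, H2 * ph, W2 * pw, c)
        out = np.zeros(self._shape, dtype=g.dtype)
        out[:, : H2 * ph, : W2 * pw, :] = d
        return out


class GlobalMaxPool2D(Layer):
    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        flat = x.reshape(n, h * w, c)
        self._arg = flat.argmax(axis=1)
        self._shape = x.shape
        return flat.max(axis=1)

    def backward(self, g):
        n, h, w, c = self._shape
        d = np.zeros((n, h * w, c), dtype=g.dtype)
        np.put_along_axis(d, self._arg[:, None, :], g[:, None, :], axis=1)
        return d.reshape(self._shape)


class NeuralNet:
    """A sequential network with Adam training and Grad-CAM support.

    ``feature_layer`` marks the index (into ``layers``) of the final
    convolutional activation; :meth:`gradcam` backpropagates the class score
    only through the head above that index.
    """

    def __init__(self, layers: Sequence[Layer], feature_layer: int | None = None):
        self.layers = list(layers)
        self.feature_layer = feature_layer
        self.history: dict[str, list[float]] = {}

    @property
    def dtype(self):
        for layer in self.layers:
            for p in layer.params.values():
                return p.dtype
        return np.float64

    # ------------------------------------------------------------------ core
    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def predict_proba(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        out = [
            sigmoid(self.forward(X[i : i + batch_size])).reshape(-1)
            for i in range(0, X.shape[0], batch_size)
        ]
        return np.concatenate(out) if out else np.empty(0)

    def _param_items(self):
        for li, layer in enumerate(self.layers):
            for name in layer.params:
                yield li, name

    def get_weights(self):
        return [copy.deepcopy(layer.params) for layer in self.layers]

    def set_weights(self, weights):
        for layer, w in zip(self.layers, weights):
            layer.params = copy.deepcopy(w)

    # ------------------------------------------------------------------- fit
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        *,
        epochs: int = 30,
        batch_size: int = 64,
        lr: float = 1e-4,
        seed: int = 42,
        val_fraction: float = 0.1,
        val_data: tuple[np.ndarray, np.ndarray] | None = None,
        patience: int = 3,
        restore_best: str | None = "val_accuracy",
        verbose: bool = False,
    ) -> dict[str, list[float]]:
        """Train with Adam + BCE; early-stop on validation loss.

        ``patience`` counts consecutive epochs without a validation-loss
        improvement. ``restore_best='val_accuracy'`` checkpoints the weights
        with the best validation accuracy and restores them after training
        (``None`` keeps the final weights).
        """
        X = np.asarray(X, dtype=self.dtype)
        y = np.asarray(y, dtype=float).reshape(-1)
        rng = np.random.default_rng([int(seed) % (2**31), 17])
        if val_data is None:
            tr_idx, va_idx = _stratified_holdout(y, val_fraction, rng)
            X_tr, y_tr = X[tr_idx], y[tr_idx]
            X_va, y_va = X[va_idx], y[va_idx]
        else:
            X_tr, y_tr = X, y
            X_va, y_va = val_data
            y_va = np.asarray(y_va, dtype=float).reshape(-1)

        state = {key: (np.zeros_like(self.layers[key[0]].params[key[1]]),
                       np.zeros_like(self.layers[key[0]].params[key[1]]))
                 for key in self._param_items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-7
        t = 0
        history: dict[str, list[float]] = {"loss": [], "val_loss": [], "val_accuracy": []}
        best_val_loss = np.inf
        best_ckpt_metric = -np.inf
        best_weights = None
        bad_epochs = 0

        n = X_tr.shape[0]
        for epoch in range(epochs):
            perm = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = perm[start : start + batch_size]
                z = self.forward(X_tr[idx], train=True, rng=rng)
                loss, dz = bce_with_logits(z, y_tr[idx])
                epoch_loss += loss * len(idx)
                g = dz.astype(self.dtype)
                for layer in reversed(self.layers):
                    g = layer.backward(g)
                t += 1
                for (li, name), (m, v) in state.items():
                    grad = self.layers[li].grads[name]
                    m += (1 - beta1) * (grad - m)
                    v += (1 - beta2) * (grad * grad - v)
                    mhat = m / (1 - beta1**t)
                    vhat = v / (1 - beta2**t)
                    self.layers[li].params[name] -= lr * mhat / (np.sqrt(vhat) + eps)
            epoch_loss /= n

            z_va = self.forward(X_va)
            val_loss, _ = bce_with_logits(z_va, y_va)
            val_acc = float(np.mean((sigmoid(z_va).reshape(-1) >= 0.5) == (y_va >= 0.5)))
            history["loss"].append(epoch_loss)
            history["val_loss"].append(val_loss)
            history["val_accuracy"].append(val_acc)
            if verbose:  # pragma: no cover - debugging aid
                print(f"epoch {epoch + 1}: loss={epoch_loss:.4f} val_loss={val_loss:.4f} val_acc={val_acc:.3f}")

            if restore_best == "val_accuracy" and val_acc > best_ckpt_metric:
                best_ckpt_metric = val_acc
                best_weights = self.get_weights()

            if val_loss < best_val_loss - 1e-12:
                best_val_loss = val_loss
                bad_epochs = 0
                if restore_best == "val_loss":
                    best_weights = self.get_weights()
            else:
                bad_epochs += 1
                if bad_epochs >= patience:
                    break

        if restore_best is not None and best_weights is not None:
            self.set_weights(best_weights)
        self.history = history
        return history

    # --------------------------------------------------------------- gradcam
    def gradcam(self, X: np.ndarray, class_sign: float = 1.0, batch_size: int = 64) -> np.ndarray:
        """Grad-CAM maps at the feature-layer resolution, one per input row.

        Channel weights are the spatial means of the class-score gradient at
        the marked feature layer; the map is the rectified weighted sum of
        the activation channels. ``class_sign`` is +1 for the positive class
        (its score is the logit) and -1 for the negative class.
        """
        if self.feature_layer is None:
            raise ValidationError("this network has no feature_layer marked for Grad-CAM")
        cams = []
        for start in range(0, X.shape[0], batch_size):
            xb = X[start : start + batch_size]
            h = xb
            acts = None
            for i, layer in enumerate(self.layers):
                h = layer.forward(h, train=False)
                if i == self.feature_layer:
                    acts = h
            g = np.full((xb.shape[0], 1), float(class_sign), dtype=self.dtype)
            for layer in reversed(self.layers[self.feature_layer + 1 :]):
                g = layer.backward(g)
            if not np.any(g):
                warnings.warn("Grad-CAM: zero gradient at the feature layer (saturated output)")
            spatial_axes = tuple(range(1, acts.ndim - 1))
            w = g.mean(axis=spatial_axes, keepdims=True)
            cam = np.maximum((w * acts).sum(axis=-1), 0.0)
            cams.append(cam)
        return np.concatenate(cams, axis=0)


def _stratified_holdout(y: np.ndarray, fraction: float, rng: np.random.Generator):
    """Deterministic per-class holdout split; returns (train_idx, val_idx)."""
    if not (0.0 < fraction < 1.0):
        raise ValidationError(f"val_fraction must be in (0, 1), got {fraction}")
    val_idx = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        n_val = max(1, int(round(fraction * len(idx))))
        val_idx.append(idx[:n_val])
    val_idx = np.sort(np.concatenate(val_idx))
    train_idx = np.setdiff1d(np.arange(len(y)), val_idx)
    if len(train_idx) == 0:
        raise ValidationError("validation fraction leaves no training rows")
    return train_idx, val_idx


# ----------------------------------------------------------------- builders
def build_gene_cnn1d(
    n_features: int,
    seed: int = 42,
    filters: tuple[int, int] = (32, 64),
    kernel: int = 5,
    dense_units: int = 64,
    dropout: float = 0.3,
    dtype=np.float32,
) -> NeuralNet:
    """Gene-level 1-D CNN: two conv blocks (conv, ReLU, batch norm, max pool,
    dropout) over the DEG axis, then a dense head with a sigmoid output.

    Filter counts and kernel size are package defaults (the architecture
    sketch fixes the block structure, not the widths).
    """
    if n_features < 4:
        raise ArchitectureError(
            f"gene 1D-CNN needs at least 4 features for its two 2x poolings, got {n_features}"
        )
    rng = np.random.default_rng([int(seed) % (2**31), 11])
    f1, f2 = filters
    layers = [
        Conv1D(1, f1, kernel, rng, padding="same", dtype=dtype),
        ReLU(),
        BatchNorm(f1, dtype=dtype),
        MaxPool1D(2),
        Dropout(dropout),
        Conv1D(f1, f2, kernel, rng, padding="same", dtype=dtype),
        ReLU(),
        BatchNorm(f2, dtype=dtype),
        MaxPool1D(2),
        Dropout(dropout),
        Flatten(),
        Dense((n_features // 2 // 2) * f2, dense_units, rng, dtype=dtype),
        ReLU(),
        Dense(dense_units, 1, rng, he=False, dtype=dtype),
    ]
    return NeuralNet(layers)


def build_pathway_cnn1d(
    n_features: int,
    seed: int = 42,
    filters: tuple[int, int, int] = (128, 64, 32),
    kernels: tuple[int, int, int] = (15, 15, 5),
    dense_units: int = 64,
    dropout: float = 0.3,
    dtype=np.float32,
) -> NeuralNet:
    """Pathway-pair 1-D CNN: three conv blocks (128xk15, 64xk15, 32xk5, each
    conv -> ReLU -> dropout -> max pool 2), flatten, dense 64, sigmoid."""
    if n_features < 8:
        raise ArchitectureError(
            f"pathway 1D-CNN needs at least 8 features for its three 2x poolings, got {n_features}"
        )
    rng = np.random.default_rng([int(seed) % (2**31), 12])
    f1, f2, f3 = filters
    k1, k2, k3 = kernels
    layers = [
        Conv1D(1, f1, k1, rng, padding="same", dtype=dtype),
        ReLU(),
        Dropout(dropout),
        MaxPool1D(2),
        Conv1D(f1, f2, k2, rng, padding="same", dtype=dtype),
        ReLU(),
        Dropout(dropout),
        MaxPool1D(2),
        Conv1D(f2, f3, k3, rng, padding="same", dtype=dtype),
        ReLU(),
        Dropout(dropout),
        MaxPool1D(2),
        Flatten(),
        Dense((n_features // 2 // 2 // 2) * f3, dense_units, rng, dtype=dtype),
        ReLU(),
        Dropout(dropout),
        Dense(dense_units, 1, rng, he=False, dtype=dtype),
    ]
    return NeuralNet(layers)


def build_pathway_cnn2d(
    height: int,
    width: int,
    seed: int = 42,
    filters: tuple[int, int] = (128, 64),
    dense_units: int = 64,
    dropout: float = 0.3,
    dtype=np.float32,
) -> NeuralNet:
    """Pathway-image 2-D CNN: conv 128@3x3 'same' -> ReLU -> dropout -> 2x2
    pool, conv 64@3x3 'valid' -> ReLU -> dropout -> 2x2 pool, global max
    pool, dense 64, sigmoid. Grad-CAM reads the second conv's activations.
    """
    h2, w2 = height // 2, width // 2
    if h2 - 2 < 2 or w2 - 2 < 2:
        raise ArchitectureError(
            "pathway 2D-CNN needs an image of at least 8x8 "
            f"(two 2x2 poolings around a valid 3x3 conv); got {height}x{width}"
        )
    rng = np.random.default_rng([int(seed) % (2**31), 13])
    f1, f2 = filters
    layers = [
        Conv2D(1, f1, (3, 3), rng, padding="same", dtype=dtype),
        ReLU(),
        Dropout(dropout),
        MaxPool2D((2, 2)),
        Conv2D(f1, f2, (3, 3), rng, padding="valid", dtype=dtype),
        ReLU(),
        Dropout(dropout),
        MaxPool2D((2, 2)),
        GlobalMaxPool2D(),
        Dense(f2, dense_units, rng, dtype=dtype),
        ReLU(),
        Dropout(dropout),
        Dense(dense_units, 1, rng, he=False, dtype=dtype),
    ]
    return NeuralNet(layers, feature_layer=5)  # ReLU after the final conv
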