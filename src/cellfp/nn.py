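"""Minimal convolutional-network core in numpy.

Implements exactly the pieces the feature-profiling workflow needs: stride-1
"same" convolutions, batch normalization, ReLU, 2x2 max pooling, dense layers,
inverted dropout, a softmax/cross-entropy head, Adam with cosine learning-rate
decay, and reverse-mode gradients both for the parameters and for the input
image (the latter drives the gradient-map interpretation).

Layers are functional: ``forward`` returns ``(output, cache)`` and ``backward``
consumes the cache, so a network instance can be used concurrently for
training and for input-gradient queries without hidden state beyond the
parameters and batch-norm running statistics.

Tensor layout is NCHW for images and (N, D) for dense activations.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats


def truncated_normal(rng: np.random.Generator, shape, std=0.1, dtype=np.float32):
    """Weights drawn from a normal truncated at +-2 sigma (std defaults to 0.1)."""
    vals = stats.truncnorm.rvs(-2.0, 2.0, scale=std, size=shape, random_state=rng)
    return np.asarray(vals, dtype=dtype)


class Layer:
    """Base layer; subclasses override forward/backward."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}

    def forward(self, x, train=False, rng=None):
        raise NotImplementedError

    def backward(self, dout, cache):
        """Return (dx, grads) where grads maps param name -> gradient."""
        raise NotImplementedError


def _im2col(x, k):
    """x: (N, C, H, W) padded -> columns (N*Ho*Wo, C*k*k) for stride-1 windows."""
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # N, C, Ho, Wo, k, k
    n, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), (n, ho, wo)


class Conv2D(Layer):
    """k x k convolution (cross-correlation), stride 1, zero "same" padding."""

    def __init__(self, c_in, c_out, k=3, rng=None, std=0.1, dtype=np.float32):
        super().__init__()
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.pad = k // 2
        rng = rng or np.random.default_rng(0)
        self.params = {
            "W": truncated_normal(rng, (c_out, c_in, k, k), std=std, dtype=dtype),
            "b": np.zeros(c_out, dtype=dtype),
        }

    def forward(self, x, train=False, rng=None):
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols, (n, ho, wo) = _im2col(xp, self.k)
        wmat = self.params["W"].reshape(self.c_out, -1)
        out = cols @ wmat.T + self.params["b"]
        out = out.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)
        return out, (cols, x.shape)

    def backward(self, dout, cache):
        cols, x_shape = cache
        n, _, h, w = x_shape
        dm = dout.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        wmat = self.params["W"].reshape(self.c_out, -1)
        dW = (dm.T @ cols).reshape(self.params["W"].shape)
        db = dm.sum(axis=0)
        # dx = full correlation of dout with the flipped kernels
        p = self.pad
        dpad = np.pad(
            dout.astype(cols.dtype, copy=False), ((0, 0), (0, 0), (p, p), (p, p))
        )
        dcols, _ = _im2col(dpad, self.k)
        wflip = self.params["W"][:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        dx = dcols @ wflip.reshape(self.c_in, -1).T
        dx = dx.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)
        return dx, {"W": dW, "b": db}


class BatchNorm2D(Layer):
    def __init__(self, c, momentum=0.9, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {"gamma": np.ones(c, dtype=dtype), "beta": np.zeros(c, dtype=dtype)}
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)

    def forward(self, x, train=False, rng=None):
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        out = g * xhat + b
        return out, (xhat, inv, train, x.shape)

    def backward(self, dout, cache):
        xhat, inv, train, x_shape = cache
        g = self.params["gamma"][None, :, None, None]
        dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        dbeta = dout.sum(axis=(0, 2, 3))
        if not train:
            dx = dout * g * inv[None, :, None, None]
            return dx, {"gamma": dgamma, "beta": dbeta}
        n, _, h, w = x_shape
        m = n * h * w
        dxhat = dout * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[None, :, None, None]
        return dx, {"gamma": dgamma, "beta": dbeta}


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        out = np.maximum(x, 0)
        return out, (x > 0)

    def backward(self, dout, cache):
        return dout * cache, {}


class MaxPool2D(Layer):
    """Non-overlapping 2x2 max pooling."""

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        return out, (idx, x.shape)

    def backward(self, dout, cache):
        idx, (n, c, h, w) = cache
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(n, c, h, w), {}


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        return x.reshape(x.shape[0], -1), x.shape

    def backward(self, dout, cache):
        return dout.reshape(cache), {}


class Dense(Layer):
    def __init__(self, d_in, d_out, rng=None, std=0.1, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params = {
            "W": truncated_normal(rng, (d_in, d_out), std=std, dtype=dtype),
            "b": np.zeros(d_out, dtype=dtype),
        }

    def forward(self, x, train=False, rng=None):
        return x @ self.params["W"] + self.params["b"], x

    def backward(self, dout, cache):
        x = cache
        return dout @ self.params["W"].T, {"W": x.T @ dout, "b": dout.sum(axis=0)}


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p):
        super().__init__()
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p <= 0:
            return x, None
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * mask.astype(x.dtype), mask

    def backward(self, dout, cache):
        if cache is None:
            return dout, {}
        return dout * cache.astype(dout.dtype), {}


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs, y, eps=1e-12):
    """Mean categorical cross-entropy; y is an int class vector."""
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))


@dataclass
class ConvNet:
    """A sequential conv net with a designated feature layer.

    ``feature_layer`` indexes the Dense layer whose (pre-activation) output is
    the feature profile; the layers after it form the classification head.
    """

    layers: list
    feature_layer: int
    dtype: type = np.float32

    def forward(self, x, train=False, rng=None):
        caches = []
        h = np.asarray(x, dtype=self.dtype)
        features = None
        for i, layer in enumerate(self.layers):
            h, cache = layer.forward(h, train=train, rng=rng)
            caches.append(cache)
            if i == self.feature_layer:
                features = h
        return features, h, caches

    def predict_proba(self, x, batch_size=256):
        out = []
        for i in range(0, len(x), batch_size):
            _, logits, _ = self.forward(x[i : i + batch_size], train=False)
            out.append(softmax(logits))
        return np.concatenate(out, axis=0)

    def features(self, x, batch_size=256):
        out = []
        for i in range(0, len(x), batch_size):
            f, _, _ = self.forward(x[i : i + batch_size], train=False)
            out.append(f)
        return np.concatenate(out, axis=0)

    def loss_and_grads(self, x, y, rng=None):
        """Cross-entropy loss and parameter gradients for one minibatch."""
        _, logits, caches = self.forward(x, train=True, rng=rng)
        probs = softmax(logits)
        loss = cross_entropy(probs, y)
        n = len(y)
        dout = probs.copy()
        dout[np.arange(n), y] -= 1.0
        dout /= n
        grads = [None] * len(self.layers)
        for i in range(len(self.layers) - 1, -1, -1):
            dout, g = self.layers[i].backward(dout, caches[i])
            grads[i] = g
        return loss, grads

    def input_gradient(self, x, feature_index):
        """d feature[feature_index] / d input, summed over the batch axis.

        Runs the network in inference mode (batch-norm uses running statistics,
        dropout disabled), so the map is deterministic given the weights.
        """
        x = np.asarray(x, dtype=self.dtype)
        features, _, caches = self.forward(x, train=False)
        if not 0 <= feature_index < features.shape[1]:
            raise IndexError(f"feature index {feature_index} out of range")
        dout = np.zeros_like(features)
        dout[:, feature_index] = 1.0
        for i in range(self.feature_layer, -1, -1):
            dout, _ = self.layers[i].backward(dout, caches[i])
        return dout

    def astype(self, dtype):
        """A copy of the network with parameters cast to ``dtype`` (useful
        for float64 gradient verification of a float32-trained model)."""
        clone = copy.deepcopy(self)
        clone.dtype = dtype
        for layer in clone.layers:
            for k in layer.params:
                layer.params[k] = layer.params[k].astype(dtype)
            if isinstance(layer, BatchNorm2D):
                layer.running_mean = layer.running_mean.astype(dtype)
                layer.running_var = layer.running_var.astype(dtype)
        return clone

    # -- weight snapshots -------------------------------------------------
    def get_weights(self):
        state = []
        for layer in self.layers:
            entry = {k: v.copy() for k, v in layer.params.items()}
            if isinstance(layer, BatchNorm2D):
                entry["_running_mean"] = layer.running_mean.copy()
                entry["_running_var"] = layer.running_var.copy()
            state.append(entry)
        return state

    def set_weights(self, state):
        for layer, entry in zip(self.layers, state):
            for k in layer.params:
                layer.params[k] = entry[k].copy()
            if isinstance(layer, BatchNorm2D):
                layer.running_mean = entry["_running_mean"].copy()
                layer.running_var = entry["_running_var"].copy()


def build_feature_net(
    n_classes,
    input_shape=(1, 64, 64),
    n_conv_blocks=8,
    base_channels=16,
    fc1_units=128,
    feature_dim=64,
    dropout=0.05,
    n_fc_layers=3,
    init_std=0.1,
    seed=0,
    dtype=np.float32,
):
    """Assemble the protein-identity network.

    Conv blocks are (conv 3x3, batch norm, ReLU) with channel width doubling
    every second block and 2x2 max pooling after every second block (after
    every block for very shallow nets), never shrinking the map below 4x4.
    The head is fc1 -> ReLU -> fc2 (feature layer) -> ReLU -> dropout ->
    classification layer; with ``n_fc_layers=2`` the fc1 output doubles as the
    feature layer (used by the cell-cycle classifier).
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")
    if feature_dim < 1 or n_conv_blocks < 1:
        raise ValueError("feature_dim and n_conv_blocks must be positive")
    c, h, w = input_shape
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    pool_every = 2 if n_conv_blocks >= 4 else 1
    max_pools = int(math.log2(min(h, w) // 4))
    n_pools = 0
    c_in = c
    for i in range(n_conv_blocks):
        c_out = base_channels * (2 ** (i // 2))
        layers.append(Conv2D(c_in, c_out, 3, rng=rng, std=init_std, dtype=dtype))
        layers.append(BatchNorm2D(c_out, dtype=dtype))
        layers.append(ReLU())
        if (i + 1) % pool_every == 0 and n_pools < max_pools:
            layers.append(MaxPool2D())
            n_pools += 1
        c_in = c_out
    flat = c_in * (h // 2**n_pools) * (w // 2**n_pools)
    layers.append(Flatten())
    if n_fc_layers >= 3:
        layers.append(Dense(flat, fc1_units, rng=rng, std=init_std, dtype=dtype))
        layers.append(ReLU())
        layers.append(Dense(fc1_units, feature_dim, rng=rng, std=init_std, dtype=dtype))
    else:
        layers.append(Dense(flat, feature_dim, rng=rng, std=init_std, dtype=dtype))
    feature_layer = len(layers) - 1
    layers.append(ReLU())
    layers.append(Dropout(dropout))
    layers.append(Dense(feature_dim, n_classes, rng=rng, std=init_std, dtype=dtype))
    return ConvNet(layers=layers, feature_layer=feature_layer, dtype=dtype)


class Adam:
    """Adam optimizer with optional cosine learning-rate decay."""

    def __init__(self, net, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8, total_steps=None):
        self.net = net
        self.lr0 = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.total_steps = total_steps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in net.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in net.layers]

    @property
    def lr(self):
        if not self.total_steps:
            return self.lr0
        frac = min(self.t / self.total_steps, 1.0)
        return self.lr0 * 0.5 * (1.0 + math.cos(math.pi * frac))

    def step(self, grads):
        lr = self.lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for li, layer in enumerate(self.net.layers):
            for k, p in layer.params.items():
                g = grads[li][k]
                self.m[li][k] = b1 * self.m[li][k] + (1 - b1) * g
                self.v[li][k] = b2 * self.v[li][k] + (1 - b2) * g * g
                mhat = self.m[li][k] / corr1
                vhat = self.v[li][k] / corr2
                p -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
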