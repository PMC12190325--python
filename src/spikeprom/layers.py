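"""Spiking 1-D convolution blocks, batch normalization, pooling, dropout, and
the spiking linear readout — each with an explicit reverse pass.

Shapes follow the (channels, positions) convention: a conv layer maps
(B, C_in, L) -> (B, C_out, L) with "same" zero padding, stride 1 and no bias
(bias-free layers are what the model's parameter budget assumes).  Time-step
stacks are handled by reshaping (T, B, ...) to (T*B, ...) for the stateless
layers; only the neuron layers carry state across steps.
"""

from __future__ import annotations

import numpy as np

from .neurons import NeuronConfig, SpikingNeuronLayer
from .seqdata import ValidationError


def _as_strided_cols(xp: np.ndarray, K: int, L: int) -> np.ndarray:
    """View padded input (N, C, L+K-1) as sliding windows (N, C, K, L)."""
    N, C, _ = xp.shape
    s0, s1, s2 = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp, shape=(N, C, K, L), strides=(s0, s1, s2, s2), writeable=False
    )


def conv1d(X: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Cross-correlation with "same" zero padding and no bias.

    X: (C_in, L) or (N, C_in, L); kernels: (C_out, C_in, K) with K odd.
    Output length equals input length.
    """
    X = np.asarray(X)
    squeeze = X.ndim == 2
    if squeeze:
        X = X[None]
    C_out, C_in, K = kernels.shape
    if K % 2 == 0:
        raise ValidationError("kernel size must be odd for same padding")
    if X.shape[1] != C_in:
        raise ValidationError(f"input channels {X.shape[1]} != kernel C_in {C_in}")
    N, _, L = X.shape
    pad = K // 2
    xp = np.pad(X, ((0, 0), (0, 0), (pad, pad)))
    cols = _as_strided_cols(xp, K, L).reshape(N, C_in * K, L)
    out = np.matmul(kernels.reshape(C_out, C_in * K), cols)
    return out[0] if squeeze else out


class Conv1dSame:
    """Trainable same-padding conv layer (stride 1, no bias)."""

    def __init__(self, c_in: int, c_out: int, K: int, rng: np.random.Generator,
                 dtype=np.float32):
        # Kaiming-uniform fan-in initialization
        bound = float(np.sqrt(1.0 / (c_in * K)))
        self.W = rng.uniform(-bound, bound, size=(c_out, c_in, K)).astype(dtype)
        self.dW = np.zeros_like(self.W)
        self._cols = None
        self._in_shape = None

    def params(self):
        return {"W": (self.W, self.dW)}

    def forward(self, X: np.ndarray) -> np.ndarray:
        C_out, C_in, K = self.W.shape
        N, _, L = X.shape
        pad = K // 2
        xp = np.pad(X, ((0, 0), (0, 0), (pad, pad)))
        cols = np.ascontiguousarray(_as_strided_cols(xp, K, L)).reshape(N, C_in * K, L)
        self._cols = cols
        self._in_shape = X.shape
        return np.matmul(self.W.reshape(C_out, C_in * K), cols)

    def backward(self, g: np.ndarray) -> np.ndarray:
        C_out, C_in, K = self.W.shape
        N, _, L = self._in_shape
        W2 = self.W.reshape(C_out, C_in * K)
        # dW accumulates over the batch
        self.dW += np.tensordot(g, self._cols, axes=([0, 2], [0, 2])).reshape(self.W.shape)
        dcols = np.matmul(W2.T, g).reshape(N, C_in, K, L)
        pad = K // 2
        dxp = np.zeros((N, C_in, L + 2 * pad), dtype=g.dtype)
        for k in range(K):
            dxp[:, :, k:k + L] += dcols[:, :, k, :]
        return dxp[:, :, pad:pad + L]


class BatchNorm:
    """Per-channel batch normalization with running statistics.

    Accepts (N, C, L) or (N, C); statistics pool over every axis except the
    channel axis (axis 1).  eps = 1e-5, momentum = 0.1.
    """

    EPS = 1e-5

    def __init__(self, C: int, dtype=np.float32, momentum: float = 0.1):
        self.gamma = np.ones(C, dtype=dtype)
        self.beta = np.zeros(C, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(C, dtype=dtype)
        self.running_var = np.ones(C, dtype=dtype)
        self.momentum = momentum
        self._cache = None

    def params(self):
        return {"gamma": (self.gamma, self.dgamma), "beta": (self.beta, self.dbeta)}

    @staticmethod
    def _bcast(v: np.ndarray, ndim: int) -> np.ndarray:
        shape = [1] * ndim
        shape[1] = -1
        return v.reshape(shape)

    def forward(self, X: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(i for i in range(X.ndim) if i != 1)
        if train:
            mean = X.mean(axis=axes)
            var = X.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.EPS)
        xhat = (X - self._bcast(mean, X.ndim)) / self._bcast(std, X.ndim)
        self._cache = (xhat, std, axes, train)
        return self._bcast(self.gamma, X.ndim) * xhat + self._bcast(self.beta, X.ndim)

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, std, axes, train = self._cache
        self.dgamma += (g * xhat).sum(axis=axes)
        self.dbeta += g.sum(axis=axes)
        gs = self._bcast(self.gamma / std, g.ndim)
        if not train:
            return g * gs
        m = np.prod([g.shape[i] for i in axes])
        gmean = self._bcast(g.mean(axis=axes), g.ndim)
        gx = self._bcast((g * xhat).mean(axis=axes), g.ndim)
        return gs * (g - gmean - xhat * gx)


def batchnorm(X: np.ndarray, gamma: np.ndarray, beta: np.ndarray, mode: str = "train",
              running_mean: np.ndarray | None = None,
              running_var: np.ndarray | None = None) -> np.ndarray:
    """Functional BN over a batch of (C, L) maps stacked as (N, C, L)."""
    bn = BatchNorm(len(gamma), dtype=np.asarray(X).dtype)
    bn.gamma, bn.beta = np.asarray(gamma), np.asarray(beta)
    if running_mean is not None:
        bn.running_mean = np.asarray(running_mean)
    if running_var is not None:
        bn.running_var = np.asarray(running_var)
    return bn.forward(np.asarray(X), train=(mode == "train"))


class MaxPool1d:
    """Non-overlapping max pooling (kernel 2, stride 2) on the last axis."""

    def __init__(self, k: int = 2):
        self.k = k
        self._cache = None

    def forward(self, X: np.ndarray) -> np.ndarray:
        F = X.shape[-1]
        if F % self.k:
            raise ValidationError(f"pooling axis length {F} not divisible by {self.k}")
        Xr = X.reshape(*X.shape[:-1], F // self.k, self.k)
        if self.k == 2:
            right = Xr[..., 1] > Xr[..., 0]     # ties route to the left slot
            self._cache = (right, X.shape)
            return np.maximum(Xr[..., 0], Xr[..., 1])
        idx = Xr.argmax(axis=-1)
        self._cache = (idx, X.shape)
        return np.take_along_axis(Xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        out = np.zeros(shape, dtype=g.dtype).reshape(*shape[:-1], shape[-1] // self.k, self.k)
        if self.k == 2:
            out[..., 0] = np.where(idx, 0, g)
            out[..., 1] = np.where(idx, g, 0)
        else:
            np.put_along_axis(out, idx[..., None], g[..., None], axis=-1)
        return out.reshape(shape)


def maxpool1d(v: np.ndarray, k: int = 2, s: int = 2) -> np.ndarray:
    if k != s:
        raise ValidationError("only non-overlapping pooling (k == s) is supported")
    return MaxPool1d(k).forward(np.asarray(v))


class Dropout:
    """Inverted dropout: train mode zeroes entries w.p. p and scales by 1/(1-p)."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValidationError(f"dropout p={p} must be in [0, 1)")
        self.p = p
        self._mask = None

    def forward(self, X: np.ndarray, train: bool, rng: np.random.Generator | None = None) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return X
        if rng is None:
            raise ValidationError("train-mode dropout requires an rng")
        u = rng.random(X.shape, dtype=np.float32)
        self._mask = ((u >= self.p) / np.float32(1.0 - self.p)).astype(X.dtype)
        return X * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask


def dropout(v: np.ndarray, p: float, mode: str = "train",
            rng: np.random.Generator | None = None) -> np.ndarray:
    return Dropout(p).forward(np.asarray(v), train=(mode == "train"), rng=rng)


class Linear:
    """Fully connected map v -> v @ W (+ b); the readout uses no bias."""

    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator,
                 bias: bool = False, dtype=np.float32):
        bound = float(np.sqrt(1.0 / f_in))
        self.W = rng.uniform(-bound, bound, size=(f_in, f_out)).astype(dtype)
        self.dW = np.zeros_like(self.W)
        self.b = np.zeros(f_out, dtype=dtype) if bias else None
        self.db = np.zeros_like(self.b) if bias else None
        self._x = None

    def params(self):
        p = {"W": (self.W, self.dW)}
        if self.b is not None:
            p["b"] = (self.b, self.db)
        return p

    def forward(self, X: np.ndarray) -> np.ndarray:
        self._x = X
        out = X @ self.W
        if self.b is not None:
            out = out + self.b
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = g.reshape(-1, g.shape[-1])
        self.dW += x2.T @ g2
        if self.b is not None:
            self.db += g2.sum(axis=0)
        return g @ self.W.T


def linear(v: np.ndarray, W: np.ndarray) -> np.ndarray:
    v, W = np.asarray(v), np.asarray(W)
    if v.shape[-1] != W.shape[0]:
        raise ValidationError(f"linear shape mismatch {v.shape} x {W.shape}")
    return v @ W


class SpikingConvBlock:
    """conv -> (BN) -> IF neuron, applied per time step.

    The first block of the network receives the same one-hot matrix at every
    step (static coding) and performs the spike encoding itself; later blocks
    receive spike trains.  Input/output shape (T, B, C, L).
    """

    def __init__(self, c_in: int, c_out: int, K: int, rng: np.random.Generator,
                 normalize: bool = False, neuron: NeuronConfig | None = None,
                 soft: bool = False):
        self.conv = Conv1dSame(c_in, c_out, K, rng)
        self.bn = BatchNorm(c_out) if normalize else None
        self.neuron = SpikingNeuronLayer(neuron or NeuronConfig(), soft=soft)

    def params(self):
        p = {f"conv.{k}": v for k, v in self.conv.params().items()}
        if self.bn is not None:
            p.update({f"bn.{k}": v for k, v in self.bn.params().items()})
        return p

    def forward(self, X_seq: np.ndarray, train: bool) -> np.ndarray:
        T, B = X_seq.shape[:2]
        drive = self.conv.forward(X_seq.reshape(T * B, *X_seq.shape[2:]))
        if self.bn is not None:
            drive = self.bn.forward(drive, train)
        drive = drive.reshape(T, B, *drive.shape[1:])
        return self.neuron.forward(drive)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.neuron.backward(g)
        T, B = g.shape[:2]
        g2 = g.reshape(T * B, *g.shape[2:])
        if self.bn is not None:
            g2 = self.bn.backward(g2)
        gx = self.conv.backward(g2)
        return gx.reshape(T, B, *gx.shape[1:])


def spiking_conv_block(X_seq: np.ndarray, kernels: np.ndarray,
                       neuron: NeuronConfig | None = None) -> np.ndarray:
    """Functional conv+IF block (no BN): (T, B, C_in, L) -> (T, B, C_out, L)."""
    from .neurons import simulate
    T, B = X_seq.shape[:2]
    drive = conv1d(X_seq.reshape(T * B, *X_seq.shape[2:]), kernels)
    drive = drive.reshape(T, B, *drive.shape[1:])
    S, _ = simulate(drive, neuron or NeuronConfig())
    return S
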