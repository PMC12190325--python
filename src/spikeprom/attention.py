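"""Spiking self-attention (SSA) and its multi-head form (MSSA).

Attention here operates entirely on binary spike tensors of shape
(T, B, N, D): T simulation steps, batch B, N tokens (sequence positions) and
embedding dimension D (the channel count of the upstream conv block).  The
three projections are encoded into spikes first,

    Q = LIF(BN(X @ W_Q)),  K = LIF(BN(X @ W_K)),  V = LIF(BN(X @ W_V)),

and the attention map is the plain product Q K^T V scaled by a factor s —
no softmax anywhere.  Because Q, K, V are binary, every multiplication in
Q K^T V is a logical AND followed by integer addition, which is what makes
the block cheap on spike-driven hardware.  The scaled product drives an
inner LIF layer, and a shared output projection (with bias) + BN + outer LIF
produce the block's spike output.  All LIF neurons use the sigmoid surrogate
(alpha = 4).

Multi-head attention splits Q, K, V into H contiguous chunks of size D/H,
computes the attention product per head, and concatenates heads before the
shared projection.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .layers import BatchNorm, Linear
from .neurons import LIF_CONFIG, NeuronConfig, SpikingNeuronLayer
from .seqdata import ValidationError


@dataclasses.dataclass(frozen=True)
class SSAConfig:
    D: int = 64
    heads: int = 8
    s: float = 0.125
    neuron: NeuronConfig = LIF_CONFIG

    def __post_init__(self):
        if self.D % self.heads:
            raise ValidationError(f"D={self.D} not divisible by heads={self.heads}")
        if self.s <= 0:
            raise ValidationError("attention scaling factor s must be > 0")


def attention_product(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
                      heads: int = 1) -> np.ndarray:
    """Per-head Q K^T V on (T, B, N, D) (or (N, D)) arrays.

    On binary inputs every product is an AND + integer add; the result is the
    raw (unscaled) attention drive with heads re-concatenated along D.
    """
    squeeze = Q.ndim == 2
    if squeeze:
        Q, K, V = Q[None, None], K[None, None], V[None, None]
    T, B, N, D = Q.shape
    d = D // heads
    Qh = Q.reshape(T, B, N, heads, d).transpose(0, 1, 3, 2, 4)
    Kh = K.reshape(T, B, N, heads, d).transpose(0, 1, 3, 2, 4)
    Vh = V.reshape(T, B, N, heads, d).transpose(0, 1, 3, 2, 4)
    A = np.matmul(Qh, Kh.swapaxes(-1, -2))          # (T, B, H, N, N)
    M = np.matmul(A, Vh)                            # (T, B, H, N, d)
    out = M.transpose(0, 1, 3, 2, 4).reshape(T, B, N, D)
    return out[0, 0] if squeeze else out


class MultiHeadSSA:
    """Trainable multi-head spiking self-attention block.

    Learnable parameters: W_Q, W_K, W_V (D x D, bias-free) with one BN pair
    each, a shared output projection W_proj (D x D, with bias) and its BN pair
    — 4 D^2 + D + 8 D values in total (16,960 at D = 64).
    """

    def __init__(self, cfg: SSAConfig, rng: np.random.Generator, soft: bool = False):
        self.cfg = cfg
        D = cfg.D
        self.lin_q = Linear(D, D, rng, bias=False)
        self.lin_k = Linear(D, D, rng, bias=False)
        self.lin_v = Linear(D, D, rng, bias=False)
        self.bn_q = BatchNorm(D)
        self.bn_k = BatchNorm(D)
        self.bn_v = BatchNorm(D)
        self.lif_q = SpikingNeuronLayer(cfg.neuron, soft=soft)
        self.lif_k = SpikingNeuronLayer(cfg.neuron, soft=soft)
        self.lif_v = SpikingNeuronLayer(cfg.neuron, soft=soft)
        self.lif_inner = SpikingNeuronLayer(cfg.neuron, soft=soft)
        self.proj = Linear(D, D, rng, bias=True)
        self.bn_out = BatchNorm(D)
        self.lif_out = SpikingNeuronLayer(cfg.neuron, soft=soft)
        self._cache = None

    def params(self):
        p = {}
        for name, layer in (("W_Q", self.lin_q), ("W_K", self.lin_k), ("W_V", self.lin_v),
                            ("bn_Q", self.bn_q), ("bn_K", self.bn_k), ("bn_V", self.bn_v),
                            ("proj", self.proj), ("bn_out", self.bn_out)):
            for k, v in layer.params().items():
                p[f"{name}.{k}"] = v
        return p

    def _branch_forward(self, X2, lin, bn, lif, shape, train):
        Y = bn.forward(lin.forward(X2), train)
        return lif.forward(Y.reshape(shape))

    def project_qkv(self, X: np.ndarray, train: bool = False):
        """Encode the input spike train into binary Q, K, V (T, B, N, D)."""
        T, B, N, D = X.shape
        X2 = X.reshape(T * B * N, D)
        Q = self._branch_forward(X2, self.lin_q, self.bn_q, self.lif_q, X.shape, train)
        K = self._branch_forward(X2, self.lin_k, self.bn_k, self.lif_k, X.shape, train)
        V = self._branch_forward(X2, self.lin_v, self.bn_v, self.lif_v, X.shape, train)
        return Q, K, V

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        T, B, N, D = X.shape
        if D != self.cfg.D:
            raise ValidationError(f"embedding dim {D} != configured D {self.cfg.D}")
        Q, K, V = self.project_qkv(X, train)
        return self.attend(Q, K, V, train)

    def attend(self, Q: np.ndarray, K: np.ndarray, V: np.ndarray,
               train: bool = False) -> np.ndarray:
        """Scaled spiking attention on already-encoded binary Q, K, V:
        per step, head-split Q K^T V times s drives the inner LIF, then the
        shared projection + BN + outer LIF emit the output spike train."""
        cfg = self.cfg
        T, B, N, D = Q.shape
        H, d = cfg.heads, D // cfg.heads
        # Per-head (Q K^T) V computed associatively as Q (K^T V): the d x d
        # inner product matrix is tiny, and on small-integer spike counts the
        # float32 result is identical to forming the N x N attention map.
        Qh = np.ascontiguousarray(Q.reshape(T, B, N, H, d).transpose(0, 1, 3, 2, 4))
        Kh = np.ascontiguousarray(K.reshape(T, B, N, H, d).transpose(0, 1, 3, 2, 4))
        Vh = np.ascontiguousarray(V.reshape(T, B, N, H, d).transpose(0, 1, 3, 2, 4))
        KV = np.matmul(Kh.swapaxes(-1, -2), Vh)          # (T, B, H, d, d)
        M = np.matmul(Qh, KV) * np.asarray(cfg.s, dtype=Q.dtype)
        M = M.transpose(0, 1, 3, 2, 4).reshape(T, B, N, D)
        Sm = self.lif_inner.forward(M)
        P = self.bn_out.forward(self.proj.forward(Sm.reshape(T * B * N, D)), train)
        out = self.lif_out.forward(P.reshape(T, B, N, D))
        self._cache = (Qh, Kh, Vh, KV, Q.shape)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        Qh, Kh, Vh, KV, x_shape = self._cache
        T, B, N, D = x_shape
        H, d = self.cfg.heads, D // self.cfg.heads
        g = self.lif_out.backward(g)
        g2 = self.bn_out.backward(g.reshape(T * B * N, D))
        g2 = self.proj.backward(g2)
        gM = self.lif_inner.backward(g2.reshape(T, B, N, D))
        gM = gM * np.asarray(self.cfg.s, dtype=gM.dtype)
        gMh = np.ascontiguousarray(gM.reshape(T, B, N, H, d).transpose(0, 1, 3, 2, 4))
        gQh = np.matmul(gMh, KV.swapaxes(-1, -2))
        gKV = np.matmul(Qh.swapaxes(-1, -2), gMh)        # (T, B, H, d, d)
        gKh = np.matmul(Vh, gKV.swapaxes(-1, -2))
        gVh = np.matmul(Kh, gKV)

        def merge(gh):
            return np.ascontiguousarray(gh.transpose(0, 1, 3, 2, 4)).reshape(T, B, N, D)

        gX2 = np.zeros((T * B * N, D), dtype=g.dtype)
        for gh, lif, bn, lin in ((gQh, self.lif_q, self.bn_q, self.lin_q),
                                 (gKh, self.lif_k, self.bn_k, self.lin_k),
                                 (gVh, self.lif_v, self.bn_v, self.lin_v)):
            gb = lif.backward(merge(gh))
            gX2 += lin.backward(bn.backward(gb.reshape(T * B * N, D)))
        return gX2.reshape(T, B, N, D)


def parameter_count(D: int) -> int:
    """Closed-form learnable count of one MSSA block: 4 D^2 + D + 8 D."""
    return 4 * D * D + D + 8 * D
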