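"""Discrete-time integrate-and-fire neuron dynamics with surrogate gradients.

Every spiking layer in the network shares the same three-phase update per
simulation step t:

    charge   H(t) = f(V(t-1), X(t))          (IF:  H = V + X;
                                              LIF: H = V + (X - (V - V_reset)) / tau)
    fire     S(t) = step(H(t) - V_thr)        (threshold equality fires)
    reset    V(t) = H(t) * (1 - S(t)) + V_reset * S(t)   (hard reset)

The continuous IF/LIF membrane equations are discretized with one Euler step
per simulation step (dt = 1); the leakage resistance R is folded into the
upstream synaptic weights, so X(t) is the full input drive.

The step function is non-differentiable, so the backward pass substitutes the
derivative of a smooth gate g(x) for d step / dH ("surrogate gradient"):

    arctan  g(x) = (1/pi) * arctan((pi/2) * alpha * x) + 1/2   (alpha = 2 in
            convolutional and readout neurons)
    sigmoid g(x) = 1 / (1 + exp(-alpha * x))                   (alpha = 4 in
            spiking self-attention)

The forward pass always uses the hard step; gradients also flow through the
hard reset, so the backward pass is exactly the gradient of the network with
g substituted for the step (the "soft" mode below exposes that smoothed
forward for finite-difference checking).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .seqdata import ValidationError


@dataclasses.dataclass(frozen=True)
class NeuronConfig:
    """IF/LIF dynamics parameters.

    V_thr is dimensionless (a nominal 1 mV threshold is treated as 1.0 since
    nothing else in the model carries units).  tau only applies to LIF and
    must exceed 1 for a stable Euler step.
    """

    kind: str = "IF"                 # "IF" | "LIF"
    v_thr: float = 1.0
    v_reset: float = 0.0
    tau: float = 2.0
    surrogate: str = "arctan"        # "arctan" | "sigmoid"
    alpha: float = 2.0

    def __post_init__(self):
        if self.kind not in ("IF", "LIF"):
            raise ValidationError(f"unknown neuron kind {self.kind!r}")
        if self.surrogate not in ("arctan", "sigmoid"):
            raise ValidationError(f"unknown surrogate {self.surrogate!r}")
        if self.v_thr <= self.v_reset:
            raise ValidationError("V_thr must exceed V_reset")
        if self.kind == "LIF" and self.tau <= 1.0:
            raise ValidationError("LIF tau must be > 1")
        if self.alpha <= 0:
            raise ValidationError("surrogate alpha must be > 0")


IF_CONFIG = NeuronConfig(kind="IF", surrogate="arctan", alpha=2.0)
LIF_CONFIG = NeuronConfig(kind="LIF", surrogate="sigmoid", alpha=4.0, tau=2.0)


def charge(V: np.ndarray, X: np.ndarray, cfg: NeuronConfig) -> np.ndarray:
    """One Euler charging step: membrane potential plus drive (pre-spike H)."""
    V = np.asarray(V, dtype=float)
    X = np.asarray(X, dtype=float)
    if V.shape != X.shape:
        raise ValidationError(f"state shape {V.shape} != drive shape {X.shape}")
    if cfg.kind == "IF":
        return V + X
    return V + (X - (V - cfg.v_reset)) / cfg.tau


def fire(H: np.ndarray, v_thr: float) -> np.ndarray:
    """Binary spike wherever H - V_thr >= 0 (equality fires)."""
    return (np.asarray(H) - v_thr >= 0).astype(np.asarray(H).dtype)


def reset(H: np.ndarray, S: np.ndarray, v_reset: float) -> np.ndarray:
    """Hard reset: fired neurons jump to V_reset, the rest keep H."""
    return H * (1 - S) + v_reset * S


def surrogate_grad(x: np.ndarray, cfg: NeuronConfig) -> np.ndarray:
    """Derivative g'(x) of the surrogate gate at pre-threshold offset x."""
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(float)
    one = x.dtype.type(1)
    if cfg.surrogate == "arctan":
        z = x.dtype.type((np.pi / 2.0) * cfg.alpha) * x
        return x.dtype.type(cfg.alpha / 2.0) / (one + z * z)
    # |z| > 30 underflows g' to 0; clipping avoids float32 exp overflow
    z = np.clip(x.dtype.type(cfg.alpha) * x, -30, 30)
    s = one / (one + np.exp(-z))
    return x.dtype.type(cfg.alpha) * s * (one - s)


def surrogate_gate(x: np.ndarray, cfg: NeuronConfig) -> np.ndarray:
    """The smooth gate g(x) itself (used by the soft forward mode)."""
    x = np.asarray(x, dtype=float)
    if cfg.surrogate == "arctan":
        return (1.0 / np.pi) * np.arctan((np.pi / 2.0) * cfg.alpha * x) + 0.5
    return 1.0 / (1.0 + np.exp(-np.clip(cfg.alpha * x, -60, 60)))


def simulate(X_seq: np.ndarray, cfg: NeuronConfig, V0: np.ndarray | None = None):
    """Run charge -> fire -> reset over T steps.

    X_seq has shape (T, ...); returns (spikes of the same shape, final V).
    """
    X_seq = np.asarray(X_seq, dtype=float)
    T = X_seq.shape[0]
    if T < 1:
        raise ValidationError("need at least one time step")
    V = np.full(X_seq.shape[1:], cfg.v_reset, dtype=float) if V0 is None else np.array(V0, dtype=float)
    S_seq = np.empty_like(X_seq)
    for t in range(T):
        H = charge(V, X_seq[t], cfg)
        S = fire(H, cfg.v_thr)
        V = reset(H, S, cfg.v_reset)
        S_seq[t] = S
    return S_seq, V


class SpikingNeuronLayer:
    """Stateful multistep neuron layer with backprop-through-time.

    ``forward`` consumes the full drive sequence (T, ...) and emits spikes;
    membrane potentials start from V_reset on every call (no state leaks
    between batches).  ``backward`` propagates gradients through the temporal
    recurrence, substituting the surrogate derivative for the spike step and
    keeping the reset pathway (no detach).

    With ``soft=True`` the forward emits the smooth gate value g(H - V_thr)
    instead of binary spikes (and resets with it); backward is then the exact
    gradient of that forward, which is what finite-difference tests check.
    """

    def __init__(self, cfg: NeuronConfig, soft: bool = False):
        self.cfg = cfg
        self.soft = soft
        self._H = None
        self._S = None

    def forward(self, X_seq: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        T = X_seq.shape[0]
        V = np.full(X_seq.shape[1:], cfg.v_reset, dtype=X_seq.dtype)
        H_seq = np.empty_like(X_seq)
        S_seq = np.empty_like(X_seq)
        for t in range(T):
            X = X_seq[t]
            if cfg.kind == "IF":
                H = V + X
            else:
                H = V + (X - (V - cfg.v_reset)) / cfg.tau
            if self.soft:
                S = surrogate_gate(H - cfg.v_thr, cfg).astype(X_seq.dtype)
            else:
                S = (H - cfg.v_thr >= 0).astype(X_seq.dtype)
            V = H * (1 - S) + cfg.v_reset * S
            H_seq[t] = H
            S_seq[t] = S
        self._H, self._S = H_seq, S_seq
        return S_seq

    def backward(self, grad_S: np.ndarray) -> np.ndarray:
        """Given dL/dS per step, return dL/dX per step."""
        cfg = self.cfg
        H_seq, S_seq = self._H, self._S
        T = grad_S.shape[0]
        grad_X = np.empty_like(grad_S)
        gV = np.zeros(grad_S.shape[1:], dtype=grad_S.dtype)
        dH_dV = 1.0 if cfg.kind == "IF" else 1.0 - 1.0 / cfg.tau
        dH_dX = 1.0 if cfg.kind == "IF" else 1.0 / cfg.tau
        for t in range(T - 1, -1, -1):
            H, S = H_seq[t], S_seq[t]
            gprime = surrogate_grad(H - cfg.v_thr, cfg).astype(grad_S.dtype)
            # V = H(1-S) + V_reset*S  =>  dV/dH = (1-S) + (V_reset - H) * dS/dH
            gH = grad_S[t] * gprime + gV * ((1 - S) + (cfg.v_reset - H) * gprime)
            grad_X[t] = gH * dH_dX
            gV = gH * dH_dV
        return grad_X
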