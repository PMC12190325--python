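"""The full promoter-classifier architecture and its ablation variants.

The network presents the one-hot matrix of a sequence identically at every
one of T simulation steps (static coding).  A first spiking conv block
(conv -> BN -> IF) performs the spike encoding; its spike train feeds two
parallel branches — a second spiking conv block extracting local features
and a multi-head spiking self-attention block extracting global features.
Both branch outputs are flattened, concatenated (conv branch first),
max-pooled (kernel 2, stride 2), passed through a bias-free linear readout
and a final IF layer; the classifier score of each class is that readout
neuron's firing rate over the T steps.

Ablation variants keep the readout stage identical and rewire the middle:

    conv_only    Conv_1 -> flatten -> pool -> readout
    serial_conv  Conv_1 -> Conv_2 -> flatten -> pool -> readout
    serial_ssa   Conv_1 -> MSSA   -> flatten -> pool -> readout
    full         Conv_1 -> {Conv_2 || MSSA} -> concat -> pool -> readout
"""

from __future__ import annotations

import dataclasses
import io
import json
from pathlib import Path

import numpy as np

from .attention import MultiHeadSSA, SSAConfig
from .layers import Dropout, Linear, MaxPool1d, SpikingConvBlock
from .neurons import IF_CONFIG, NeuronConfig, SpikingNeuronLayer
from .seqdata import ValidationError

CHECKPOINT_VERSION = "spikeprom-checkpoint-1"

VARIANTS = ("full", "conv_only", "serial_conv", "serial_ssa")


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults follow the reference network)."""

    L: int = 300            # input length (nt)
    T: int = 9              # simulation time steps
    channels: int = 64      # conv kernels / embedding dim
    K: int = 5              # kernel size
    heads: int = 8          # attention heads
    dropout_p: float = 0.5
    s: float = 0.125        # attention scaling factor
    tau: float = 2.0        # LIF membrane time constant
    variant: str = "full"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValidationError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.L <= self.K:
            raise ValidationError("input length must exceed kernel size")
        if self.T < 1:
            raise ValidationError("need at least one time step")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValidationError("dropout_p must be in [0, 1)")
        if (self.channels * self.L * (2 if self.variant == "full" else 1)) % 2:
            raise ValidationError("flattened feature width must be even for 2x pooling")


class PromoterNet:
    """Assembled network; see :func:`build`."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, soft: bool = False):
        self.cfg = cfg
        C, K = cfg.channels, cfg.K
        if_cfg = IF_CONFIG
        lif_cfg = NeuronConfig(kind="LIF", surrogate="sigmoid", alpha=4.0, tau=cfg.tau)
        self.conv1 = SpikingConvBlock(4, C, K, rng, normalize=True, neuron=if_cfg, soft=soft)
        self.conv2 = None
        self.mssa = None
        if cfg.variant in ("full", "serial_conv"):
            self.conv2 = SpikingConvBlock(C, C, K, rng, normalize=False, neuron=if_cfg, soft=soft)
            self.drop_conv = Dropout(cfg.dropout_p)
        if cfg.variant in ("full", "serial_ssa"):
            self.mssa = MultiHeadSSA(
                SSAConfig(D=C, heads=cfg.heads, s=cfg.s, neuron=lif_cfg), rng, soft=soft)
            self.drop_ssa = Dropout(cfg.dropout_p)
        self.pool = MaxPool1d(2)
        width = C * cfg.L * (2 if cfg.variant == "full" else 1)
        self.readout = Linear(width // 2, 2, rng, bias=False)
        self.drop_readout = Dropout(cfg.dropout_p)
        self.readout_neuron = SpikingNeuronLayer(if_cfg, soft=soft)

    # -- parameter plumbing -------------------------------------------------

    def params(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """name -> (value, gradient) for every trainable array."""
        p = {f"conv1.{k}": v for k, v in self.conv1.params().items()}
        if self.conv2 is not None:
            p.update({f"conv2.{k}": v for k, v in self.conv2.params().items()})
        if self.mssa is not None:
            p.update({f"mssa.{k}": v for k, v in self.mssa.params().items()})
        p.update({f"readout.{k}": v for k, v in self.readout.params().items()})
        return p

    def buffers(self) -> dict[str, np.ndarray]:
        """Non-trainable state (BN running statistics)."""
        b = {}
        bns = {"conv1.bn": self.conv1.bn}
        if self.mssa is not None:
            bns.update({"mssa.bn_Q": self.mssa.bn_q, "mssa.bn_K": self.mssa.bn_k,
                        "mssa.bn_V": self.mssa.bn_v, "mssa.bn_out": self.mssa.bn_out})
        for name, bn in bns.items():
            b[f"{name}.running_mean"] = bn.running_mean
            b[f"{name}.running_var"] = bn.running_var
        return b

    def zero_grads(self) -> None:
        for _, (val, grad) in self.params().items():
            grad[...] = 0

    # -- forward / backward -------------------------------------------------

    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None,
                record: dict | None = None) -> np.ndarray:
        """Run the T-step pass on one-hot batch (B, 4, L); return (B, 2) rates."""
        cfg = self.cfg
        if X.ndim != 3 or X.shape[1] != 4 or X.shape[2] != cfg.L:
            raise ValidationError(f"expected batch shape (B, 4, {cfg.L}), got {X.shape}")
        B = X.shape[0]
        xt = np.broadcast_to(X[None], (cfg.T, B, 4, cfg.L)).astype(np.float32)
        s1 = self.conv1.forward(np.ascontiguousarray(xt), train)
        if record is not None:
            record["conv1_spikes"] = s1
        feats = []
        self._branches = []
        if self.conv2 is not None:
            a = self.conv2.forward(s1, train)
            if record is not None:
                record["conv2_spikes"] = a
            a = self.drop_conv.forward(a, train, rng)
            feats.append(a.reshape(cfg.T, B, -1))
            self._branches.append("conv2")
        if self.mssa is not None:
            xb = np.ascontiguousarray(s1.transpose(0, 1, 3, 2))  # tokens = positions
            b = self.mssa.forward(xb, train)
            if record is not None:
                record["mssa_spikes"] = b
            b = self.drop_ssa.forward(b, train, rng)
            feats.append(b.reshape(cfg.T, B, -1))
            self._branches.append("mssa")
        if not feats:
            feats.append(s1.reshape(cfg.T, B, -1))
            self._branches.append("conv1")
        f = np.concatenate(feats, axis=-1) if len(feats) > 1 else feats[0]
        p = self.pool.forward(f)
        if record is not None:
            record["readout_input"] = p
        z = self.readout.forward(p)
        z = self.drop_readout.forward(z, train, rng)
        spikes = self.readout_neuron.forward(z)
        if record is not None:
            record["readout_spikes"] = spikes
        return spikes.mean(axis=0)

    def backward(self, grad_rates: np.ndarray) -> None:
        cfg = self.cfg
        B = grad_rates.shape[0]
        g = np.broadcast_to(grad_rates[None] / cfg.T, (cfg.T, B, 2)).astype(np.float32)
        g = self.readout_neuron.backward(np.ascontiguousarray(g))
        g = self.drop_readout.backward(g)
        g = self.readout.backward(g)
        g = self.pool.backward(g)
        C, L = cfg.channels, cfg.L
        gs1 = None
        offset = 0
        for name in self._branches:
            gpart = g[..., offset:offset + C * L]
            offset += C * L
            if name == "conv2":
                ga = self.drop_conv.backward(gpart.reshape(cfg.T, B, C, L))
                contrib = self.conv2.backward(np.ascontiguousarray(ga))
            elif name == "mssa":
                gb = self.drop_ssa.backward(gpart.reshape(cfg.T, B, L, C))
                contrib = self.mssa.backward(np.ascontiguousarray(gb)).transpose(0, 1, 3, 2)
            else:  # conv_only: gradient flows straight into conv1's spikes
                contrib = gpart.reshape(cfg.T, B, C, L)
            gs1 = contrib if gs1 is None else gs1 + contrib
        self.conv1.backward(np.ascontiguousarray(gs1))

    # -- inference ----------------------------------------------------------

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Argmax of firing rates; ties go to label 0 (non-promoter)."""
        rates = self.forward(X, train=False)
        return (rates[:, 1] > rates[:, 0]).astype(int)


def build(cfg: ModelConfig, seed: int = 0, soft: bool = False) -> PromoterNet:
    """Construct a network with seed-deterministic initialization."""
    return PromoterNet(cfg, np.random.default_rng(seed), soft=soft)


def count_parameters(net: PromoterNet) -> tuple[list[tuple[str, int]], int]:
    """Per-layer learnable counts (grouped by stage) plus the total."""
    groups: dict[str, int] = {}
    order = []
    display = {"conv1.conv": "Conv_1", "conv1.bn": "BatchNorm", "conv2.conv": "Conv_2",
               "mssa": "MSSA", "readout": "Linear"}
    for name, (val, _) in net.params().items():
        stage = name.rsplit(".", 1)[0]
        if stage.startswith("mssa"):
            stage = "mssa"
        label = display.get(stage, stage)
        if label not in groups:
            groups[label] = 0
            order.append(label)
        groups[label] += val.size
    rows = [(label, groups[label]) for label in order]
    return rows, sum(groups.values())


def save_checkpoint(net: PromoterNet, path: str | Path) -> None:
    """Write a versioned archive of config + parameters + BN statistics."""
    arrays = {f"param::{k}": v for k, (v, _) in net.params().items()}
    arrays.update({f"buffer::{k}": v for k, v in net.buffers().items()})
    meta = {"version": CHECKPOINT_VERSION,
            "config": dataclasses.asdict(net.cfg)}
    buf = io.BytesIO()
    np.savez(buf, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    Path(path).write_bytes(buf.getvalue())


def load_checkpoint(path: str | Path) -> PromoterNet:
    with np.load(str(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValidationError(
                f"incompatible checkpoint version {meta.get('version')!r}, "
                f"expected {CHECKPOINT_VERSION!r}")
        net = build(ModelConfig(**meta["config"]), seed=0)
        params = net.params()
        for k, (val, _) in params.items():
            val[...] = data[f"param::{k}"]
        buffers = net.buffers()
        for k, buf in buffers.items():
            buf[...] = data[f"buffer::{k}"]
    return net
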