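"""Theoretical power accounting for the spiking network.

The cost model counts, for each layer l, the number of multiply-accumulate
operations FLOPs(l) an equivalent conventional network would execute on one
sample, and converts the spike-driven layers to accumulate-only synaptic
operations via

    SOPs(l) = f_r * T * FLOPs(l)

where f_r is the empirical firing rate of the spikes entering l and T the
number of simulation steps.  With 45 nm per-operation energies
E_MAC = 4.6 pJ and E_AC = 0.9 pJ, the per-sample energies are

    P_SNN = E_MAC * FLOPs(Conv_1) + E_AC * (SOPs(Conv_2 + MSSA) + SOPs(FC))
    P_ANN = E_MAC * (FLOPs(Conv_1) + FLOPs(Conv_2 + MSSA) + FLOPs(FC))

Conv_1 consumes the real-valued one-hot input, so it stays in MAC mode;
every later layer consumes spikes.  Because the input is static across the T
presentations, Conv_1's MAC term is counted once per sample by default
(``conv1_per_step=True`` switches to a strict per-step accounting).  A layer
is cheaper as an SNN exactly when f_r * T * E_AC < E_MAC, i.e. when
f_r < E_MAC / (E_AC * T).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .model import PromoterNet
from .seqdata import ValidationError

E_MAC_PJ = 4.6
E_AC_PJ = 0.9


@dataclasses.dataclass
class LayerCost:
    name: str
    flops: float                # MACs for one forward sample
    firing_rate: float = 0.0    # mean spikes per input neuron per step
    T: int = 1
    mode: str = "AC"            # "MAC" (real-valued input) | "AC" (spike input)

    def __post_init__(self):
        if self.flops < 0:
            raise ValidationError("flops must be nonnegative")
        if not 0.0 <= self.firing_rate <= 1.0:
            raise ValidationError("firing rate must lie in [0, 1]")
        if self.mode not in ("MAC", "AC"):
            raise ValidationError(f"unknown mode {self.mode!r}")

    @property
    def sops(self) -> float:
        return sops(self.firing_rate, self.T, self.flops)


def conv1d_flops(c_in: int, K: int, c_out: int, l_out: int) -> float:
    return float(c_in * K * c_out * l_out)


def linear_flops(f_in: int, f_out: int) -> float:
    return float(f_in * f_out)


def attention_product_flops(N: int, D: int, heads: int) -> float:
    """Q K^T and A V products: N^2 * (D/H) each, summed over the H heads."""
    return float(heads * 2 * N * N * (D // heads))


def mssa_flops(N: int, D: int, heads: int) -> float:
    """Token-wise Q/K/V/projection linears plus the attention products."""
    return 4 * N * linear_flops(D, D) + attention_product_flops(N, D, heads)


def layer_flops(kind: str, **shape) -> float:
    """MAC count of one layer; kinds: conv1d, linear, attention_product, mssa."""
    table = {"conv1d": conv1d_flops, "linear": linear_flops,
             "attention_product": attention_product_flops, "mssa": mssa_flops}
    if kind not in table:
        raise ValidationError(f"unknown layer kind {kind!r}")
    return table[kind](**shape)


def measure_firing_rate(spikes: np.ndarray) -> float:
    """Mean of a binary spike record: spikes / (T * neurons)."""
    spikes = np.asarray(spikes)
    if spikes.size == 0:
        raise ValidationError("empty spike record")
    return float(spikes.mean())


def sops(f_r: float, T: int, flops: float) -> float:
    if not 0.0 <= f_r <= 1.0:
        raise ValidationError("firing rate must lie in [0, 1]")
    if T < 1:
        raise ValidationError("T must be >= 1")
    return f_r * T * flops


def power_snn(costs: list[LayerCost], e_mac: float = E_MAC_PJ, e_ac: float = E_AC_PJ,
              conv1_per_step: bool = False) -> float:
    """Per-sample SNN energy in pJ."""
    if not any(c.mode == "MAC" for c in costs):
        warnings.warn("no MAC-mode layer: computing pure-AC energy", stacklevel=2)
    total = 0.0
    for c in costs:
        if c.mode == "MAC":
            total += e_mac * c.flops * (c.T if conv1_per_step else 1)
        else:
            total += e_ac * c.sops
    return total


def power_ann(costs: list[LayerCost], e_mac: float = E_MAC_PJ) -> float:
    """Per-sample energy of a conventional network with the same structure."""
    return e_mac * sum(c.flops for c in costs)


def crossover_rate(T: int, e_mac: float = E_MAC_PJ, e_ac: float = E_AC_PJ) -> float:
    """Firing rate below which a spike-driven layer beats its MAC equivalent."""
    return e_mac / (e_ac * T)


def model_costs(net: PromoterNet, X: np.ndarray) -> list[LayerCost]:
    """Measure firing rates on a batch and assemble the model's layer costs."""
    cfg = net.cfg
    record: dict = {}
    net.forward(X, train=False, record=record)
    C, L, K, T = cfg.channels, cfg.L, cfg.K, cfg.T
    costs = [LayerCost("Conv_1", conv1d_flops(4, K, C, L), mode="MAC", T=T)]
    f_conv1 = measure_firing_rate(record["conv1_spikes"])
    if net.conv2 is not None:
        costs.append(LayerCost("Conv_2", conv1d_flops(C, K, C, L),
                               firing_rate=f_conv1, T=T, mode="AC"))
    if net.mssa is not None:
        costs.append(LayerCost("MSSA", mssa_flops(L, C, cfg.heads),
                               firing_rate=f_conv1, T=T, mode="AC"))
    f_fc = measure_firing_rate(record["readout_input"])
    costs.append(LayerCost("FC", linear_flops(net.readout.W.shape[0], 2),
                           firing_rate=f_fc, T=T, mode="AC"))
    return costs


def energy_report(net: PromoterNet, X: np.ndarray, conv1_per_step: bool = False,
                  e_mac: float = E_MAC_PJ, e_ac: float = E_AC_PJ) -> dict:
    """JSON-ready per-layer and total energy report (pJ per sample)."""
    costs = model_costs(net, X)
    layers = []
    for c in costs:
        pj = (e_mac * c.flops * (c.T if conv1_per_step else 1)) if c.mode == "MAC" \
            else e_ac * c.sops
        layers.append({"name": c.name, "mode": c.mode, "flops": c.flops,
                       "firing_rate": c.firing_rate, "sops": c.sops, "pJ": pj})
    return {
        "layers": layers,
        "P_SNN_pJ": power_snn(costs, e_mac, e_ac, conv1_per_step),
        "P_ANN_pJ": power_ann(costs, e_mac),
        "constants": {"E_MAC_pJ": e_mac, "E_AC_pJ": e_ac},
        "conv1_mac_per_step": conv1_per_step,
        "crossover_rate": crossover_rate(net.cfg.T, e_mac, e_ac),
    }
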