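# Methods

`spikeprom` classifies fixed-length DNA sequences as promoter / non-promoter
with a spiking neural network (SNN) and accounts for the theoretical energy
advantage of spike-driven computation. This note documents the model, its
parameters, the synthetic data the package is validated on, and the numerical
choices a maintainer would want to know.

## Model

A sequence of length L over {A,C,G,T} is one-hot encoded into an L×4 binary
matrix (column order A,C,G,T) and presented unchanged at each of T simulation
steps (static coding; T = 9 by default). The network is

```
one-hot → Conv_1(4→64, k=5, same, no bias) → BN → IF
        → ┌ Conv_2(64→64, k=5, no bias) → IF → dropout ┐
          │                                            ├ concat → maxpool(2,2)
          └ MSSA(D=64, H=8) ............... → dropout  ┘
        → linear(64·L → 2, no bias) → dropout → IF → firing rates
```

The class score is each readout neuron's firing rate over the T steps
(values k/T); the predicted label is the larger rate, ties resolved to
non-promoter. Ablation variants (`conv_only`, `serial_conv`, `serial_ssa`)
rewire the middle stages but keep the readout identical so comparisons
isolate the feature extractor.

### Neuron dynamics

Each step applies charge → fire → reset:

- charge: IF `H = V + X`; LIF `H = V + (X − (V − V_reset))/τ` (one Euler step
  per simulation step, Δt = 1; the leakage resistance is folded into the
  upstream weights).
- fire: `S = 1` iff `H − V_thr ≥ 0` (threshold equality fires).
- reset: hard, `V = H(1−S) + V_reset·S`.

Defaults: `V_thr = 1`, `V_reset = 0`, `τ = 2` (τ is not pinned down by the
rate-coding formulation; 2 is the common multistep default and is exposed in
the config). Membrane potentials are re-zeroed at the start of every forward
pass, so no state leaks between batches.

A consequence of the *hard* reset worth knowing: for constant drive
0 < X ≤ V_thr an IF neuron fires with rate `1/ceil(V_thr/X)`, not `X/V_thr`
— the overshoot residual is discarded at reset. The two coincide exactly
when `V_thr/X` is an integer, and the tests assert both forms accordingly.

### Spiking self-attention

Tokens are sequence positions (N = L) and the embedding is the channel axis
(D = 64); this orientation is what makes the block's learnable size
4D² + D + 8D = 16,960 at D = 64. Q, K, V are themselves spike-encoded
(`LIF(BN(X·W))`), so the attention product QKᵀV involves only logical AND and
integer addition — there is no softmax anywhere, and a test guards this
structurally. The product is scaled by s (default 0.125, configurable; the
scale only controls drive into the inner LIF), then projected
(`LIF(BN(W_proj·+bias))`). Heads split D contiguously.

Implementation detail: the layer evaluates Q(KᵀV) rather than (QKᵀ)V. By
associativity the results are identical — exactly so in float32, because all
intermediates are small integers — and the d×d inner matrix is ~100× cheaper
than the N×N attention map. The explicit-map route is kept as
`attention_product` and cross-checked in tests.

### Surrogate-gradient training

Forward passes always use the hard step. The backward pass substitutes the
derivative of a smooth gate for dS/dH: arctan
`g(x) = (1/π)·arctan((π/2)·α·x) + ½` with α = 2 in conv/readout neurons, and
sigmoid `g(x) = 1/(1+e^(−αx))` with α = 4 inside the attention block (both
give g′(0) = 1). Gradients also flow through the hard reset (no detaching),
so the backward pass is the exact gradient of the network with g substituted
for the step; a `soft=True` neuron mode exposes that smoothed forward, which
is how the finite-difference tests verify every layer's reverse pass.

Training minimizes the mean-square error between rates and one-hot targets
(mean over all entries), optimized with Adam (lr 0.0009 by default, from the
tuned {0.0007, 0.0009} range; β = 0.9/0.999, ε = 1e-8). Batch size 32,
up to 50 epochs with early stopping on validation accuracy (patience 10), and
an optional `stop_acc` threshold for runs that only need to demonstrate
convergence. Dropout (default p = 0.5 from the tuned 0.3–0.7 range) is
inverted (survivors scaled by 1/(1−p)) and applied after the Conv_2 spikes,
after the MSSA output, and after the readout linear. Everything is
deterministic given the seed: initialization, shuffling, and dropout masks
all derive from it, and the whole pipeline is NumPy on CPU.

The entire network — including backpropagation through time across the T
steps and through BN, convolution, pooling and attention — is implemented
directly on NumPy arrays with hand-written reverse passes, verified by
central-difference checks per layer and end-to-end on the soft model.

## Evaluation

Confusion-matrix metrics (Sn, Sp, Pre, Acc, F1, MCC) follow the standard
formulas; any zero denominator reports 0. Ranking metrics use the
positive-class firing rate as the score: AUC is the pairwise rank statistic
with ties credited ½ (computed via trapezoidal ROC integration), AUPRC is the
step-interpolated precision–recall area. Rates are quantized to k/T, so ties
are common and the ½-credit convention matters; a brute-force O(P·N) oracle
in the tests pins the tie handling down exactly. Cross-validation is
stratified K-fold (default K = 5) with per-fold reports and arithmetic means.

## Energy model

For layer l, FLOPs(l) counts the multiply-accumulate operations of a
conventional network of the same shape (conv: C_in·K·C_out·L; linear:
F_in·F_out; attention products: 2N²·(D/H) per head; the token-wise Q/K/V and
projection maps as linears per token). Spike-driven layers perform
accumulate-only operations: `SOPs(l) = f_r · T · FLOPs(l)` with f_r the
measured firing rate of the spikes entering l (estimated empirically on a
held-out batch). With 45 nm energies E_MAC = 4.6 pJ and E_AC = 0.9 pJ:

- `P_SNN = E_MAC·FLOPs(Conv_1) + E_AC·(SOPs(Conv_2 + MSSA) + SOPs(FC))`
- `P_ANN = E_MAC·ΣFLOPs`

Conv_1 consumes the real-valued input and stays in MAC mode. Because the
input is static over the T presentations, its MAC term is counted once per
sample by default; `conv1_per_step=True` gives the strict per-step
accounting, and the chosen convention is recorded in every report. BN,
pooling, dropout, and the neuron updates themselves are excluded from the
count, which enumerates only Conv/MSSA/FC terms. A spiking layer is cheaper
than its MAC equivalent exactly when `f_r < E_MAC/(E_AC·T)` (≈ 0.568 at
T = 9). Energies are reported in pJ per sample; dataset-level totals require
an explicit sample-count multiplier from the caller.

## Synthetic data

The generator emulates the structure of promoter benchmark sets:
fixed-length i.i.d. background sequence (uniform composition by default)
with degenerate consensus motifs stamped into positives at fixed offsets,
each motif position independently substituted (uniformly over the other
three bases) with probability `sub_prob` (default 0.15). Two profiles:

- `prok81`: 81 bp, TSS fixed at position 60 (0-based), TTGACA at −35 and
  TATAAT at −10 — the canonical bacterial σ70 boxes.
- `euk300`: 300 bp, TSS fixed at position 200, TATAAA 30 bp upstream — a
  TATA-box promoter.

Negatives are pure background. What this does *not* emulate: real genomic
background composition and k-mer structure, motif position/spacing
variability, TATA-less promoters, CpG islands, or any species-specific
signal. Passing the learning checks therefore shows that the architecture
and the surrogate-gradient machinery can extract localized degenerate motifs
from sequence — not that the published accuracies on real species data are
reproduced, which would require the external benchmark downloads.

Test/acceptance problem sizes are chosen to exercise the claims at desk
scale: the learning checks use 400+400 sequences of 81 bp with substitution
probability 0.05 (easily separable; a position-weight-matrix scan oracle
confirms separability) and a harder 0.25 set for the ablation comparison;
multi-seed replication uses 5 seeds. Structural and algebraic checks
(parameter counts, oracles, energy identities) run at full reference size
since they cost seconds.

## Numerical choices and edge cases

- float32 throughout the network (float64 in oracle tests); BN ε = 1e-5,
  momentum 0.1, statistics pooled over batch × time × tokens.
- Weight init: uniform Kaiming-style fan-in bounds, seed-controlled.
- Sigmoid surrogate arguments are clipped at |αx| = 30 before exp — beyond
  that g′ underflows to 0 anyway and float32 exp would overflow.
- Max-pool ties route the gradient to the left slot; prediction ties go to
  label 0.
- Degenerate metric denominators (no predicted positives, single-class MCC)
  report 0; AUC on single-class input raises instead.
- FASTA input is strict by default (non-ACGT raises, naming record and
  position); a `zeros` policy maps ambiguity codes to all-zero rows.
- Checkpoints are versioned npz archives (config JSON + arrays); loading a
  mismatched version raises.

## Known limitations

- CPU NumPy only: minutes per training run at the reference width; no GPU.
- Binary classification only; all records in a dataset must share one length.
- The attention block has no positional encoding — position information
  enters only through the conv branch and the position-wise readout weights.
- Aggregate (dataset-level) energy totals are intentionally not produced
  without an explicit multiplier, since per-sample pJ is the well-defined
  quantity here.
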