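# gahtnet

Decoding motor imagery from EEG with a graph-attention, hierarchical-temporal
network — plus everything needed to exercise the pipeline end to end without
any external downloads.

## The problem

Motor-imagery brain–computer interfaces classify which movement a subject
*imagines* (left hand, right hand, feet, tongue) from multichannel EEG.
The usable signal is event-related desynchronisation (ERD): imagined
movement attenuates the 8–30 Hz sensorimotor rhythm over the contralateral
motor cortex (electrodes C3/Cz/C4).  The decoding difficulty comes from low
SNR, non-stationarity and strong inter-subject variability.

## The model

The network couples three stages:

1. **GATE** — a spatial graph over the electrode montage.  The binary
   adjacency A (unit diagonal, edges between physically neighbouring
   10–20 electrodes) is symmetrically normalised,
   Â = D̃^{-1/2}(A + I)D̃^{-1/2} with D̃ the degree matrix of A + I, and a
   K = 3 Chebyshev polynomial basis T₀ = I, T₁ = Â,
   T_k = 2ÂT_{k-1} − T_{k-2} filters each time step:
   Z_t = Σ_k T_k(Â) X_t W_k.  Squeeze-and-excitation attention gates the
   electrodes, and an EEGNet-style encoder (length-64 temporal convolution
   → F₁ = 16 maps, depthwise spatial convolution over all C electrodes
   → F₂ = 32 maps, average-pool 8, length-16 convolution, average-pool
   P = 7) compresses a C × 1125 epoch to a 20 × 32 feature sequence.
2. **HADTE** — residual efficient-channel-attention, then masked multi-head
   self-attention restricted to a local window (M_ij = 0 iff |i−j| ≤ w·d,
   w = 16, d = 1; 2 heads × dim 8), then global pre-layer-norm attention,
   then a causal dilated TCN whose last-position vector is the embedding.
3. A linear softmax classifier trained with cross-entropy, Adam (lr 0.001,
   batch 64), and early stopping (patience 300 within 1000 epochs) on a
   stratified validation holdout.

Every stage can be bypassed by an exact identity through the ablation
switchboard (`gahtnet.model.TABLE_VARIANTS`).

Because no deep-learning framework is assumed, the network runs on a
compact numpy reverse-mode autodiff engine inside the package
(`gahtnet.nn`) — float64, deterministic, seeded end to end.

## Data paths

* **Real**: GDF recordings (BCI Competition IV 2a/2b layout) via
  `gahtnet.io.load_gdf_recording`, cue-locked epoching
  ([−0.5 s, +4.0 s) at 250 Hz → 1125 samples), per-channel z-scoring on
  training statistics, session-based and leave-one-subject-out splits.
* **Synthetic**: `gahtnet.synth` draws labelled trials with class-dependent
  lateralised ERD (left hand → C4, right hand → C3, feet → Cz, tongue →
  bilateral) over a pink-noise floor with distance-mixed shared noise and
  per-subject gain variation.  A band-power nearest-centroid oracle
  provides an independent ceiling/floor reference.

## Worked example

```python
import numpy as np
from gahtnet.experiments import learnability_run

res = learnability_run(attenuation=0.9, seed=42, max_epochs=30)
print(f"held-out accuracy: {res.test_accuracy:.3f}")
print(f"band-power oracle: {res.oracle_accuracy:.3f}")
print(f"train/test trials: {res.n_train}/{res.n_test}")
```

prints

```
held-out accuracy: 0.980
band-power oracle: 1.000
train/test trials: 150/50
```

meaning: on a 200-trial synthetic 2-class set with deep ERD (attenuation
0.9, strong 6 dB mu rhythm) the full network classifies 49 of 50 held-out
trials correctly, essentially matching the oracle that knows the
generating ERD layout — the architecture extracts the lateralised
band-power feature rather than memorising.  Across attenuation levels
spanning the psychometric range (0 / 0.25 / 0.9) the mean held-out
accuracy rises monotonically, e.g. 0.50 → 0.81 → 0.91
(`gahtnet.experiments.dose_response`, 3 replicates per level) — the
expected dose-response in effect size, with chance performance when the
ERD contrast is switched off entirely.

A CLI mirrors the library: `gahtnet synth`, `gahtnet train`,
`gahtnet evaluate --protocol {dependent,loso}`, `gahtnet ablate --list`.

## Layout

| module | contents |
|---|---|
| `gahtnet.montage` | electrode montages, adjacency, normalisation, Chebyshev basis |
| `gahtnet.io` | GDF loading, epoching, z-scoring, splits, HDF5 cache |
| `gahtnet.synth` | synthetic ERD generator + band-power oracle |
| `gahtnet.nn` | numpy autodiff tensors, layers, Adam |
| `gahtnet.gate` | graph convolution, SE gate, temporal-spatial encoder |
| `gahtnet.hadte` | residual-ECA, local/global attention, causal TCN |
| `gahtnet.model` | assembly, loss, training, ablation switchboard, checkpoints |
| `gahtnet.evaluation` | accuracy, kappa, Wilcoxon, protocol runners |
| `gahtnet.experiments` | self-contained synthetic benchmarks |

See `docs/methods.md` for modelling assumptions, parameter choices and
limitations.
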