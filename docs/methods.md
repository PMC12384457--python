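# Methods

This note documents the modelling assumptions, parameter choices, numerical
decisions and known limitations of the package. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## Signal model and preprocessing

Input is cue-locked epoched EEG, `(trials, channels, time)` at 250 Hz.
Epochs span `[cue − 0.5 s, cue + 4.0 s)` (half-open, 0-based samples), i.e.
1125 samples. No filtering or artifact handling is applied; the only
preprocessing is per-channel z-scoring, `z = (x − μ)/σ`, with *population*
statistics (divide by n) pooled over all trials and samples of the
**training partition** and applied unchanged to the test partition. The
scope of the statistics is a design choice: computing them per trial or on
the pooled partitions are both defensible readings of "each channel was
standardized"; the training-partition scope was chosen because it is the
only one that cannot leak test-set information into the normalisation. A
zero-variance channel is a hard error (it indicates a dead channel or a
degenerate fixture), not something to silently epsilon away.

## Electrode graph

Electrodes are nodes; edges connect physical neighbours of the projected
10–20 layout. The 3-channel bipolar montage (C3–Cz–C4) is a chain. For
the 22-channel montage no canonical edge list exists, so the package ships
one generated **once** by Delaunay triangulation of the standard grid
projection of the 22 positions (53 edges). Delaunay was chosen because it
is deterministic, reproducible from the shipped coordinates, and yields
physiologically local neighbourhoods; the triangulation is re-derivable at
test time as an independent oracle.

The adjacency rule sets `A_ii = 1` *and* the normalisation adds `I` again:
`Â = D̃^{-1/2}(A + I)D̃^{-1/2}` with `D̃` the degree matrix of `A + I`, so
the self-loop weight is 2 before normalisation. This double self-loop is
implemented literally; it changes nothing qualitative (Â remains symmetric
with largest eigenvalue exactly 1, spectrum in (−1, 1]) and merely weights
self-information slightly higher than a single self-loop would.

The Chebyshev basis is evaluated **at Â directly** (`T₀ = I`, `T₁ = Â`,
`T_k = 2ÂT_{k−1} − T_{k−2}`), not at a rescaled Laplacian. Because Â's
spectrum lies in (−1, 1], the recursion is numerically stable and equals
the spectral-domain polynomial (verified against eigendecomposition to
1e-10 in the tests).

## GATE

The graph convolution uses **scalar node features**: one input and one
output feature map per electrode, `Z_t = Σ_k T_k(Â) X_t w_k` with one
learnable scalar per order (K = 3). This is the only reading under which
the subsequent stages compose: the depthwise spatial convolution needs an
explicit electrode axis, so `Z` must remain `time × electrodes`. The
Chebyshev weights are initialised near `(1, 0, 0)` (identity filter plus
small noise) so the raw signal passes through at the start of training.

SE channel attention acts over the **electrode** axis: temporal average →
bottleneck (reduction 4, at least 1 hidden unit, no biases) → sigmoid gate
in (0, 1), multiplied back over time. With zero weights the gate is
exactly 0.5 (a useful analytic fixture).

The encoder follows the compact-EEG-decoder pattern: length-64 temporal
convolution into F₁ = 16 maps with batch norm; depthwise spatial
convolution spanning all C electrodes with multiplier 2 into F₂ = 32 maps,
batch norm, ELU, average-pool 8; length-16 temporal convolution, batch
norm, ELU, average-pool 7, dropout 0.3. Both temporal convolutions use
'same' padding (for even kernels the extra pad sample sits on the left),
which is what makes the sequence-length arithmetic exact:
`T′ = floor(floor(T/8)/7)`, so 1125 → 140 → 20.

## HADTE

* **Residual-ECA**: gate = sigmoid of a kernel-3 1-D convolution over the
  global-average-pooled 32-map descriptor (the adaptive kernel rule gives
  k = 3 at 32 maps; fixed). Output `F + gate ⊙ F`; with zero conv weights
  this is exactly 1.5·F.
* **Local masked attention**: additive band mask `M_ij = 0` iff
  `|i−j| ≤ w·d` (w = 16, d = 1), sentinel −1e9 added to pre-softmax
  logits. 2 heads × head-dim 8: Q/K/V project 32 → 16 and the output
  projects 16 → 32 so the residual adds in 32-dim space — the only
  consistent reading of a 16-dim inner attention inside a 32-dim stream.
  No layer norm at this stage (the residual adds the raw input).
* **Global attention**: pre-layer-norm, `MHA(LN(x)) + x`.
* **TCN**: 2 causal residual blocks, kernel 4, dilations 1 and 2, 32
  filters, batch norm + ELU + dropout 0.3 per convolution, left-only
  padding. The classifier consumes the **last-position** vector (the
  full-flatten alternative was rejected to keep the embedding
  length-independent). Receptive field: 1 + 2·(4−1)·(1+2) = 19 ≈ T′ = 20.

No positional encoding anywhere: temporal order is carried by the
convolutions; the attention stages are permutation-equivariant in
isolation (tested).

## Classifier, loss, training

Linear map to class logits, softmax, mean cross-entropy (probabilities
clipped at 1e-12 on the evaluation path). Adam, lr 0.001, batch 64, up to
1000 epochs, early stopping with patience 300. The monitored quantity is
unstated territory: this package holds out a stratified 20 % validation
split of the *training* trials (seeded) and monitors validation accuracy —
monitoring the test set would leak. Best-epoch weights are restored.

One integer seed drives weight init, the validation split, batch shuffling
and dropout; all arithmetic is float64 numpy, so a fixed seed reproduces
training bit-for-bit on one device.

**Batch-norm running statistics use momentum 0.9** (`running ←
0.9·running + 0.1·batch`), epsilon 1e-3. The common compact-EEG
convention of 0.99 assumes thousands of optimiser steps; at this package's
desk-scale problem sizes (a few steps per epoch, tens of epochs) running
statistics at 0.99 are still dominated by their initialisation when the
weights have already converged, and evaluation-mode normalisation is then
so mis-scaled that predictions collapse to a single class even though the
same weights classify perfectly under batch statistics. Momentum 0.9
makes inference statistics track the training distribution within tens of
steps and is transparent at large step counts.

## Ablation switchboard

Six flags remove stages exactly, keeping everything else wired:

| flag | effect |
|---|---|
| `channel_attention` | SE gate bypassed, `Z′ = Z` |
| `ts_encoder` | encoder replaced by an average-pool-56 adapter so the graph+SE output reaches HADTE at length T′ = 20 with feature dimension C |
| `residual_eca` | ECA stage is the identity |
| `local_mha` | local attention stage is the identity |
| `global_mha` | global attention stage is the identity |
| `hadte` | whole HADTE block is the identity; the classifier consumes the GATE output's last-position feature vector |

Bypassed stages are not instantiated, so every flag strictly reduces the
parameter count. The seven published-grid variants (including the
local+global pair) are predefined in `TABLE_VARIANTS`.

## Synthetic data

The generator reproduces the statistical structure the decoder exploits,
not the biophysics:

* **Background**: 1/f (pink) Gaussian noise per channel, unit variance,
  plus one shared pink source mixed into every electrode with weight
  `exp(−‖pos‖/2)` (volume-conduction surrogate), renormalised to unit
  channel variance.
* **Rhythm**: every electrode carries an 11 Hz sinusoid with per-trial
  random phase, ±0.2 Hz jitter and 20 % slow amplitude modulation.
  `snr_db` fixes the band-limited SNR of the unattenuated rhythm against
  the noise power inside 8–13 Hz (default 0 dB — a plausible mu-rhythm
  prominence; 6 dB is used as the "strong rhythm, clearly separable"
  condition).
* **ERD**: each class multiplies the rhythm amplitude on its ERD
  electrodes by `(1 − attenuation)`; the layout mirrors physiology (left
  hand → C4, right hand → C3, feet → Cz, tongue → broad bilateral), with
  half-strength attenuation on secondary electrodes in the 4-class map.
* **Subjects**: log-normal global gain and noise scale (σ = 0.1).

What this does **not** emulate: non-stationarity within a session, ocular
and muscular artifacts, beta-band ERD/ERS dynamics, realistic volume
conduction, electrode impedance drift. Passing tests on this generator
therefore demonstrates that the pipeline can extract lateralised
band-power structure end to end — not that it attains any particular
accuracy on real recordings.

A nearest-centroid classifier on log band power at the ERD electrodes
(Welch, ±2.5 Hz around each entry's band centre, 2-fold cross-prediction
so the null configuration scores at chance) serves as an independent
ceiling/floor reference.

## Scaled-down benchmark sizes

`gahtnet.experiments.learnability_run` uses 200 trials (100 per class) on
the 3-channel montage, a stratified 50-trial holdout, and
`max_epochs = patience = 30`: large enough for the model to converge on
the separable condition, small enough to run in minutes on one CPU.

The dose-response sweep (`dose_response`) uses attenuation levels that
span the model's psychometric range under the strong-rhythm condition:
0.0 (no class signal at all, so true accuracy is chance by construction),
0.25 (transition region) and 0.9 (near ceiling). Closely spaced upper
levels are uninformative — above the transition the curve saturates and
orderings become coin flips within noise. Each level is measured as the
mean over 3 independent data/training replicates (replicate seeds paired
across levels) with a 100-trial test split, because a single training run
carries optimisation variance comparable to the spacing between adjacent
effect sizes.

## Numerical and engineering notes

* The network runs on the package's own reverse-mode autodiff layer
  (`gahtnet.nn`): float64 tensors, explicit `numpy.random.Generator`
  seeding, a tape walked in reverse topological order. 1-D convolution
  switches between a per-tap loop (short or dilated kernels) and an
  FFT-based path (long undilated kernels); both paths are cross-checked
  against each other and against finite differences in the tests.
* Attention logits use a −1e9 additive sentinel rather than true −∞ so the
  softmax stays NaN-free; a fully masked row is rejected as an error.
* Average pooling floors the sequence length (trailing remainder samples
  are dropped), matching the `T′ = floor(floor(T/8)/7)` contract.
* Wilcoxon signed-rank: zero differences dropped, average ranks for ties,
  exact null for n ≤ 25, normal approximation with continuity correction
  above; two-sided. At n = 9 (the per-subject comparison size) the exact
  test is mandatory. Significance annotation: `*` p < 0.05, `**` p < 0.01.
* Cohen's kappa on a degenerate single-cell confusion matrix (expected
  agreement 1) is defined as 0 with a warning.
* GDF reading delegates to mne; the HDF5 TrialSet cache
  (`data`/`labels`/`subjects`/`sessions` datasets, `fs`/`class_names`
  attributes) is the round-trippable interchange format.

## Known limitations

* Reproducing published accuracies on the real BCI Competition IV data is
  out of scope here: it requires the GDF downloads and many long
  stochastic training runs. The evaluation protocols (session-based
  subject-dependent split, LOSO) are implemented and tested on synthetic
  multi-subject data.
* The graph convolution is fixed to scalar node features; multi-map graph
  features (`d_g > 1`) are not implemented beyond the config surface.
* Training is single-device, full-precision, CPU-oriented; there is no
  hyperparameter search, learning-rate schedule, or augmentation.
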