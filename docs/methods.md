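# Methods

## Model

The classifier is a three-layer 3D convolutional network over topographic
EEG blocks `9 × 9 × T` (scalp rows × scalp columns × samples; `T = 128` for
one-second windows at 128 Hz).  Two convolutional branches run in parallel
on the input: kernels 3×3×4 and 3×3×5, both with zero padding 1, stride 1,
ReLU, and 1×1×2 max pooling at stride 2.  With `T = 128` the branches emit
temporal lengths 127 and 126, which pool to the same 63
(`⌊127/2⌋ = ⌊126/2⌋`), so their feature maps concatenate without cropping —
this is why the merge is placed after the first pooling.  A 3×3×4
convolution (64 maps by default) with ReLU and a further 1×1×2 pooling
follows, then inverted dropout (p = 0.6) and a fully connected softmax layer
over the four classes.  All output sizes obey `O = (I − K + 2P)/S + 1`; the
implementation refuses configurations where this is not a positive integer.

The `same_scale` variant replaces the 3×3×5 branch kernel with 3×3×4 and is
otherwise identical; the two variants differ by exactly
`branch_maps · 3 · 3 · 1` weights.

Training minimises categorical cross-entropy with Adam (learning rate 0.001,
β = 0.9/0.999); AdaDelta is available via `TrainConfig(optimizer="adadelta")`.
Batches are shuffled each epoch; weight initialisation (He normal), batch
order and dropout masks all derive from the single `TrainConfig.seed`, so a
fit is reproducible bit-for-bit at a fixed thread count.

### NumPy implementation notes

The network runs in float32 on the CPU.  Convolutions keep activations
channels-last `(batch, H, W, T, C)` and unfold only the temporal axis, so a
kernel's `(k₃, C)` footprint is one contiguous block; each of the nine
spatial offsets is then a single GEMM over block-contiguous slices.  Large
scratch arrays are owned by the layers and reused across steps — fresh
allocations of hundreds of megabytes per step would be dominated by page
faults rather than arithmetic.  Gradients are analytic and are checked
against central finite differences and a brute-force convolution in the test
suite.  Evaluation-mode forward passes are deterministic; `1e-6` is the
tolerance used for softmax normalisation checks.

## Preprocessing

* Band-pass: 4–45 Hz Butterworth of order 4, applied forward-backward
  (`sosfiltfilt`), i.e. zero-phase with the order effectively doubled.  The
  rhythm bands are theta 4–8, alpha 8–13, beta 13–30, gamma 30–45 Hz.
* Resampling: polyphase (`resample_poly`) with the rational rate ratio;
  output length `round(n · fs_out/fs_in)`.
* Baseline handling: the pre-stimulus period is cut into `N` segments of
  length `L` (one second by default), averaged elementwise into
  `Z ∈ ℝ^{C×L}`, and `Z` is subtracted from each of the `M` stimulus
  segments; the corrected segments are re-merged.  The operation is
  invariant to adding any constant matrix to both baseline and stimulus.
* Windowing: half-open windows `[start, start + len)`, 0-based; window count
  `K = 1 + ⌊(S − w)/step⌋`; trailing samples that do not fill a window are
  dropped.  When bands and baseline correction are combined, band
  decomposition is applied first (the order is exposed in the CLI/config).
* Grid mapping: the 32-channel 10–20 montage occupies 32 of the 81 cells of
  a 9×9 matrix (row 0 = front, column 0 = left, midline on column 4); empty
  cells are exactly zero at every sample.  The coordinates ship as an
  editable `name,row,col` text table.
* Normalisation: per-segment, per-occupied-cell z-scoring by default
  (zero-variance cells are left at zero); min-max to `[0, 1]` and `none` are
  alternatives.  The scope (per segment) is a deliberate choice — per-trial
  or per-subject scoping would leak information across windows that later
  land in different cross-validation folds.

## Synthetic data

`generate_deap_like` emits 32-channel trials of 63 s at 128 Hz: a 3-s
pre-stimulus baseline of background noise followed by 60 s of stimulus.
`generate_seed4_like` emits `n_subjects × 3 sessions × n_trials` one-second
clips.  Background activity is 1/f (pink) noise of unit RMS per channel,
matching the broadband spectral decay of resting EEG; white noise is
available for ablations.  Each class adds a sinusoidal oscillation with a
random phase in its own carrier band — 6, 10, 20 and 35 Hz, one per rhythm
band inside the 4–45 Hz analysis range — on eight frontal/parietal channels
(Fp1, Fp2, F3, F4, Fz, P3, P4, Pz), at amplitude `class_effect` × the noise
RMS.  `class_effect = 1` (the default) gives a clearly learnable four-class
problem; `class_effect = 0` makes labels statistically independent of the
data, which the test suite verifies by ANOVA on band power.  DEAP-like
ratings are drawn uniformly from the class's quadrant of the `[1, 9]²`
valence/arousal square (low `[1, 5]`, high `(5, 9]`), so threshold-5
discretisation recovers the generating class exactly; SEED-IV-like labels
are emitted directly and near-balanced (counts within 1 of `n/4`).

What the generator does *not* emulate: volume conduction and channel
correlation, ocular/muscle artifacts, non-stationarity, inter-subject
variability, and class differences subtler than narrow-band power.  Passing
tests therefore demonstrate that the pipeline is implemented correctly and
can recover a known class-conditional spectral signal — not that it attains
any particular accuracy on real recordings.

## Evaluation protocol

Cross-validation shuffles segments into 10 folds (sizes within 1 of each
other) and reports the mean fold accuracy.  Fold assignment is at segment
level by default, matching the accuracy regime the method targets;
trial-level leakage control can be built by passing explicit index splits.
The lockbox protocol holds out 10% of segments, tunes only on the remaining
90%, and allows exactly one lockbox evaluation — a second call is refused.

Metrics: per-class precision, recall and F1 come from one-vs-rest confusion
counts with the 0/0 → 0 convention; macro F1 and macro AUC are unweighted
means over the four classes.  ROC curves sweep a threshold over the class
probability with TPR = TP/(TP+FN), FPR = FP/(FP+TN) and trapezoid AUC; ties
are collapsed so the result equals the Mann–Whitney pairwise statistic.  An
AUC over a single-class truth vector is undefined and reported as NaN.

Fisher electrode ranking scores channel v as
`Σₘ nₘ(μ_{m,v} − μ_v)² / Σₘ nₘ σ²_{m,v}` with population (1/n) class
variances (`ddof=1` switches to sample variances).  The per-electrode
feature is the segment's power in each rhythm band, with the electrode
scored by its best band: classes that differ by carrier frequency leave
broadband power unchanged, so a broadband feature would be blind to them
(and exactly constant on z-scored segments).  Broadband `mean_power` and raw
sample pooling remain available.  Channel-subset runs zero every cell
outside the top-k electrodes and retrain.

## Scaled-down experiment sizes

The learning experiments in the test suite run at sizes a single CPU
finishes in minutes, chosen once and fixed: 20 DEAP-like trials → 1,200
one-second segments (960 train / 240 held out), a reduced-width network
(8 maps per branch, 16 in the head; kernels, pooling, dropout, optimiser and
learning rate unchanged), and 2 training epochs — the synthetic task
converges within the first epoch, the second is margin.  Three fixed seeds
(0, 1, 2) are used for the class-recovery check (> 0.80 held-out accuracy on
separable data, chance 0.15–0.35 on label-shuffled data) and for the
multiscale-vs-same-scale kernel comparison (non-inferiority within 2
accuracy points).  The full-width architecture (32/64 maps) remains the
package default.

## Known limitations

* The published headline accuracies on the real DEAP/SEED-IV datasets are
  not reproducible here: the datasets are licensed downloads and the
  training runs are long and stochastic.  The package reproduces the
  arithmetic of the published evaluation tables and the pipeline's shape
  contracts exactly, and the learning behaviour on synthetic data.
* The grid layout follows the standard 10–20 topographic arrangement; a
  publication-exact digitisation of a specific figure can be supplied as a
  replacement layout table.
* The synthetic ablation cannot resolve a ~3-point real-data advantage of
  multiscale kernels: both variants saturate on the synthetic task, so only
  non-inferiority is asserted.
* MAT round-trips are value-lossless but not byte-deterministic (the writer
  embeds a timestamp); the HDF5 dialect is byte-deterministic.
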