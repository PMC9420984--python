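# ern — multiscale-kernel 3D CNN for EEG emotion recognition

`ern` classifies four emotional states from multichannel EEG.  It implements
the complete pipeline used in EEG-based affective computing with DEAP-style
(32-channel music-video trials, continuous 1–9 valence/arousal ratings) and
SEED-IV-style (film-clip trials, four categorical emotions) recordings:

1. **Preprocessing** — band-pass 4–45 Hz, resampling to 128 Hz, and
   *baseline-mean subtraction*: the 3-s pre-stimulus signal is cut into
   one-second segments, their per-channel mean `Z ∈ ℝ^{C×L}` is subtracted
   from every stimulus segment.
2. **Topographic mapping** — each channel's series is placed at its
   10–20-system scalp coordinate in a sparse 9×9 grid, giving 9×9×128
   spatiotemporal blocks that preserve electrode adjacency.
3. **Classification** — a 3D convolutional network with *multiscale
   temporal kernels*: two parallel branches convolve the input with 3×3×4
   and 3×3×5 kernels (zero padding 1, ReLU, 1×1×2 max pooling), their
   feature maps are concatenated and passed through a third 3×3×4
   convolution, pooling, dropout (p = 0.6) and a softmax classifier.
   Convolution output sizes follow `O = (I − K + 2P)/S + 1`.
4. **Evaluation** — 10-fold cross-validation, per-class precision/recall/F1
   and one-vs-rest ROC/AUC with unweighted macro averages, a lockbox
   (90/10) protocol, and Fisher-score electrode ranking
   `F(v) = Σₘ nₘ(μ_{m,v} − μ_v)² / Σₘ nₘ σ²_{m,v}` for channel-subset
   experiments.

Valence/arousal ratings map to the four classes by thresholding at the
neutral midpoint 5: LVLA→0, LVHA→1, HVLA→2, HVHA→3 (low is ≤ 5, high is > 5).

The network is implemented directly in NumPy (im2col convolutions with exact
analytic gradients, Adam optimiser, inverted dropout), so the package has no
deep-learning-framework dependency.  A synthetic-EEG generator (pink-noise
background plus class-specific band-limited oscillations on frontal/parietal
channels) makes the entire pipeline runnable and testable without the
licensed benchmark datasets.

## Worked example

```python
import numpy as np
from ern import (SynthSpec, generate_deap_like, bandpass, assemble_dataset,
                 EmotionRecognizer, TrainConfig, ERNConfig)

spec = SynthSpec(n_trials=20, class_effect=1.0, seed=0)
trials = generate_deap_like(spec)                      # 20 trials, 63 s @ 128 Hz
trials.data = bandpass(trials.data, trials.fs, 4.0, 45.0)
dataset = assemble_dataset(trials, baseline_s=3.0)     # 1-s windows on the 9x9 grid
print(f"{len(dataset)} segments of shape {dataset.grids.shape[1:]}")

rng = np.random.default_rng(0)
perm = rng.permutation(len(dataset))
test_idx, train_idx = perm[:240], perm[240:]

model = EmotionRecognizer(dataset, ERNConfig(branch_maps=8, head_maps=16))
results = model.fit(TrainConfig(max_epochs=3, seed=0), train_idx, test_idx)
print(results.summary())
```

prints

```
1200 segments of shape (9, 9, 128)
Emotion Recognition Network Results
=======================================================
variant:            multiscale
branch kernels:     (3, 3, 4) / (3, 3, 5)
feature maps:       8 per branch, 16 head
dropout:            0.6
parameters:         170,604
optimizer:          adam (lr=0.001)
epochs:             3, final loss 0.0166
train segments:     960
-------------------------------------------------------
accuracy:           1.0000
macro F1:           1.0000
macro AUC:          1.0000
class   precision   recall       F1      AUC
  0       1.0000   1.0000   1.0000   1.0000
  1       1.0000   1.0000   1.0000   1.0000
  2       1.0000   1.0000   1.0000   1.0000
  3       1.0000   1.0000   1.0000   1.0000
```

The 20 trials yield 60 one-second windows each (1,200 labelled segments);
after baseline subtraction and per-segment z-scoring, the reduced-width
network separates the four synthetic emotion classes perfectly on the 240
held-out segments — the synthetic classes differ by oscillation band
(6/10/20/35 Hz), which the temporal kernels pick up within one epoch.
With `class_effect=0` the same pipeline stays at the 0.25 chance level.

A command-line interface mirrors the library:

```bash
ern synth deap-like raw.h5 --n-trials 20 --seed 0
ern preprocess raw.h5 topo.h5 --baseline-s 3
ern train topo.h5 model.npz --epochs 10 --metrics metrics.json
ern fisher topo.h5 --top-k 8
ern ablation --seeds 0,1,2
```

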