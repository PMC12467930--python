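# gliomark

Multi-task deep learning for glioma MRI: voxel-wise cross-modality
attention fusion of the four standard sequences (T1, T1ce, T2, FLAIR),
a hybrid CNN / 3D shifted-window-transformer encoder, hierarchical
segmentation of the four post-treatment tumor subregions — enhancing tumor
(ET), non-enhancing tumor core (NETC), surrounding non-enhancing FLAIR
hyperintensity (SNFH), resection cavity (RC) — and segmentation-gated,
attention-pooled prediction of the molecular markers IDH, 1p/19q and TERT.

## Who this is for

Researchers in radiogenomics and medical image analysis who want a fully
tested, configurable reference implementation of this multi-task
architecture that runs end to end on a laptop: every stage — synthetic
phantom generation, preprocessing, fusion, encoding, decoding, marker
prediction, training, Gaussian sliding-window inference, and the complete
metric stack — is importable, unit-tested against independent oracles, and
exercised by a desk-scale study on synthetic data. The whole network stack
(reverse-mode autodiff, 3D convolution, windowed attention, AdamW) is
implemented in NumPy inside `gliomark.nn`.

## The model in brief

At each voxel (i,j,k), modality embeddings F_m = f_emb(X_m) (one shared
3×3×3 convolution) are scored by a small MLP and softmax-normalized into
weights α with Σ_m α_m = 1; the fused volume F = Σ_m α_m F_m feeds a
two-branch encoder (residual CNN + shifted-window transformer, fused at
1/8 resolution by 1×1×1 convolution). A U-Net-style decoder with skip
connections, squeeze-and-excitation and deep supervision emits per-voxel
class probabilities Softmax(Conv1×1×1(F_dec)); the segmentation loss is
λ_Dice·L_Dice + λ_CE·L_CE. The predicted tumor extent gates the latent
volume, attention-based global pooling z = Σ w_ijk F_ijk with
w = Softmax(W_a tanh(W_f F)) condenses it to a patient vector, and three
independent sigmoid heads predict the markers with label-smoothed binary
cross-entropy. See `docs/methods.md` for the full account.

## Worked example

```bash
python examples/03_train_and_evaluate.py
```

trains the tiny configuration for 60 steps on 6 phantoms and evaluates on
8 held-out phantoms. A run prints (numbers from this machine):

```
compound segmentation loss: 4.494 (first step) -> 1.138 (last), a 75% drop
held-out Dice per class: {1: 0.268, 2: 0.341, 3: 0.499, 4: 1.0}
held-out marker AUC: {'idh': 0.8, '1p19q': 0.733, 'tert': 0.75}
```

The loss drop shows the multi-task objective is being optimized; Dice per
class is voxel overlap with the planted subregions (class 4 = RC is absent
from these phantoms, so its Dice is 1 by the absent-in-both convention);
marker AUC is the probability that a positive-marker phantom outranks a
negative one (0.5 = chance). At this 60-step toy budget the numbers are
noisy and segmentation is only beginning to form — the fixed-seed
300-step study in the test suite reaches core-class Dice of about 0.75.
Other examples: `01_generate_phantoms.py` (cohort generation and planted
truth), `02_fusion_attention.py` (attention-map export),
`04_sliding_window_inference.py` (Gaussian patch merging).

## Command-line interface

```bash
gliomark make-phantoms spec.yaml out/ --n 20 --seed 0   # NIfTI cohort + marker CSV
gliomark train config.yaml run/ --seed 0                # checkpoint + history
gliomark predict run/checkpoint.npz cases/ case_0000 pred/
gliomark evaluate pred/ cases/ report.json
```

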