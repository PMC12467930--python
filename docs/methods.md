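# Methods

`gliomark` implements a multi-task volumetric network for glioma MRI: it
segments four post-treatment tumor subregions and predicts three molecular
markers from the same shared representation. This note documents the model,
the numerical choices, what the synthetic phantoms do and do not emulate,
and the limits of what the desk-scale experiments show.

## Model

**Cross-modality attention fusion (CMAF).** The four co-registered
sequences X_m (m ∈ {T1, T1ce, T2, FLAIR}) are embedded by a *shared*
3×3×3 convolution + batch norm + ReLU into a common C′-channel space,
F_m = f_emb(X_m). At each voxel the concatenated vector
z = [F_T1, F_T1ce, F_T2, F_FLAIR] ∈ R^{4C′} passes through a two-layer MLP
(hidden width 4C′, ReLU, dropout 0.2) whose 4 output logits are
softmax-normalized into modality weights α with Σ_m α_m = 1. The fused
volume is the convex combination F = Σ_m α_m F_m. The MLP is applied as a
1×1×1 convolution — mathematically identical to the per-voxel formulation.
An optional extra hidden layer of width C′/2 and a 1×1×1 embedding kernel
are exposed as configuration; C′ defaults to 32. The attention field is
exportable as four NIfTI maps and is the package's modality-attribution
readout.

**Hybrid encoder.** Two parallel branches consume the fused volume. The
CNN branch is a stem convolution followed by three stages of (stride-2
downsampling, two pre-activation residual blocks); downsampling is
space-to-depth + channel projection, which is exactly a 2×2×2 stride-2
convolution. Features before each downsampling form the skip pyramid at
/1, /2, /4. The transformer branch is a 3D shifted-window design: stride-2
patch embedding, then windowed multi-head self-attention blocks with
learned relative-position bias, cyclic shifts of half a window on
alternating blocks with the standard region mask, post-block layer
normalization, and 2×2×2 patch merging between stages; token grids are
padded to window multiples per stage and cropped back. Both branches end
at /8 with C″ channels and are fused by concatenation + 1×1×1 convolution
into the latent volume (C_out channels) shared by both heads. The skip
pyramid is drawn from the CNN branch (`skips: cnn`); drawing from the
fused representation would require extra projections at every scale for
little expected benefit at this model size.

**Segmentation decoder.** Three upsampling blocks climb /8→/1; each
doubles resolution by trilinear interpolation (voxel centers aligned, no
corner alignment — this changes borders and is therefore fixed here),
concatenates the matching skip, applies conv 3×3×3 + batch norm + ReLU,
and adds a pointwise projection of the interpolated input as a residual
path. A squeeze-and-excitation block (reduction 4) recalibrates the final
features; additive attention gates on the skips are available behind a
flag and default off. The 1×1×1 head emits K = 5 classes — background plus
ET/NETC/SNFH/RC — because a softmax over tumor classes only cannot express
"no tumor"; a 4-class mode reproduces the tumor-only head. Deep
supervision adds auxiliary heads at /2 and /4 during training (weights
0.5, 0.25); they are loss terms only and never averaged into the
inference output. Inference is voxel-wise argmax followed by removal of
connected components smaller than `min_component` voxels (default 20; 0
disables).

**Marker head.** The predicted tumor extent gates the latent volume:
during training a *soft* gate (1 − background probability, average-pooled
to latent resolution) keeps the path differentiable so segmentation errors
backpropagate; at inference a *binary* gate (tumor-union argmax mask,
max-pooled to preserve small lesions) is used. Attention-based global
pooling scores each voxel by W_a·tanh(W_f·F), softmax-normalizes over the
volume, multiplies in the gate value as a prior on the attention mass
(`gate_prior`, default on — gated-out voxels then contribute exactly
zero), renormalizes, and sums to the patient vector z. Three independent
two-layer heads (hidden 64, dropout 0.3, zero-initialized output layer)
map z to sigmoid probabilities for IDH, 1p/19q and TERT. Decision
thresholds come from Youden's J (ties broken toward higher sensitivity) or
a sensitivity-floor rule; the floor rule returns the largest threshold
maintaining the requested sensitivity, i.e. the max-specificity operating
point subject to the floor.

**Losses and training.** Segmentation: L_seg = λ_Dice·L_Dice + λ_CE·L_CE
with λ_Dice = λ_CE = 1; soft Dice uses smoothing 1e-5 in numerator and
denominator, is computed per class and averaged over the four foreground
classes; cross-entropy is the voxel mean of −log p_truth with probabilities
clamped at 1e-12 (clamps are logged). Classification: label-smoothed
(ε = 0.1) binary cross-entropy per marker, optional focal modulation
(γ_f = 2), weighted by β = (1,1,1); missing (NA) labels are masked and the
remaining weights rescaled so the total weight matches the all-present
case. The multi-task total is L_seg + γ·L_clf with γ = 1. Optimization is
AdamW (lr 1e-4, weight decay 1e-5, batch 2, up to 150 epochs for the
full-scale recipe) under a cosine schedule with validation-based early
stopping; the kept checkpoint is the one with the best validation total
loss, so both objectives jointly drive model selection. Class heads
(segmentation, auxiliary, marker outputs, CMAF
logits) are zero-initialized so training starts from uniform predictions
rather than saturated softmax logits — without this, early steps are spent
escaping clamped cross-entropy. The CMAF hidden layer is
identity-initialized (the embeddings are non-negative, so the hidden layer
starts as a pass-through and the logit layer can correlate embedding
channels with modality relevance from the first step), and the AGP score
layer starts at zero so pooling begins as the gated spatial mean — the
composition statistic the marker heads build on.

**Inference.** Whole volumes are predicted by Gaussian-weighted
overlapping patches (default 128³, overlap 0.5, σ = 0.125·patch): each
voxel's probability is Σ_p w_p(v)·p_p(v) / Σ_p w_p(v), an exact partition
of unity, so merged probabilities stay on the simplex. Volumes small
enough for a single pass use one whole-volume forward, and marker
probabilities then come from the full latent; otherwise marker
probabilities are pooled over patch outputs with patch-level Gaussian
weights (the mode is recorded in the output metadata).

## Preprocessing

Pipeline order is resample → normalize → pad/crop (the order is recorded
in configuration, not asserted as canonical). Z-scoring uses the nonzero
voxels of each modality as foreground (population SD; constant foreground
is an error), sets background to 0, and is idempotent to 1e-5. Resampling
to 1 mm isotropic is trilinear for images and nearest-neighbor for labels.
Pad/crop to 240×240×155 centers symmetrically with the extra voxel on the
high side; the inverse metadata supports un-cropping predictions. Training
samples 128³ patches centered on a uniformly drawn tumor voxel (clamped to
fit; uniform fallback with a logged warning when no tumor exists).
Augmentation: elastic deformation (B-spline-like displacement field from a
coarse Gaussian grid, control spacing 16, SD 2 voxels), axis flips
(p = 0.5), per-modality intensity scale/shift (±10%), and modality dropout
(whole-channel zeroing after normalization, never all four channels).
N4 bias-field correction and atlas registration are expected upstream; a
documented identity hook marks the seam. Coordinates are 0-based with
half-open intervals everywhere.

## Synthetic phantoms

Phantoms plant a concentric tumor — NETC sphere, ET shell, SNFH shell —
plus an optional offset RC ellipsoid in a homogeneous background, with
per-(modality, class) intensity means and additive Gaussian noise, an
optional smooth second-order polynomial bias field (off by default), and
seeded determinism (per-case seeds derived from a master seed via
`SeedSequence((seed, index))`). Geometry that cannot be rasterized
disjointly (RC intersecting the shells) is rejected with the overlapping
classes named. The default contrast signature follows clinical intuition:
rim bright in T1ce, edema bright in FLAIR/T2, core hypo-intense in T1,
cavity fluid-like.

Marker labels are drawn from coupling rules mapping planted phenotype
descriptors to probabilities (logistic in the descriptor; an infinite
slope gives a deterministic step; a constant baseline when no descriptor
is set). Descriptors are recomputable from the label volume alone; the
available set spans absolute per-class volume fractions, within-tumor
composition shares, and equivalent-sphere rim thickness / halo width.
The default couplings raise P(IDH+) with the core fraction, P(TERT+)
with the rim fraction and P(1p19q+) with the halo fraction; the
end-to-end study uses its own deterministic variant (below). Coupling
choice matters for learnability: attention pooling produces a normalized
(convex) representation of the tumor, so composition ratios are directly
expressible while absolute size enters only through boundary-mixture
effects at the coarse latent grid — both representable here, but with
very different sample efficiency.

What the phantoms do **not** emulate: MR physics (no partial-volume
effects, no Rician noise floor, no texture), anatomy (no brain, no
anatomical priors), registration error, scanner/site effects, or label
noise. Passing the phantom studies therefore demonstrates that the
architecture, losses, optimization and evaluation machinery work end to
end and that the planted signal is recovered — not that the reported
numbers transfer to clinical data.

## Desk-scale study

The end-to-end study (`gliomark.experiments`, rerun by
`scripts/acceptance.py`) uses 48³ phantoms, 20 training and 40 held-out
cases, a tiny configuration (C′ = 8, C″ = C_out = 16, one transformer
stage, window 4), 32³ patches, batch 1, and 300 AdamW steps at lr 3e-3 —
sizes chosen so a single CPU completes the study in minutes while every
stage of the method is exercised. The phantom cohort plants each subregion
in exactly one sequence (core in T1, rim in T1ce, halo in FLAIR, cavity in
T2) with balanced contrast magnitudes and noise SD 0.08, and the study
reads out the mean attention per modality inside the halo as its
modality-attribution check. Tumor geometry follows a two-phenotype design:
the outer radius, the rim-to-core ratio and the halo-to-inner ratio are
each drawn from one of two disjoint bands, mimicking molecular subtypes
with distinct imaging phenotypes, and each marker couples
deterministically to one factor (IDH to tumor volume fraction, TERT to the
rim share of the core complex, 1p/19q to the halo share of the tumor) with
the threshold inside its band gap. Training patches are centered on the
tumor centroid, which keeps every tumor fully inside its patch so the
visible composition matches the label's planted phenotype; the
uniformly-drawn tumor-voxel centering remains the library default.
The checkpoint with the best validation total loss (4 of the 20 cases
serve as validation) is evaluated: a whole-volume forward pass per
held-out case for segmentation (argmax + component post-processing,
per-class Dice) and attention; marker probabilities are scored on a
tumor-centroid patch of the training patch size — the distribution the
marker heads were fit on — and summarized as AUC per marker. lr 3e-3
(rather than the full-scale 1e-4) is the standard choice for a small model
trained from scratch for few steps.

At this scale the study separates what the architecture demonstrably
learns from what it cannot identify. Segmentation and the size-coupled
marker are learned reliably. The shell-ratio markers depend on
sub-latent-voxel structure pooled into a 16-channel vector from roughly
20 training subjects, and their AUC fluctuates substantially between
otherwise identical runs. The attention margin is structurally fragile: a
direct probe on trained models shows that forcing all-FLAIR attention
inside the halo *raises* the compound loss and that the loss gradient
with respect to the attention weights is near zero — the decoder adapts
to whatever mixing the fusion produces, so the training objective does
not uniquely identify a FLAIR-concentrated attention pattern at this
model scale and step budget. The attention maps remain a faithful readout
of what the fusion learned; the study does not force what it learns.

## Numerical choices and degenerate inputs

- Dice/HD95 conventions for absent classes: absent in both → Dice 1,
  HD95 0; absent in one → Dice 0, HD95 = volume diagonal (configurable);
  all logged per case.
- HD95 uses 6-connectivity surface voxels and spacing-aware distance
  transforms; AUC uses Mann–Whitney tie handling (0.5 credit); McNemar
  uses the continuity-corrected χ² when discordant pairs ≥ 25, else the
  exact two-sided binomial; zero discordance gives p = 1.
- Calibration bins are equal-width on [0,1]; empty bins report count 0 and
  NaN frequency.
- An all-zero segmentation gate falls back to ungated pooling (logged);
  all-NA marker labels give zero classification loss (logged).
- Attention softmax subtracts the row maximum; sigmoid uses the
  numerically stable two-branch form; BCE probabilities are clamped at
  1e-12.
- The tensor engine runs in float64 throughout; gradient checks against
  central finite differences hold to relative error < 1e-3 (typically
  ~1e-8) for parameters in every module.

## Known limitations

- The network stack is a compact NumPy autodiff engine: single-device,
  CPU-only, no mixed precision; full-scale (240×240×155, C′ = 32) training
  is out of reach here — the full-scale defaults are configuration, not a
  tested regime.
- Shifted-window padding does not mask padded tokens (only the shift mask
  is applied); with token grids that are window multiples — every
  configuration used here — this is exact.
- The swin skip pathway is CNN-only by default; `skips: fused` is a
  declared extension point, not implemented.
- Marker probabilities are uncalibrated by construction at desk scale
  (20 training cases); the calibration-curve machinery quantifies, not
  fixes, this.
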