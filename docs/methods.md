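# Methods

## Problem

Midsagittal spine images contain a column of intervertebral discs that look
nearly identical. Clinical reading of disc degeneration needs exactly three
of them — L1/L2, L4/L5 and L5/S1 — so the task is not "segment all discs"
but "segment these specific instances among look-alikes". Direct semantic
segmentation handles the *what* well and the *which* poorly: typical errors
are a neighbouring disc segmented instead of the target, or the target split
into several fragments.

## The cascade

`disccascade` implements a three-stage coarse-to-fine cascade.

**Stage 1 — center saliency.** Each lower target disc (L4/L5, L5/S1) is
represented by a dense regression target built from the distance transform
to its center point (x₀, y₀):

    D_i = 1 − (d_i²)^(1/n) / max_j (d_j²)^(1/n),

with d_i the Euclidean distance of pixel i to the center and n the *power of
distance*. D is 1 at the center and 0 at the farthest pixel of the image.
The typeset form of this expression is ambiguous between an n-th root and an
n-th power of the squared distance; we use the root reading, under which a
larger n lowers every off-center value (a sharper peak), which is the
direction in which localization accuracy is reported to improve. The
alternative reading is available as `exponent_mode="power"`. Default n = 3.
A segmentation network regresses one saliency channel per lower disc (MSE
loss); the center is recovered as the argmax of the predicted map (ties:
rounded centroid of the argmax set; a constant map is an explicit failure).
Before extraction the pipeline smooths the predicted map with a Gaussian
(σ = 2 px by default) — single-pixel argmax jitter otherwise dominates the
localization error; the extraction rule itself is unchanged. A localization
is counted correct when the L1 error |x − x₀| + |y − y₀| is below 10 px.

**Stage 2 — crop-then-segment.** A square window with side = half the image
side is centered on each recovered center, clamped into bounds, and a second
network segments the disc inside the window; the predicted mask is pasted
back at the preserved window position. Training crops are centered on
ground-truth centers **jittered uniformly within ±4 px (desk profile; ±24 at
full scale)**. The jitter matters: trained on perfectly centered crops the
model acquires a positional prior and fails under test-time localization
error of a few pixels. The jitter radius stays below half the disc spacing,
so "the disc nearest the window center" remains unambiguous.

A scanning baseline (`scanning_localize`) is also provided: slide the window
left-to-right, bottom-to-top, segment in each position, and stop when the
predicted foreground area stabilizes (the disc is then fully inside the
window). Stabilization additionally requires a nonzero area — otherwise the
scan would stop on the first pair of empty windows; if the area never
stabilizes the maximal-area window is returned with a warning.

**Stage 3 — distance-map-augmented selection.** The upper target L1/L2 is
surrounded by look-alike neighbours; an image-only model has no reliable way
to tell them apart. From each stage-2 mask we build a distance map — zero at
the mask centroid, growing with Euclidean distance, normalized by the
per-image maximum (the exact complement of the n = 2 saliency target) — and
stack [image, map(L4/L5), map(L5/S1)] as a 3-channel input. The distance
values at the true L1/L2 location are a nearly positional encoding of "three
levels above the lower discs", a *local* cue. Training uses ground-truth
masks for the distance maps, testing uses stage-2 predictions; this
train/test asymmetry is deliberate and kept.

**Backbone.** All stages use a MultiResUNet re-implementation: MultiRes
blocks chain three 3×3 convolutions carrying W/6, W/3 and W/2 filters
(W = α·U, α = 1.67, U the nominal U-Net width), concatenated and added to a
1×1 residual; skip connections pass through Res paths whose length shrinks
with depth. A plain U-Net is available behind the same interface
(`arch="unet"`) — the cascade, not the backbone, is the point. Because no
GPU framework is assumed, the network stack is a self-contained float32
numpy implementation with hand-written backprop (im2col GEMM convolutions,
with numba direct kernels on the high-resolution low-channel layers), batch
normalization, 2×2 max pooling, stride-2 transposed convolutions and Adam.
Stage 1 uses MSE on the sigmoid output; stages 2–3 use BCE + soft Dice.
Binarization threshold 0.5. All randomness (init, batch order) is seeded;
runs are bit-reproducible on a fixed BLAS.

## Evaluation protocol

Per image j and disc k: IoU_jk between predicted and ground-truth masks.
An image is correct (flag f_j = 1) iff **every** disc is predicted as exactly
one 8-connected component with IoU_jk ≥ 0.7. Accuracy A = B/T is the mean
flag. Mean IoU is reported per disc and overall (grand mean over images and
discs; failed branches contribute 0). SSIM (11×11 Gaussian window, σ = 1.5,
unit dynamic range) is computed between the integrated 3-label images scaled
to [0, 1]. Percentile bootstrap (2000 resamples, seeded) provides optional
95% CIs. IoU of two empty masks is undefined and raises; an empty prediction
against a nonempty truth is 0.

The conservative sample-size rule ceil((z·σ/m)²) is included; at z = 1.96,
σ = 0.01, m = 0.0004 it gives 2401 (~2400 images).

## Synthetic phantom

The original MRI dataset is restricted, so the package ships a generator
that reproduces the *statistical structure* the cascade assumes rather than
MRI appearance: a vertical column of n ≥ 7 bright elliptical discs on a
darker vertebral band over a dark background, with per-disc size, intensity
and tilt jitter, a bowed centerline, a random vertical offset of the whole
column, and additive Gaussian noise (σ = 0.03), clipped to [0, 1]. Targets
are discs 1, 2 and 5 counted from the bottom (L5/S1, L4/L5, L1/L2 analogs),
leaving ≥ 2 non-target discs above the upper target and 2 between the
targets — the distractors that make stage 3 a selection problem. Ground
truth is one mask per target plus its rounded-centroid center.

The column is anchored above a bottom margin (the sacral region sits below
L5/S1 in real scans), and discs beyond the topmost target may run off the
top of the image, as thoracic levels do. The margin is chosen so that crop
windows around the lower targets are never clamped at the image border —
with the column touching the bottom edge, both lower-disc windows clamp
into nearly identical crops with different intended targets, which no
shared segmenter can learn.

Desk-profile geometry (128-px images): disc semi-axes 11–13.5 × 5–5.75 px,
gaps 3.5–4.5 px, bottom margin 34–42 px, curvature ≤ 6 px, tilt ≤ 6°. The disc thickness is chosen so that
the boundary-error-to-object-size ratio matches the full-scale setting: at
512 px a 1-px boundary error costs ~0.1 IoU; with 10–12-px-tall desk discs a
full 1-px erosion still leaves IoU ≈ 0.75, above the 0.7 threshold. What the
phantom does **not** model: MRI texture and bias fields, vertebra/disc shape
detail, pathology, anatomic abnormality. Passing tests therefore demonstrate
that the cascade solves the instance-selection problem under controlled
conditions, not clinical performance.

## Scale profiles and numerical choices

The `desk` profile is what the test suite and the acceptance script run on
one CPU: 128-px phantoms, 64-px crops, base_filters 8, depth 3, 200 train /
50 test, epochs 15/16/15, batch 8, Adam 2e-3 (epoch counts were set where
the training losses plateau). Two further desk economies, both config
fields, keep the budget while preserving the science:

* stages 1 and 3 run their networks at 64-px internal resolution (bilinear
  down/up); the pure-resampling IoU ceiling is 0.93–0.96, far above 0.7;
* Res-path lengths are capped at 1 (full-scale profile keeps the reference
  lengths depth…1).

Stage 3 uses depth 1 in the desk profile (`stage3_depth`). This is a
receptive-field calibration, not an economy: at 64-px resolution a depth-3
net sees essentially the whole image, and an image-only stage 3 can find
"the 5th disc from the bottom" by counting — which the full-scale setting
forbids, since there no receptive field spans the ~300 px from the sacrum to
L1/L2. Depth 1 gives an RF of ~29 px at 64-res (~58 px at image scale), just
under the sacrum-to-L1/L2 distance (~60 px), restoring the full-scale
regime; the distance-map cue is local and unaffected.

The `paper` profile (512-px images, 256-px crops, base_filters 32, depth 4,
500 epochs, 2674/308 split) is provided for completeness and is not run
routinely.

## Failure semantics

A failed branch (ambiguous saliency map, empty stage-2 mask — the distance
map of an empty mask is undefined) yields an empty mask plus a per-stage
flag instead of an exception; evaluation then counts the image as an error,
matching how accuracy treats error images. Mask integration resolves
overlaps by fixed priority L5/S1 > L4/L5 > L1/L2 and reports the overlap
pixel count.

## Known limitations

* The phantom's intensity model is far simpler than MRI; absolute metric
  values are not comparable to the clinical dataset, only directions and
  protocol behaviour are.
* The scanning baseline's stride and stabilization tolerance are free
  parameters (defaults 32 px, 0 px²); published numbers for it depend on
  unstated choices and cannot be replicated exactly.
* Whether saliency/distance maps should be normalized per image or by a
  dataset constant is undocumented in the source method; per-image
  normalization is used throughout.
* Training hyperparameters (optimizer, learning rate, batch size, losses)
  are unstated in the source method; standard choices are used and exposed
  in the config.
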