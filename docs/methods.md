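# Methods

## Problem and pipeline

Radiographic knee-OA assessment assigns a composite Kellgren–Lawrence (KL)
grade (0–4) and, in the feature-specific OARSI scheme, separate 0–3 grades
for lateral/medial joint-space narrowing (JSN-L, JSN-M) and for osteophytes
at four sites (femoral/tibial × lateral/medial: FL, FM, TL, TM). The
pipeline mirrors how a reader works: find the joint, center the attention on
the joint space, compare the two compartments.

Stages: raw radiograph → polarity normalization → double-knee split → 8-bit
conversion + histogram equalization → cascaded detection (box + six key
points) → key-point-driven ROI refinement → symmetric patch split (right
half mirrored) → shared-weight Siamese SE-ResNeXt grading with gated fusion
→ eight softmax heads (KL, six OARSI features, binary OA).

## Preprocessing

* Polarity: radiographs arrive in both conventions. An image of unknown
  polarity is called bright-background when the mean of a 5 %-wide border
  frame exceeds the mean of the central 50 % region (the knee is centered and
  bone is the bright object in the normalized convention); bright images are
  inverted as `max_representable − p`. DICOM MONOCHROME1 is tagged
  bright-background directly from the header.
* Double-knee frames are split at the vertical midline; for odd widths the
  right half receives the extra column (deterministic).
* 16-bit data are min–max rescaled per image, then globally histogram
  equalized (256 bins). Contrast-limited adaptive equalization is available
  behind a flag but off by default. A constant image maps to itself.

## Detector

Stage 1 is fully convolutional with three (3×3 valid conv, 2×2 max-pool)
stages followed by three convolutions, the last two sized to collapse a
`stage1_input_size` window (default 48 px, tiny profile 24 px) to a 1×1 cell.
All convolutions are unpadded, so the sliding-window output grid (stride 8)
is *exactly* the per-crop evaluation of the corresponding windows — the
property the tests assert at 1e-5. Stage 2 shares the conv/pool trunk shape,
adds one valid convolution and two fully connected layers, and fans out into
knee logit (1), box offsets (4) and key points (12).

Regression targets are normalized by the candidate window side:
`(truth − window)/side` for boxes, `(kp − window_origin)/side` for key
points. The loss is `α_det·CE + α_box·MSE(box) + α_kp·MSE(kp)` per batch
with stage-1 weights (1, 0.5, 0) and stage-2 weights (0.8, 0.6, 1.5);
negatives contribute only the classification term, part samples
(IoU 0.4–0.65) only the box term.

Training windows are mined per phantom: positives IoU ≥ 0.65 with generous
scale (0.8–1.3×) and translation (±18 % of the side) jitter, negatives
IoU < 0.3, plus part windows. The jitter magnitude matters: the stride-8
sliding grid at coarse pyramid scales shifts windows by tens of pixels, and
box regression must cover that range. Stage 2 additionally trains on the
candidates the trained stage 1 actually produces (labeled against truth by
the same IoU bands) — without this the refinement network faces a candidate
distribution it never saw and rejects valid knees; adding it raised held-out
detection accuracy from 0.58 to ≈1.0 in development runs.

Inference: image pyramid with scales `(input/min_knee)·0.709^k` until the
smaller side drops below the stage-1 input; threshold 0.6 → offset
refinement → NMS at IoU 0.7 → square crops → stage 2 → threshold 0.7 →
refinement → NMS at 0.5 → highest score wins (one knee per single-knee
image is assumed). What counts as a correct detection is IoU ≥ 0.5 with the
truth box (configurable).

## ROI refinement and patching

Knee width `w` = span of the six key points' x coordinates. The refined box
keeps the detected x-range and spans `[min_y − 0.2w, max_y + 0.2w]` over the
key points' y coordinates (raster convention, y down: the *top* of the crop
is `min_y − 0.2w`). A symmetric margin is used because the crop should
center the joint space; the margin factor is configurable. The crop is split
at its vertical midline (odd widths: extra column to the right half), the
right half is mirrored, and both patches are resized to the grader's input
size (default 128 px; tiny profile 64 px).

## Grading network

Blocks combine the ResNeXt aggregated transform — cardinality C parallel
bottlenecks realized as 1×1 reduce → grouped 3×3 → 1×1 expand — with an SE
unit (channel means → C/r bottleneck → sigmoid gate → channel rescale, r=16
full / 8 tiny) applied to the branch output before the residual addition.
Blocks have no post-addition ReLU, so a block with zero transform weights is
exactly the identity; inside a network the following block's convolution
provides the nonlinearity boundary. Batch normalization is omitted: the
desk-scale networks are small enough to train without it, and exact
determinism plus bit-identical freeze semantics are worth more here than the
optimization aid.

Stage plans: the full profile follows the 50-layer plan (3, 4, 6, 3 blocks;
output widths 256/512/1024/2048; cardinality 32, bottleneck width 4; 7×7
stride-2 stem). The tiny profile has a 3×3 stride-2 stem and one block per
stage (widths 32/64, cardinality 4). The tiny stem downsamples immediately
so the grid entering global average pooling is 4×4: osteophyte bumps occupy
only a few pixels, and with an 8×8 grid their contribution to a channel mean
(≈1/64) proved too dilute for the heads to pick up, while at 4×4 all eight
tasks become learnable. Features are globally average-pooled to a d-vector
(d = 2048 full, 64 tiny).

Fusion operates on the pooled vectors: `g = σ(W_g(f_left ⊕ f_right))` is a
per-feature gate (W_g maps 2d→d) and `f = g⊙f_left + (1−g)⊙f_right`. Eight
heads — dropout 0.5 followed by a linear layer — share the fused feature. A
single-branch variant (whole ROI through one backbone) and the probability-
averaging ensemble of the two are provided.

## Training protocol

The default protocol is the transfer-learning one: epochs 1–2 train only the FC layers
(fusion gate + heads) at lr 0.01 with the backbone frozen — frozen means the
backbone receives no gradient and its parameters stay bit-identical — epoch
3 trains everything at 0.001, and from epoch 4 the rate is 0.0001; Adam,
weight decay 1e-4, 20 epochs, dropout 0.5. That decay schedule presumes a
pretrained backbone (pretraining is intentionally unsupported here for
reproducibility), so the tiny from-scratch profile keeps the structure —
two fc-only epochs, then full training — at rates suited to random
initialization: constant 3e-3 after the freeze, 60 epochs, batch 16.

The grading loss is the unweighted sum of per-task cross-entropies; rows
with a missing label are masked out of that task's term. Augmentation
families: contrast scaling (±20 % about the mean), gamma (0.7–1.3), rotation
(±10°), translation (±5 %); the magnitudes are package choices and each
family can be disabled. The tiny profile uses the photometric families only,
since the phantom generator already randomizes pose. Model selection keeps
the lowest-validation-loss epoch. Data are split train/val/test 5:1:3,
stratified by KL.

## Metrics

top1 = exact-grade accuracy; top±1 = |pred − truth| ≤ 1, the ordinal
relaxation appropriate for semi-quantitative grades (reported for ordinal
tasks only — for a binary task any in-range prediction is within one grade).
Cohen's kappa is reported in all three weightings with quadratic as the
default (conventional for ordinal radiographic grading); the degenerate
single-shared-class case returns NaN. MSE is on integer grades. Confusion
matrices are (true × predicted) counts.

## Phantom generator

Each phantom renders femur and tibia as bright rounded rectangles
(intensity 200 on background 20) with half-open boundaries, so a geometric
gap of g px is exactly g background rows. The tibial plateau is flat; the
femoral undersurface sits `gap = base_gap·(1 − 0.25·jsn)` above it per
compartment (base_gap 24 px; lateral = image-left). Two triangular tibial
spines flank the midline. Osteophytes are semicircular bumps of radius
`2·grade + 1` px at the four compartment corners. Key points: the two
femoral margins, two tibial margins, two spine tips. Nuisance parameters:
knee width 140–170 px, bone height 75–95 px, translation jitter ±12 px,
rotation ±2°, Gaussian blur σ 1.2, noise σ 6, optional polarity inversion.
Labels: the six feature grades are drawn independently with marginals
(0.45, 0.25, 0.15, 0.15); an optional shared-severity knob correlates them.
KL is derived deterministically as `min(4, max(osteophytes) + max(JSN))` —
a clinically flavored surrogate that guarantees label consistency (definite
osteophytes push KL ≥ 2; combined features saturate at 4) — and OA = (KL ≥ 2).

What the phantoms do *not* emulate: soft-tissue gradients, trabecular
texture, beam-hardening artifacts, anatomical shape variation, reader noise
in labels. Passing tests therefore demonstrate that the pipeline's machinery
(localization, geometry, fusion, multi-task learning, evaluation) works end
to end, not that the trained weights transfer to clinical radiographs.

## Problem sizes and numerics

The reference study trains the detector on windows mined from 150 phantoms
(2 positive / 1 part / 3 negative per image, ≈900 windows) and evaluates on
200 held-out phantoms; the grader trains on 1000 phantoms (200 validation)
and evaluates on 300; the end-to-end closure runs 50 double-knee frames with
a 30 % inverted-polarity mix. These sizes keep the full study within tens of
minutes on one CPU while leaving comfortable accuracy margins.

All arithmetic is float64. Convolution is im2col + matmul with an exact
scatter-add backward; every layer's backward pass is validated against
central finite differences at 1e-7 tolerance. NMS ties break by input index;
equalization maps constant images to themselves; IoU uses the half-open box
convention throughout. All randomness flows through seeded
`numpy.random.Generator` instances, so same-seed runs are bit-identical on a
single thread.

## Known limitations

* The full 50-layer profile is provided and tested for construction and
  forward execution, but desk-scale training uses the tiny profile only.
* ImageNet pretraining and Grad-CAM visualization are out of scope.
* The detector assumes exactly one knee per single-knee image.
* The ensemble combination is probability averaging; no uncertainty
  calibration is attempted.
* Phantom realism is deliberately minimal (see above); reported accuracies
  characterize the pipeline, not clinical performance.
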