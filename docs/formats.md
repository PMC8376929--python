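# File formats

Conventions shared by every interchange file: coordinates are 0-based with
the origin at the top-left corner, y increases downward, and boxes are
half-open `[min, max)` in both axes.

## Images

* Input: grayscale PNG/TIFF (8- or 16-bit) or single-frame monochrome DICOM.
  DICOM `PhotometricInterpretation == MONOCHROME1` is treated as
  bright-background and inverted during preprocessing.
* Output of `kneepipe preprocess`: 8-bit PNG per single knee, named
  `<source_id>_<L|R>.png` (L/R is image-space position).

## Labels CSV (`labels.csv`)

Columns: `knee_id, kl, jsn_l, jsn_m, fl, fm, tl, tm, oa[, split]`.
KL in 0–4; the six OARSI features in 0–3; `oa` = 1 iff KL ≥ 2. The optional
`split` column holds `train`/`val`/`test` (5:1:3, stratified by KL).

## Key points JSON (`keypoints.json`)

One object per image:

```json
{"<knee_id>": {"image": "<file>.png",
               "box": [x1, y1, x2, y2],
               "keypoints": [[x, y], ...six points...]}}
```

Key-point order: lateral femoral margin, medial femoral margin, lateral
tibial margin, medial tibial margin, lateral tibial spine, medial tibial
spine.

## Detections CSV

Columns: `image, score, x1, y1, x2, y2, kx1, ky1, ..., kx6, ky6` (same
key-point order). One row per detected knee; images with no surviving
detection have no row.

## Patch manifest (`manifest.csv`)

Columns: `image, left, right` — the source image and the two patch PNGs
(the right patch is stored already mirrored).

## Predictions CSV

Columns: `knee_id`, then per task the argmax grade (`kl`, `jsn_l`, ...,
`oa`) and the probability vector (`p_kl`, ...) as space-separated floats.

## Evaluation report (JSON)

`{"n_samples": N, "tasks": {<task>: {"top1", "top_pm1" (ordinal tasks only),
"kappa", "kappa_all": {none, linear, quadratic}, "mse",
"confusion": [[...]]}}}`.

## Model checkpoints

NumPy `.npz` archives containing the flat parameter arrays plus a
`__config__` JSON string with the architecture/cascade configuration, so a
checkpoint reconstructs its own network.
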