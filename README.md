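# fibrotex

Quantification of fibrillar collagen organisation and matrix remodeling from
microscopy images, built for studies of desmoplastic tumors (most notably
pancreatic ductal adenocarcinoma) where tumor cells degrade and reorganise
the collagen-rich stroma as they invade.

It covers the image-analysis read-outs such studies rely on:

* **Collagen texture from second-harmonic-generation (SHG) imaging.** The
  maximum projection of an SHG z-stack is automatically thresholded to a
  collagen mask, and a gray-level co-occurrence matrix (GLCM) is accumulated
  for every pixel-comparison distance *d* = 1..100 and each of four
  directions (0°, 45°, 90°, 135°), skipping any pixel pair that touches
  background. Each matrix is summarised by five Haralick parameters —
  angular second moment, contrast, correlation, inverse difference moment
  and entropy — giving 2,000 parameter values per image. The correlation
  parameter decays with distance; a double-exponential decay model

  $$y(d) = A_1 e^{-d/d_1} + A_2 e^{-d/d_2} + b, \qquad A_i \ge 0,\; d_1 \le d_2,$$

  is fitted to the direction-averaged curve, and the sample is summarised by
  the **weighted mean decay distance**
  $(A_1 d_1 + A_2 d_2)/(A_1 + A_2)$, in pixels and micrometres: intact,
  long-range-organised collagen decays slowly (large statistic), degraded or
  disorganised collagen decays fast.

* **Depth-resolved fibrillar collagen area**: the cell/collagen interface
  plane is detected from a paired cell channel, and the thresholded collagen
  area fraction is reported at 2.5 µm depth increments below it.

* **Collagen degradation area**: the dark-hole percentage of a fluorescent
  (FITC-labelled) collagen film.

* **Invasion and staining scores**: organotypic invasion percentage and
  invasion index (sample % / control %), Ki67-positive cell fractions, and
  the weighted immunohistochemistry histoscore
  $H = 1\cdot\%_\text{weak} + 2\cdot\%_\text{moderate} + 3\cdot\%_\text{strong} \in [0, 300]$
  with multi-rater consensus by mean.

* **Synthetic data**: seeded generators (correlated random fields with exact
  exponential autocorrelation, fiber images, depth stacks, degradation
  films, invasion masks, class fractions) that plant recoverable ground
  truth for every stage, so the whole pipeline is testable without any
  microscope data.

## Worked example

Generate a synthetic SHG-like field with a planted 8 px correlation length,
then run the full texture pipeline:

```sh
fibrotex simulate field --seed 7 --size 256 --correlation-length 8 --out field.tif
fibrotex preprocess --input field.tif --pixel-size-um 1.0 --z-step-um 1.0 \
    --out-projection proj.tif --out-mask mask.tif
fibrotex texture --input proj.tif --mask mask.tif --levels 64 --max-distance 100 \
    --out profile.csv
fibrotex decay --profile profile.csv --pixel-size-um 1.0 --out fit.json
```

which prints

```
field 256x256, correlation length 8.0 px -> field.tif
projection 256x256, otsu threshold 128, foreground 48.40%
2000 parameter values -> profile.csv
weighted mean decay distance 11.251 px (11.251 um)
```

`profile.csv` holds the 2,000 texture parameter values (five features × 100
distances × four directions); `fit.json` records the fitted decay model —
here $A_1 = 0.76$, $d_1 = 3.5$ px, $A_2 = 0.19$, $d_2 = 42.1$ px, baseline
$-0.056$ — and the statistic of 11.25 px. The fast component reflects the
Otsu mask truncating the field's own histogram (see `docs/methods.md` for
why masking a signal-everywhere image biases the curve, and why the
statistic still orders samples by correlation length); on the unmasked field
the statistic recovers the planted length to within 20%.

The other assay read-outs follow the same pattern, e.g.:

```sh
fibrotex simulate degradation --seed 3 --fraction 0.25 --out fitc.tif
fibrotex degrade --input fitc.tif --out degrade.json
# -> degraded area 25.00%
```

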