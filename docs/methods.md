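# Methods

## Scope and data model

All computation runs on calibrated integer rasters: `ImageGrid` (2-D, 8- or
16-bit, pixel size in µm) and `ImageStack` (ordered planes, z-step in µm).
Rasters are row-major with the origin at the top-left. Calibration never
defaults silently: an explicit argument overrides TIFF metadata, and absence
of both is an error (the z-step of a single-plane file, which nothing
consumes, defaults to 1 µm). Thresholding follows one package-wide tie
rule — foreground is strictly above the threshold — so every derived
quantity (mask areas, depth fractions, degradation fractions) is reproducible
to the pixel.

## Automatic thresholding

The default method is Otsu's criterion, implemented as an exhaustive search
over all integer cut points of the full bit range, maximising the
between-class variance; ties take the lowest cut. The exhaustive integer
form (rather than a binned variant) makes the result exactly checkable
against independent enumeration and invariant under a constant intensity
shift. IsoData is available as an alternative where a workflow calls for it;
the two are offered as alternatives, not as a claim about any particular
historical pipeline.

## GLCM texture sweep

For gray levels the masked intensity range [min, max] of the *valid* pixels
is binned by `level = floor((L−1)(v−min)/(max−min))` with L = 64 by default
(configurable up to the full bit range). Quantizing over the masked range
rather than the bit range spends the level budget on the collagen signal's
dynamic range.

Co-occurrence matrices are accumulated per offset — distance d = 1..100,
directions 0° (0,+d), 45° (−d,+d), 90° (−d,0), 135° (−d,−d) in (row, col) —
counting a pair only when **both** endpoints are valid under the mask, each
pair contributing symmetrically to (i, j) and (j, i), then normalising to
total mass 1. Symmetric accumulation makes the two marginals identical,
which simplifies the correlation parameter. Offsets with no valid pair are
recorded as missing, never as zero. The five per-offset parameters use the
standard definitions: ASM = Σp², contrast = Σ(i−j)²p, IDM = Σp/(1+(i−j)²),
entropy = −Σp ln p (natural log, 0·ln 0 = 0), and correlation
= Σ(i−µ)(j−µ)p/σ² with µ, σ² the marginal moments; σ² = 0 flags correlation
undefined (NaN), and aggregation excludes such entries. The vectorised
accumulator is held bit-exact to a brute-force pair enumeration in the test
suite.

## Decay model and the weighted mean decay distance

The direction-averaged correlation-vs-distance curve is fitted by nonlinear
least squares (bounded trust-region) to
y = A1·exp(−x/d1) + A2·exp(−x/d2) + baseline with A ≥ 0 and d > 0, using a
deterministic multi-start over all pairings of decay starts {2, 10, 40} px,
amplitudes split evenly from the initial drop above the tail-mean baseline.
The best residual sum of squares wins and components are ordered d1 ≤ d2.
Two numerical choices matter:

* **Upper bound d ≤ 2·max(x).** A component decaying more slowly than twice
  the observation window is indistinguishable from the baseline term; left
  unbounded, that degeneracy occasionally lets an arbitrary huge d carry
  real amplitude and inflate the statistic by orders of magnitude. The bound
  scales with the window, preserving the fit's equivariance under rescaling
  of x.
* **Amplitude weighting.** The per-sample statistic is
  (A1·d1 + A2·d2)/(A1 + A2) — a convex combination, always between d1 and
  d2. Weighting by amplitudes is the most direct reading of a "weighted
  mean" of two decay components; integrated-area weighting (A·d) is a
  defensible alternative and would emphasise the slow component more. The
  choice is an interpretation, fixed here and stated rather than hidden.

Aggregation averages each parameter over the directions present at each
distance; per-direction fits remain available but are not the default.

## Synthetic fields and what recovery does (and does not) show

`gen_correlated_field` synthesises a stationary Gaussian field with
isotropic exponential autocorrelation ρ(r) = exp(−r/ℓ) by circulant
embedding on a 2× padded torus (eigenvalues clipped at zero), then maps it
affinely to 8 bits (defaults mean 128, sd 30 — comfortably inside the bit
range, so clipping is negligible and the empirical autocorrelation of the
stored image matches the model within 0.05 out to lag 40 at 512²).
Exponential autocorrelation is chosen deliberately: it makes the GLCM
correlation-vs-distance curve itself near-exponential, so decay-distance
recovery is a meaningful end-to-end oracle.

Two systematic effects shape what "recovery" means:

* **Direction mixing.** Axial offsets probe physical lag d but diagonal
  offsets probe d·√2, so the direction-averaged curve is a mixture of decay
  lengths ℓ and ℓ/√2; its amplitude-weighted mean sits near 0.85ℓ, within
  the ±20% recovery band used by the tests (measured medians over ten seeds
  at 512²: 3.5, 8.9, 20.4 px for ℓ = 4, 10, 25).
* **Mask truncation.** The synthetic field is signal everywhere, so the
  automatic threshold — whose job on real SHG data is to remove dark
  background — instead truncates the field's own histogram at roughly its
  median. The correlation of upper-truncated Gaussian pairs is a nonlinear
  compression of ρ (≈0.9ρ near ρ = 1 falling to ≈0.4ρ for small ρ), which
  splits the fitted curve into a fast head plus a true-ℓ tail and pulls the
  amplitude-weighted mean to ≈0.5–0.6ℓ. This is an artifact of the
  stand-in, not of the statistic: the tests therefore assert *quantitative*
  recovery (±20%) on the fully valid field, and assert that the complete
  masked pipeline still orders samples strictly by planted ℓ, which is the
  property the statistic is used for. Passing these tests shows the texture
  and fitting machinery is correct and monotone; it does not certify
  absolute decay distances on real tissue, where mask quality, anisotropy
  and depth attenuation all intervene.

## Depth profiles, degradation, scoring

The cell/collagen interface is the deepest plane whose thresholded
cell-channel coverage reaches 5% (threshold fixed once from the
maximal-signal plane); if no plane qualifies the surface plane is used and a
warning flag returned. The SHG threshold is fixed once, from the interface
plane (falling back to the pooled stack histogram, then to "nothing
foreground" for a constant stack), and reused at every depth so threshold
drift cannot imitate depth decay. Planes map to the nearest 2.5 µm increment
(half-steps round deeper); empty increments are reported missing, never
interpolated. Fractions are reported as dimensionless area fractions; the
pixel calibration converts to absolute areas when needed.

Degradation area uses a fraction-of-mode threshold by default (0.5 × the
modal intensity — the intact film dominates the histogram), counting pixels
at or below it as degraded; "at or below" keeps the two boundary cases exact
(a uniformly bright film scores 0%, an all-zero image 100%). The inverted
Otsu partition is available where the film is not mode-dominated, and is
invariant to constant intensity shifts.

Invasion scoring consumes cell and region masks from any segmentation
(invading area = cells ∩ region; index = sample % / control %, a ratio, with
a zero control undefined rather than clamped). A deliberately simple
baseline segmentation (threshold + connected-component size filter) ships
with the synthetic generators for end-to-end tests only and makes no claim
to match any production cell detector. Class fractions for the histoscore
must sum to 100 within ±0.01 (renormalized exactly; larger deviations are
rejected as probable double counting).

## Synthetic generator defaults

Depth stacks plant exact bright-pixel counts (background 5–25, signal
200–240, 8-bit) so recovered fractions are exact to rounding; the cell
channel covers planes down to the stated interface at 50%. Degradation films
are 200 ± 4 with 30-intensity holes placed as random discs trimmed
pixel-exactly to the target fraction; invasion masks use the same
exact-count construction. Class-fraction generation rejection-samples random
weight mixtures scaled to the target score (deterministic two-class
construction as fallback; targets 0 and 300 have unique solutions). All
generators draw from one `numpy.random.Generator` seeded per call.

## Problem sizes

The test suite verifies the texture sweep at the full working configuration
(500–512 px images, 100 distances, four directions, 64 levels; about half a
second per image) and uses ten seeds per condition for the statistical
recovery checks, which keeps the whole suite around half a minute on one
CPU. Brute-force GLCM equivalence runs on a hundred random images up to
12×12, where enumeration is exact and cheap.

## Known limitations

* No fiber tracing, orientation analysis or 3-D texture; the GLCM sweep is
  strictly 2-D on the projection.
* No model selection between single- and double-exponential decay, and no
  uncertainty (bootstrap) on the statistic.
* The weighting scheme and the presence of a baseline term in the decay
  model are documented interpretations (see above), not the only options.
* Synthetic images emulate second-order statistics and planted fractions,
  not SHG optics, noise physics or H&E colour; results on them bound
  algorithmic correctness, not biological accuracy.
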