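# Methods

`hemdetect` implements an automatic hemorrhage (HE) detection pipeline for
color fundus photographs: adaptive quality enhancement, matched-filter seed
extraction, smart window-based adaptive thresholding (SWAT) segmentation,
and a shallow convolutional classifier (HemNet).  Because the pipeline is
exercised end-to-end on synthetic fundus images with exact ground truth,
this note records both the model itself and the choices made where the
method's published description leaves the design open.

## Quality enhancement

Each 8-bit RGB image passes, per channel, through:

1. **CLAHE** — contrast-limited adaptive histogram equalization (tile side
   = image side / 8, clip limit 0.01; both configurable).  Constant
   channels pass through.
2. **Gradient-adaptive gamma correction.**  For each channel scaled to
   [0, 1], φ is the Otsu threshold of the Sobel gradient-magnitude image —
   the gray level separating smooth regions from edges, read as a
   brightness/sharpness summary.  The correction exponent is

       γ = α · ⌊φ · 100⌋ / 10,      α = 2 (default)

   applied as the power law V = I_max (I / I_max)^γ with I_max = 255.
   γ is deliberately unclamped: φ → 1 would drive γ to 20 and crush the
   image; in practice φ ≈ 0.10–0.15 on enhanced fundus-like content
   (γ ≈ 2–3).  The Sobel magnitude of a [0, 1] channel is itself already
   in [0, 1]; normalizing it by its observed maximum instead would tie φ
   to the single strongest edge in the image, inflate γ to ≈ 4–5, and
   collapse the retinal intensity mass to a few gray levels — incompatible
   with the bright-background calibration this pipeline depends on.
3. **Fuzzy-style unsharp masking of the green channel** (the channel with
   the strongest lesion contrast).  With d = center − 3×3 neighborhood
   mean, the sharpened value is clip(center + λ·s(d)) using the odd,
   saturating nonlinearity

       s(d) = σ_s · tanh(d / σ_s) · d² / (d² + θ²)

   with gain λ = 1.5, saturation σ_s = 30 and noise floor θ = 4 intensity
   units.  The tanh caps the boost for strong edges; the d²/(d²+θ²) gate
   leaves differences at the sensor-noise scale nearly untouched, which
   matters because a matched filter consumes this channel next.

All downstream stages consume the *un-rounded* float enhancement output
(`EnhancedImage.float_pixels`).  Rounding to 8 bits mid-pipeline is only a
rendering step: after a γ of 2–3 the retinal histogram occupies few 8-bit
levels, and premature quantization destroys the lesion/vessel/retina
separation that SWAT thresholds on.

## Calibration and the search region

The retinal disc mask comes from the raw green channel: 25×25 median
filter, Otsu binarization, largest connected component, convex hull.  The
hull (rather than hole filling) is load-bearing: a dark lesion at the rim
carves a *notch* open to the background, which is not a topological hole;
the camera field of view is convex, so the hull reclaims it.  The rim band
is the mask minus its erosion by a 10×10 square.

The calibrated image replaces the black background and the rim band with
`mean_gray`, the mean enhanced-green intensity over the mask interior
(mask minus rim).  Averaging over the interior only makes calibration
exactly idempotent.  The bright background removes the dominant dark-rim
edge, so rim-adjacent lesions look like ordinary dark blobs on a bright
field — the stated purpose of this stage.

The search region S is the retinal mask dilated by a square of side
2·80+1 pixels (Chebyshev distance 80, configurable); all SWAT window
growth is gated by S.

## Seed extraction

An inverted-Gaussian matched filter bank scans for dark blobs and lines:
the 0° kernel is K(x, y) = −exp(−x²/2σ²) on |x| ≤ 3σ across the line and
|y| ≤ (L−1)/2 along it, mean-subtracted over its support (so constant
offsets produce zero response), with σ = 4 px, L = 9 px, and 12 analytic
rotations over 180°.  The response is the pixel-wise maximum correlation
over orientations (FFT correlation with reflective padding).

Thresholding is local, following the GLCM cross-entropy idea: at a
candidate threshold t the gray-level co-occurrence matrix splits into
background–background and foreground–foreground quadrants (the two edge
quadrants are ignored); t* maximizes the sum of the two renormalized
quadrant Shannon entropies, ties to the smallest t.  Operationally:

- the positive response is compressed to a square-root scale first —
  matched-filter responses are heavy-tailed (dark vessels crossing the
  bright optic disc respond an order of magnitude above lesions), and a
  uniform quantization would hand most levels to that tail;
- t* is computed per sliding 64-px window at half-window stride, each
  window min–max quantized to 256 levels in its own range; every pixel
  takes the **minimum** threshold over its covering windows (degenerate
  windows inherit the whole-image t*).  The minimum favors recall;
  the opening and the classifier absorb the extra detections;
- thresholds are floored at zero response: an inverted-Gaussian kernel is
  positive only at dark-object centers.

The binary map is post-processed by filling enclosed holes (a matched
filter answers a blob wider than its kernel with a *ring*), then
re-punching strictly-negative-response pixels: the kernel's negative
flanks trace vessels, and this cut is what separates vessel-attached
lesions from the vessel run.  An 11×11 square opening removes structures
thinner than the SE (vessels); seeds are the centroids of the 8-connected
**erosion cores** — for an isolated blob identical to the opened
component's centroid, but when a component drags a vessel stub along, the
stub vanishes under erosion and the centroid stays on the blob.

Known limitation: the positive-response band of an isolated thin dark bar
is as wide as the kernel's zero-crossing (~11–12 px for σ = 4) regardless
of the bar's true width, so an isolated high-contrast thin structure can
survive the opening.  In context, vessel responses compete with lesions
and the disc inside each local window, the threshold trims their bands
below the SE, and surviving vessel fragments are rejected by the
classifier.

## SWAT segmentation

Each seed anchors a 61×61 window (configurable; windows are expanded to at
least 16 px a side at image borders) on the calibrated channel, lightly
median-filtered (3×3) because window thresholding is pixel-level with no
spatial averaging and speckle otherwise bridges the dark regions.  Float
windows are min–max quantized to 256 levels in their own range; the
effectiveness of a multi-level Otsu partition is scale-invariant, so this
costs nothing and preserves contrast.

Per window, the region count ϱ starts at 2 and increments while the
effectiveness

    η = σ_B²(τ*) / σ_T²   < 0.8      and ϱ ≤ 20,

where σ_B² is the between-region variance of the optimal ϱ-region
partition and σ_T² the window's total variance.  The optimal threshold
vector ϑ (ϱ−1 ascending levels) is found *exactly* by dynamic programming
over cumulative histogram moments; the DP state is shared across the ϱ
escalation, so each increment costs one sweep.  The window binarizes to
the darkest region, W₁ = [W ≤ min(ϑ)].

Of the connected components of W₁ the two largest are kept (bigger lesions
are prioritized; dark shades are often large), and of those two the one
whose centroid is nearest the seed survives.  If it touches a window
border, the window grows on the touched sides — left/top by 5 px,
right/bottom by 10 px, exactly the printed asymmetric steps (a
`symmetric_growth` switch uses 5 px everywhere) — provided the moved edge
stays inside S; then the whole window is re-thresholded.  The loop stops
when the object is enclosed, growth is blocked, or after `max_iter` = 50
rounds.  Degenerate (constant) windows and empty binarizations drop the
seed with a log entry, not an error.

On synthetic images, vessel-*clear* planted lesions segment at IoU
0.92–1.00 against their ground-truth supports, including rim-adjacent ones
(growth clipped by S, candidate still returned).  Vessel-*attached*
lesions return merged lesion+vessel objects: by the printed rules the
attached vessel run shares the darkest Otsu region at the η-stop, and
isolating it is deliberately the classifier's job.

## HemNet

The classifier consumes 256×256×3 tensors composed from a candidate
window: RGB green, HSV value (max of R, G, B), and CIE-Lab L (sRGB, D65;
L rescaled from [0, 100] to [0, 1]), each in [0, 1], resized bilinearly.
The architecture (19 individual layers counting input, the addition
junction, softmax and the classification output):

| layer | kernel/stride | output |
|---|---|---|
| input | – | 256×256×3 |
| conv_1 + ReLU + BN + avg pool 2×2 (stride 1) | 11×11 / 3 | 86×86×16 |
| conv_2 + ReLU + BN + avg pool 2×2 (stride 1) | 5×5 / 2 | 43×43×16 |
| skip from pool_1: avg pool 5×5 (stride 2) + BN | – | 43×43×16 |
| addition | – | 43×43×16 |
| conv_4 + ReLU + BN + avg pool 2×2 (stride 1) | 11×11 / 2 | 22×22×16 |
| fully connected + softmax + cross-entropy | – | 2 |

Same padding is the only convolution padding consistent with these shapes
(256 → 86 at stride 3 needs 5 px per side); the 2×2 pools are
shape-preserving (stride 1, same padding, zeros included in the mean,
which affects only border cells), and the 5×5 skip pool is the only
stride-2 reading consistent with the addition shape.  The skip source is
the first pool's output, the only upstream tensor the halving pool maps to
43×43×16.  `build_hemnet` audits every realized shape against this layout
at construction and refuses to build on any mismatch.

The backend is NumPy (float32, im2col lowering to BLAS matmuls, explicit
backward passes, verified against central finite differences).  Large
intermediates are allocated once per shape and reused; freshly mapped
pages cost orders of magnitude more than warm ones, and training touches
the same shapes thousands of times.  The first convolution skips its input
gradient (nothing upstream needs it).

Training: softmax cross-entropy, SGD with momentum 0.9, batch size 32,
default learning rate 0.01 / 15 epochs (both configurable; the synthetic
study below uses 5 epochs).  The data are shuffled **once** with the given
seed and the batch partition is fixed across epochs: runs are bitwise
reproducible, and a zero learning rate yields an exactly flat training
loss.  The trailing `val_fraction` of the shuffle is the validation split,
evaluated in inference mode (running batch-norm statistics) per epoch.

Evaluation: confusion counts at a 0.5 threshold give

    SE = TP/(TP+FN)   SP = TN/(TN+FP)   P = TP/(TP+FP)
    AC = (TP+TN)/(TP+TN+FP+FN)

with PR and ROC curves swept over all distinct score thresholds and both
areas by the trapezoid rule.  Candidates are labeled positive when at
least half of the object mask overlaps the ground-truth lesion mask
(boundary inclusive; fraction configurable).

## Synthetic fundus generator

The generator renders the structure the pipeline assumes, with exact
masks, as a pure function of its seed:

- reddish-orange retinal disc (base RGB ≈ (180, 90, 40) with smooth
  texture jitter) of radius 340 px in a 768-px image on a black background
  with additive Gaussian sensor noise (σ = 4);
- a bright optic disc and dark branching vessels (widths 3–9 px) that
  emerge spaced around the disc rim — not from a single point, which would
  stack them into a solid hub no opening could break, unlike real anatomy;
- 6 dark irregular lesions per image, elliptical supports with a smooth
  periodic radial perturbation (±12 %, harmonics 2–4), semi-axes 8–25 px,
  darkening green most strongly (matching the pipeline's green-channel
  reliance); 25 % are placed within ~15 px of the rim and 25 % centered on
  a vessel; the remainder must keep a clear margin from vessels so that
  attachment is a controlled condition (crowded vessel nets relax the
  margin after bounded retries rather than failing);
- a multiplicative illumination field (tilted plane plus mild radial
  vignette, ±20 %).

What the generator does *not* emulate: true fundus texture and optics,
microaneurysms and exudates as labeled classes, JPEG artifacts,
inter-camera color variation.  Passing the synthetic study therefore shows
the pipeline's mechanics are correct under the assumed structure, not
clinical performance on real fundus photographs.

The patch harness derives balanced classifier sets from compact 384-px
source images (lesion pixel sizes preserved): positives are jittered
windows centered on planted lesions, negatives sample the classifier's
real confusers — vessel segments, the retinal rim, and plain shaded
retina — with windows rejected if lesion pixels exceed 5 % of their area.
Patches are stored as uint8 composed tensors and converted per batch.

## Study sizes and observed results

The acceptance study (tests and `scripts/acceptance.py`) uses 20 generated
images for seed recovery, 3–5 images for segmentation quality, and a
2,000-patch training set with a 400-patch held-out split, 5 epochs —
sizes at which every stage's behavior is already stable.  Observed on
seeded runs: seed recovery ≈ 95–97 % of planted lesion centroids within
10 px; vessel-clear segmentation IoU ≥ 0.9; held-out patch classification
accuracy ≈ 0.97–0.99 with AUROC ≈ 1.00.  The numbers printed by
`scripts/acceptance.py` are recomputed from scratch on every run.

## Numerical notes

- Multi-level Otsu: exact DP over 256-bin cumulative moments; σ_B² =
  Σ S1²/S0 − μ_T²; η clipped to [0, 1]; ties resolved toward smaller
  thresholds (argmax of the first maximum).
- Quadrant entropies use the identity H(q/m) = −S/m + log m over raw
  p·log p cumulative sums; empty quadrants contribute zero.
- FFT correlation cleans |response| < 1e−8 · scale to exactly zero so
  constant inputs give identically zero response.
- Degenerate inputs: constant windows raise a typed error inside
  `multilevel_otsu` and drop the seed in `swat_segment`; single-level
  GLCMs raise a typed error; all-black images fail the retinal mask with
  a typed error.
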