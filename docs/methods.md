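# Methods

`hyperfod` implements an inline inspection pipeline that finds foreign
objects (plastics, metal, wood, paper, rubber, belt fragments) on pork belly
imaged by a near-infrared line-scan camera. This note records the models and
procedures, their assumptions, the parameters that matter, and what the
synthetic experiments do and do not demonstrate.

## Sensor model and calibration

The camera measures one spatial line of 640 pixels × 224 spectral bands per
frame over 942–1723 nm (≈3.5 nm/band); conveyor motion supplies the second
spatial axis, so a scene is a hypercube ordered `(line, sample, band)`.
Line-scan sensors exhibit *fixed-pattern noise*: temporally coherent
per-column sensitivity differences that appear as vertical stripes, plus a
dark-current offset, both drifting with sensor temperature and exposure.

Flat-field correction removes the per-(column, band) gain and offset using a
dark frame `D` (shutter closed) and a flat frame `F` (homogeneous bright
target):

    C = (I − D) · m / (F − D),      m = mean(F − D)

Equivalently `C = (I − D)/G` with gain `G = (F − D)/m`. The correction
assumes `F − D > 0` everywhere (enforced; violations are reported with the
offending column/band) and that dark/flat were acquired under the acquisition
settings of `I` — hence the `CalibrationLibrary`, which selects the pair
nearest in sensor temperature (ties to the lower temperature). Negative
corrected intensities are clamped to zero. The 20 weakly illuminated bands at
each spectral edge are then dropped, leaving 184 bands (indices 20–203,
≈1012–1653 nm).

Per-pixel spectral normalization makes the representation invariant to
residual multiplicative drift. The default `minmax` mode maps each spectrum
`s` to `(s − min s)/(max s − min s)`, which cancels *any* per-pixel affine
map with positive gain — including smooth multiplicative shadow fields — and
each pixel attains 0 and 1. A `max` mode `(s − min s)/max s` is
also provided; it cancels pure gain only. `minmax` is the default because
shadow attenuation requires the offset term to cancel. Spectra whose
denominator falls below 1e−8 (dead pixels) normalize to the zero vector and
are counted in a log warning rather than raising.

Affine invariance is exact in real arithmetic but not bitwise in floating
point (rounding of `g·s + b` perturbs the quotient); tests allow deviations
at the float32-ulp scale (≤2e−6) and require exact equality for
power-of-two gains, where the scaling is representable.

## Segmentation model

Each 20×16 tile of a normalized cube is classified densely: all 320 pixels
receive one of 13 labels. Every pixel is one token whose embedding is its raw
184-band spectrum (no patch projection); four pre-norm transformer blocks
(8-head self-attention over the 320 tokens, head dimension 23, then a
two-layer GELU MLP of hidden width 736 = 4×184, residual connections around
both) refine the tokens, and a final linear layer maps 184 → 13. Total:
1,637,061 parameters.

There is no positional embedding by default — nothing in the design requires
one, and its absence makes the network exactly permutation-equivariant over
pixel positions, which is a strong structural test. A learned 320-position
table is available as a config option, as is residual-branch dropout
(default 0). Weights are truncated-normal (σ = 0.02, resampled at ±2σ),
biases zero, LayerNorm unit/zero; initialisation is seeded. Argmax ties
resolve to the lowest class index, which favours `meat` (index 0), a
deliberate background-leaning tie-break.

The network, backward pass, and optimizer are plain NumPy. The model is
small enough that batched BLAS matmuls train it on one CPU core in minutes;
gradients are verified against finite differences in the test suite.

## Loss and training recipe

The per-pixel loss is label-smoothed cross-entropy scaled by a penalty
factor:

    L = W[t, ŷ] · ( −Σ_c q_c log softmax(z)_c ),
    q_c = (1 − ε)[c = t] + ε/K,   ŷ = argmax z

with ε = 0.3 and K = 13. `W` is a 13×13 matrix over (true, predicted)
classes: misclassifying meat or fat *as a contaminant* costs `w_high`
(default 2.0); belt-as-contaminant costs `w_low` (default 0.5); all other
entries are 1. The penalty structure is principled (false alarms on product
are the dominant operational cost; belt-only alarms are cheap); the numeric
defaults are this package's choice and are config-exposed. The factor is
gated by the hard argmax and carries no gradient; the expected-cost variant
Σ_c W[t,c]·p_c·CE was deliberately not implemented, to keep a single
well-tested path. Pixels labelled 255 (unannotated) stay in the input for
spatial context but are excluded from the loss.

Optimisation is AdamW (β = 0.9/0.999, weight decay 2e−4 applied to weight
matrices only) at peak learning rate 1e−3 under a linear warm-up followed by
polynomial decay `(1 − s/S)^p` with power 1.0 (the exponent was an open
choice). The reference recipe is 24 epochs at batch 520; the synthetic
recovery experiment uses a reduced recipe (below). Training is seeded and
deterministic on a given machine; there is no augmentation and no early
stopping. With a validation split, the parameters with the best validation
mIoU are returned; otherwise the final ones.

## Tiling

Training tiles are cut with 50% overlap (stride 10×8); inference uses
disjoint tiles. The right/bottom remainder is covered by shifting the final
tile origin onto the border — no padding, because padded spectra would be
fabricated data. Overlapping predictions are merged by averaging logits
before the argmax (majority vote is available).

## Post-processing

Two stages, in order, both unable to *create* contaminant pixels:

1. **Spectral rules.** Three pixel-wise conditions re-examine pixels
   predicted as the two spectrally fat/meat-like classes, with `I(w)` the
   normalized intensity at the band nearest `w` nm: PEHD with a fat-like
   1222 nm rise (`I(1225.5) − I(1211.5) > I(1026) − I(1012)`) and *without*
   the sharp PEHD step above 1407 nm (`I(1411)/I(1407.5) < 1.04`) becomes
   fat; PEHD with a belt-like rise (`I(1117) > I(1099.5)`) becomes conveyor
   belt; PA-PP lacking its sharp 1225 nm peak
   (`I(1225.5) − I(1215) < I(1232.5) − I(1012)`) becomes meat. The third
   rule's pairing of 1232.5 nm against 1012 nm is asymmetric but
   intentional and implemented verbatim. Rules evaluate on the original
   prediction (no chaining); rule 1 outranks rule 2 when both fire; a
   near-zero ratio denominator counts as "no step", i.e. the clause is
   false. Rules default to normalized intensities — the representation the
   model saw — with corrected-unnormalized evaluation available for
   ablation.
2. **Erosion.** Each contaminant class's binary mask is eroded with the full
   3×3 structuring element. Blobs (8-connected; 4-connectivity would shatter
   the 1–2 px ribbons) lacking a 3×3 core vanish entirely; border pixels of
   surviving blobs are also removed. All removed pixels are relabelled with
   the fallback class (fat). Erosion is per class, not on the union mask, so
   adjacent blobs of different classes cannot prop each other up. The image
   border counts as background, so a 3×3 blob flush against the edge is
   removed — accepted as conservative. Background predictions are never
   modified by either stage.

## Evaluation

Blobs are 8-connected components. On contaminated images, a ground-truth
blob counts as *detected* when at least one predicted contaminant pixel of
any contaminant class overlaps it — the operational goal is flagging, not
per-class identification. On clean images every predicted contaminant pixel
is a false positive and one such pixel makes a false-positive image.
Segmentation quality is mIoU over classes present in the ground truth,
excluding unannotated pixels. Four arms are compared: raw model, erosion
only, rules only, rules + erosion. Throughput (images/s) is logged but is
hardware-dependent and never a target.

## Synthetic data

The generator renders what the pipeline assumes, so every stage is testable
without external data:

* **Spectra.** Each of the 13 classes is a baseline plus 2–4 Gaussian or
  sigmoid features on the 224-band grid, with per-pixel feature-amplitude
  jitter (σ = 0.08 relative), a per-pixel brightness jitter (σ = 0.02,
  cancelled by normalization), and additive read noise (σ = 6 counts).
  Curves are parametric inventions; only their structure is modelled: the
  classes are mutually separable (minimum pairwise spectral angle > 3× the
  mean intra-class angle), PEHD is deliberately the most fat-like class, its
  distinguishing handles being the 1222 nm rise and the sharp step near
  1409 nm that the first spectral rule tests.
* **Hard fat mode.** `pehd_hard` pixels are ground-truth fat whose spectra
  carry the 1222 nm bump (mean amplitude 1.1× PEHD's, sd 0.25) but no
  1409 nm step. The mean hard curve remains closer to fat than any other
  class pair, yet per-pixel jitter pushes a controllable fraction across a
  spectrum-only decision boundary toward PEHD — the designed fixture for
  rule 1 and for the false-positive experiment. Clean evaluation scenes are
  salted with small (≤2×2) hard speckles; training scenes contain none, so
  the model meets them unseen.
* **Scenes.** Belt background, an elliptical belly with a wavy meat/fat
  split (either side up), contaminants as rectangles, ellipses, or
  meandering ribbons whose every crossed scan line holds ≥2 pixels
  (mirroring the sensor's minimum object size), smooth multiplicative
  shadows, per-column lognormal stripe gains (log-sd 0.05), a dark offset,
  and affine temperature/exposure gain (T ∈ [10, 55] °C). The matching
  dark/flat pair is generated at the same temperature, so flat-field
  correction inverts the forward model exactly up to read noise — asserted
  to 1e−6 relative in the noise-free configuration.

Not modelled: radiometric realism (halogen spectrum, absolute flux), optical
point-spread/diffraction at blob borders (synthetic boundary pixels are
spectrally pure, unlike real mixed pixels), annotation noise, and real
intra-class covariance structure. Passing tests therefore demonstrate the
pipeline's mechanics and its false-positive logic under the stated
assumptions, not field performance on real produce.

## The recovery experiment and problem sizes

`run_synthetic_recovery` renders 200 training scenes of 128×160 px, takes 4
tiles per scene (up to 3 containing contaminant pixels — contaminants cover
only a few percent of a scene, and oversampling keeps the positive classes
visible in the loss — plus one background tile), and trains the full
4-block model with the recipe above reduced to 3 epochs (1 warm-up) at
batch 16. Smaller batches trade BLAS efficiency for more optimizer steps per
tile pass, which converges faster in wall-clock on one core. It then
measures: mIoU aggregated over 6 held-out contaminated scenes; false
positives per arm on 50 clean scenes each salted with 6 hard speckles; and
retention of ground-truth blobs that own a 3×3 core after rules + erosion.
These sizes are the package's desk-scale defaults; every count is
configurable in `RecoveryConfig`.

## Numerical choices

* Processing states (`raw224 → corrected224 → trimmed184 → normalized184`)
  are explicit and enforced; stages cannot be skipped or repeated.
* Wavelength lookup takes the nearest grid band, lower index on ties, and
  rejects queries outside the grid ± half a band spacing.
* LayerNorm ε = 1e−6; GELU is the exact erf form; softmax is computed
  max-shifted.
* ENVI I/O supports BIL/BIP/BSQ interleaves and data types 4 (float32) and
  12 (uint16), round-tripping bit-exactly; wavelengths are written at full
  repr precision. Label masks are palettised PNGs with 255 = unannotated.
* Degenerate inputs raise early with specific messages (empty calibration
  library, non-positive flat−dark, uncovered pixels when stitching,
  all-unannotated training sets).

## Known limitations

* The rule thresholds and wavelengths are fixed constants; on real data they
  would need re-validation per sensor unit.
* The cost-matrix values (2.0/0.5) and the polynomial power (1.0) are
  package defaults, not measured quantities.
* mIoU on synthetic scenes overstates real-world accuracy because boundary
  pixels are spectrally pure.
* Erosion removes genuine contaminants thinner than 3×3 by design; the
  blob-level retention metric counts only blobs that own a 3×3 core.
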