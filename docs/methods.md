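# Methods

## Problem and pipeline

`fingervein` implements verification of identity from near-infrared (NIR)
finger images. Deoxyhemoglobin absorbs NIR light, so subcutaneous veins
appear as dark curvilinear structures inside the brighter finger silhouette.
The recognition pipeline is:

1. **Finger-region detection.** The horizontal extent of the finger is fixed
   per capture device (`X_L`, `X_R`: 180–480 for the good-quality setup,
   220–470 for the mid-quality one at 640×480, 20–268 for the open setup at
   320×240) because the device hole constrains finger placement. The upper
   and lower finger boundaries are found per column as the argmax of a 4×20
   edge-mask response: row weights (−1,−1,+1,+1) top-to-bottom for the upper
   boundary (dark background → bright finger) and the negation for the lower
   boundary, each weight spanning the 20-column window, with replicate
   padding at the image border. The mask coefficients are a difference-of-
   row-means edge detector; only the mask geometry, not its coefficients, is
   standard, so ±1 weights were fixed here once for determinism. The upper
   search is restricted to rows [2, H/2), the lower to [H/2, H−2), which
   guarantees non-crossing curves for centered fingers; both ranges are
   overridable. Ties in the argmax take the smallest row. Each boundary
   curve is median-filtered over 5 columns to suppress single-column
   outliers.
2. **Normalization.** The region between the boundary curves is linearly
   stretched to 150×60: output column j samples source column
   `X_L + j(X_R−X_L)/150`, output row i samples the point i/60 of the way
   from the (linearly interpolated) upper boundary to the lower one, with
   bilinear intensity interpolation. A 3×3 block average then yields the
   50×20 working image. Intensities stay real-valued from here on — no
   re-quantization — so later stages keep full contrast.
3. **Gabor enhancement.** Four even-symmetric (cosine-phase) Gabor channels
   at orientations θ_k = kπ/4, k = 1..4 (180° ≡ 0° for an even filter),
   f = 0.2 cycles/px, σ_x = σ_y = 2.38 px, sampled on an 11×11 grid
   (≈ ±2.3σ, >95 % of the envelope). Kernels are made zero-mean so flat
   regions give zero response; each channel output is input + response,
   clipped to [0,255], and the four channels are combined by per-pixel
   minimum — a vein is darker than tissue, so the best-matching orientation
   wins. The raw filter response is a signed band-pass signal; the add-back
   formulation is what makes a minimum over channels well-defined on the
   original gray scale. Convolution uses replicate padding to avoid dark
   frame artifacts that would read as veins.
4. **LBP coding.** Every interior pixel of the 50×20 image yields an 8-bit
   local binary pattern over its 8-connected neighbors (clockwise from
   top-left; bit = 1 when neighbor − center ≥ 0, ties inclusive), giving
   18 × 48 × 8 = 6912 bits. The neighbor order is a free convention: any
   fixed order yields identical Hamming distances; it matters only for code
   file interoperability. The original (non-uniform) LBP is used throughout;
   uniform LBP collapses distinct patterns and is deliberately absent.
5. **Matching.** Normalized Hamming distance, popcount(a⊕b)/6912. Identical
   codes score 0; unrelated codes concentrate near 0.5.

## Enrollment and fusion

Multi-image enrollment registers each later image to the first by
exhaustive integer-shift template matching (normalized cross-correlation
over the overlap, window ±5 px; NCC is robust to the global brightness
changes that a Hamming-based search would over-penalize), applies the
negated measured shift with replicate fill, averages per pixel, and codes
the enhanced average. Averaging happens on the sub-sampled images *before*
enhancement; enhancing first would let the min-combination interact with
residual misalignment nonlinearly. Tie-breaks in the shift search follow
(smallest |dx|+|dy|, then dy, then dx) so flat or symmetric inputs resolve
deterministically to (0,0). The representative-selection baseline codes all
enrollment images and keeps the one with the smallest summed Hamming
distance to the rest (earliest index on ties).

Score fusion combines N per-comparison distances by the SUM rule (Σd_i,
range [0,N], left unnormalized — thresholds are swept per rule so scale is
immaterial) or the PRODUCT rule (Πd_i). PRODUCT-fused authentic scores are
strongly right-skewed; the evaluation runner screens them with a
D'Agostino–Pearson normality test (α = 0.01) and emits
`UnreliableDPrimeWarning` when d-prime should not be read as an accuracy
proxy. This is a warning, not an assertion: the skew is expected behavior.

## Evaluation

Authentic/imposter comparisons are enumerated under four class definitions:
per physical finger (person × hand × finger type), per person, per hand
(2 classes), per finger type (3 classes). For a balanced database (M
classes × N images) the counts are A = C(N,2)·M and I = N²·C(M,2); each
unordered cross-class pair is counted once, which reproduces every
published count for the 1200/1980/3816-image layouts. The exhaustive
multi-enrollment design counts are A = C(N,E)·(N−E)·M and
I = C(N,E)·N·(M−1)·M (100,800 / 17,136,000 at E = 3; 151,200 / 35,985,600
at E = 5 for M = 120, N = 10).

FAR(t) = %{imposter < t}, FRR(t) = %{authentic ≥ t} over an evenly spaced
10,001-point grid spanning the observed score range (the ≥ boundary
convention is fixed arbitrarily; nothing downstream depends on it). The EER
is (FAR+FRR)/2 at the grid point minimizing |FAR−FRR|, refined by linear
interpolation when the curves cross strictly between grid points. Note that
for heavily interleaved score sets the two curves can be *equal* over an
interval, in which case the EER is read directly there (no convex-hull
interpolation of the ROC is attempted). d-prime is
(μ_I − μ_A)/√((σ_A²+σ_I²)/2) with population standard deviations — at the
pair counts involved the sample/population distinction is far below
reporting precision, but a convention must be fixed. Degenerate inputs:
equal-mean zero-variance pairs give 0; distinct-mean zero-variance pairs
give ±∞ with a warning.

## Synthetic data generator

The generator emulates the structure the pipeline assumes rather than the
optics of tissue: a bright finger band (default 160 gray) on a dark
background (40), boundaries gently curved by a zero-mean quadratic wobble
(±2 % of image height), 5–9 veins per finger drawn as cubic tracks inside
the band (widths 6–14 px at 640×480, contrast ≈ 60 gray with ±30 %
per-vein variation, Gaussian cross-profile), soft 1.5 px band edges,
additive pixel noise (σ = 3 gray), and per-trial whole-finger translation
jitter. One vein pattern per physical finger; all randomness flows from a
single seed through per-pattern and per-trial `SeedSequence` streams, so
any image is reproducible in isolation.

Two modelling choices matter for what the experiments can show:

* **Fingers of one person are independent.** Real data shows two fingers of
  one person to be nearly as dissimilar as fingers of strangers; the
  generator encodes that directly, which is why the per-person class
  definition lands near (but below) chance-level EER purely through the
  fraction of same-finger pairs inside each class.
* **One vein per finger follows a per-finger-type archetype** (perturbed
  with σ = 0.09 of band thickness per finger). Index fingers resemble other
  index fingers slightly more than they resemble ring fingers, as real
  finger-type geometry does. Without this, the finger-type and hand class
  definitions differ only through class-size bookkeeping — a ≈0.4 % EER gap
  at the 10-person scale, smaller than pattern-sampling noise — and their
  ranking would be a coin flip rather than a property of the data. With it,
  the full ranking (per-finger < per-person < per-finger-type < per-hand)
  is a stable consequence of the generated structure. Hands carry no
  systematic signal at all, matching their near-chance separability.

Quality presets mirror the three capture setups: `good` (guiding-bar
device, jitter σ = 2 px, 640×480), `mid` (no guiding bar, σ = 10 px),
`open` (σ = 12 px at 320×240 plus reduced vein contrast 40 and thinner
veins). Jitter magnitudes are set at the raw-image scale where finger
placement actually varies; the normalization stage cancels vertical shifts
almost completely and compresses horizontal ones by the crop-to-working
ratio (≈6×), so only a raw horizontal scatter of several pixels survives
as the ±1–3 px working-image misalignment that drives matching errors.
Single-pixel raw jitter would be invisible after preprocessing and could
not reproduce a quality gap.

What passing synthetic tests does **not** show: robustness to rotation,
scale, perspective, illumination gradients, skin texture, image blur or
segmentation failures — none of these are generated. Results on synthetic
data validate the pipeline's mechanics and relative orderings, not absolute
error rates on real fingers.

## Experiment scaling

End-to-end experiments run on 10-person databases (600 images per preset)
with a fixed pipeline configuration. The enrollment experiment uses 5
rotated consecutive-trial enrollment subsets per class instead of all
C(10,E) subsets, and single probe/enrollment splits are used for fusion;
closed-form count checks cover the exhaustive designs separately. EER
resolution at these sizes is limited by authentic-pair counts (e.g. 1/2100
at E = 3), which is ample for the monotone-trend comparisons made.

## Known limitations

* Translation-only alignment; rotation or scale misalignment between
  enrollment images is not compensated.
* Fixed `X_L`/`X_R` crop bounds assume a device-constrained finger; no
  automatic horizontal segmentation is attempted.
* The boundary-mask coefficients, kernel size, border policy and signed-
  response mapping are package conventions chosen for determinism where the
  published method leaves them open; codes produced under different
  conventions are not interchangeable.
* At near-chance separations (per-person, per-finger-type and per-hand
  classes) the EER estimate inherits class- and pattern-level sampling
  noise of up to one or two percent at the 10-person scale, and the
  3-to-5-image enrollment gain is a fraction of a percent (integer-only
  shift compensation leaves sub-pixel blur that grows with the number of
  averaged images). The trend comparisons in the test suite are therefore
  made under a fixed generator seed as part of the study conditions;
  individual generator seeds can reorder the two smallest gaps. Larger
  databases tighten all of these estimates.
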