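# Methods

## Model

The package segments microaneurysms (MAs) in single-channel FFA frames in
three stages. All intermediate arithmetic is float64; 8-bit quantization
happens only on file output. Borders are edge-replicated in every
neighborhood operation (morphology and convolution) so the frame edge does
not generate spurious bright rims that would become false MA candidates.

### 1. Preprocessing

* **White top-hat**, `I − (I ∘ B)` with a flat disk `B` of radius 45 px
  (membership rule `u² + v² ≤ r²`). Grayscale opening is erosion
  (neighborhood minimum) followed by dilation (neighborhood maximum).
  A printed source formula for dilation uses a minimum; that definition
  would make opening ill-defined (it is the standard max), so dilation is
  implemented as the neighborhood maximum. The disk is far larger than any
  MA (≤ ~12 px across), so lesions pass through the top-hat unchanged while
  smooth illumination is removed.
* **Gray stretch** to `[G_min, G_max] = [0, 255]` (configurable). The input
  extremes map exactly onto the output bounds; a constant frame has no
  dynamic range and maps to all-`G_min` with a warning instead of raising,
  so batch runs survive blank frames.
* **Gaussian smoothing**, σ = 1 px by default, kernel truncated at
  ⌈3σ⌉ and renormalized to sum exactly 1 (constants are preserved exactly).
  σ = 1 is small enough to keep 3-px lesions detectable.

### 2. Coarse segmentation

* **Matched filter.** Gaussian-cross-section template
  `f(x, y) = (2πs²)^{-1/2} e^{−x²/2s²} − m` on the support
  `|x| ≤ t·s`, `|y| ≤ L/2`, with `t = 3`. Defaults: scale `s = 1.5` px
  (kernel FWHM ≈ 3.5 px, matched to capillaries and to MA diameters of
  3–12 px after preprocessing) and `L = max(5, round(4s))` — short
  templates at fine scales. The discrete support is `|x'| ≤ ⌈t·s⌉`,
  `|y'| ≤ ⌈L/2⌉` evaluated in the rotated frame directly on the integer
  grid (no resampling, hence no interpolation error), and the zero-mean
  offset `m` is the arithmetic mean of the profile over exactly that
  support, which makes every kernel sum to zero to machine precision. The
  analytic value of `m` (integral of the profile over its support divided
  by the support length) is retained as a numerical cross-check only.
* **Orientation bank.** 12 kernels at 15° steps over [0°, 180°); the
  response is the pixelwise maximum of the cross-correlations. A round dot
  responds at every orientation, a vessel mainly at its own. Both vessels
  and MAs are hyperfluorescent in FFA, so no polarity inversion is applied.
  A list of scales is accepted (pixelwise max across scales) but the default
  is single-scale: with a global threshold downstream, wide-scale vessel
  responses dominate the rescaled range and suppress the dot responses.
* **GA threshold.** The response is min-max rescaled to [0, 255] and rounded
  to integers, tying the 8-bit chromosome range to the data range and making
  the histogram-based fitness evaluation exact. Fitness of threshold T is
  `p₁·p₂·(µ₁−µ₂)²` with counts and means of the classes `>T` / `≤T`
  (an empty class scores 0). GA settings: chromosome length 8, population
  10, elitism (1 elite), roulette-wheel selection (uniform fallback when all
  fitnesses are 0), single-point crossover, per-bit mutation; probabilities
  0.7/0.4 for the first half of the run and 0.3/0.3 afterwards; 50
  generations with the late stage starting at generation 25 (the stage
  boundary is not prescribed anywhere; half-way is the natural reading of
  "later stages" and is configurable). The best threshold ever seen is
  returned; ties break toward the smaller threshold. A single seeded
  generator drives the GA, and the seed is recorded in the run record.
  Since the space is only 256 thresholds and the GA evaluates ~500
  candidates, it recovers the exhaustive optimum essentially always; the
  exhaustive search is also exposed (`exhaustive_best`) and used as the test
  oracle, never as the pipeline path.

### 3. Fine segmentation

Connected components (8-connected by default; diagonally touching lesion
pixels are one lesion) are filtered by area first (cheap), then shape:

* **Area rule:** keep `5 ≤ S ≤ 100` px, bounds inclusive.
* **Roundness rule:** keep `4πS/C² ≥ 0.51`, bound inclusive.

`C` is the length of the component's outer contour, measured by
Moore-neighbor boundary tracing of the hole-filled component with Jacob's
stopping criterion, summing axial steps as 1 and diagonal steps as √2. This
estimator is pinned by a release gate in the tests: a centered digital disk
of radius 10 scores roundness in [0.85, 1.15], every disk of radius ≥ 8
scores above 0.51, and a 1×20 line scores far below it. `S` counts only
foreground pixels; holes inflate neither `S` nor `C`. Single-pixel
components have no traceable contour and are treated as non-round
(roundness 0) — the area rule removes them first regardless. Border-touching
components are retained, measured with their visible boundary, and flagged
in the region record.

### Evaluation

Pixel-level confusion counts give Acc, Se, Sp, PPV and IOU. Zero
denominators (e.g. a reference frame with no MA pixels) yield an undefined
marker that is excluded from batch aggregation with a warning — undefined
is not the same as 0 and silently coercing it would inflate means. Batch
summaries report per-image mean ± sample (n−1) standard deviation.
`lesion_recall` additionally counts a reference lesion as detected when at
least one predicted pixel falls inside its truth component.

## Phantom generator

The phantom emulates exactly the structures the model assumes: a smooth
quadratic illumination field (amplitude 20 gray levels on a base of 70),
random-walk vessel centerlines with bounded curvature and Gaussian
cross-section (FWHM 3–12 px, contrast 80), Gaussian MA dots (half-maximum
radius 1.5–6 px so truth areas span ~7–113 px — some lesions deliberately
violate the 100-px area cut), and additive zero-mean Gaussian noise
(σ = 5 by default; a frame is 384×384 px with 4 vessels and 20 MAs). Half
of the MAs are placed within 15 px of a vessel centerline, the rest
scattered; lesions never overlap each other or a vessel (clearance = lesion
radius + maximal vessel half-width + 2 px), because an MA fused to a vessel
in the mask would be removed with it and no unambiguous per-lesion truth
would exist. Placements that fail after 300 rejection-sampling attempts
reduce the lesion count and are recorded.

Truth masks are geometric, not renders: a pixel belongs to a lesion iff it
lies within the lesion's half-maximum radius, and vessel truth uses the
same half-maximum rule, with MA pixels carved out so the two masks are
disjoint. The half-maximum convention matters: reported IOU values depend
on it, since the soft Gaussian fringe outside the half-max contour is
scored as background.

The suite generator varies MA contrast (ranges centered on 30/55/80 gray
levels) against noise (σ = 2/5/8) on a 3×3 grid, each cell with a distinct
seed derived from the base seed.

What the phantom does **not** emulate: dye-leakage haloes, the optic disc
and macula, vessel branching/crossing complexity of a real fundus, motion
blur, or grader disagreement. Passing the phantom suite demonstrates the
mechanics of the pipeline — enhancement, candidate capture, shape
discrimination, metric bookkeeping — not clinical-grade accuracy on patient
data.

## Numerical and design choices

* **Dilation via maximum** (see above); the printed min-form is treated as a
  typo, not silently absorbed — it is documented here.
* **Coarse coverage of wide vessels is partial by design.** A global
  between-class threshold cuts a structure at roughly half of its *response*
  peak; for a vessel much wider than the filter scale this lies inside the
  half-maximum footprint, so only the vessel core enters the coarse mask
  (~70% coverage for 8–12-px vessels, ≥99% for capillary-scale 3–4-px
  vessels). This costs nothing downstream: vessels are removed by the fine
  stage regardless, and MA dots are matched to the kernel scale.
* **Strict `>` for the target class**, `≥`/`≤` inclusive bounds for the
  area and roundness rules; these boundary conventions are asserted in the
  tests.
* **Determinism.** Phantom and GA own a single seeded generator each; a
  fixed seed + config reproduces every mask, CSV and intermediate image
  byte-for-byte. The run-record JSON is the one exception, because it
  embeds wall-clock timings.
* **Problem sizes in the test suite.** Oracle comparisons (brute-force
  neighborhood min/max, direct convolution, flood fill) run on images up to
  32×32–256×256; the end-to-end suite uses nine 384×384 frames with 20
  lesions each. These sizes exercise every code path while keeping the suite
  fast to run routinely.

## Known limitations

* The area band 5–100 px presumes a pixel pitch similar to typical FFA
  exports (768×868 frames); images at other magnifications need rescaled
  bounds (`morph.area_min/area_max` in the config).
* A real MA overlapping a vessel merges with it in the coarse mask and is
  removed with the vessel — an inherent limitation of the component-wise
  shape filter, shared by the modeled approach.
* Sensitivity degrades quickly once MA contrast approaches the noise floor
  (visible in the low-contrast cells of the suite); the method has no
  mechanism to trade PPV for Se, since the threshold is chosen by a global
  variance criterion rather than a tunable operating point.
* Lesions with truth area > 100 px are removed by the area rule even when
  perfectly segmented; the phantom intentionally renders a few such lesions
  to exercise that branch.
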