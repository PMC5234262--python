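# Methods

## Model and assumptions

The segmentation model assumes a single wound region that is (a) darker
than the surrounding skin in grayscale amplitude and (b) large relative to
noise structure — the operating characteristics of stage-IV pressure ulcers
photographed after debridement.  Everything up to contour fusion is a
per-pixel (neighbourhood-free) transform chain:

1. **Amplitude.**  CIE 1931 luminance of the RGB image, kept real-valued;
   quantizing back to 8 bits would discard contrast the later stages
   amplify.  Stored amplitudes `A ∈ [0, 255]` are shifted to
   `Ã = A + 1 ∈ [1, 256]` (config `amplitude_offset`, default 1): the
   frequency map divides by `Ã^r`, and the shift removes the singularity at
   black pixels while pinning `f(Ã=1) = 1` for every `r`.

2. **Synthetic frequency.**  `f = Ã^{-r}` is strictly decreasing in both
   `Ã` (for fixed `r > 0`) and `r` (for `Ã > 1`), with range (0, 1].
   Sweeping `r` linearly over `[r_min, r_max]` (defaults 0.013–0.015,
   30 levels) produces the contrast stack.  Linear spacing is the minimal
   assumption; an explicit `r_values` list can override it.

3. **Toroidal decomposition.**  `THD` and `TVD` evaluate the torus'
   planar components per pixel with the pixel's own frequency.  The
   per-pixel reading (rather than one scalar `f` per level) is the only one
   under which image contrast modulates the decomposition at all.  The
   coordinate grids are symmetric linear ramps spanning
   `±(n−1)/n` along each axis — the minimal construction consistent with a
   symmetric normalized pixel domain; it is isolated in `make_grids` so an
   alternative mapping is a one-function swap.  With `R = 100` (px,
   default) the additive operator is dominated by
   `R·(cos + sin)(2π·arctan f)`; the carrier crosses zero inside the
   working frequency band, which is the contrast-amplification mechanism.
   The operators use the same shifted `Ã` as the frequency map, keeping the
   two stages consistent.

4. **Otsu thresholding.**  Self-contained optimizer over 256 equal-width
   bins on the normalized [0, 1] operators, maximizing the between-class
   variance `J(t) = ω₀(μ₀−μ_T)² + ω₁(μ₁−μ_T)²` over thresholds with both
   classes nonempty; ties break at the smallest `t` for determinism.  The
   returned class statistics satisfy `ω₀+ω₁ = 1` and `ω₀μ₀+ω₁μ₁ = μ_T` to
   1e-9 by construction.  The threshold is optimized on the `T̄_p`
   histogram and applied to `T̄_a` (config `threshold_target`, default
   `ta`; `tp` applies it to `T̄_p` itself — in practice `tp` produces
   near-empty partitions on wound-like images and exists to make both
   readings testable).  A pixel belongs to Ω₁ when its bin index is below
   `t`, i.e. its value is below `t_value = t/256`.

5. **Contours and fusion.**  Per level, the inner boundary of Ω₁ (pixels
   4-adjacent to Ω₂; outside the frame counts as Ω₂).  The edge map is the
   per-pixel count of level contours.

6. **Morphological refinement.**  Edge support → disk closing
   (`morph_radius`, default 5 px) → hole filling → removal of components
   below `min_component_area` (default 0.5% of image area) → selection of
   the component with the lowest mean amplitude (`component_selection:
   darkest`; `largest` available).  Darkness is the direct
   operationalization of "the wound is the darkest region"; area is the
   fallback when that assumption is known to fail.

## Robustness of the fusion stage

An important empirical property of the chain: `T̄_a` is nearly independent
of `r` across the narrow default sweep, while the Otsu threshold derived
from `T̄_p` varies strongly with `r`.  The sweep therefore effectively
multi-thresholds one fixed `T̄_a` image at 30 data-driven cut points.  On
clean images every cut lands in the wide empty gap between the lesion and
background distributions and all levels agree; under pixel noise a minority
of levels place the cut inside the background distribution, producing huge
spurious Ω₁ regions whose contours flood the edge map and weld everything
into one component.  Three configurable defaults make fusion robust to
this:

- **Level consensus** (`level_consensus_ratio`, default 3): levels whose
  Ω₁ area falls outside `[median/3, 3·median]` of the sweep's median area
  are excluded from fusion.  The median over 30 levels is a robust estimate
  of the lesion's area; a gross outlier means the threshold missed the gap.
  `None` fuses every level.
- **Edge-support floor** (`min_edge_support_frac`, default 0.1): a pixel
  counts as edge support only if at least 10% of the fused levels put a
  contour through it.  Setting 0 recovers the any-single-level rule.
- **Despeckle** (`min_contour_component`, default 32 px): connected support
  fragments smaller than this — isolated noise-pixel rings — are discarded
  before closing.

These defaults were calibrated on phantom suites only (several independent
suite seeds give mean correlations of 0.94–0.97; with literal
any-single-level fusion of all levels the same suites average ≈ 0.44).

## Degenerate and pathological inputs

- A level whose operator is identically zero, or whose `T̄_p` histogram has
  a single occupied bin, is skipped with a log record rather than aborting
  the sweep.
- An image with **zero amplitude range** raises the all-levels-degenerate
  error before the sweep: a constant image yields a constant frequency
  field, so the decomposition would respond only to the coordinate grids
  and never to the image — thresholding it would segment pure grid
  artifact.  A *nearly* constant image (std below `saturation_std_floor`,
  default 1 gray level — the signature of channel saturation) emits a
  warning and proceeds, since partial saturation sometimes still leaves
  usable contrast.
- An empty final mask is a legal outcome, flagged on the result, never an
  exception.
- Images longer than `max_side` (default 1024 px) on their longest side are
  downscaled with anti-aliased interpolation after grayscale conversion;
  the target is a choice (source photographs vary from 1280×960 to
  5184×3456 and no canonical size exists).

## Evaluation

Digital image correlation is the plain Pearson product-moment correlation
over all pixels, computed on {0, 1} masks at the processing resolution
(ground truth resized nearest-neighbour when resolutions differ; a
grayscale comparison is a caller choice since the function accepts any
arrays).  It is undefined for constant inputs; batch summaries count such
failures separately and exclude them from the moments.  The batch standard
deviation is the sample (n−1) convention by default with `ddof=0`
switchable to the population convention.

## Phantoms

The generator emulates exactly the image features the method responds to:
a dark reddish elliptical lesion (default RGB (120, 30, 25)) on a skin-tone
background (default (210, 170, 150)) with a ±10% horizontal illumination
gradient (clinical photographs are never flat-lit), optional Gaussian blur
of the lesion alpha (blurred edges indicate growing tissue), additive
i.i.d. Gaussian channel noise, and bright distractor disks (gauze white,
marker blue).  Ground truth is the pre-blur ellipse raster, fixed before
degradation.  The standard suite draws semi-axes 15–60 px, orientation
uniform, blur cycling {0, 2, 4, 8} px, noise uniform 0–10 gray levels and
0–2 distractors, all from one seed.

What phantoms do **not** emulate: skin texture, specular highlights,
necrotic/granulation tissue heterogeneity inside the wound, rulers and
probes touching the wound, shadows.  Passing phantom tests therefore
demonstrates correctness of the transform chain and robustness to blur,
noise, lighting gradient and isolated distractors — not clinical-grade
performance on real photographs.

## Numerical choices

- All transforms in float64; normalization divides by the max magnitude, so
  `T̄` attains exactly 1.0 on every non-degenerate level.
- Histogramming uses `[0, 1]` equal-width bins, last bin right-closed; bin
  assignment by `floor(v·L)` clipped to `L−1`.
- Otsu tie-break: smallest maximizing threshold (first arg-max).
- The problem sizes used by the test suite and the acceptance script —
  256×256 phantoms, 30 levels, suites of 20 — match the standard protocol's
  level count at a phantom resolution chosen to keep per-image work well
  under a second while leaving lesions of 15–60 px semi-axes comfortably
  resolvable.

## Known limitations

- Multiple wounds: exactly one component is returned; a second wound is
  discarded by the selection rule.
- A wound touching the image border survives contour extraction (outside
  counts as background) but hole filling cannot recover interiors that
  drain across the border.
- Very dark non-wound objects (shadows, dark clothing) defeat the
  darkest-component selection; the `largest` selection mode is the manual
  fallback.
- The method has no notion of scale beyond `min_component_area`; a lesion
  smaller than 0.5% of the image area is filtered out unless the floor is
  lowered.
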