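# Methods

`ulcerseg` implements a fully automated, training-free pipeline that localizes
fluorescein-stained corneal ulcers in cobalt-blue slit-lamp photographs, plus
the synthetic scene generator used to validate it and the pixel-level metrics
used to score it. This note records the model, the parameters that matter,
the numerical choices, and the limits of what the synthetic validation shows.

## Imaging model and signal assumptions

Under cobalt-blue illumination with instilled fluorescein:

* epithelial defects (ulcers) and lid-margin tear menisci fluoresce bright
  green — the green channel carries the segmentation signal;
* the sclera and surrounding skin render in blues/violets;
* the tear film produces compact, saturated specular highlights, brightest of
  all in every channel — the blue channel squared separates them well.

All images are handled as float RGB in [0, 1] (8-bit inputs divided by 255),
row-major with 0-based (row, col) pixel coordinates. Inputs smaller than
64×64 are rejected.

## Pipeline

1. **Specular-reflection mask.** Square the blue channel, binarize (Otsu by
   default), close with a disk (radius 5 px), and take the complement. The
   complement is multiplied into everything downstream so highlights can never
   be mistaken for fluorescein. *Caveat:* with the per-image Otsu threshold
   this step is not idempotent — once the saturated class is removed, Otsu
   re-splits the remaining intensities. The fixed-threshold mode
   (`preprocess.threshold_method: fixed`) is exactly idempotent.
2. **Green-channel conditioning.** Gaussian smoothing (σ = 2 px — enough to
   suppress sensor noise without erasing point lesions), reflection masking,
   squaring, binarization. Squaring before thresholding stretches bright
   fluorescein away from the dimmer sclera and moves the Otsu split point
   into the valley between them.
3. **Ellipse pre-mask.** Centroid and 2·std semi-axes of the binarized
   foreground, axis-aligned (eyes are near-horizontal in this protocol),
   inflated by 1.15 so the pre-mask never clips the true border. Applied after
   a closing that repairs gaps punched into the meniscus line by reflection
   masking.
4. **Thinning** to a 1-px, 8-connected skeleton. What survives is essentially
   the centerline of the lid-margin meniscus — a noisy tracing of the
   palpebral aperture border — plus skeletal fragments of lesions.
5. **Eye-border recognition.** The border template is the Gielis Superformula
   curve r(φ) = [|cos(mφ/4)/a|^{n2} + |sin(mφ/4)/b|^{n3}]^{−1/n1} with
   a = b = n1 = n2 = n3 = 1 and m = 2, which traces the lens-like aperture
   outline. The dimensionless curve (extents 1 × 1/√2) is scaled per axis in
   pixels; anisotropy lives entirely in the (semi-major, semi-minor) pixel
   scales, never in a/b. A generalized Hough transform searches center ×
   per-axis scale × small rotation (±10° default; one rotation step reproduces
   a rotation-free search). Voting is dual-template (edge pixels vote for
   centers), with a ±1 px tolerance band implemented by dilating the edge
   image 3×3. Accumulator bins are 2 px; the winning bin is refined at 1 px,
   where the score of a center is the count of template offsets landing on a
   dilated edge pixel, so `vote_fraction = votes / |template|` ∈ [0, 1].
   Fits below `min_vote_fraction` = 0.15 are rejected as unrecognized —
   below that level fixture studies cannot distinguish a fit from noise.
   Ties break deterministically: coarse bins by lowest row, col, then
   smallest scale cell; the refinement prefers the exact (undilated) match
   count first, which makes render→refit an exact fixed point.
6. **Cornea disk.** Centered on the recognized border with diameter equal to
   the semi-minor axis (radius = semi_minor/2). The rule is implemented
   literally; because it is geometrically ambiguous,
   `cornea.radius_mode: semi_minor` switches to the full semi-minor radius.
7. **Candidate extraction and eyelid rejection.** Candidates are the
   square-binarized smoothed green intensities, thresholded over the support
   of the *filled fitted border* (threshold estimated from support pixels
   only, so the dark surround cannot bias it). Extracting over the full
   aperture rather than the cornea disk is deliberate: lid-margin stains must
   stay connected to the border for the contact test. Each 8-connected
   segment is kept unless it both touches the rendered border (dilated 2 px
   to absorb rasterization gaps) and has moment-ellipse axis ratio
   (semi-major / max(semi-minor, 0.5 px)) above `extract.ratio_threshold` =
   3.0. Survivors are clipped to the cornea disk and the reflection mask.
   An empty final mask is a valid healthy-eye outcome, not a failure.

The segmentation path contains no randomness; identical inputs and
configuration produce bit-identical masks.

## Evaluation metrics

With ulcer as the positive class: accuracy (TP+TN)/total, specificity
TN/(TN+FP), sensitivity TP/(TP+FN), IoU (Jaccard) TP/(TP+FP+FN), and Dice
2TP/(2TP+FP+FN). Undefined ratios are reported as missing, never zero, so
healthy images cannot silently drag down aggregate sensitivity. Batch reports
emit aggregates under both conventions — pooled counts and per-image means —
because the two diverge whenever image sizes or prevalences differ; headline
numbers quoted in the README use the per-image mean.

## Synthetic scenes: what they emulate, and what they do not

Each 240×320 scene renders: violet periocular skin, a Gielis-shaped aperture
with bluish sclera, a darker cornea disk placed by the same semi-minor rule
the pipeline uses, a bright tear-meniscus line (thickness 5 px) along the
border, optional elongated lid-stain arcs along the upper border (separated
from the meniscus by a small angular gap, as distinct pools), 2+ saturated
reflection disks placed away from lesions, ulcer blobs, and additive Gaussian
noise. Every scene is reproducible from its seed, and all ground-truth masks
(border pose, cornea, ulcer, reflections, eyelid stain) are exact by
construction.

Ulcer blobs are elliptical generalized-Gaussian bumps of order 6 whose
half-peak contour defines the truth mask. The steep shoulder keeps the truth
contour stable under any mid-range data-driven threshold; with a plain
Gaussian profile the predicted area would swing steeply with the Otsu split
point and the "truth" would be an artifact of the threshold convention.

Difficulty ladder (defaults chosen once): *easy* — one blob, peak green
0.85–0.95, noise σ 0.01, no arc; *medium* — 1–3 blobs, peak 0.75–0.90, noise
σ 0.02, arc in half the scenes; *hard* — peak 0.55–0.75, noise σ 0.045,
rotation ±4°, arc always. About 10% of scenes are healthy negative controls.

Deliberately **not** modeled: eyelashes, motion blur, uneven illumination,
camera vignetting, diffuse haze around lesions, and partially occluded or
closed eyes. Passing the synthetic suites therefore demonstrates that the
algorithmic chain is implemented correctly and is robust to its nominal
confounders (reflections, lid stains, noise), not that the tool meets any
particular accuracy on clinical photographs; real-data performance must be
assessed on a labeled ocular-surface dataset.

## Numerical choices and degenerate inputs

* Thresholds are defined on squared intensities in [0, 1]; Otsu per image by
  default (global fixed thresholds supported via config).
* Constant-input degeneracies: a constant blue channel yields an all-true
  reflection complement (nothing to exclude, warned); a constant gray image
  binarizes to empty (warned); an empty foreground at the ellipse-pre-mask
  stage raises "no fluorescein response detected"; a single-pixel foreground
  degenerates to a disk of the closing radius.
* The recognizer requires ≥ 50 edge pixels; cornea disks below 5 px radius
  are rejected; disks clipped by the image border warn rather than silently
  cropping.
* The filled border region includes its 1-px outline, so its pixel count is
  the quadrature area ∫½r²dφ (scaled) plus ≈ half the perimeter.
* Problem sizes used by the validation suites — 240×320 scenes, 20-scene
  pose-recovery sets, a 50-scene easy suite and a 16-scene medium suite, and
  an 8×8×1-cell evaluation search grid bracketing the generator's pose
  distributions — were chosen as the smallest sets at which the suite
  statistics are stable.

## Known limitations

* The eye-border search assumes one eye per image and near-horizontal pose;
  the default scale grid assumes the aperture occupies roughly half the
  frame in each dimension (configurable).
* The cornea-disk rule ties the cornea to the aperture's semi-minor axis;
  with widely-opened or partially-closed lids the true limbus can be larger
  or displaced.
* A lid stain that merges with an ulcer into a single connected component is
  either kept or rejected as a whole; no splitting is attempted.
* Otsu thresholds are per-image and contrast-dependent; very low-contrast
  lesions (hard-suite conditions) lose Dice mainly through threshold
  placement, not border recognition.
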