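# Methods

## The assay and the quantity measured

Molecular combing stretches deproteinized DNA onto a silanized coverslip at
a constant extension of **2 kb per μm**, uniformly and independently of
sequence. A telomere-specific PNA probe labels the TTAGGG tract of each
combed molecule, so the physical extent of a probe signal is an absolute
measurement of that telomere's length. With camera pixel size *p* (μm/px)
and stretch factor *S* (kb/μm), a fiber spanning *L* pixels measures

    length_kb = L · p · S

exactly and linearly. The package's output is the distribution of
individual telomere lengths in a sample — mean, median, extremes, Tukey
quartiles — rather than a population average, because it is the shortest
telomeres that drive senescence and disease.

## Synthetic scene model

The simulator produces the ground-truthed scenes that every downstream
stage is tested against. It emulates:

* **Geometry.** Straight fibers along a combing axis (default 0° = image
  vertical) with Gaussian orientation jitter (default sd 3°). Each telomere
  is placed at the end of a counterstained DNA fiber (*terminal*), in its
  interior (*interstitial*, default 5%), or alone (*orphan*, emulating
  extra-chromosomal telomeric repeats, default 5%). Counterstain context
  fibers are drawn from a lognormal (mean 150 kb) and clipped to the field
  of view; telomere draws are never clipped — an infeasible draw raises a
  placement error instead.
* **Optics.** An anti-aliased line profile of configurable FWHM (default
  2 px at the default 0.1625 μm/px, i.e. ≈0.3 μm — a high-NA 40×
  acquisition) convolved with a Gaussian PSF (default σ 0.8 px). The
  along-axis extent between half-maximum points equals the calibrated true
  length exactly, before PSF and gaps.
* **Photobreaking.** A Poisson number of breaks per fiber (default
  0.02 /μm) with exponential gap lengths (default mean 0.4 μm), applied to
  the telomere signal; the per-fiber gap count is recorded in the truth
  table.
* **Noise.** Constant background (100 counts), Poisson shot noise on
  signal plus background, additive Gaussian read noise (sd 8), and sparse
  roundish background speckle. Output is 16-bit.
* **Separation.** Fibers are placed with a minimum segment distance of
  25 px by rejection sampling; residual near misses are recorded per fiber
  (`n_crossings`). Two collinear fibers closer end-to-end than the
  gap-closing radius plus mask broadening are physically indistinguishable
  from a single photobroken fiber, so "well-separated" placement must clear
  that radius.

Identical (spec, seed) reproduces identical images bit for bit.

What the simulator does **not** model: hybridization efficiency variation
along a fiber, curved or stretched-inhomogeneous fibers, coverslip
autofluorescence gradients, camera fixed-pattern noise, and tile-stitching
artifacts. Tests passing on these scenes therefore demonstrate the
correctness and calibration of the algorithms, not the full variability of
microscope data.

## Detection

Two presets mirror the published semi-automated recipes.

**Preset A** — tubeness → MCT → shape criteria → gap closing.

* *Tubeness* is the single-scale Hessian ridge response
  σ²·max(0, −λ₂) computed with Gaussian derivatives. The scale is a free
  parameter (the recipes name the filter but not its scale); the default,
  half an expected apparent width of 7 px (σ = 3.5 px), is chosen so the
  thresholded ridge mask of a diffraction-limited fiber has a mean width
  near the low-middle of the printed 5–15 px acceptance window — the scale
  and the width criterion are only meaningful as a self-consistent pair.
* *MCT* (maximum correlation threshold) is defined as the level, among all
  distinct intensities (or 256 evenly spaced levels for continuous images),
  maximizing the Pearson correlation between the image and its
  binarization; ties resolve to the smallest level. The selected
  binarization is invariant to affine intensity rescaling, which makes the
  whole detection path invariant as well (a property test asserts this).
* *Shape criteria*: moment-ellipse axis ratio > 2 (strict), eccentricity
  ≥ 0.75, mean width strictly within (5, 15) px, orientation within ±15°
  of the combing axis. Mean width is area / skeleton length (the recipes do
  not define "width"). Candidates whose skeleton has more than two
  endpoints (branching, usually crossing fibers) are excluded by default.
  Boundary semantics follow the printed inequalities verbatim; whether the
  width bounds were meant inclusive is unknowable from the text, so they
  are strict as printed.
* *Width bounds and pixel size.* The pixel-unit width window is **not**
  rescaled when the pixel size differs from the reference 0.1625 μm/px
  (an option exists). The apparent width of a combed fiber is set by the
  PSF and the ridge-filter scale, not by the specimen, so it does not
  scale proportionally with pixel size; proportional rescaling at
  0.1 μm/px would demand masks ≥ 0.8 μm wide and reject every
  diffraction-limited fiber.

**Preset B** — background mask → tubeness → threshold → subtraction →
size/circularity → gap closing.

* The background mask is the union of grayscale openings with a disk and
  with line elements horizontal and at ±45° to the rows — shapes that
  cannot be a combing-direction fiber. (The published recipe lists "45° and
  145°" lines; whether 145 is a typo for 135 is undecidable, so the angles
  are a parameter and both readings are selectable.) The union is
  binarized halfway between its flat (noise) level and the bright end of
  the raw image: full-brightness structured debris is flagged, the faint
  PSF halo a real fiber leaves under an opening is not.
* The threshold on the tubeness response is user-defined (the published
  recipe uses a slider) or automatic (MCT).
* Criteria: area > 0.250 μm² (strict) and circularity = 4π·area/perimeter²
  ≤ 0.5. Circularity of a single-pixel object (zero perimeter estimate) is
  defined as 1.

**Gap closing** merges accepted fragments that are collinear within the
orientation tolerance, laterally offset by no more than the wider
fragment's mean width, and separated along the axis by at most 1 μm
(default; the recipes say only "small gaps"). Fragment ends are the mask
pixels with extreme projections on the major axis — skeleton tips are
unsuitable because thinning erodes fiber ends. Merging is transitive via
union-find and independent of input order; merged objects span the gap
(the photobreak must not truncate the length) and descriptors are
recomputed.

## Measurement

Length is the geodesic path along the morphological skeleton between its
two endpoints — unit steps for 4-neighbors, √2 for diagonals — **plus 1 px**
endpoint correction, then converted by the calibration. The skeleton
metric, rather than the ellipse major axis or Feret diameter, is robust to
slight waviness and to gap-merged objects, and it self-corrects most of the
symmetric mask broadening: thinning terminates roughly half a mask-width
inside each rounded end, canceling the half-width the threshold adds at
each end. A small residual underestimate (~2–3 px, visible as an intercept
of about −0.5 kb in measured-vs-true regressions) remains; it is constant,
so it matters only for the shortest fibers.

Fibers touching the image border are flagged and excluded from
distributions by default (censored lengths). Branched objects are flagged
and excluded. With a counterstain channel, each telomere is classified
*terminal* if one of its endpoints lies within 1 μm (default tolerance) of
the end of the overlapping counterstain fiber, *interstitial* if it
overlaps but is interior, *orphan* if it overlaps nothing; restricting
distributions to terminal telomeres is configurable and off by default,
since the source protocol "minimizes" rather than excludes interstitial
and extra-chromosomal signals. Channel registration is assumed.

## Statistics

* Summaries: mean ± SEM (sd/√n), median, min/max, quartiles by linear
  interpolation of order statistics (type 7 — the convention is not stated
  in the source, this is the common default), Tukey whiskers at the most
  extreme points within 1.5·IQR of the quartiles.
* Comparisons: two-sided Student's t (pooled variance) or two-sided
  Mann-Whitney U — exact null distribution for combined n ≤ 20 without
  ties, tie-corrected normal approximation otherwise. The caller chooses
  the test; normality is never auto-tested.
* Method agreement: ordinary least squares with R².
* Attrition: −1000 × OLS slope of mean length (kb) against population
  doubling, i.e. bp lost per PD (positive = shortening). On the published
  fibroblast means (10.55/9.32/4.52 kb at PD 20/40/60) OLS gives
  150.75 bp/PD; mapping PD to cell divisions is left to the caller.
* Flow-FISH RTL: (exp probe − exp no-probe)/(ctrl probe − ctrl no-probe) —
  the ratio of background-subtracted signals, the only reading of the
  printed formula that yields RTL = 1 for identical populations.
* Cohort banding: reference percentile curves (1st/10th/50th/90th/99th vs
  age) are consumed as data and linearly interpolated in age; a value is
  assigned to the band containing it, boundary values to the lower band.
  Ages outside the reference range raise unless clamping is enabled.

## Problem sizes used by the test suite and acceptance script

Scenes are rendered at 0.1 μm/px with 3 px fiber FWHM and σ = 1 px PSF
(the same physical optics as the defaults, finer sampling). The
acceptance script sweeps fiber length over {0.5, 0.75, 1, 1.5, 2, 4} kb
(20 fibers/scene, 20 seeds) downward and {20, 40, 80, 100, 120} kb
(single-fiber scenes, 20 seeds) upward, and regresses 50 lognormal fibers
(mean ≈ 4.5 kb) against truth; the test suite runs the same sweeps with 6
seeds and checks distribution-mean recovery on ten 1200² scenes of ~50
fibers with means spanning 4–40 kb.

## Known limitations

* **Short-fiber cutoff.** Preset A's printed criteria exclude sub-μm
  objects regardless of implementation: the width criterion forces the
  thresholded mask of a genuine fiber to be wider than 5 px, while axis
  ratio > 2 on a short object's mask (extent ≈ L + b for mask width b)
  requires L > b > 5 px — strictly more than 1 kb at 0.1 μm/px, in
  practice ≈ 3 kb for moment-ellipse ratios. The shortest length the
  automated preset-A pipeline recovers reliably is therefore ~3 kb (the
  acceptance sweep grid reports 4 kb); measuring sub-kb telomeres requires
  manual scoring or a detector without elongation criteria. For the same
  reason a distribution's measured minimum cannot reach true minima below
  that cutoff, and short-end censoring slightly raises measured means at
  low mean lengths.
* Preset B's circularity ≤ 0.5 likewise admits only clearly elongated
  masks (roughly ≥ 5 kb at these optics).
* Lengths are measured along the skeleton of a single connected object; a
  photobreak gap larger than the gap-closing radius splits a fiber into
  two records, and a fragment that fails the shape criteria before gap
  closing is lost (visible as rare low outliers in measured-vs-true
  scatter).
* The constant −0.5 kb skeleton bias is not corrected; the endpoint
  correction is fixed at 1 px by design.
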