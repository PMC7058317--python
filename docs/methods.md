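# Methods

## The estimation procedure

The package turns an en-face reflectance view of the superficial retina
into a binary (two-gradation) estimate of the central 10-degree visual
field and scores that estimate against perimetry.  The chain is:

    10-2 grid -> retinal projection (+ RGC displacement)
              -> NFB presence at each point (windowed binarisation)
              -> estimated field (defect = NFB absent, flipped to field
                 orientation)
              -> per-eye confusion table vs probability-plot flags
              -> accuracy, Cohen's kappa, cluster accuracies, cohort means

The estimate is deliberately categorical: it locates defects but carries
no information about their depth in dB.

## Grid and projection

**Grid geometry.**  The 10-2 pattern is reconstructed as the odd-integer
degree lattice in [−9, 9]² restricted to x² + y² ≤ 82.  This is the only
lattice-plus-radius rule that yields exactly 68 points, matching the
device pattern; 34 points fall in each hemifield.  Ordering is row-major
from the superior row down.

**Projection.**  Field coordinates use temporal-positive x and
superior-positive y.  The retinal (fundus-view) frame has the fovea at
the origin and, for either eye, the optic disc on the nasal side; the
projection inverts the vertical axis (superior field → inferior retina)
and mirrors the horizontal axis for left eyes, so a single code path
handles both lateralities.  Degrees convert to millimetres at
0.288 mm/deg, the emmetropic schematic-eye value.  No axial-length
(Littmann) magnification correction is applied — the scale is a single
configurable number precisely so such a correction can be hooked in.

**RGC displacement.**  Near the fovea the responding ganglion cells sit
centrifugally away from the stimulated cones, so each projected point is
pushed radially outward (polar angle preserved) by a smooth unimodal
profile d(e): zero at the fovea, maximum `peak_amplitude_deg` at
`peak_deg`, identically zero at and beyond `cutoff_deg`, continuous
everywhere.  The implemented profile is

    d(e) = A · (e/p) · ((c − e)/(c − p))^((c−p)/p),   0 ≤ e ≤ c,

with defaults p = 1.8°, A = 1.2°, c = 13° chosen to match the qualitative
shape and scale of published macular displacement curves.  The three
numbers are plain configuration, so an exact literature parameterisation
(e.g. a Drasdo-family fit) can be substituted without code change.
e + d(e) is strictly increasing below the peak, so displacement never
reorders points along a ray.

**Clusters.**  C1 is the papillomacular area; C2/C3 are the superior and
inferior hemifields excluding C1.  Since cluster membership is a
convention rather than device metadata, C1 ships as a named default index
mask — the 12 points with |y| = 1° at x ≥ −1° (the temporal inner strip
plus the four central points) — and is overridable in configuration.

## En-face image construction

All steps are deterministic re-specifications of what is usually done
interactively in vendor software and a photo editor:

* **ILM flattening** shifts each A-scan by an integer (circular) offset so
  the ILM sits at depth 0; no interpolation, per-A-scan intensities are
  preserved as a multiset.
* **Slab extraction** averages [depth, depth + thickness] below the ILM;
  thickness 0 (the default) selects a single cross-sectional plane, which
  is the acquisition style emulated here; a positive thickness supports
  the fixed-slab variant.  The depth where bundles are most clearly
  distinguishable is chosen automatically as the candidate maximising the
  coefficient of variation of non-vessel slab intensity (striated
  bundle/gap texture maximises it), ties broken to the smallest depth.
* **Tile registration** is translation-only (same device, same scale):
  normalised cross-correlation evaluated at every integer shift via FFT
  running sums, over vessel masks when both tiles carry them, otherwise
  over intensities.  The overlap is blended by averaging and landmarks are
  re-expressed in mosaic coordinates.  A best-shift correlation below a
  floor (default 0.2) raises a registration error rather than returning a
  wrong mosaic.
* **Normalisation** is a 1st/99th-percentile contrast stretch to [0, 1]
  followed by a gamma power; monotone, so pixel ranking is preserved.
  Constant images normalise to zero with a logged warning.

ILM segmentation itself is out of scope: volumes carry their ILM surface
as data (synthetic volumes are generated with it), and real-volume
segmentation is a named extension point.

## NFB presence judgement

In the clinical procedure presence/absence at each point is judged by
three masked examiners with majority vote.  The package's automated
reader replaces that subjective step with windowed binarisation: a point
is *present* when at least `min_present_fraction` (default 0.25) of the
non-vessel pixels within `window_radius_mm` (default 0.15 mm, about half
the 2-degree point spacing, so neighbouring windows do not overlap) lie
above a global threshold.  The threshold is Otsu's value on the
non-vessel histogram of the whole mosaic, refined by isodata iterations
to the midpoint of the two class means — Otsu's argmax is resolved at
histogram-bin granularity and, on the plateau produced by a well-separated
bimodal histogram, returns the lowest candidate, which can sit flush
against the dark mode.  Windows fully covered by vessels or outside the
image are *indeterminate*; they default to "present" (the conservative
human reading) and are reported separately.

The multi-examiner protocol is retained as a simulator: graders are
i.i.d. bit-flippers of the truth with error p, consensus by strict
majority.  The closed-form majority error for three graders,
3p²(1−p) + p³, and the two-way random-effects ICC(A,1) on the 0/1
ratings support agreement studies.  Degenerate ICC inputs (no
between-point variance) are reported as undefined (NaN), never as 0.

## Concordance statistics

Per eye and per (metric, threshold) cell — metric TD or PD, threshold
5/2/1% — each point contributes to one confusion cell: positive (defect
in both fields), negative (defect in neither), false positive
(estimated-only), false negative (actual-only).  Probability categories
nest (<0.5% ⊂ <1% ⊂ <2% ⊂ <5%), so threshold t flags every category at or
beyond t.  Accuracy is (positive + negative)/68 × 100; Cohen's kappa uses
the same four cells.  Kappa of a degenerate table (all 68 points one
class in both fields) is undefined; it is reported as NaN and excluded
from cohort means with a count, because silently coding 0 would bias the
averages downward.

Aggregation is per-eye-then-average, not pooled over points.  The myopia
split assigns an eye to the high-myopia group only when spherical
equivalent is strictly below −6 D.  Cluster accuracies use the cluster
size as denominator, so the size-weighted cluster mean reproduces the
overall accuracy exactly.  Group comparisons use the two-sided
Mann-Whitney U test: exact p by full enumeration of group assignments
(midrank ties included) when min(n₁, n₂) ≤ 8, the tie-corrected normal
approximation otherwise.

## Synthetic data: what it emulates, and what it does not

The generator produces matched image/exam pairs shaped like a POAG
cohort: 38 eyes by default, early-to-advanced damage (structural defect
counts 5–60 of 68), predominantly superior-field (inferior-retina)
arcuate defects with papillomacular sparing, spherical equivalent from
N(−4.3, 4.0) D truncated to [−11.375, 2.625] (about a third of eyes fall
below the −6 D cutoff), and reliability indices drawn to pass QC unless
failures are requested.

**Fiber geometry.**  Bundles follow non-crossing arcs labelled by their
disc entry angle θ₀; a point's bundle coordinate is
θ₀(p) = φ(p)/(1 + β·r(p)) with φ the disc-polar angle (zero toward the
fovea) and β = 0.12 /mm.  The sign of θ₀ equals the sign of φ, so no arc
crosses the temporal horizontal raphe; the disc sits on the foveal
horizontal for this model.  An arcuate defect is a θ₀ interval rendered
dark (default 85% reflectance loss); vessels are dark curves along
sampled arcs, recorded in a mask.

**Structural truth is defined at the judgement aperture.**  A test point
is a structural defect when the defect wedges cover the reader's own
pixel window (same footprint, same vessel exclusion) beyond the
complement of the presence rule.  Wedge placements are resampled until no
window's bright fraction falls within ±0.10 of the presence threshold, so
the truth is unambiguous at the aperture scale and, in the noise-free
limit, the automated reader reproduces it exactly.  This is a deliberate
modelling choice: a boundary-straddling location has no well-defined
point-wise answer at the resolution the procedure operates at, so truth
is defined the way an ideal examiner reading a small neighbourhood would
call it.  Consequence: the perfect-pipeline guarantee holds for the
judgement parameters the cohort was generated with.

**Function from structure.**  Functional truth is structural truth XOR
Bernoulli(q) per point — the comparison under study is purely
categorical, so discordance is modelled directly on the flags rather than
through simulated dB thresholds.  The default q = 0.1 matches the order
of point-wise disagreement implied by ~88% published agreement.  Exam
categories are drawn consistently with the functional truth: defect
points print <1% or <0.5% (so they are flagged at every threshold),
normal points print normal, with an optional mild-<5% rate for
threshold-dependent realism (off by default).  TD and PD carry the same
flags with independently drawn categories; defect points get deeply
depressed dB values, giving the cohort a realistic spread of mean
deviation.

Under this model the closed-form expected confusion cells for an eye
with k structural defects are (k(1−q), (n−k)(1−q), kq, (n−k)q), from
which an expected kappa per eye follows; cohort means of the simulated
kappa agree with the mean closed form to within small-sample bias of the
per-eye estimate.

**What passing tests do not show.**  The images are cartoons: no OCT
speckle, no peripapillary atrophy, no foveal darkening, no media opacity,
no segmentation error, and defects are crisp wedges rather than ragged
real lesions.  Agreement numbers obtained on synthetic cohorts
demonstrate that the pipeline's geometry, reading rule and statistics are
correct and well calibrated — not that the method achieves any particular
accuracy on clinical data.

## Numerical choices and degenerate inputs

* Slab-depth selection ties break deterministically to the smallest depth.
* Registration refuses to return a mosaic when the best-shift correlation
  is below the floor or the admissible overlap is empty.
* Kappa and ICC report NaN (undefined) for degenerate inputs instead of a
  misleading 0; cohort means skip and count them.
* The reader's decision is strict (`fraction ≥ min_present_fraction`,
  pixel `value > threshold`); determinism is bitwise given identical
  inputs.
* Problem sizes in the test-suite experiments — 38-eye image cohorts,
  200-eye truth-only cohorts, 10⁵-point grader simulations, 50
  registration offsets — were chosen as the smallest sizes at which the
  binomial/Monte-Carlo tolerances in use are meaningful.

## Known limitations

* Defect depth is not estimated; the output field is binary.
* No axial-length magnification or disc-inclination correction (both are
  exposed only as configuration hooks).
* The displacement profile is a configurable stand-in with literature-
  scale defaults, not a fitted anatomical model.
* The automated reader is intensity-based; it inherits every artifact of
  the reflectance image (vessel shadows are masked, but e.g. atrophy or
  media opacity would read as defect).
* Real-device file parsing and retinal layer segmentation are out of
  scope.
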