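# Methods

## The measurement problem

In fatty muscle degeneration the clinically meaningful quantity is how much
of the fascia-enclosed muscle compartment has been replaced by fat. On
T1-weighted MR images fat is bright and muscle mid-gray, so the fraction
can be measured by counting pixels — provided the subcutaneous fat ring
(SAT) is separated from intramuscular fat (IMAT), which requires reliable
boundaries: the outer limb outline and the fascia. `myofat` automates that
boundary determination and reports

intramuscular fat fraction = |IMAT| / (|IMAT| + |muscle|)

per slice, aggregated as the arithmetic mean over the 20 middle slices of
the stack (a mean of ratios, not a pooled pixel count; the middle window is
centered on the stack midpoint, shifted one slice proximally when the split
is uneven).

## Tissue clustering

Each slice is clustered independently into k = 3 intensity classes by
Lloyd k-means (k-means++ seeding, 8 restarts, explicit integer seed,
best fixed point by inertia). For 1-D data the assignment step uses sorted
centroid midpoints; a pixel exactly on a midpoint goes to the darker
centroid, which makes results reproducible bit-for-bit. The darkest class
is background/cortical bone/flow voids, the middle class muscle, the
brightest fat. No bias-field correction is applied; the pipeline is
expected to tolerate mild (≤ 20%) smooth inhomogeneity because the three
intensity modes stay separable, and the tests exercise that.

Cleanup uses a disk of radius 3 px: fat specks absorbed when the muscle
mask is closed (vessel lumina) are reassigned to muscle, and muscle-class
components that touch the outer background and vanish under erosion (the
skin rim) are reassigned to background. Cleanup only ever changes pixels
within twice the closing radius of a class boundary. The cleaned map
drives contour fitting; the IMAT/muscle separation itself always comes
from the raw clustering, since cleanup deliberately destroys fine speckle.

## Active contour

The limb and fascia boundaries are fitted with a greedy polygonal snake:
N = 50 points minimizing Σ α·E_cont + β·E_curv + γ·E_image with
(α, β, γ) = (0.1, 0.6, 0.3), a 7×7 integer search window per point, full
sweeps over all points, equal-arc-length resampling after each sweep, and
termination when fewer than `move_tol` = 2% of points move (or the energy
stalls for three sweeps; `max_iter` = 200 sets a warning, not an error).

Two numerical choices make those weights workable:

- **E_image is the squared distance (px²) to the nearest edge pixel of the
  binary target.** Edges are exact minima, and the attraction basin spans
  the whole frame, so initialization only needs to enclose the target.
- **The internal terms are divided by the polygon's mean squared point
  spacing**, frozen at the start of each sweep. Raw ‖pᵢ−pᵢ₋₁‖² terms scale
  with contour size and point count; normalized, the three weights are
  comparable regardless of geometry, and near an edge the image force
  (gradient ≈ 2d per px) dominates the curvature penalty, giving sub-pixel
  equilibrium. Because each greedy move minimizes every energy term that
  involves the moved point, with the normalization frozen, the total
  energy is non-increasing within a sweep — asserted on traces in the
  tests. `normalize_internal=False` restores the raw px² convention used
  by the closed-form energy identities in the test suite.

A property worth knowing: with γ = 0 and rigidity-dominated weights, greedy
*integer* moves cannot shrink a fine polygon — the per-move spacing penalty
(≈ δ²) exceeds the tension gain (≈ r·θ²·δ) — so a free snake stalls rather
than collapsing. This is a feature of greedy coordinate descent, not a bug;
with an image term present it is irrelevant.

Initialization is the boundary of the convex hull of the target support,
pushed 4 px outward. The limb target is the filled fat ∪ muscle support of
the **raw** map (the cleaned map has lost the skin rim, which is part of
the limb outline). The fascia target is built from the cleaned muscle
class by (1) morphological closing with an adaptively grown radius —
starting at the cleanup radius and increasing until the filled largest
component stops growing by 2% — and (2) the convex hull of the result.
The adaptive closing reconnects muscle that heavy speckle has fragmented
(at 60% infiltration the muscle class is below the 2-D percolation
threshold); the hull bridges fat pockets that open onto the SAT ring and
therefore can never be closed morphologically. The hull step assumes the
fascia cross-section is approximately convex, which holds for the thigh;
without it the fitted boundary selectively excludes boundary fat and
biases the fraction low by up to ~0.03 at 60% infiltration.

## Compartments, bone, failure detection

Contours are rasterized with pixel-center point-in-polygon tests (boundary
pixels interior). SAT = fat class between the contours; IMAT/muscle = fat/
muscle classes inside the fascia minus bone; everything else (skin rim,
stray pixels) is coded `outside`, so the five compartments partition the
slice exactly. The femur is found as the dark connected component inside
the fascia whose filled interior holds a bright (fat-class) marrow core;
the filled mask (cortical + marrow) is excluded from both IMAT and muscle,
so marrow never counts as intramuscular fat. Bone is detected per slice,
with no 3-D continuity constraint.

A slice is flagged for manual correction when (a) the fascia-enclosed area
falls below 20% of the limb area, (b) the fascia touches the limb outline
(no SAT ring), or (c) more than 20% of the fascia boundary has no
muscle-class pixel within 5 px. Criterion (c) is the practical signature
of confluent infiltration merging with the SAT ring: ordinary moth-eaten
speckle keeps muscle evidence close to the whole boundary (measured ≤ 18%
unsupported at 60% infiltration on default phantoms), while severe
infiltration (85%) exceeds the threshold with margin. A connectivity- or
width-based "fat bridge" test cannot make this distinction, because random
speckle above ~50% infiltration percolates and connects SAT to deep fat
through arbitrarily wide paths. Flagged slices are excluded from the
aggregate; `apply_manual_contours` recomputes the single mid-slice
fraction from user-drawn polygons and marks the result `manual_corrected`.
Manual results are deterministic: identical contours give identical
fractions, so the ICC of repeated identical input is exactly 1.

## Phantoms

The thigh phantom is nested circles — skin (2 px), SAT ring (12 px),
fascia-enclosed muscle (radius 56 px at the 160 px default), femur
(cortical ring radius 13 px, marrow 7 px) — with prescribed T1-like means
(fat 230 > marrow 215 > muscle 110 > skin 70 > cortical bone 12 ≈
background 8). Contrast is prescribed, not simulated from sequence
physics. IMAT speckle thresholds a Gaussian-smoothed random field
(correlation scale `speckle_grain`, default 2.5 px) at the quantile that
hits the target fraction inside the muscle mask, reproducing the
moth-eaten texture at an exactly known fraction; a `gradient` pair
interpolates the per-slice target linearly, with defaults ≈ 11.6% proximal
and ≈ 27.2% distal reflecting typical proximo-distal infiltration.
Noise is Rician (modulus of a complex Gaussian perturbation, the standard
magnitude-MRI model); the recovery tests run at SNR 15 (σ = muscle
mean/15). The bias field is one broad multiplicative Gaussian bump. Optional
bright vessel dots exercise the cleanup stage and carry their own
ground-truth label so they never contaminate the true fat fraction.

What the phantom does **not** model: partial-volume mixing at tissue
interfaces, anatomical (non-circular, multi-muscle) geometry, two-bone
lower-leg anatomy, fascia visible as its own structure, coil-profile
shading beyond one bump, and patient-realistic SAT/IMAT texture
statistics. Passing recovery tests therefore demonstrates correctness of
the algorithmic chain under controlled contrast, not clinical accuracy on
scanner data.

Cohort score tables draw each muscle grade as round(clip(archetype mean +
N(0, sd), 1, 4)) per side, with three thigh archetypes (near-normal mean
1.7; posterior-dominant 3.7 posterior / 2.5 anterior; diffuse 3.4), three
leg analogues, default subgroup sizes (16, 10, 9), grade noise sd 0.4 and
a 3.1% STIR flag rate — the typical cohort structure this kind of study
reports. True cluster labels are retained for recovery tests.

## Cohort statistics

Patient clustering uses the same Lloyd core on side-averaged per-muscle
grades (thigh and leg separately; 20 restarts; final labels renumbered so
cluster 1 is mildest). ICC is the two-way random-effects,
absolute-agreement, single-measure form ICC(2,1) from the mean-squares
decomposition, the conservative choice for method reproducibility; the
consistency form ICC(3,1) is available for comparison. CV is per-subject
sd/mean × 100, summarized mean ± sd over subjects. Spearman's rho is the
Pearson correlation of mid-ranks; its p-value is computed by full
permutation enumeration for n ≤ 10 (chunked, exact under ties) and by the
t approximation with n − 2 df above; Bonferroni adjustment is
min(1, m·p). The t-test is the pooled-variance two-sample form. The
log-vs-linear comparison fits the fraction and its logarithm on the mean
visual score by least squares; zero fractions are offset by half the
smallest positive value (with a warning) before the log — relevant only
for near-normal cohorts.

## Degenerate inputs and errors

Fewer distinct intensities than clusters, non-distinct centroids, constant
vectors, zero pooled variance, and an empty IMAT ∪ muscle region raise
typed errors rather than returning 0. An empty muscle class raises a
segmentation failure that the pipeline converts to a per-slice flag. A
volume with fewer than 20 valid slices aggregates over all valid slices
with a warning.

## Problem sizes in the shipped checks

The test suite and acceptance script run on 160 px single- or few-slice
phantoms (2 slices per infiltration level, one 24-slice gradient volume),
150-patient synthetic cohorts, 10,000 t-test null replicates, 500
regression replicates and full 8-element permutation enumeration — sizes
chosen so the whole verification runs in a few minutes on one core while
keeping every statistical check comfortably powered.
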