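# Methods

This note records the models, conventions, and numerical choices behind each
pipeline stage, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the analysis recipe left genuine
freedom.

## Coordinate and intensity conventions

Image arrays are ordered `(z, y, x)` (TIFF plane order); physical
coordinate vectors are `(x, y, z)` in nm.  The physical position of voxel
index *i* is `(i + 0.5) · voxel_size` (voxel-center convention).  All
intensities live on the 16-bit 0–65,535 scale.  Default voxel size is
50 × 50 × 150 nm (lateral × lateral × axial), mimicking confocal anisotropy
after pseudo-super-resolution restoration.

## Synthetic scenes

The generator emulates high-NA confocal z-stacks of immunostained cortical
neuropil in which each labeled protein appears as a discrete sub-micron
spot.  Spots are isotropic-in-XY 3D Gaussians with σ = (80, 80, 200) nm,
truncated at 3σ, with per-spot peak intensities uniform in
[20,000, 45,000], a constant background (default 1,000) and additive
Gaussian read noise (default SD 300).  The default desk-scale field is
12.8 × 12.8 × 3 µm (256 × 256 × 20 voxels) rather than the full ~50 × 50 µm
acquisition: it keeps single-scene tests around a second while preserving
realistic spot densities; parameter-recovery studies that only need
centroids use `plant_ground_truth` on full-size 50 × 50 × 3 µm fields
without rendering.

Colocalized partners are planted by copying `round(fraction · n_source)`
(half-to-even) source centroids into the target channel, displaced by a
jitter that is isotropic in PSF-scaled space: direction biased by the
(80, 80, 200) nm anisotropy, magnitude |N(0, σ_jitter)| truncated at
3σ_jitter, so planted pair distances are bounded by 3σ_jitter and a single
scalar controls overlap tightness.  Remaining target spots are uniform.
Partners that would leave the field are reflected at the boundary.

Two guards keep scenes meaningful: a density guard refuses channels whose
uniform density gives a spot a >50% chance of a same-channel neighbor
within one blob σ (computed as `1 − (1 − v_σ/V)^(n−1)`), and an optional
`min_separation_sigma` enforces an anisotropic (σ-scaled) minimum pairwise
separation by rejection sampling — used to build the "separation ≥ 4σ"
scenes on which segmentation recovery must be exact.

Spot densities per field are not fixed by the experimental description, so
they are configurable everywhere and echoed into logs and resolved configs;
defaults (200 spots/channel per desk-scale field) were chosen to match the
qualitative crowding of cortical neuropil staining.

What the generator does **not** emulate: real PSF convolution (blobs are
Gaussian, not Airy), spectral bleed-through, uneven illumination, Poisson
shot noise (read noise is additive Gaussian only), tissue autofluorescence,
and clustered (non-uniform) background spot placement.  Passing recovery
tests therefore demonstrates correctness of the measurement machinery under
controlled conditions, not robustness to every real-microscopy artifact;
the noise and threshold knobs exist so users can stress segmentation
further.

Microglia-like masks are unions of solid spheres (default 4 blobs of radius
1.5 µm) at a high plateau intensity (30,000).  Planted "engulfed" centroids
sit at most 0.8 r from a blob center and "outside" centroids at least one
voxel diagonal beyond r, so ground-truth membership is unambiguous at voxel
resolution.

Flow events draw per-channel intensities from two log-normals (negatives
exp N(4.0, 0.5), positives exp N(7.5, 0.4)) — well separated, as for a
clean secondary-control vs stained comparison.  Population counts are exact
(rounded), not binomial, so planted fractions are recovered up to gate
leakage alone.  Densitometry tables multiply the clean mixed signal by
log-normal noise with unit mean and the requested CV.

## Spot segmentation

Seeds are voxels strictly greater than every other voxel within an
anisotropic ellipsoidal radius and at least `noise_floor` bright.  The
radius is not fixed by the recipe; the default is one PSF ellipsoid
(200 nm lateral, 500 nm axial).  Plateaus (exactly equal neighbors) yield
no seed — irrelevant for continuous-valued data.

Watershed runs on the inverted intensity image with the seeds as markers,
restricted to voxels at or above the global hard threshold (default 6,000,
the center of the conventional 5,000–7,000 band).  Each seed's region is
then re-thresholded at `max(global threshold, local mean)` where the local
mean is taken in a window of 3× the maxima radius around the seed (an
undefined detail in the original recipe; with a large window this
reproduces the fixed-threshold limit), and reduced to the connected
component containing the seed.  Centroids are intensity-weighted.  Raising
the global threshold can only shrink regions and drop seeds, so object
count is monotonically non-increasing in the threshold.  Border-touching
spots are kept but flagged.  Whether thresholds were applied per channel or
per image is unstated upstream; the configuration takes one threshold per
channel.

## Colocalization

"Maximal lateral and axial sizes of 200 and 500 nm" is read as full axis
lengths (diameters), i.e. semi-axes (100, 100, 250) nm; the `semi-axis`
convention is available and every output records which was used.  Overlap
of two identical axis-aligned ellipsoids is computed exactly in
semi-axis-scaled space (each becomes a unit ball; overlap ⇔ scaled distance
≤ 2); tangency counts as overlap (closed sets), making the predicate a
deterministic total function.  The fast path queries a KD-tree in scaled
space with radius 2, which is mathematically identical to the all-pairs
predicate (and is tested against a brute-force double loop).

The colocalized fraction is referenced on channel A; an A object
overlapping several B objects counts once, though all pairs are listed.
Whether the original object-matching deduplicated multi-way ties is
unknowable; once-per-reference is this package's documented choice.  The
fraction is NaN (undefined, distinct from 0) when A is empty.  The triple
("synaptic") analysis filters both channels to spots overlapping ≥1
synapse-marker object, then runs the pairwise analysis with synaptic A as
the reference population.

## Shuffle null

The null hypothesis is complete spatial randomness of one channel: B's
centroids are re-placed i.i.d. uniformly over the full image cuboid (no
neuropil mask — masked shuffling is a natural extension but the default
domain is the cuboid; no minimum-separation constraint between shuffled
points).  100 iterations by default; each iteration's CFD of per-A-spot
nearest-B distances is evaluated on a common 64-point grid spanning
[0, 95th percentile of pooled distances].  The envelope is the pointwise
2.5/97.5 percentile band across iterations (no normality assumption),
widened — rarely, at far-tail grid points where >97.5% of iterations have
CFD exactly 0 — to contain the pointwise mean, so `ci_low ≤ mean ≤ ci_high`
holds everywhere.

"Median of the CFD" is read as the distance at cumulative frequency 0.5:
the observed median is the sample median of the n_A minimal distances, and
the null median is where the mean null CFD crosses 0.5 (linear
interpolation on the grid).  Across images the per-image (observed, null)
median pairs enter a two-sided Wilcoxon signed-rank test (≥6 pairs
required; all-zero differences short-circuit to p = 1 with a degenerate
flag).  Randomness is governed by one master seed with per-iteration child
generators spawned deterministically.

Calibration measured by simulation (see `scripts/acceptance.py`): with both
channels uniform, 18-image experiments reject at ≈5% (Type I); with a
planted colocalized fraction of 0.5 at 50 nm jitter, detection is ~100%.

## Engulfment

The microglial volume is `intensity ≥ threshold` with fully enclosed
cavities filled (engulfed material can sit inside unevenly stained
cytoplasm); optional largest-component selection.  The marker-channel
threshold is a required analysis choice — it is not pinned by the recipe —
so `threshold_sweep` reports the readout across candidate thresholds for
auditability.  "Completely surrounded by microglia" is operationalized as
centroid-in-mask (the voxel containing the centroid is mask-true); the
stricter whole-ellipsoid-inside mode is a straightforward extension but
centroid mode is the default and the tested path.  Raising the threshold
monotonically shrinks the mask and the inside count.

## Flow quadrants

Gates are rectangular and independent per channel ("1% false positive" read
per channel, matching single-channel secondary controls).  The threshold is
the nearest-rank (1 − fpr) empirical quantile — the `ceil((1 − fpr)·n)`-th
smallest observed control intensity — so the gate is always an observed
value, with no interpolation dialects.  Positivity is strict exceedance;
with distinct values this leaves exactly `floor(fpr·n)` control events
above the gate.  Stored percentages are the marginals (as quadrant displays
are annotated); single-positive occupancies derive from them and the four
occupancies sum to 100 exactly.  Conditionals are ratios of percentages
(double/marginal), NaN when the reference marginal is 0.  Spillover
compensation and scatter gating are out of scope.  Cross-sample statistics
(paired t-tests) are delegated to standard routines.

## Fraction deconvolution

Column normalization — marker signal per fraction divided by that marker's
total across the three preparations — is the adopted reading of fraction
composition ("relative amount in the lysates"); each column then sums to 1.
A row-composition alternative sits behind `normalization="row"` and the
choice is recorded in the result.  The solve is the exact unconstrained
3×3 linear system; negative components are reported as-is with a flag
(no stated non-negativity constraint), and a non-negative least-squares
mode exists for noisy data.  Condition numbers above a configurable bound
flag ill-conditioning.  Replicates are solved independently (each with its
own replicate-specific mixing matrix) and summarized as mean ± SEM,
matching a per-animal experimental structure; the repeated-measures
ANOVA/Bonferroni used for cross-compartment inference is standard-library
territory, not re-derived here.

The real study's fraction-level numbers exist only as figure bars with no
printed marker table, so exact reproduction is impossible; correctness is
established by the forward-then-invert round trip (exact to ≤1e−9 relative
error) and by ranking stability under 10% CV noise with 4 replicates.

## Problem sizes used in tests and the acceptance script

Chosen to exercise the study's own experiment shapes at desk scale:
segmentation recovery on one 256 × 256 × 20 noiseless scene with 200
spots at ≥4σ separation; triple-fraction recovery over 18 fields × 5 seeds
at 200 spots/channel on full-size 50 × 50 × 3 µm fields (centroids only);
null calibration over 200 repeats of 18-image experiments at 100 spots per
channel and 100 shuffle iterations, power over 40 repeats; engulfment over
16 fields of 400 spots; flow gating on 10,000-event tables; deconvolution
round trips over 100 random mixing matrices and 200 noisy-ranking repeats.
The full default suite runs in well under two minutes on one CPU.

## Known limitations

- The Gaussian-blob PSF and additive-noise model understate real-world
  segmentation difficulty; threshold defaults are conventions, not fits.
- Uniform shuffling over the cuboid ignores tissue anatomy; in dense
  neuropil a masked shuffle domain would be more conservative.
- Engulfment's centroid-in-mask rule counts partially overlapping spots
  as inside whenever the centroid voxel is inside; at 50–150 nm voxels the
  difference from the strict whole-spot rule is below spot scale.
- The flow model plants exact population counts; biological replicate
  variance across samples must be added by the caller (or taken from the
  per-sample tables) rather than assumed from event-level noise.
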