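# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `enclavekit`.  All lengths are micrometres, times minutes,
angles radians; raster coordinates follow x = column × pixel_size,
y = row × pixel_size with 0-based pixel indices and background label 0.

## Synthetic colony generator

`synthetic.grow_rod_colony` emulates a monolayer colony growing from the
founder's two daughters (t = 0 is their birth).  Cells are spherocylinders
(pole-to-pole length l, width w, default w = 1.0 µm, birth length 2.5 µm)
that elongate exponentially and divide at an absolute division time sampled
at birth from a log-normal distribution parameterized by its arithmetic
mean and SD (defaults 48 ± 13 min, the slow/25 °C condition; 21 ± 6 min is
the fast/37 °C condition).  At division the mother splits into two
half-length daughters placed end-to-end at ±l/4 along her axis with
angular noise σ = 0.05 rad, so sisters are born in contact.

**Elongation.**  By default each cell's elongation rate is ln 2 divided by
its own division duration, so every cell exactly doubles its birth length
before dividing.  This sizer-like homeostasis keeps lengths in the
realistic 2.5–5 µm band; a fixed global rate (`elongation` parameter)
instead lets the division-clock noise random-walk the length distribution,
which no real rod-shaped bacterium does.  The per-chain elongation-rate
recovery test uses the fixed-rate mode.

**Mechanical relaxation.**  After every growth/division substep (substep
≤ 1 min), overlapping rod pairs are pushed apart along the line of minimum
separation between their spine segments, with a torque from the contact
lever arm; updates are synchronous, displacement per iteration is capped at
a quarter cell width and rotation at 0.08 rad.  Iteration stops when the
maximum overlap falls below `overlap_tolerance` (0.1 µm) or after
`relaxation_iters` (60) sweeps; a non-converged frame is flagged
(`ColonyFrame.relaxed = False`) and warned about, never silent.

**Rendering.**  Frames are recorded every `frame_interval` (3 min,
matching typical time-lapse imaging) and rasterized as 16-bit labeled masks
on an origin shared across the whole movie (so physical coordinates are
frame-independent).  Contested pixels go to the cell whose surface is
nearest.  Default pixel size 0.1 µm/px, of the order of a 60× oil
objective.

**What the generator does not emulate:** phase-contrast optics and
segmentation errors (masks are perfect), mono-to-multilayer transition,
nutrient gradients, substrate friction heterogeneity, and cell death.
Tests that pass on generator output therefore demonstrate correctness of
the algorithms under ideal segmentation, not robustness to segmentation
noise — the tracker's unresolved-cell reporting is the hook for the
imperfect real-data case.

## Label-free tracker

Three stages per frame pair, with cutoffs in `TrackingConfig`:

1. **Centroid matching** (d_c = 0.75 µm, about one cell width): a pair is
   linked only when each cell is the *only* candidate of the other frame
   within d_c.  The mutual form prevents chain swaps when two cells straddle
   a single candidate.
2. **Division detection**: each unmatched cell's two dummy centroids
   (± `dummy_offset_fraction`·l_c along the axis, default 1/4 — the exact
   daughter-centroid positions for a symmetric end-to-end split) are matched
   to unassigned next-frame centroids within d_c, greedily by distance over
   all (dummy, centroid) pairs so that adjacent simultaneous divisions
   cannot steal each other's daughters.  A mother is resolved only when both
   dummies claim distinct cells; single claims are released to stage 3.
3. **Pole rescue** (cutoff 1.5 µm = 2 d_c; the value is a package choice,
   exposed as a parameter): centroid and both pole displacements must stay
   below the cutoff (poles paired by the better of the two orderings),
   greedy by total displacement.  Survivors are reported in
   `LineageForest.unresolved` — the automated counterpart of manual
   correction — and excluded from chain statistics rather than crashing
   the run.

Cell features: length l_c is the pole-to-pole distance (poles = contour
points of extreme projection on the major axis from image moments); width
follows w_c ≈ 4a_c/(π l_c), exact for ellipses, ~20% above the true width
of a long spherocylinder (both the formula value and the fitted-ellipse
minor axis are reported).  The colony outline is obtained by dilation, hole
filling and erosion (disk radius 3 px).

## Enclave geometry

**Partition.**  The colony support is the morphological closing (radius
≈ 1 cell width) of the cell union with holes filled.  Every colony pixel is
then assigned to the chain of its nearest member-cell pixel (distance
transforms).  The nearest-chain step both absorbs intercellular voids and
guarantees the two enclaves tile the colony exactly, which makes
L_interface = (Ps₁ + Ps₂ − L_colony)/2 self-consistent with the directly
traced shared boundary (they agree to a few tenths of a percent on a split
disc and within 5% on colonies).  If an enclave fragments, the largest
component is kept, minor fragments are reassigned, and the partition is
flagged.  Minor-fragment reassignment also covers the rare "encircled"
case.

**Contours.**  All outlines (colony, enclaves) are extracted as the 0.5
level set of the Gaussian-blurred (σ = 1.5 px) region indicator.  The
subpixel contour removes the marching-squares staircase: a rasterized disc's
perimeter and area are recovered to ~0.1% and ~0.5%.

**Contacts.**  Two cells are neighbors when their centroids are within
10 µm and the exact polygon–polygon distance between their contours is
below 1.2 µm.  Exact distances replace boundary-point sampling, removing
the sampling-density sensitivity of the point-cloud approach while keeping
the same tolerance.  The inter-enclave contact fraction averages
(inter-chain neighbors)/(all neighbors) over non-isolated cells.

**Shannon entropy.**  Boxes of side s = 5.5 µm tile the bounding box of
the centroids at stride s/2; each box containing at least one centroid
contributes SE(B) = −p_r ln p_r − p_g ln p_g (natural log; per-box maximum
ln 2 ≈ 0.693 — multiply by 1/ln 2 for bits), and the colony value is the
mean over occupied boxes.  Empty boxes carry no arrangement information and
are excluded; including them would only rescale all patterns by the same
occupancy factor at fixed geometry.  The null distribution permutes chain
labels over fixed positions with fixed per-chain counts (default 2 × 10⁵
iterations; computed by sparse box-membership × permuted-label products, so
10⁵ iterations on a 128-cell colony take seconds).

**Curvature.**  The interface polyline is resampled uniformly by arc
length (0.2 µm), coordinates are Gaussian-smoothed with σ = 0.5 µm (half a
cell width; wrapped for closed curves), and
κ = (x′y″ − y′x″)/(x′² + y′²)^{3/2} is evaluated by central differences.
Smoothing biases κ by O((κσ)²) — under 1% for radii above 2.5 µm.  On a
rasterized 5 µm circle the mean recovers 1/r within 2%; pointwise values
ripple by a few percent with the residual rasterization noise.  High-
curvature points are local maxima of |κ| above a threshold defaulting to
1/(2 × cell width) = 0.5 µm⁻¹ (the threshold is a free parameter of the
analysis and is echoed in outputs).  The κ sign is oriented positive
toward a caller-supplied reference point (e.g. the chain-1 centroid).

**Invasion regions.**  Candidate fingers are arcs between two
high-curvature points, closed by their chord; a candidate must protrude at
least `min_depth` (1.0 µm, one cell width) and be at least half as deep as
its chord is long (a finger, not a gentle bulge).  Overlapping candidates
are resolved greedily by depth/chord aspect, so a finger's mouth pair beats
chords spanning several fingers.  The mean invasion width is the average
extent of the region parallel to the chord at 7 equally spaced depths.

## Orientation field and defects

The structure tensor is Gaussian-averaged with σ = cell size / 4; the
orientation Φ ∈ (−π/2, π/2] is the eigenvector of the smaller eigenvalue
(along elongated structures).  Only pixels inside cells with non-vanishing
gradient energy are valid.  Generator masks are converted to
pseudo-intensity by a per-cell distance transform (bright axial ridges,
dark seams between touching cells).

S_R is computed with the square root, the standard scalar nematic order
parameter; it shares the [0, 1] range and the S = 1 uniform case with the
root-free variant, and the 0.3 candidate threshold is applied to this form.
Windows default to ~3–4 cell lengths with stride no coarser than a third of
the window (floor rounding — a coarser stride can step over a defect core).
Candidates are local minima of S_R below 0.3, non-maximum-suppressed within
one window.

The topological charge is the standard nematic winding number: nematically
wrapped increments δΦ ∈ (−π/2, π/2] summed around a counterclockwise square
loop (radius 3 px, escalated up to 3× when the loop crosses invalid
pixels), divided by 2π and rounded to the nearest half-integer with the raw
residual reported.  Location classes: CI within d_i = 1.5 µm of the enclave
interface, else CO within the same margin of the colony outline (the paper
gives no separate boundary margin, so d_i is reused and exposed as a
parameter), else CB.  Defect tracks are greedy nearest-neighbor links
between same-charge defects in consecutive frames within `max_step`.

## Lattice model

Two sister cells start on adjacent sites (chain 1 at the center, chain 2
uniformly in the Moore neighborhood).  Each cell carries an absolute
division timestamp; a binary heap on (timestamp, cell id) implements the
ascending division-time list, ties broken by lower id.  Bookkeeping stores
absolute timestamps rather than remaining durations — the two are
equivalent when durations are resampled at birth.  At division one
daughter keeps the mother's site and both get fresh clocks; the other
daughter takes a uniformly random empty site within the placement range
(Chebyshev ≤ 1; the weakened-adhesion variant allows ≤ 2).  When no site is
free, a direction is sampled over the 8 lattice directions with weight
∝ 1/(run length) — the contiguous occupied sites outward to the first
empty one, counted in Chebyshev steps so diagonals behave like the Moore
geometry — and the whole run is translated outward one site (the uniform
variant samples directions equiprobably).  The grid is an unbounded
dictionary keyed by absolute sites, so no artificial wall ever blocks a
shove.  In the chain-rate variant, chain 2's clock mean is multiplied by
the rate factor with the SD scaled proportionally (CV preserved).

On-lattice metrics: the inter-enclave contact fraction averages
opposite-chain Moore neighbors over occupied Moore neighbors, and the
lattice Shannon entropy applies the same moving-box kernel to site
occupants with a default 4 × 4-site box (~16 cells, chosen to hold a
similar count to the 5.5 µm off-lattice box) at half-box stride.

## Problem sizes and determinism

Default study sizes: generator colonies of 64 cells (≈ 62 division events,
~35–80 frames depending on the clock), lattice ensembles of 20 seeds at
n = 128.  All stochastic stages take explicit integer seeds
(`numpy.random.default_rng`); identical (configuration, seed) pairs give
bit-identical truth tables, masks and trajectories, and every CLI run
writes a manifest echoing the full parameter set.

## Known limitations

* The tracker's perfect accuracy holds for well-separated 3-min frames on
  clean masks; tripling the frame interval or heavy segmentation noise
  pushes cells past the cutoffs, and those cells end in `unresolved` (by
  design, not silently dropped).
* The width formula w = 4a/(πl) inherits the ellipse approximation and
  overestimates the width of long rods by ~20%.
* Curvature values within ~2 smoothing lengths of an open interface's ends
  are boundary-affected; high-curvature points there should be interpreted
  with care.
* The lattice model has no cell shape, orientation or nutrient field; it
  isolates division-clock stochasticity, sister adhesion and shoving as
  the minimal ingredients of enclave formation.
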