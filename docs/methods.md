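# Methods

This note documents the models, conventions and numerical choices behind
`spindletomo`, and what the synthetic-data generator does and does not
emulate.

## Coordinate frame and units

All geometry is held in nanometres.  The reconstruction frame is the
native tomogram frame: X is nominally the chromosome-segregation axis
(oriented from the polar-body-proximal mass toward the
pronucleus-proximal mass), Z the sectioning direction, Y the remaining
in-plane axis.  The scene descriptor stores the axis explicitly, so data
traced in any frame can be loaded; the planar angle conventions below are
defined relative to the stored axis and the frame Y/Z axes.  Inter-centroid
distances from live imaging are reported in µm — conversion happens only at
the reporting boundary.

Traces are interchanged as long-format CSV
(`filament_id, point_order, x_nm, y_nm, z_nm`), the least common
denominator of Amira/IMOD exports.  Coordinates are written with six
decimal places, which bounds save→load round-trip error at 5·10⁻⁷ nm.
Chromosome masses are either labeled voxel masks (multi-page TIFF,
1 = PB-proximal, 2 = PN-proximal, with nm voxel size and origin in the
descriptor) or ellipsoids (used by the generator).

## Filament geometry

**Length** is polyline arclength.  **Direction** is the end-to-end chord,
not a mean tangent: traced microtubules here are short (mostly < 1 µm) and
near-straight, so the chord is a robust orientation estimate and is
insensitive to tracing jitter.  The chord is folded into the hemisphere
with non-negative axis component (microtubule orientation has no sign at
this level; parallel and antiparallel are equivalent), then decomposed
into two signed planar angles, each in (−90°, 90°]:

* inclination θ = atan2(v·ẑ′, v·â) in the plane spanned by the axis and
  the frame Z axis (ẑ′ is Z orthogonalized against the axis),
* azimuth φ = atan2(v·ŷ′, v·â) in the axis–Y plane.

Both are invariant to reversing the filament's point order and to
translating the scene.  The convention (which plane carries which name,
and that folding happens before angle extraction) is a package decision —
the quantity "fraction with |θ| ≤ 30° and |φ| ≤ 30°" is insensitive to the
naming, and folding before vs after tilt correction is exposed by doing
the correction as an explicit scene rotation (`tilt_correct`) ahead of any
angle measurement.

**Tilt estimation.** Reconstructed spindles are never perfectly aligned
with the tomogram frame.  The tilt relative to the frame Y and Z axes is
estimated as the mean signed chord angle of the central-spindle population
in the X–Z plane (tilt_Y) and the X–Y plane (tilt_Z), chords folded into
the +X hemisphere.  `tilt_correct` applies Ry(+tilt_Y)·Rz(−tilt_Z), after
which the central population's mean θ and φ are below 0.1° on synthetic
scenes (the residual is second-order in the angles).  Voxel-mask
geometries are not rotated (the mask would need resampling); tilt
correction is intended for the measurement path, not for re-persisting
scenes.

**Containment** uses the strict interior of the slab box: an endpoint
exactly on a boundary face counts as outside, because an endpoint on the
section surface is a truncation artifact, not a microtubule end.  Length
summaries therefore sum every filament for total length but average only
the fully contained subset, whose lengths are not lower bounds.

**Histograms** use left-closed, right-open bins of 500 nm by default,
starting at zero.

## Classification

Region planes are placed at each chromosome mass's *inner face* — its
extreme axial extent toward the spindle midpoint (the `centroids` mode is
available but centroid planes would claim intra-mass filament portions for
the central region).  The rules, applied deterministically per filament:

1. contact with a mass (an endpoint inside or within `contact_tolerance`
   of its surface; default tolerance 0 nm, since "direct contact" is the
   strictest defensible reading) overrides the region test: the filament
   is central-spindle if the mean axial position of its non-contacting
   points lies between the region planes, pole otherwise (pole remnants
   sit on the poleward faces and may touch a mass);
2. otherwise the filament is central-spindle iff its arclength midpoint's
   axial coordinate lies strictly between the planes.

Central-spindle filaments are sub-labeled by end contact: both masses →
`both_contact`; PB only → `chromosomal_PB`; PN only → `chromosomal_PN`;
neither → `central_array`.  The labels partition the filament set, and are
invariant under rigid motion of the whole scene (the axis and masses
transform with it).

Point-to-ellipsoid distance is solved exactly from the stationarity
condition of the closest surface point (Lagrange parameterization,
bracketed root in one scalar variable); voxel-mask distances use a cached
Euclidean distance transform at the mask's voxel size.

The **chain estimate** `chain_count(D, L, o)` returns the smallest *n*
with L + (n−1)(L−o) ≥ D — the minimal number of microtubules of mean
length L, consecutive members sharing a mean overlap o, needed to bridge
an inter-chromosomal distance D.  All three inputs are explicit: the
analysis does not hard-code which stage's means are used.

## Overlap detection

Parameters: lateral cutoff 45 nm (centerline-to-centerline — microtubule
radius is not subtracted, matching a threshold stated for centerline
traces), minimum stretch 200 nm, resample step 5 nm (far below both
thresholds, so discretization error is negligible at the 45/200 nm
scales).

Both filaments are resampled at ≤ 5 nm spacing.  For each candidate pair,
every sample point of filament A is tested against the *polyline* of B
(exact point-to-segment distance, not point-to-sample); maximal contiguous
runs of points below the cutoff become candidate stretches, with no
gap-bridging — a single ≥ cutoff point breaks the run.  The matching
stretch on B is the arclength span of the closest points, and the overlap
length is the minimum of the two spans (conservative and symmetric).
Candidates shorter than 200 nm are dropped; a pair may contribute several
disjoint segments; stretches are found from the sorted-id side so results
are independent of input order.

A single KD-tree over all resampled points prefilters pairs (radius
cutoff + step: any pair with a sub-cutoff polyline approach necessarily
has sample points within that radius), which keeps the pair loop
near-linear in practice; the contract — verified in the tests — is
equality with a dense all-pairs brute-force oracle at 1 nm sampling (same
pairs, lengths within 2 resample steps).

## Live-imaging metrics

Segregation traces hold per-frame centroids of the two chromosome masses
(µm).  Distance is 3D Euclidean by default; a 2D-projection flag mimics
measurements on maximal projections.  Phase segmentation is a latch: a
frame is anaphase A while distance stays below the transition threshold
(default 2.54 µm, the separation at which the A→B transition was observed;
configurable, since it is anchored to one reconstruction rather than a
universal constant), and the first crossing switches to anaphase B for the
rest of the trace — so noisy dips back below the threshold do not revert
the phase.

Linescan **width** is the full width at half maximum of the
background-subtracted profile (background = profile minimum; crossings
interpolated linearly).  FWHM is parameter-free and strictly monotone in
the spread of a unimodal profile, which is what the pole-focusing score —
mean pole width / center width — needs.  Flat profiles are rejected.

Intensity corrections follow the two bookkeeping formulas exactly:
tubulin-style `IntDen(spin)/Mean(bck)` then min–max normalization to
[0, 1]; dynein-style `(IntDen(spin) − IntDen(bck))/IntDen(bck)`.  Both are
invariant to a global intensity scale.  `roi_integrate` supplies the
per-frame sums/means from (T, Y, X) or (T, Z, Y, X) stacks with sum or max
Z-projection, and `stack_centroids` (Otsu threshold + intensity-weighted
centers of mass, split along the separation axis) closes the loop on
synthetic two-mass stacks — real data would normally come in as centroid
tables from a tracking tool.

## Synthetic-data generator

`generate_scene` builds: two ellipsoidal chromosome masses (semi-axes
500 × 900 × 700 nm) with centroids separated by D along +X; chromosomal
filaments anchored 20 nm inside each mass's inner face and extending
inward within an orientation cone; both-contact filaments spanning the
full gap with endpoints inside each mass; central-array filaments with
arclength midpoints strictly between the inner-face planes; and isotropic
pole filaments placed entirely beyond the outer faces.  Lengths are gamma
distributed with the requested mean/sd (strictly positive and
right-skewed, putting the histogram mode below 500 nm as observed);
directions are uniform within a spherical cap.  Constructed overlap pairs
are parallel central filaments offset 40 nm laterally and sharing a stated
stretch (default 300 nm).

Placement margins (default 30 nm) keep filament midpoints and free ends
away from the region planes, and chromosomal filaments get a
depth-dependent minimum length so that anchors on the curved inner face
still clearly extend into the inter-chromosomal region — generated labels
are unambiguous by construction, which is what makes the exact-recovery
tests meaningful.  Long filaments that cannot fit the gap are redrawn;
this truncates the central-array length distribution slightly (about 2% of
draws at the mid-anaphase defaults, a ≲ 20 nm downward bias in the mean),
which the statistical tests allow for.

Defaults and presets: separation 2.54 µm (mid) / 3.51 µm (late);
chromosomal mean lengths 508/848 nm and central-array means 665/956 nm at
the two stages; preset class totals 2880 and 1310 filaments with 12 and 6
both-contact members and pole counts 1225 and 81.  Two published values
are not available and are package choices: the chromosomal/central
sub-array split (totals were published, the split was not; presets divide
the remainder evenly) and the per-class length sd (set to mean/2, which
reproduces the right-skewed sub-500 nm histogram peak).  The preset
orientation cone for central-spindle classes is 35°: for a uniform
spherical cap that leaves ≈ 85–90% of directions inside the ±30°
double-planar window, bracketing the observed 86.1%/81.1%.  The default
`ClassSpec` cone elsewhere is 25°.  Everything is driven by one
`numpy.random.default_rng(seed)`, so scenes are byte-identical across runs
for a given seed.

What the generator does **not** emulate: filament curvature (generated
filaments are straight polylines; the analysis accepts arbitrary
polylines and is tested on curved ones separately), slab truncation (all
generated filaments are fully contained; containment logic is tested on
constructed truncated filaments), tracing noise and stitching artifacts,
microtubule dynamics, and EM image formation.  Passing the recovery tests
therefore shows the analysis is correct on clean geometry at realistic
scales and parameter values — not that it is robust to segmentation error
in real tomograms.

`generate_trace` produces a piecewise-linear biphasic separation (defaults:
0.55 µm/min anaphase A, 1.1 µm/min anaphase B — rates in the observed
range with B roughly twice A — switching at 2.54 µm, 10 s frames) with
optional Gaussian centroid noise; `generate_stack` renders Gaussian
emitters on a flat background with optional Poisson noise, returning
analytic integrated intensities as truth.

## Problem sizes in the test suite

The suite exercises scenes of 50–500 filaments (the brute-force overlap
oracle is quadratic, and 50 filaments already probe every code path, with
the detector additionally run at the full 2880-filament preset scale
during development); tilt and statistics tests use 200–500 filaments,
which puts sampling error well below the asserted tolerances (e.g. tilt
SEM ≈ 0.5° against a 2° bound).

## Known limitations

* Overlap polarity (parallel vs antiparallel pairs) is out of scope —
  plus-end identification from tip morphology is an EM-interpretation
  step, not a geometry step.
* The ellipsoid mass model ignores the lobed shape of real chromosome
  masses; voxel masks cover that case for real data.
* `tilt_correct` leaves the axis-aligned slab box untouched; containment
  must be computed before tilt correction.
* The angle convention degenerates when the segregation axis is parallel
  to the frame Y or Z axis; loaders reject such scenes rather than
  silently picking a different reference.
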