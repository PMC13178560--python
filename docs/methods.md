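# Methods

## The problem

Adaptor protein complex 3 (AP3) and the small GTPase ARF1 assemble into a
protein coat that pulls membranes into narrow tubules: a ~40-nm-diameter
protein layer scaffolding a ~20-nm membrane tube.  Subtomogram averaging
(STA) of such tubules yields a *particle table* — one position and one ZYZ
Euler orientation per coat complex — and all of the coat's architecture
must then be read out of the geometry of that table: the helical lattice
parameters, the stripes of stacked arches, and the class of every
ARF1-dimer linkage between stripes.  `coatlattice` implements that readout
as a reusable, tested pipeline, together with a synthetic lattice generator
that provides ground truth for every stage.

## Conventions

* Positions in Angstrom, angles in degrees.  Orientations are intrinsic
  ZYZ Euler triples (rot, tilt, psi) with `R = Rz(rot)·Ry(tilt)·Rz(psi)`
  mapping body frame → tomogram frame — the RELION particle convention.
  Canonical ranges are tilt ∈ [0°, 180°], rot/psi ∈ (−180°, 180°]; at the
  gimbal poles the ties are broken as rot := 0 (tilt = 0) and psi := 0
  (tilt = 180).
* Body frame of a coat complex: +x runs along the arch from the δ end to
  the β3 end (circumferential), +y is the stripe stacking direction
  (≈ tube axis), +z is the outward membrane normal.
* A pseudo-helical lattice is parameterized per subunit by a signed twist
  (degrees; the sign is the handedness) and a rise (Å).  Units per turn
  = 360/|twist|; pitch = units-per-turn × rise.

## Synthetic lattice generator

The `ap3_arf1` preset encodes the coat as reported: coat radius 200 Å,
membrane radius 100 Å, twist 360/6.05 = 59.504°/subunit, rise
75.0/6.05 = 12.397 Å/subunit, i.e. 6.05 complexes per turn and a 7.5-nm
pitch.  Handedness is not constrained by the source data, so the preset is
right-handed by convention and the sign is configurable; every estimator
carries the signed twist and never assumes a sign.

Particle *k* sits at azimuth *k*·twist and height *k*·rise with stripe id
*k* mod 6.  Because 6.05 is not an integer, the six stripes (lattice step
n → n+6) spiral slowly around the tube, by 6·59.504 − 360 = −2.98° of
azimuth per step.  Each stripe carries a direction bit; members of flipped
(bit = 1) stripes are rotated 180° in-plane about the outward normal,
modelling antiparallel stripes.  Two ARF1 sites per complex sit at body
offsets (+100, 0, −80) Å (β3 side) and (−100, 0, −80) Å (δ side); these
offsets are package constants (configurable), chosen to put partner sites
of adjacent stripes ~56 Å apart — well separated from the next-nearest
inter-stripe candidate at ~105 Å, so geometric dimer pairing (greedy
nearest-first within an 80 Å radius, inter-stripe only) is unambiguous.
The generator also emits uniform membrane-surface points and oversampled
ring-seeded tables with nearest-true-particle assignments for testing the
cleaning stages.

Noise is applied only after ground truth is recorded: per-axis Gaussian
positional noise, and orientational noise as a rotation about a uniformly
random axis by a half-normal angle (an isotropic small-rotation model).
The random draw order is fixed, so one seed yields the same lattice at any
noise level.  Scores emulate an alignment cross-correlation as
1 − normalized displacement magnitude.

What the generator does *not* emulate: missing-wedge and CTF anisotropy,
per-particle alignment failure modes (score–error correlation is exact by
construction), membrane elasticity, curved or branching tubes, and
multi-tube fields.  Passing tests therefore demonstrate correctness of the
geometric readout, not robustness to every cryo-ET artifact.

### Linkage-class rule

Between circumferentially adjacent stripes s (lower azimuth side of the
boundary) and s+1, the complex of stripe s presents its +x (β3) site to
the boundary when its bit is 0 and its δ site when flipped; stripe s+1
presents the opposite end.  Hence equal bits give heterotypic β3–δ
linkages (parallel stripes), bits (0, 1) give β3–β3, and (1, 0) give δ–δ
(antiparallel).  Around the six cyclic boundaries of a closed tube, 0→1
and 1→0 bit transitions necessarily occur in equal number, which is why homotypic
β3–β3 boundaries are always matched by an equal number of δ–δ boundaries.

## Pipeline stages and numerical choices

**Seeding.**  Annotation centerlines are resampled piecewise-linearly at
1 Å (original vertices retained).  Rings are placed every `spacing` of arc
length, each with ⌊2πr/spacing⌋ seeds, staggered by half an azimuthal step
per ring to avoid axial alignment artifacts; seed +z is the outward
normal, the in-plane angle is fixed at 0 for determinism.  The default
spacing is 12 voxels at a 6.191 Å bin4 pixel size = 74.292 Å (7.43 nm),
which yields eight seeds per turn on a 20-nm tube.

**Cleaning.**  Duplicate removal is greedy by descending score (ties by
ascending id) — reproducible and idempotent; no surviving pose is ever
mutated.  Neighbor-count cleaning is a single pass with counts computed on
the input table, so it is order-independent.  There is no universal score
cut-off; thresholds are explicit arguments and are echoed in the cleaning
report.

**Cylinder fit.**  PCA supplies candidate axes (all three principal
directions are tried, which handles both long tubes and flat rings);
nonlinear least squares then refines the axis over four parameters with
the radius eliminated analytically as the mean axial distance.  Inputs
with fewer than 6 points, collinear geometry, or less than 90° of arc
coverage are rejected as degenerate.

**Tube frame.**  The fitted axis is mapped to +z with the sign chosen so
particle-id order runs toward +z, and the in-plane rotation and z offset
anchored on the lowest-id particle.  This canonicalization is purely
rigid, which is what makes all downstream estimates invariant to rigid
motion of the input (tested to <1e-3 relative).

**Unrolling and neighbor analysis.**  Unrolling maps (x, y, z) →
(u = r·θ, z) with the seam at θ = π and all displacement math wrapping
azimuth differences.  Neighbor pairs are collected by 3D chord distance
with a default cutoff of 2.5 × (estimated membrane radius) = 1.25 × coat
radius, clamped to [150, 400] Å.  The factor is chosen so that every
first-shell displacement cluster (chords up to ~217 Å at preset geometry)
sits well inside the cutoff — a cluster straddling the cutoff gets
truncated asymmetrically under noise and measurably biases the refined
generators — while the 2·g1 shell (~345 Å) stays excluded.

**Generator vectors.**  Sign-canonicalized (Δz ≥ 0) displacements are
histogrammed in 2 Å bins; peaks are collected with ±2-bin non-maximum
suppression (ties toward smaller |Δz|) and refined as the centroid of the
raw displacements in the ±2-bin window (refining on bin centers would
quantize exact lattices by half a bin).  The lattice basis is the two
shortest non-collinear peaks, Lagrange-reduced; g1 is the basis vector
with the larger |Δu| (the one-start generator), g2 the larger |Δz| (the
stripe generator).  A final refinement integer-indexes every displacement
to the basis (rounding in generator coordinates, residual < 0.3 ×
min(|g1|, |g2|)) and re-solves both generators by linear least squares.
Twist and rise are read from g1; the spiral rate of the stripes is
reported as the azimuthal drift of g2.

**Stripe tracing.**  Particles are connected when their displacement
matches ±g2 within 0.35·|g2| and stripes are the connected components —
safe because the nearest foreign cluster (±g1) lies |g1| ≈ 2.8·|g2| away.

**Linkage classification.**  For a lateral pair, each member's side is
the sign of the inter-member displacement along its own body x axis
(+x → β3, −x → δ); pairs whose displacement is dominated by the body y
component are axial contacts and are rejected; a <5% margin between the
two flags the record as ambiguous.  Parallel vs antiparallel is the
in-plane angle of the neighbor's body x expressed in the member's frame:
|angle| < 90° is parallel, and the confidence is the margin from the 90°
boundary scaled to [0, 1].  Lateral pairs for the census are selected by
integer-indexing displacements against the (g1, g2) basis and keeping
(m, n) = (±1, 0): a plain distance tolerance around ±g1 is unsafe here
because the g2±g1 shells lie only |g2| ≈ 75 Å from the g1 cluster and
leak in under noise.

**Census balance.**  Along an open helix the raw per-linkage difference
count(ββ) − count(δδ) is bounded by ±1 but is not exactly zero for every
stripe-bit assignment (transitions alternate along the one-start walk; the
terminal bits decide the remainder).  The closed-tube equal-count
constraint is exact at the level of the six cyclic stripe boundaries, so
the census `balance_statistic` is computed on boundary classes — majority
vote over interior linkages (both members with ≥ 2 lateral contacts) per
boundary — and is exactly zero on every closed synthetic tube, for every
bit assignment.  Raw per-class linkage counts are reported alongside.

**Interface recentring.**  A linkage is recentred by rotating-then-
shifting onto the ARF1:ARF1 interface: position = midpoint of the two
members' contact-facing ARF1 sites; frame z = normalized mean member
normal, x = inter-member direction orthogonalized to z.  Homotypic
interfaces are two-fold symmetric, so each is collapsed to a single C2
representative: of the two orientations related by a 180° rotation about
the interface x dyad, the one whose y axis points along the tube axis is
kept (ties broken by global +z, then +x).  The collapse is idempotent and
constant on the orbit.

**Surface density.**  The membrane area available to one lattice unit is
one helical-turn band shared by the units in that turn,
`2πr·pitch / units_per_turn`; at the preset membrane radius (100 Å) this
is 77.9 nm² per complex, and the amphipathic-helix surface density follows
as helices-per-unit divided by that area.  The radius at which to evaluate
the band (membrane vs coat surface) is an explicit argument.

## Problem sizes and tolerances

Tests and the acceptance script run on tubes of 10–30 helical turns
(61–183 particles), with standard noise of σ_pos = 3 Å and σ_ang = 3°,
and 5 independent realizations where a mean is quoted — sizes at which
every stage is exercised end-to-end in seconds while the estimator noise
(≈ 0.006 units/turn, ≈ 0.04 nm pitch across seeds) stays an order of
magnitude below the acceptance tolerances (± 0.05 units/turn, ± 0.1 nm).
Key tolerances: Euler/matrix round trips to 1e-9 rad; rigid-motion
invariance to 1e-3 relative; STAR round trips to 1e-6 Å / 1e-6°; stripe
agreement ≥ 0.99 adjusted Rand at standard noise; linkage class recovery
100% at zero noise and ≥ 95% at σ_ang = 5°.

## Known limitations

* Straight-axis tubes only: curved tubules must be segmented upstream
  (the annotation model supports curved centerlines for seeding, but the
  lattice estimator assumes one cylinder per table).
* Single-tube estimation; multi-tube batches are handled per tube.
* The ARF1 site offsets are generator constants, not values calibrated
  from an experimental map; on real data they should be overridden with
  offsets measured from the averaged density.
* No subtomogram re-extraction, re-averaging, or density rendering —
  the pipeline starts and ends at particle tables.
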