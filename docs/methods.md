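# Methods

## Base-pair centroid tracks

All geometry in this package consumes one point per base pair: the
arithmetic mean of the positions of all non-hydrogen atoms of the two
paired nucleotides (`mode="c1"` restricts the mean to the C1′ atoms as a
sensitivity check; on well-resolved B-DNA the two modes differ by well
under an ångström and do not change any classification).  Strand pairing
is positional — the registry names the two strands and their residue
ranges, and base pair *k* of the track pairs the *k*-th residue of strand
I (5′→3′) with the *k*-th-from-last residue of strand J.  Pairing is
never inferred from geometry or sequence: the intended users work with
nucleosome-positioning constructs whose register is known exactly, and
positional pairing avoids fragile hydrogen-bond detection.  Base pairs
with at least one atom per nucleotide are accepted; fully missing
nucleotides become NaN rows, which are tolerated (and reported as NA
downstream) in the linkers but are a hard error inside the 147-bp core.

## The nucleosome frame

Three anchor base pairs define the frame: the central base pair of the
core (point 1), and the base pairs 38 bp upstream (point 2) and 39 bp
downstream (point 3) of it, which lie on the two DNA gyres on the far
side of the dyad.  The dyad-axis approximation is
u = normalize(p1 − midpoint(p2, p3)); the disc-normal approximation is
v = normalize(p3 − p2); w = normalize(u × v).  Angles are measured in two
planes: the *disc plane* span(u, w) for α and the *perpendicular plane*
span(u, v) for β.  Orthonormal plane bases come from Gram–Schmidt on
(u, v); projection removes the component along the plane normal.  The
anchor offsets (38/39) are defaults and can be overridden per run.

Both u and v are approximations by construction.  On the uniform
superhelix template the u axis lies within ~1° of the true radial dyad
axis, but v is a crude normal (the anchors are 77 bp apart, not a full
superhelical turn, so v carries a large in-plane chord component).  This
does not affect the α/β machinery — prescriptions and measurements use
the same construction — but it makes v unsuitable for comparing disc
orientations between nucleosomes; stacking metrics therefore use the
best-fit-plane normal of the 147 core centroids (smallest principal
component) as the disc normal.

Sign conventions: u points from the gyre midpoint toward the dyad, v from
point 2 toward point 3.  The signed-angle axes are additionally pinned to
the winding handedness of the wrapped DNA (the sign of the Gram–Schmidt
axis is chosen from the winding sense of the core centroids).  For every
physically wound nucleosome this is identical to the naive convention;
its one observable consequence is the expected mirror behavior — mirror a
structure through its disc plane and β changes sign while α is unchanged
— which would otherwise invert (the naive frame axes co-flip with the
reflected coordinates).  Degenerate frames (anchors collinear within
1e-6 rad) are an error, orthonormality holds to 1e-9, and frames are
exactly equivariant under rigid motions.

## Linker vectors, α/β and Δα/Δβ

Each linker side is summarized by one vector: from the base pair 5 bp
into the core (counted inclusively from that side's core edge) to the
base pair 10 bp outside the core.  Both registers are configurable; the
classifications reported here are insensitive to ±1-bp changes.  A side
whose 10th linker base pair is missing or outside the track is *undefined*
— a first-class NA state, never an error and never coerced to zero.
α and β are the signed angles (range (−180°, 180°]) from u to this vector
after projection onto the disc and perpendicular planes respectively;
projections shorter than 1e-9 yield NA.

Δ angles compare a target nucleosome to a reference mononucleosome (one
with both linkers defined).  The reference core is superposed onto the
target core by Kabsch least squares over the 147 ordered core centroids —
a coordinates-only stand-in for fitting a reference model into the
density of each nucleosomal unit, which is the published protocol this
approximates; with both structures' cores near-canonical the difference
is immaterial.  The reference linker vectors are carried through the
fitted rotation, and Δβ is the unsigned angle between the projections of
the target and mapped-reference vectors in the target's perpendicular
plane (Δα likewise in the disc plane).  Because both vectors are measured
as signed angles in the same frame, this equals |signed β difference|;
the test suite asserts the equality, so the two readings of "angle
between the projected vectors" coincide by construction.  Δ values are
unsigned; averages run over the defined sides.  The package ships a
synthetic reference (below); reproducing published Δ values for deposited
arrays requires the user to supply the corresponding H1-bound
mononucleosome coordinates.

The Kabsch implementation (numpy SVD) carries an explicit reflection
guard (det = +1 always, also for near-planar inputs), raises on fewer
than 3 points or collinear configurations, and reports the minimized
RMSD.

## Stacking metrics

For a nucleosome pair: center distance between core-centroid means,
disc-normal angle (between the PCA plane normals, folded to [0°, 90°]),
dyad tilt (between the u axes, folded), and lateral offset (component of
the center-to-center vector perpendicular to the mean normal).  A pair is
*stacked* when the centers are within 75 Å and the normals within 30°;
stacked pairs split into face-to-face *aligned* versus *offset* at 15 Å
lateral offset.  These thresholds quantify what published array
structures describe qualitatively (near-parallel stacked discs,
closely packed versus slightly offset interfaces); they were chosen once
against the synthetic generator and are exposed in configuration.  The
aligned/offset labels are geometric only — no claim about which histone
surfaces form the interface is implied.

## H1 compatibility and the steric screen

The classifier implements the Δβ rule: compatible iff every *defined*
side has Δβ ≤ 6.0° (inclusive).  The threshold default comes from the
reported bound at the always-occupied nucleosome of short-repeat arrays
and is configurable, since it is a bound rather than a calibrated
cutoff.  A nucleosome with no defined side yields an *indeterminate*
call, distinct from incompatible.  H1 presence in an input model is an
annotation (a registry-named chain), never inferred, so prediction and
observation can be compared independently.

The steric screen is deliberately coarse: the H1 footprint is three
pseudo-atom spheres — an 8 Å "dome" for the winged-helix globular domain
placed 14 Å outside the dyad base pair along u, and two 5 Å lobes offset
±8 Å along the disc normal toward the two linker contact regions.  The
footprint is defined on the reference, mapped onto a target by core
superposition, and a clash is any environment point within
(cutoff + sphere radius) of a sphere center, with a 4.0 Å default
cutoff.  The environment of a nucleosome is the rest of the array minus
the 10 linker base pairs nearest its own core on each side (the
legitimate H1 contact zone).  Sphere positions and radii were calibrated
once on the generator such that natural (reference-like) trajectories
clear the footprint by a wide margin (~23 Å) while trajectories bent
toward the dyad region collide with it; all-atom van-der-Waals detail is
out of scope because the underlying claim is geometric.

## The synthetic generator

One pseudo-atom per base pair suffices because every measured quantity
consumes base-pair centroids only.  A core is 147 centroids on an ideal
left-handed superhelix (radius 41.9 Å, pitch 25.9 Å, 1.65 turns —
canonical literature values for nucleosomal DNA, not fit to any
particular structure); linkers are straight runs at 3.4 Å/bp rise.
Builder errors enforce the two-gyre anchor geometry (anchors must be on
different gyres across the dyad; planar parameter choices are rejected).

Linker directions are prescribed through the *measured* angles: given a
target (α, β), the generator solves for the straight-linker axis such
that the vector from the 5-bp-in core point to the 10-bp-out linker point
has exactly those projected angles in the nucleosome's own frame.
Prescriptions are absolute or relative to the *natural* angles of the
tangent-continued linker, and each inter-nucleosome linker carries exit
angles (for the upstream nucleosome) and entry angles (for the downstream
one, default equal), plus a twist of the downstream nucleosome about the
linker axis.  Because the prescription targets exactly what the pipeline
measures, ground truth is analytic and exact at zero noise — the
noise-free recovery residual is pure floating-point error.  Noise is
isotropic Gaussian per centroid, applied once to the assembled array from
the spec seed; ground truth refers to the pre-noise coordinates; builds
are bit-reproducible for a given spec and seed.  Constructions whose
non-bonded centroids (more than 4 bp apart along the chain — nearer
neighbors are closer than 10 Å on the superhelix by construction)
approach within 10 Å are flagged and warned about, never silently
accepted.

The packaged reference mononucleosome has natural linkers on both sides
and defines the zero point of the generator's Δ angles.  The four array
presets (4×177/187/197/207) are *hand-tuned test data, not predictions*:
their per-linker angle offsets encode the experimentally reported trend —
large deviations at the stacked nucleosomes of short-repeat arrays
(nucleosome-3 entry Δβ of 25/12/8/3° across the NRL series, nucleosome-1
exit 8/4/3/2°, with the 177-bp nucleosome-1 exit additionally bent 22° in
α toward the dyad so the steric conflict is realized geometrically) and
near-reference trajectories everywhere else.  The twists were calibrated
by grid search so that nucleosomes 1 and 3 stack face-to-face (56–67 Å
center distance, disc normals within 3–18°), nucleosomes 2 and 4 extend
away, no other pair stacks, nothing self-intersects, and the footprints
of all H1-bound nucleosomes are contact-free.

What the generator does *not* emulate: sequence-dependent DNA geometry,
linker bending/elasticity (linkers are straight), thermal ensembles,
all-atom sterics, and experimental-map artifacts.  Passing tests
therefore demonstrate the correctness of the measurement machinery and
the internal consistency of the classification rules — not a biological
re-derivation of H1 occupancy from first principles.

Fixtures are emitted as standard mmCIF (or PDB) with one pseudo-atom per
base pair on each of two antiparallel strands placed at the centroid (so
extraction reproduces the construction exactly), H1/octamer footprint
spheres as extra chains with radii in the B-factor column, plus the
registry YAML and a ground-truth TSV.  PDB output carries 3 decimals,
hence the 1e-3 Å cross-format tolerance.

## Validation studies and problem sizes

Two studies back the ground-truth-recovery claims, both fast enough to
run in full in the default test suite:

* *noise-free grid*: both linkers of a mononucleosome prescribed over
  (α, β) ∈ {−40°, …, +40°}² in 10° steps (81 builds, 324 angle
  measurements); maximum |measured − true| must stay below 0.5° and is in
  practice ~1e-14°;
* *noise study*: 200 seeded replicates, each drawing (α, β) uniformly
  from the grid range and applying σ = 0.5 Å centroid noise; the
  statistic is the fraction of measured angles (two sides × two angles
  per replicate, 800 in total) within 3° of truth, required ≥ 95% and
  empirically 98–99%.  The per-angle definition is the natural reading of
  "measured angles match truth within tolerance"; error magnitudes are
  dominated by the 3-point frame construction (the anchor centroids enter
  the axes directly), and single-angle errors at σ = 0.5 Å have ~1.2°
  spread with occasional ~5° tails at extreme prescriptions.

The validation CLI (`nucarray validate`) reports PASS/FAIL against these
tolerances and always exits 0 — validation reports, it does not crash.

## Numerical choices and degenerate inputs

Orthonormality/equivariance tolerances 1e-9; frame degeneracy 1e-6 rad;
projection cutoff 1e-9; signed angles on (−180°, 180°] with the wrap at
exactly −180° mapped to +180°.  Report TSVs print angles at 3 decimals
with NA (never 0) for undefined values.  Undefined linker sides, core
gaps, degenerate frames, unequal strand ranges and duplicate atoms each
have dedicated error or NA paths named after the offending stage.

## Known limitations

* The reference shipped with the package is synthetic; published Δ
  values on deposited models require user-supplied reference coordinates.
* The frame's v axis is a poor disc normal on the uniform template (and
  to a lesser degree on real nucleosomes); stacking metrics avoid it, but
  β's plane orientation inherits the approximation — consistently for
  target and reference, so Δβ is unaffected to first order.
* The steric screen is a three-sphere caricature of the H1 globular
  domain; it demonstrates geometric occlusion, not binding energetics.
* The stacked/aligned/offset thresholds are engineering choices; real
  interface chemistry (which histone surfaces touch) is out of scope.
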