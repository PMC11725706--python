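# Methods

This note documents the models, conventions, numerical choices, and known
limitations behind `archolimb`. It is written for users who want to judge
what the package computes and what passing tests do and do not show.

## Coordinate conventions

The global anatomical frame is +X craniad, +Y left, +Z dorsad. "Craniad
offset" of the COM is its +X distance from the acetabular midpoint;
"ventrad offset" is the −Z distance. Each joint carries a joint coordinate
system (JCS) shared by parent and child at the reference pose:
flexion/extension rotates about the JCS z-axis (extension positive),
ab/adduction about y, and long-axis rotation (LAR) about x (external
positive). Joint rotations compose in x → y → z order and joints only
rotate — no translations. Angles are degrees at every interface and
radians internally. Limb joints have one DOF except the hip and shoulder
(three). Cartilage space is a fixed translation applied to the child's
reference placement at model build; the hip and ankle default to zero
offset because those joints articulate tightly.

## Mass properties

Volume, COM, and inertia of a watertight mesh are obtained by exact
integration: each surface triangle forms a signed tetrahedron with the
origin, and the polynomial moments (1, xᵢ, xᵢ², xᵢxⱼ) of a tetrahedron
have closed forms. The only numerical error is round-off, so a unit cube
is reproduced to 1e−12 relative and lofted octagonal prisms to the exact
shoelace-area × length volume. Face orientation is normalized
automatically (a flipped mesh logs a warning rather than erroring);
non-watertight meshes are rejected with the offending edges named.
Composite bodies rotate each part's inertia and apply the parallel-axis
theorem about the combined COM. Sagittal mirroring conjugates the inertia
tensor by diag(1, −1, 1), which negates the xy and yz products.

The test suite cross-checks this integration against an independent
column-integration oracle (an n×n grid of vertical rays, entry/exit
intervals integrated exactly along z, n = 200) with 0.5% mass and 1% COM
tolerances on seeded star-shaped meshes.

## Hoop lofting

Body segments are stacks of eight-vertex planar hoops connected by index
correspondence: each side quad is split along the same (i, i+1) diagonal
so meshes are deterministic, and end caps are fans about the hoop
centroid. Hoops need not be perpendicular to a global axis — stations
order the stack but curved body axes are allowed. Cavities are separate
hoop stacks treated as a negative-mass correction at
(ρ_cavity − ρ_tissue), so a cavity at tissue density cancels exactly and
disjoint cavities compose additively. Default densities are 1000 kg/m³
for tissue (water-equivalent, the conventional choice when a study does
not state its values) and 0 kg/m³ for air cavities, overridable per
segment. Hoop fitting to bone outlines ("shrink-wrapping") and soft-tissue
expansion factors are out of scope: hoops are inputs.

## Primitive fitting and ACS construction

Articular surfaces are reduced to geometric primitives: planes by SVD of
the centred points, spheres by the linear algebraic fit
(|x|² = 2c·x + k), cylinders by Levenberg–Marquardt on
(axis-distance − r) seeded from each principal direction (best residual
wins), ellipsoids by a 9-parameter algebraic quadric completed to centre
form, with principal axes and radii from the eigendecomposition (longest
axis primary). Axis-like outputs get a deterministic sign: positive dot
with +X, tie-broken by +Y then +Z, which makes fits invariant to point
order and equivariant under rotation up to that canonical sign.
Degenerate inputs (collinear points for a plane, coplanar for a
sphere/cylinder/ellipsoid, too few points) raise errors naming the
deficiency.

An ACS takes its z-axis from the primitive (cylinder axis, plane normal,
longest ellipsoid axis); a sphere has no orientation, so a caller-supplied
fallback axis (default global +Z) is used, and fixture files always
declare their reference directions explicitly. The x-axis is the reference
direction Gram–Schmidt-orthogonalized against z; y completes the
right-handed frame.

## Forward kinematics and ROM

Posing applies G · Rx(θx)Ry(θy)Rz(θz) · G⁻¹ to the child's reference
placement, where G is the JCS frame, so the all-zero pose reproduces the
reference exactly and every transform is a proper rigid motion. ROM
checking is inclusive at the limits. ROM *scanning* sweeps one DOF from 0°
in both directions until (a) any triangle–triangle intersection between
the parent and child meshes, excluding faces touching the declared
articular patches, or (b) the posed articular-patch centroids separate by
more than a gap threshold. The default gap is 5 mm — a package choice, as
"excessive disarticulation" is inherently a judgement call. Collision uses
an axis-aligned-box broad phase and an exact separating-axis triangle
test; grazing contact within 1e−9 m counts as no intersection so the scan
is stable at touching configurations. The scan is an automated proxy for
the visual inspection such studies perform by hand; on real bone meshes
its output is not expected to match published limits, which is why the
published *Riojasuchus* limits ship as the canonical fixture
(`riojasuchus_rom.yaml`: hip FE [−65°, 55°], ab/ad [−10°, 70°], LAR
[−50°, 50°]; knee [−110°, 0°]; ankle [−50°, 30°]; MTP3 [−80°, 50°]).

## Muscle paths and moment arms

A muscle is an ordered point list (origin, via points, insertion), each
point bound to a segment, plus optional wrap surfaces. Straight spans that
penetrate a wrap are replaced by the shortest tangent–arc–tangent route:
cylinders are solved in the plane perpendicular to the axis and unrolled
(total length = hypot of the in-plane wrapped length and the axial rise),
spheres in the plane through both endpoints and the centre. The wrap
engagement test is strict segment–surface intersection; grazing tangency
counts as not wrapped, which makes path length continuous across the
tangency configuration (verified to 1e−6 m). The cylinder `side` flag
forces a wrap direction; the default picks the shorter arc, which can
switch sides when the straight span passes near the axis — sweeps through
such configurations should set the flag.

Moment arms use tendon excursion: r = −dL/dθ by central difference,
default step h = 0.25°, θ in radians. This matches the convention that a
positive moment arm about a DOF generates a moment increasing that DOF's
angle (about z: positive = extensor). The finite difference converges at
O(h²) and agrees with the law-of-cosines hinge closed form to 0.1% at the
default step. ROM limits are deliberately not enforced during sweeps so
curves stay continuous past the admissible range. Action classification
is sign-based with a dead band (default 0.1 mm): uniformly positive →
extensor/abductor/external rotator, uniformly negative → the antagonist,
both signs → switching with the zero crossing interpolated linearly,
all within the dead band → negligible. Muscle forces and architecture
(PCSA, fibre lengths) are out of scope: the toolkit computes leverages
only.

## Whole body, statics, and allometry

The whole-body COM composes every posed segment's mass properties; the
report carries craniad/ventrad offsets from the posed acetabular midpoint
and the offset normalized by gleno-acetabular (GA) distance. Bipedal
feasibility is sagittal statics only: the COM is "supportable" iff its
craniad offset lies within the feet's craniocaudal interval (inclusive);
the margin is the distance to the nearest boundary, negative when
infeasible. Mediolateral support polygons, dynamic balance, and pitching
moments are out of scope. The preset "adjusted standing" pose flexes hip,
knee, ankle, and elbow by 10° and shoulder and wrist by 10° in the
opposite sense, mirroring the slightly crouched pose used for published
COM comparisons.

Allometric mass uses the stylopodial-circumference regression for
quadrupeds, log₁₀ BM[g] = 2.749 · log₁₀(C_h + C_f [mm]) − 1.104, with a
±25.6% prediction-error band; rounding happens only at presentation. The
skull-length mass method sometimes quoted alongside it is not implemented
(its inputs and formula are not part of this workflow).

## Posture LDA

The classifier is two-class pooled-covariance LDA from first principles:
class means μ₀ (quadrupedal) and μ₁ (bipedal), pooled covariance
Σ = scatter/(n−2) (unbiased; a ridge term is available and advised when Σ
is singular), weights w = Σ⁻¹(μ₁−μ₀), score s(x) = wᵀx − wᵀ(μ₀+μ₁)/2, and
posterior P(bipedal|x) = σ(s(x) + log π₁/π₀). Priors default to class
frequencies, with an equal-prior mode. The default feature spec is
(log₁₀ body mass, COM/GA, forelimb/hindlimb ratio); the exact features of
the published analysis live in its cited source, so the spec is
configurable. The voting harness fits one LDA per training set and
tallies bipedal votes; unfittable sets abstain with a logged reason (or
raise in strict mode). The published "12 of 22" result depends on an
external 80-taxon training dataset that is not redistributed here, so the
harness is exercised on synthetic ensembles; reproducing that exact vote
is a non-goal.

## Synthetic data

Generators are pure functions of (seed, parameters). The synthetic
skeleton is a pelvis–femur–crus–pes–digit chain (boxes and capsules) with
a 3-DOF hip and hinge knee/ankle/MTP, limbs vertical and the pes
plantigrade at reference; default dimensions are scaled to the published
skeletal summary (femur 0.179 m, hindlimb 0.320 m, GA 0.355 m) so outputs
land in a realistic regime. Muscles are two-point paths in each joint's
flexion plane with recorded law-of-cosines parameters (a, b, γ₀, sense),
closing the loop: swept moment arms must match the recorded closed form
to 0.1%. Muscle acronyms follow the shipped attachment table wherever the
synthetic chain has matching origin/insertion segments. Hoop bodies are
prisms and linear tapers of concentric similar octagons, whose exact
volumes are prismatoid sums; ground truth is stored alongside the
geometry so tests never re-derive it.

What the generators do **not** emulate: realistic bone shapes, CT noise
and segmentation artefacts, taphonomic deformation, branching muscle
paths, or the composition of the published LDA training sets. Passing
tests therefore demonstrate correctness of the geometry, kinematics, and
statistics machinery — not fidelity of any particular fossil
reconstruction.

## Numerical choices and problem sizes

- Finite-difference step h = 0.25° (curves are smooth at this scale;
  halving h reduces closed-form error ~4×).
- ROM scan step 1° by default; the scan reports the last admissible angle,
  so results are exact to one grid step.
- Collision epsilon 1e−9 m (grazing = no contact).
- Column-integration oracle grid 200² columns with exact z-integration;
  tolerances 0.5% mass, 1% COM.
- Capsule meshes use 48×48 segments (volume within ~0.3% of the analytic
  capsule); boxes and lofts are exact.
- Test problem sizes (blobs of ~1,300 faces, 22-set ensembles of 80
  records, 10⁴-sample recovery checks) were chosen so the full suite and
  the acceptance script each complete in well under a minute on one CPU.

## Known limitations

- Joint translations, 6-DOF joints, joint-mobility hypervolumes, and
  ligament constraints are not modeled.
- One wrap surface acts per straight span (the first engaged wrap wins);
  stacked wraps on a single span are not composed.
- The ellipsoid fit is algebraic least squares, not geometric
  distance-minimizing; its RMS residual is an approximation.
- `rom_scan` assumes the reference pose is admissible and scans one DOF at
  a time; DOF interactions are ignored.
- The LDA harness accepts any training sets but ships none beyond the
  synthetic generator and the two published feature rows for the study
  taxon.
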