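# Methods

## Scope and model

A polyhedral cage (p-cage) is an assembly of planar polygonal faces in
which every face edge is either shared with exactly one other face or
borders a hole; two adjacent faces share at most one edge, of two adjacent
edges at least one borders a hole, and every face has at least three
neighbours.  This package characterizes the *homogeneous,
connectivity-invariant, convex* p-cages with P-gonal faces, P = 6..17: all
faces have P edges and the cage graph admits, for every pair of faces, an
orientation-preserving automorphism carrying one onto the other while
preserving the shared/hole distinction.  Reflection-mediated equivalence is
deliberately excluded (a reflected protein face is a different molecule),
which also rules out the truncated cuboctahedron and the truncated
icosidodecahedron as duals.

The cage's dual — the *hole-polyhedron*, vertices ↔ faces, edges ↔ shared
edges, faces ↔ holes — must be vertex-transitive, hence one of: the five
Platonic solids, eleven Archimedean solids, uniform prisms and antiprisms
with 3- to 10-gonal bases (31 catalogue symbols; the square prism is the
cube, and the triangular antiprism shares the octahedron graph but keeps
its 2n-element prismatic rotation group, so both symbols are listed and may
produce coincident cages).

## Enumeration

At a hole-polyhedron vertex of degree E_h, a cage face distributes
P − E_h hole edges over its E_h corners, a_i ≥ 1 per corner.  A labeling of
all corners is connectivity-invariant iff its stabilizer inside the
rotation group is vertex-transitive, which holds iff the labeling is
constant on the corner orbits of some vertex-transitive subgroup.  The
enumerator therefore lists the minimal vertex-transitive subgroups (by a
closure search over the subgroup lattice; for the many solids whose
rotation group acts simply transitively the whole group is the only one)
and enumerates positive assignments on their corner orbits.  Completeness
is tested against a brute-force oracle that filters *all* per-vertex
compositions through the invariance definition on the solids small enough
to afford it.

Automorphisms are computed combinatorially on darts (directed edges) by
propagating a candidate image through the vertex-rotation and reversal
permutations; orientation-reversing automorphisms are obtained by
propagating against the rotation and are flagged.  Corner actions of
reversing elements are derived from the vertex and face images (the dart
image itself lands in the neighbouring face).

Two counting conventions are exposed:

* **orbit counting** (`named_distributions`): one representative per orbit
  of labelings under the full automorphism group.  This is the natural
  mathematical count — rotated copies of one diagram are identified — and
  it drives the catalogue, whose names must be unique;
* **diagram counting** (`diagram_assignments`): one entry per value
  assignment to each printed label diagram, merging only mirror-image
  assignments.  The two differ exactly where a rotation normalizes the
  diagram's defining subgroup while permuting its slots (tetrahedron,
  cuboctahedron).  This is the convention under which the published
  survivor total was compiled, so the census entry points default to it.

Names follow the `SYM_P<p>_a_b_...` convention: the leading label sits on
the base polygon for prisms/antiprisms, on the smallest face for
Archimedean solids (square for the snub cube, pentagon for the snub
dodecahedron), anywhere for Platonic solids; remaining labels are read
anticlockwise, minimizing lexicographically.  The octahedron's two diagram
families are distinguished as `Poc1`/`Poc2`; rare cube labelings that read
identically at a vertex receive a `_v2` suffix.

## Pruning constraints

Both necessary conditions are evaluated per hole with threshold deformation
κ_t = 0.1 (the 10% band used throughout):

* **angle-sum bound**: flattening the ring of sub-faces around a Q-gonal
  hole must open it, giving
  `P ≤ 2 Σ(q_i+1)/(Q−2) · (1 + κ_t (P−2)/2)`;
* **chord inequality**: the chord subtended by a face's run of q_k hole
  edges (regular P-gon geometry, all angles scaled by K) must satisfy, for
  every choice of the long side j,
  `A_j(K=1/(1+κ_t)) ≤ (1+κ_t)/(1−κ_t) Σ_{i≠j} A_i(K=1+κ_t)`.

The chord inequality is implemented exactly as printed in its source, with
a single uniform K per evaluation.  Under this form relaxation is not
provably monotone in κ_t; monotonicity is verified empirically over the
hole shapes arising in the census for κ_t ∈ [0, 0.3].  The census applies
both conditions; the survivor total under the diagram-counting convention
is 5538 for P = 6..17, against a published figure of 5743 — the residual
~4% gap persists under every documented convention variant we audited and
is attributed to unpublished details of the original pruning code.

## Realization

**Embedding.**  Each face starts as a rigid regular unit-edge P-gon on its
hole-polyhedron vertex at radius R chosen so neighbouring face centres sit
about one face diameter apart, rotated in-plane so shared-edge midpoints
face their neighbours.  Zero-rest-length springs between the two copies of
every shared-edge node are relaxed by alternating "average the copies" and
"rigid Kabsch re-fit" steps until the maximum copy gap stalls or falls
below 1e−9; copies are then merged at their midpoints.  The procedure is
deterministic.  For known regular cages it already lands on the exact
solution to machine precision.

**Minimization.**  The quality functional is

    Q = c_l Q_length + c_a Q_angle + c_p Q_planar + c_cf Q_ConvFace + c_cp Q_ConvPol

with defaults c_l = c_a = 1, c_p = 1000, c_cf = c_cp = 100 and reference
edge length L_f = 1 (all coordinates dimensionless in units of L_f).
Q_length and Q_angle are sums of squared deviations of edge lengths
(relative to L_f) and corner angles (radians) from the regular P-gon
values; the iso-weighting of the two is justified by the right-triangle
calibration (Δl)²/l² = (Δθ)², which the tests verify numerically.
Q_planar sums squared in-plane projections of the facelet normals
(facelet: triangle spanned by the face centre and two consecutive
vertices).  The two convexity terms count violations with H(0) = 0, so
boundary cases (straight corners, coplanar neighbours) are free: for face
convexity the reversed cross product (s_{i+1} × s_i)·F_f is negative at
convex corners and positive values are counted; for cage convexity the
default edge-midpoint form counts shared edges with
(d̂ + d̂′)·(M − O) < 0, and a stricter normal-tip variant
(tips of the face normals closer than their bases) is available per run.

Three minimizers cooperate:

* `metropolis_optimize` — seeded single-node Gaussian random walk on the
  full functional with geometric cooling and acceptance-rate-adaptive
  steps; the only stage that sees the integer convexity counters, used as
  a rescue when they are violated;
* `simplex_refine` — Nelder–Mead on the flattened coordinates;
* `polish` — the workhorse: the smooth part of Q is a least-squares
  problem in the node coordinates (length, angle and planarity residuals),
  minimized by a trust-region reflective solver with a sparse
  finite-difference Jacobian (each face's residual block touches only its
  own nodes).  This reaches machine-level stationarity in seconds, which
  the stochastic stages cannot, and is the package's own substitution for
  a purely stochastic protocol; convexity counters are re-checked after
  every polish.

The weight sweep relaxes the cage at `sweep_points` (default 100) values
of c_l/c_a log-spaced over [1e−2, 1e2] with c_l + c_a = 2, keeps the cage
minimizing max(Δl, Δa), and refines the surrounding bracket by
golden-section bisection on the log-ratio.  Reported metrics:
Δl = max|l − 1|, Δa = max|α − α₀|/α₀, and the pairwise face dissimilarity
maxima Ω_l, Ω_a under the best cyclic shift δ ∈ 1..P−1 of one face against
the other.

**Classification.**  regular: max(Δl,Δa) ≤ 1e−5 (regular constructions
relax to ≤1e−6; one order of slack for platform variation); near-miss:
≤ 0.1; rejected otherwise; overridden by *degenerate* when a hole has two
non-adjacent boundary nodes closer than 1e−2, or *self-intersecting* when
facelets of distinct faces intersect (Möller's interval test, ε = 1e−9 on
plane-side classifications; facelet pairs sharing a cage node are
structural contact and are skipped).

**Pinched collapses.**  Some topologies admit an exactly regular solution
in which holes pinch shut, and the deterministic polish finds it.  When
every pinched hole has all-equal edge contributions the collapse is a
ring-like cage folding flat — a minimizer artifact, not the cage's
character — and the realization is retried with a one-sided repulsion
`max(0, 0.1 − gap)` (weight 10) on non-adjacent hole boundary node pairs;
the retried cage is kept if it lands in the regular/near-miss band.  A
pinched hole with unequal contributions means a long edge run has merged
onto shorter ones, reducing the cage to a different, smaller-hole cage;
such cages are reported degenerate.  This reproduces the two published
behaviours (the heptagonal-prism P9 ring realizes as a near-miss; the
triangular-prism P8 1-1-3 arrangement is degenerate).  No automated
mapping to the equivalent cage is attempted.

## Problem sizes and determinism

Default test and census runs use reduced protocol sizes — sweeps of 3–9
points and a few bisection steps — chosen because the deterministic polish
makes the sweep landscape smooth, so a coarse sweep already brackets the
optimum; the full 100-point sweep is the configurable default for
production catalogues.  All stochastic stages draw from a single seeded
generator; identical configuration and seed give bit-identical output, and
independent seeds agree on max(Δl,Δa) to well within the 10% repeatability
band.

## What the synthetic fixtures do and do not show

Test fixtures are perturbed or deliberately broken versions of real cage
embeddings (Gaussian node noise, a pinched hole, a face reflected through
the centre), so incidence structure and orientation conventions are always
genuine.  They exercise the metrics, counters and detectors; they say
nothing about protein-level feasibility (edge lengths, dihedral
preferences or chemistry of real subunits are outside the model, which is
purely geometric).

## Known limitations

* The pruned-candidate total differs from the published census by ~4%
  under every convention we could reconstruct; the catalogue itself (which
  cages exist and how they classify) is unaffected by the counting
  convention.
* Global optimality of a realization is not guaranteed; the guarded-retry
  policy handles the observed collapse modes but other multi-basin
  topologies may still realize suboptimally.
* The two reflection-only Archimedean duals are excluded by construction;
  labelings invariant only via reflections are not enumerated.
* Hull convexity is enforced only through the pairwise face conditions,
  not by computing the hull.
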