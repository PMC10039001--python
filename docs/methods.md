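# Methods

This note records the mathematical model behind each component, the
parameter choices and their rationale, and the known limitations. All
coordinates are millimetres; volumes are reported in cubic centimetres.

## Landmark superimposition

**OPA** (ordinary Procrustes analysis) registers one configuration onto a
fixed target by translation, rotation and (optionally) scale. The optimal
rotation is the Kabsch solution: SVD of the cross-covariance of centred
coordinates with the sign of the smallest singular vector flipped when
needed, so the result is always a proper rotation — reflections are never
produced, since a reflected "fit" would be anatomically meaningless.
Configurations whose centred coordinates are rank-deficient (collinear
landmarks) raise `DegenerateGeometryError` rather than returning an
arbitrary rotation.

**GPA** (generalized Procrustes analysis) iterates OPA of every
configuration onto the running consensus until the consensus moves less
than 1e-10; with scaling, each configuration is standardised to unit
centroid size. Centroid size — the root summed squared deviation of
landmarks from their centroid — is the size variable throughout.

**Symmetrisation** reflects the configuration across the least-squares
plane through its midline landmarks, swaps left/right labels, registers
the relabelled reflection rigidly back onto the original, and averages.
The step is iterated to its fixed point (tolerance 1e-12, at most 20
iterations, always converging in a few), so the output is exactly
bilaterally symmetric and the operation is idempotent — properties a
single averaging pass only approximates.

## Thin-plate splines

The 3D TPS uses the kernel U(r) = r and solves the standard bordered
linear system (kernel matrix K plus affine border P). The fit requires at
least five non-coplanar source points and refuses duplicate sources by
name. Affine maps are reproduced exactly with zero bending energy; the
interpolation is exact at the landmarks.

**Sign convention.** With U(r) = r the quadratic form trace(WᵀKW) is
*negative* semidefinite on the admissible weights (PᵀW = 0), unlike the
familiar 2D r²·log r case. The bending energy is therefore defined as
−trace(WᵀKW), clamped at zero against rounding. This was caught by a
property test asserting positive energy for non-affine maps.

**Missing-landmark estimation**: the complete reference is registered
(with scaling) onto the target over the shared landmarks, a TPS is fitted
from the registered reference to the target over those landmarks, and the
reference's positions for the missing landmarks are mapped through it.
Estimated points are flagged in `estimated_mask`, which survives I/O, so
downstream analyses can always distinguish observation from inference.

## Fragment re-assembly

The protocol for re-assembling two disarticulated fragments against a
complete reference:

1. symmetrise fragment and reference sub-configuration (skipped with a
   warning when a fragment has missing landmarks or no usable pairing);
2. scale the reference once to the fragments' combined centroid size,
   computed pose-invariantly as sqrt(cs_a² + cs_b²) from each fragment's
   own centroid — the fragments' relative placement is unknown at this
   point, so no pose-dependent size measure is admissible;
3. register each fragment rigidly (rotation + translation only) onto the
   matching reference subset. A single global scale keeps the two
   fragments mutually consistent; per-fragment scaling would let the
   reference absorb real size signal.

Reference *ranking* measures, per fragment, the cumulative Euclidean
distance (sum over landmarks of pointwise 3D distances, in mm) after
symmetrisation, per-fragment scaling and rigid registration; the combined
score is the sum over the two fragments, with summed Procrustes distances
and then specimen id as deterministic tie-breakers. Incomplete references
are skipped with a warning rather than silently ranked on partial data.

`reconstruct_specimen` completes each fragment's missing landmarks from
the template, aligns, transforms the fragment meshes into the merged
frame, and finally estimates any template landmarks absent from *both*
fragments (bone destroyed along the break) so the merged configuration
always carries the template's full landmark set — required for projecting
reconstructions into the comparative shape space.

## Comparative shape space

GPA with scaling yields a unit-size consensus. Each specimen is centred,
scaled to unit centroid size, rotated optimally onto the consensus, and
projected orthogonally into the tangent space at the consensus (the
component along the consensus direction is removed). The principal
components are the exact covariance eigendecomposition of those tangent
coordinates (computed by SVD), with each eigenvector's sign fixed so its
largest-magnitude loading is positive.

The orthogonal tangent projection, rather than raw aligned coordinates,
is what makes three identities hold to machine precision: training scores
have zero mean, re-projecting a training specimen recovers its stored
scores, and the consensus projects to the origin. Under any
"OPA-register-then-subtract-mean" scheme these fail at ~1e-4: the mean of
unit-size shapes itself has centroid size below one, so the query path
applied to the consensus does not land on the stored centre.

Query specimens are projected through exactly the same path and never
alter the space. PC extreme maps warp a template mesh to consensus
± k·SD along one component (rendered at the template's centroid size) and
report the per-facet signed relative area change against the mean mesh —
positive where the extreme is locally inflated, negative where
contracted.

## Cranial capacity

The capacity of a target whose endocranial cavity cannot be segmented is
estimated by fitting a TPS from the reference's fixed landmarks (plus,
optionally, surface semilandmarks) to the target's, warping every vertex
of the reference's endocast mesh through it, and integrating the warped
mesh's signed volume (trimesh, divergence theorem) after normal repair;
non-watertight meshes are rejected with the offending boundary-edge
count. Identity transfers are exact and uniform scaling returns s³ times
the volume, both enforced by acceptance tests.

Surface semilandmarks are transferred by TPS on the fixed landmarks
followed by nearest-point projection onto the target surface, then slid
to minimise the TPS bending energy of the reference-to-target map: each
iteration solves the linearised quadratic (semilandmarks move in their
local tangent planes; fixed landmarks pinned), re-projects onto the
surface, and the best configuration seen is returned — energy is
non-increasing across accepted iterations, and two consecutive increases
stop the procedure with a warning. Three iterations are the default;
convergence is effectively complete after one or two on smooth surfaces.

## Occipital analysis and measurements

Group mean shapes are coordinate-wise means of GPA-aligned
configurations. Homologous point sets built from a shared triangulation
template yield meshes of identical topology, compared facet-by-facet as
signed relative area change. Midsagittal profiles intersect the mesh
with the midline plane, select the curve passing nearest both requested
endpoints, take the shorter arc on closed loops, and resample it to
equidistant points by arc length. The lambda–asteria angle is the angle
at lambda between the two lambda-to-asterion vectors; maximum cranial
breadth is the largest spread of signed distances to the midsagittal
plane over all mesh vertices, with the two achieving points reported.

## Contour polylines

The slicing frame is the unit glabella-to-opisthocranion chord; planes
sit at offsets k × spacing (default 2.0 mm, matching common practice for
vault profiling) from the opisthocranion toward the glabella, including
the chord length only when it is an exact multiple. Plane–mesh
intersections are chained into polygonal curves; on watertight input all
curves are closed (verified on spheres to < 0.5% radius error), and open
chains from defective meshes are kept but flagged with a warning.

## Discrete traits

Characters are strings with `?` for missing. `majority_state` collapses
a multi-individual sample to its per-character majority (ties → `?`);
`combine_pair` merges two individuals (disagreement → `?`);
`count_derived` counts derived states over scorable characters.
Pairwise distance is the mismatch proportion over mutually scored
characters. Neighbour joining follows Saitou–Nei with lexicographic
tie-breaking (deterministic output) and negative branch-length clamping
(deficit moved to the sister branch), recovering additive trees exactly.
Fitch parsimony treats `?` as the full observed state set. Exhaustive
maximum parsimony enumerates all unrooted topologies by stepwise
addition — capped at 10 taxa (2,027,025 topologies) because the count
grows as (2n−5)!!; 8 taxa (10,395 topologies) complete in seconds — and
reports all minimal trees plus their strict consensus (split
intersection). NEXUS I/O is a minimal DATA-block reader/writer,
round-trip tested and readable by dendropy.

## Synthetic generator

The template is a deformed ellipsoid with semi-axes (90, 70, 65) mm —
cranial order of magnitude — carrying a smooth, bilaterally symmetric
radial modulation (relative amplitude 0.03 by default; 0 gives the exact
ellipsoid so analytic volume oracles apply). It has 28 named landmarks
(8 midline, 10 bilateral pairs) snapped to the mesh, a 16/12
anterior/posterior split about a coronal cutting plane, and an occipital
patch of 5 fixed landmarks plus 150 Fibonacci-distributed surface
semilandmarks with a fixed Delaunay triangulation template.

Populations draw four groups with fixed mean landmark displacements
(6, 4, 8 and 12 mm for MPH, ERN, EWN, MOD) plus 1.5 mm isotropic
individual noise; each individual's mesh, landmarks and semilandmarks are
deformed by one TPS, so the deformation itself is the recorded ground
truth. Fragmentation partitions landmarks and mesh faces about the
cutting plane, discards a 2 mm exclusion band (no conjoining points
survive), and applies an independent recorded rigid motion per fragment.
Endocasts are inward-offset shells (default 8 mm) carried through the
individual's own TPS; for the unmodulated template their volume is
analytic. Characters evolve along a given tree with per-branch flip
probability 1 − exp(−rate × length).

These sizes (≈640-vertex meshes, 10–20 individuals, 150 semilandmarks)
are this package's own choice: large enough that every estimator's error
structure is visible, small enough that the full test suite runs in
seconds.

## Limitations

- The generator's shapes are smooth ellipsoid deformations; they exercise
  the machinery but do not mimic real cranial surface detail, sutures or
  taphonomic distortion.
- Capacity transfer inherits TPS extrapolation behaviour: accuracy
  degrades when the target is far outside the reference's shape range.
- Exhaustive parsimony is intentionally capped at 10 taxa; no heuristic
  search is provided.
- Nearest-point projection is brute force (no spatial index), fine at
  these mesh sizes but quadratic in principle.
- Headline values from external scan repositories are not recomputable
  offline; the acceptance suite is property-based on synthetic data with
  known truth instead.
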