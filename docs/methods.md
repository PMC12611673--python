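# Methods

## Scope and data contract

`platefit` consumes triangle surface meshes (STL, binary or ASCII) of a
bone and an osteosynthesis plate and produces a rigidly aligned, then
non-rigidly adapted plate plus fit metrics. All coordinates are
interpreted as millimetres; STL carries no unit metadata, so this is a
package-wide convention. DICOM import and bone segmentation are out of
scope — the bone STL is assumed to come from an upstream segmentation
tool.

STL files are read as raw triangle soup (one vertex record per facet
corner); welding is an explicit cleaning step so the file on disk stays
inspectable. Cleaning merges vertices within a weld tolerance (default
1e-6 mm — far below CT voxel size, so it only collapses numerically
duplicated corners), drops zero-area and repeated-index faces, and can
decimate to a target face count using edge-collapse with a quadric error
metric (collapse position chosen from the quadric minimizer and the
edge endpoints/midpoint; collapses that would flip a surviving face
normal are rejected). Decimation never increases face counts and keeps
decimated icosphere vertices within 2% of the radius of the original
surface in the test suite.

## Point clouds, normals, curvature

Surfaces are converted to point clouds by area-uniform sampling: faces
chosen with probability proportional to area, positions uniform in
barycentric coordinates (fold-over trick), ~10,000 points per surface by
default, deterministic per seed.

Normals are estimated per point as the smallest-eigenvalue eigenvector
of the covariance of its k nearest neighbours (k = 30 by default, robust
at 10k-point density on long-bone-scale surfaces). On a smooth, densely
sampled surface this direction converges to the analytic surface normal
(the cross product of the tangent gradients of any local
parameterization), which is why the discrete estimate stands in for the
analytic one; a point cloud has no u,v parameterization to
differentiate. Orientation is resolved either against an interior
reference point (normals flipped to point away from it — appropriate for
tube-like bones, using a medullary axis point or the cloud centroid) or,
absent a reference, by sign propagation over the minimum spanning tree
of the k-NN graph with the global sign chosen toward +z.

Local curvature is summarized by the surface-variation score
λ₀/(λ₀+λ₁+λ₂) over the ascending covariance eigenvalues: 0 on planes,
up to 1/3 for isotropic neighbourhoods. It is rigid-invariant but not
scale-invariant (the neighbourhood size changes with scale at fixed k),
which is acceptable because it is only used to *rank* candidate
landmarks on a single bone.

## Rigid alignment (ICP)

The plate is the moving source cloud and the bone the fixed target —
the clinically meaningful direction (the implant is adapted to the
anatomy, never the reverse). Each iteration finds nearest-neighbour
correspondences with a KD-tree (exactly equal to brute force), solves
the closed-form Kabsch/SVD least-squares rigid motion with reflection
correction, and composes it into the running transform. The recorded
per-iteration mean squared error is non-increasing: re-pairing can only
shorten distances and the solve is optimal for fixed pairs.

Termination is a dual criterion: relative MSE change below 1e-6 *and*
at least 20 iterations, plus a hard cap (200) to guarantee termination.
Two numerical guards: the relative change denominator is floored at
1e-30, and an absolute MSE floor of 1e-12 mm² (RMS 1 nm) counts as
converged, since below it the "relative change" is floating-point noise.
When correspondences are already exact the update is skipped so the
trace stays at exactly zero. No outlier trimming is performed — the
method is plain point-to-point ICP; trimmed and point-to-plane variants
are out of scope. The initial pose is the identity unless a 4×4
transform file is supplied (the non-interactive stand-in for manual
landmark placement).

## Non-rigid adaptation (TPS)

The deformation field combines an affine part with radial basis
functions U(r) = r² ln r at N control points, one scalar field per
output coordinate sharing the kernel matrix — a stacked 3-column solve
of the bordered system [[K + λI, P], [Pᵀ, 0]]. The r² ln r kernel is
used as specified even though the classical 3D biharmonic kernel is
|r|; an "r" kernel option is provided for comparison. U(0) = 0 (the
continuous limit of r² ln r).

Control-point selection is fully automatic for reproducibility, with a
manual CSV override: bone points are ranked by curvature score and
accepted greedily subject to

- a pairwise spacing floor (default 2% of the bone bounding-box
  diagonal) that conditions the kernel matrix,
- a contact-strip gate: only bone points within `max_pair_distance` of
  the plate are eligible, defaulting to twice the 95th percentile of
  the plate-to-bone nearest distances. Without this gate the
  highest-curvature anatomy (condyles) can lie far from the plate, and
  nearest-plate pairing would then drag plate edges across the bone —
  a non-physical warp,
- a source-side spacing floor (a quarter of the target spacing) so two
  bone landmarks never share one plate point, which would make the
  interpolation system inconsistent.

Each accepted bone point (target) is paired with its nearest plate
point (source). N defaults to 40 within an enforced 30–50 policy band.

The linear system is solved by minimum-norm least squares rather than a
direct factorization: a *flat* plate — the common case — has exactly
coplanar control sources, which leaves the affine block rank-deficient
even though the interpolation problem remains consistent; the
pseudoinverse picks the solution with no component along the affine
null space. After a λ=0 fit the control-point residual is verified and
a residual above 1e-6 mm (relative to target scale) raises a
degenerate-geometry error, which is how genuinely singular
configurations (coincident or collinear sources) are reported.

λ defaults to 0 (exact interpolation). Increasing λ trades control-point
accuracy for smoothness; the bending energy Σ_coords wᵀKw is exposed as
the standard diagnostic for over-deformation between sparse landmarks.

An optional pre-warp stage blends each plate point toward its nearest
bone point by a factor α ∈ [0, 1]. This closest-point projection blend
is **not** an angle-preserving (conformal) parameterization and is
documented and disabled by default; it exists to shrink large gaps
before the spline when a user wants it.

## Fit metrics

The gap cost is the plain sum Σ_j min_i ‖p_j − q_i‖ over plate points;
because a sum scales with sampling density, mean and max gaps are
reported alongside, and the RMS distance is the primary per-stage
summary (the convention of mm "error" figures in this field is not
standardized, so all three are reported). Penetration is detected per
plate point by the sign of (p − q)·n_q against the outward normal at
the nearest bone point, with a 1e-6 mm tolerance band — a point-cloud
test, not triangle-level boolean collision, because point clouds are
the pipeline's native representation. An optional corrective step
pushes penetrating points outward along the local normal to a requested
clearance.

## Synthetic geometry

The generator emulates the geometry that drives the registration
problem, not anatomy per se:

- **Bone**: a watertight tube swept along a circular-arc axis (chord =
  `length`, maximum lateral deviation = `bow_sagitta`), radius
  `shaft_radius`, with `condyle_count` Gaussian radial bumps (amplitude
  0.6·`condyle_radius`, width `condyle_radius`/2) near one end and
  optional Gaussian radial noise. Defaults: length 300 mm, shaft radius
  15 mm, sagitta 8 mm, two condyles of radius 25 mm, no noise, ~4000
  faces. The dimensions loosely follow a large-animal femur shaft; they
  are package conventions chosen so millimetre tolerances are
  meaningful, not measurements.
- **Plate**: a strip (default 100 × 20 mm, ~1500 faces) triangulated
  from a 2D parameter grid plus 16-vertex annular rings marking screw
  holes, optionally bent so the across-width coordinate becomes arc
  length on a cylinder of radius `arc_radius`.
- **Canonical pose**: the plate is placed tangent to the shaft
  mid-section on the convex (bowed) side with a clearance of 0.5 mm +
  3·noise_sd, which keeps the pose penetration-free; a known rigid
  displacement applied on top of it provides ground truth for
  registration tests.

What the generator does **not** emulate: real cortical-surface texture,
segmentation artifacts, partial scans/holes, anisotropic CT noise, and
anatomical shape variation. Passing tests therefore demonstrate
algorithmic correctness (exact recovery, monotone convergence, metric
equivalence, interpolation structure) and qualitative behaviour
(stage-wise improvement), not clinical accuracy figures on real femora.

## Problem sizes and numerical choices

The test suite and the acceptance study use 1,500–8,000-point clouds
and 600–4,000-face meshes, sizes at which brute-force oracles (O(N·M)
distance scans, closed-form sphere tests) remain exact and fast while
the behaviour being checked — convergence, monotonicity, interpolation
— is size-independent. The end-to-end study uses the default bone and
plate with a 5° / (2, 1, 0) mm displacement and 6,000-point clouds;
ICP removes ~90% of the initial RMS error and the TPS warp a further
~18% (see `scripts/acceptance.py`).

Tie-breaks and degenerate inputs: curvature-rank ties break by point
index; KD-tree nearest-neighbour ties follow the tree's deterministic
ordering; sampling a zero-area mesh, ICP on empty clouds, TPS with
fewer than 4 pairs, and rank-deficient rigid fits all raise typed
errors rather than returning garbage.

## Known limitations

- The warp treats the plate as a surface; plate thickness, screw holes
  as geometry, and mechanical plausibility (bending stiffness of a real
  implant) are not modelled.
- Point-to-point ICP needs a reasonable initial pose; global or
  feature-based coarse registration is out of scope.
- The r² ln r kernel in 3D is a modelling choice kept for fidelity, not
  the variational thin-plate solution in 3D (that would be |r|); both
  interpolate exactly at λ=0.
- Penetration detection is first-order (signed projection at the
  nearest sample) and can misclassify within ~one sampling distance of
  the surface.
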