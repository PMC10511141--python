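# Methods

`tetfield` builds boundary-fitted tetrahedral volume-conductor meshes from a
nested stack of closed triangle surfaces, computes EEG lead fields on them
with linear finite elements, and evaluates source localization against an
analytic concentric-sphere model.  This note records the model assumptions,
the parameter choices that matter, and the numerical decisions taken where
the design was genuinely open.

## Mesh generation

**Lattice and five-tet subdivision.**  The initial mesh is a regular cubic
lattice covering the segmentation's bounding box plus a padding margin
(default 3 mm); the lattice origin is snapped so the model centroid sits at
a cell center, making meshes reproducible regardless of absolute
coordinates.  Each cube is split into five tetrahedra (one central, four
corner tets); cubes of odd integer-coordinate parity use the mirrored
split, so that face diagonals of adjacent cubes coincide.  This is the
minimal conforming cube subdivision and avoids the uniform diagonal
direction of six-tet splits, which would imprint a directional bias on the
smoothing and inflation stages.

**Solid-angle labeling.**  A node is inside a closed surface when the
normalized subtended solid angle `s = (1/4pi) sum_f Omega_f` reaches a
threshold `T` (default 0.5; values at exactly `T` count as inside).
Per-triangle angles use the van Oosterom-Strackee arctangent formula,
which is robust next to the surface where the underlying surface integral
is nearly singular; a point coinciding with a triangle vertex skips that
triangle (the limit value).  A tetrahedron is claimed by a compartment when
all four nodes are inside its surface; compartments claim in
innermost-to-outermost priority order, so intersecting boundaries resolve
to the inner (higher-priority) tissue, and unclaimed elements keep the
bounding-box label 0.

*Far-field acceleration.*  Classification cost is dominated by nodes far
from any boundary, where the answer cannot change under small surface
perturbations.  Each surface therefore carries a decimated proxy; the
symmetric vertex-to-surface distance between surface and proxy plus both
maximum edge lengths bounds the Hausdorff distance, and any node provably
farther from the surface than this margin is classified against the proxy
with the identical solid-angle rule.  This is exact, not approximate: the
winding number of a point outside the slab between the two surfaces is the
same for both.

**Refinement.**  Boundary refinement is red/green: tets touching a flagged
compartment interface (one node suffices, on both sides of the interface)
are split into eight children through edge midpoints, with the interior
octahedron split along its shortest diagonal (ties broken by smallest node
index pair).  Neighbours with one, two or three split edges on a single
face are closed with 2-, 3- and 4-child templates; configurations not
coverable by one face are promoted to red and the closure loop iterates to
a fixed point.  Face subdivisions are decided canonically per face (quad
diagonals by length, then index), so the templates on the two sides of any
face agree and no hanging nodes remain.  Children inherit labels and child
volumes sum exactly to the parent volume.

**Re-labeling.**  After refinement, labels of tets adjacent to any
inter-label interface are re-derived from the node classifications until a
sweep changes nothing (cap 20 sweeps, warning on hitting the cap).  Node
classifications depend only on position and the fixed segmentation, so
they are cached per node and evaluated lazily for refinement midpoints;
a re-labeling sweep is then pure label logic.

## Post-processing

**Taubin smoothing.**  Forward step `x += lambda (mean_N(x) - x)` followed
by a backward step with `-mu`, with `lambda = mu = 0.4`.  The stopping rule
compares the step displacement norm against the norm of the invocation's
initial configuration, with tolerance `xi = 0.9` for volumetric and
`xi = 0.1` for surface smoothing; with these values smoothing performs a
single forward/backward pair per invocation, which in practice removes the
worst lattice staircase without eroding features.  Volumetric smoothing
moves all interior nodes (neighbourhoods are edge-connected nodes); surface
smoothing moves interface nodes within their interface sheet only.  Hull
(bounding-box) nodes are always fixed -- the box plays the role of an
outermost compartment precisely to prevent shrinkage of the scalp.

**Inflation.**  After labeling, each compartment's FE boundary lies
strictly inside its segmentation surface.  Boundary nodes of the region
formed by each compartment together with everything of higher priority move
along the incident mesh edge whose intersection with the segmentation
surface is nearest, by a fraction `zeta = 0.05` of the distance to that
intersection, for up to 10 passes (the pass count is this package's
choice).  Movement by a fraction < 1 of the remaining distance can never
cross the surface.  Intersections are Moller-Trumbore segment tests against
candidate triangles from a centroid KD-tree; candidates are gathered once
per compartment with a slack radius covering all later motion, since labels
(and hence the boundary topology) are fixed during inflation.

**Element condition and optimization.**  Element quality is
`kappa = V / l_max` (mm^2), dimensional and therefore resolution-dependent;
the reporting cut 0.01 mm^2 matches the histogram cut used for the
distributions.  Inverted elements (negative orientation) are repaired by
retracting each offending node halfway toward the centroid of its
edge-connected neighbour set, iterated to a positive state.  Then 2-3 face
flips are applied to pairs of adjacent same-label tets whose smaller
condition is below `tau = 0.01 mm^2`, worst first, only when the apex-apex
edge pierces the shared face (so the three new tets exactly tile the pair)
and the pairwise minimum condition strictly improves.  Faces between
different labels are never flipped, protecting the fitted boundaries; this
restriction is this package's choice.

## EEG forward model

P1 (linear) tetrahedral elements discretize
`div(sigma grad u) = div J_p` with the insulating Neumann condition; the
conducting domain is the union of labeled compartments (the bounding-box
label is excluded), assembled in SI units.  The stiffness matrix is
symmetric positive semi-definite with the constants as null space; solves
ground one node and results are average-referenced, which fixes the gauge
equivalently to explicit deflation.  The transfer-matrix strategy computes
one solve per electrode (`A t_e = R^T delta_e`) and forms `L = T^T G`;
solves use conjugate gradients preconditioned with an in-package zero-fill
incomplete Cholesky factorization (relative residual 1e-8), since direct
sparse factorization of 3D stiffness matrices becomes impractical beyond
roughly 10^5 nodes on one workstation.

**Dipole realization.**  The default divergence-conforming source expresses
a dipole through the four lowest-order Raviart-Thomas face functions of its
host tet, with minimum-norm coefficients matching the prescribed dipole
moment over each function's full two-tet support.  A classical
partial-integration point dipole (`g_i = q . grad phi_i`) is available as a
cross-check flag; on a single tet the two coincide analytically, and they
agree to a few percent RDM for interior sources in the tests.

**Source space.**  Dipole positions are sampled uniformly in volume over
"admissible" tets of active compartments: tets that neither touch an
inter-compartment interface by a node nor are node-adjacent to such a tet,
since a dipole next to a conductivity jump degrades the forward accuracy
disproportionately.  Orientations are either three Cartesian unit vectors
or a single constrained direction along the outward normal of the
compartment boundary (realized as the direction to the closest boundary
point).

**Error measures.**  `RDM = || J1/||J1|| - J2/||J2|| ||` (topography,
range 0..2) and `MAG = 1 - ||J1||/||J2||` (amplitude), both on
average-referenced electrode vectors, FEM vs the analytic oracle at
matching positions and orientations (matched rather than randomized
orientations: randomization only adds variance to the comparison).

## Analytic sphere oracle

The multilayer concentric-sphere potential is evaluated as a Legendre
series; per degree the radial coefficients solve the small interface
continuity system directly (exact to truncation), in outer-radius-scaled
coordinates for conditioning.  Default truncation N = 200 with automatic
extension at eccentricity > 0.9 and a tail-convergence check that raises
rather than returning unconverged values.  The homogeneous special case has
a generating-function closed form, kept as an independent oracle for the
series path.  Standard three-shell parameters: radii 87/92/100 mm,
conductivities 0.33/0.0042/0.33 S/m, 180 evenly spread scalp electrodes
(Fibonacci lattice).

## Inverse methods

**Regularization.**  With noise and prior covariances proportional to
identity (`nu` = 3% of the maximum data amplitude; prior 20 dB above it),
the weighted least-squares problem reduces to Tikhonov form.  The bare
dimensionless ratio of the two standard deviations ignores the scale of
the lead field and in practice under-regularizes by orders of magnitude,
so the default convention scales the noise-to-prior ratio by
`sqrt(mean diag(L L^T))`: `lambda = (nu/theta_0) * scale`, i.e. `lambda^2`
is 1% of the mean sensor-covariance eigenvalue scale at 20 dB prior SNR.
The bare ratio is retained under `convention="ratio"` for cross-checks.

**sLORETA.**  MNE standardized by the resolution kernel
`S = L^T (L L^T + lambda^2 I)^-1 L`: scalar diagonal for constrained
sources, symmetric inverse square root of the 3x3 diagonal block for
free-orientation sources (reducing to the scalar formula when dof = 1).

**EMD.**  Localization error against a known dipole is the earth mover's
distance between the normalized reconstruction mass and a unit point mass
at the truth; with a point target the optimal transport collapses to the
mass-weighted mean distance (closed form, cross-checked against a general
OT linear program).  The mass assignment is method-specific: amplitude
reconstructions use squared per-source amplitudes (the same weighting the
GMM stage defines); the dipole scan's goodness-of-fit map is a fit
statistic whose values concentrate near 1 and carry no mass
interpretation, so its mass is the position posterior obtained by
marginalizing dipole amplitude and noise variance from the Gaussian model,
`w_l proportional to (1 - g_l)^(-(m-d)/2)` for m channels and d
orientation degrees of freedom.

**GMM.**  Source points weighted by squared amplitude are summarized with
full-covariance weighted Gaussian mixtures (in-package EM, 5 seeded
restarts, k-means++-style seeding).  Candidate cluster counts grow while
any non-negligible weight lies outside every component's 95%
Mahalanobis radius; the final count minimizes BIC computed from the
weighted log-likelihood at the effective sample size `1 / sum w_i^2`.
Cluster size is reported as the 90% chi-square credibility ellipsoid
volume.

## Synthetic data and what passing tests show

The sphere fixtures reproduce the classical three-shell geometry exactly
(icospheres rather than UV spheres, to avoid polar triangle clustering that
would bias labeling statistics), with the high-contrast skull that makes
the forward problem hard.  Synthetic measurements add i.i.d. Gaussian noise
with standard deviation `10^(dB/20)` of the maximum clean amplitude (-30 dB
is the 3.16% level, conventionally quoted as "3%").  A folded-blob surface
with random low-order spherical-harmonic invaginations stress-tests
labeling and fitting on non-convex anatomy.  What these fixtures do not
emulate: open or self-intersecting segmentation surfaces, anisotropic
conductivity, realistic cortical folding at sub-millimeter scale, sensor
miscalibration, or correlated measurement noise -- passing tests therefore
demonstrate correctness of the algorithms and their convergence behaviour,
not clinical-grade accuracy on real head anatomy.

## Problem sizes

The test-suite and reproduction runs use sizes chosen for a single
workstation CPU: the full boundary-fitted 3.0 mm three-shell pipeline
(~4.6 M tetrahedra) for the fitting-distance figures; 5.0 mm and 8.0 mm
lattices with 180 electrodes and 600 free-orientation sources for the
forward-accuracy and localization experiments.  Finer meshes (2.0 and
1.3 mm, tens of millions of elements) follow the same code paths and
improve the forward errors further, at correspondingly larger memory and
run times.  At the 5 mm scale two localization artifacts are visible that
vanish with refinement: the admissible-source rim sits about 5 mm inside
the highest-eccentricity ring, flooring the boundary-ring EMD of the
dipole scan, and the coarse source spacing makes the scan's deep argmax
artificially stable, so the scan's EMD does not grow toward the center the
way the amplitude methods' does.

## Known limitations

Surface decimation is shortest-edge collapse with manifold and normal
guards (adequate for the smooth segmentation surfaces targeted here; a
quadric error metric would preserve sharp features better).  The extracted
boundary of a labeled region can pinch at edges where two same-label tets
meet diagonally; it is closed in the divergence-theorem sense but not
always a strict 2-manifold.  Electrodes are nearest-node point
measurements; no complete-electrode model.  Conductivities are isotropic
scalars.  Single-time-slice data only.
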