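# Methods

## Coordinate and sign conventions

Every segment frame is right-handed with +x cranial, +y dorsal, +z
right-lateral; all coordinates are millimetres, all file-level angles
degrees. In the reference pose (all joint angles zero) the limb hangs fully
extended ventrally, so each segment's long axis points along local −y and
all joint centres align vertically.

Joints rotate in the fixed order FLEXEX → ABAD → LAR with no translations:
FLEXEX about +z (positive flexes the hip, extends the knee, dorsiflexes the
ankle), ABAD about +x (positive adducts), LAR about +y (positive is medial/
internal rotation of the right limb with the femur vertical). The hip is a
3-DoF ball-and-socket; knee, ankle and metatarsophalangeal (MTP) joints are
single-axis hinges. Because moment arms inherit these senses through
`r = −dL/dθ`, figure-level conventions (knee flexion negative, hip extension
negative, …) emerge without per-muscle sign flips.

## Joint placement

Hip centres are the superposition of spheres fitted to the femoral head and
acetabulum; when the two fitted centres differ the mean is used and the
discrepancy recorded (the reconciliation is otherwise unspecified in the
source anatomy). Knee/ankle centres are the long-axis midpoint of a cylinder
fitted to the condylar surfaces. Fitting is automated least squares —
algebraic seed plus geometric Gauss–Newton refinement for spheres;
multi-start (PCA-axis-seeded) Levenberg–Marquardt for cylinders — rather than
manual placement, for repeatability; manually chosen centres can always be
written directly into the model spec. Hinge-axis polarity is disambiguated by
making the fitted axis face right-laterally.

Cartilage and other unmodelled arthrological tissue is represented by
translating the child segment distally along the parent's long axis by a
fixed fraction of the parent's reference length: 0 at the hip (centre in the
middle of the acetabulum), 5% at the knee, 7.5% at the ankle. Offsets
therefore scale linearly with the model, and normalized moment arms are
scale-invariant (a tested property).

## Muscle paths and wrapping

An MTU path is origin → via points → insertion, each point fixed in a
segment frame. Straight segments that contact an assigned wrapping surface
are replaced by the shortest tangent–geodesic–tangent route:

- **Cylinder** — solved in the cross-section plane; the axial coordinate is
  distributed linearly along the unrolled path, which is the exact geodesic
  (unrolling is an isometry). A `wrap_side` vector makes the wrap mandatory:
  the path must pass the obstacle on that side even when the chord clears the
  surface. Without a side, contact-only wrapping with the shorter direction.
- **Sphere** — tangents plus a great-circle arc in the plane through the two
  endpoints and the centre (the shortest route; engages on penetration only).
- **Ellipsoid** — the problem is mapped affinely to the unit sphere
  (tangency of a line to a quadric survives affine maps), the spherical
  solution seeds an on-surface polyline, and interior points are relaxed
  (neighbour averaging + reprojection) until the per-pass length improvement
  falls below 1e−4 × mean radius. This is a discretized shortest-path
  approximation, adequate because moment arms depend on dL/dθ, which the
  relaxation resolves far below the finite-difference step.

Surfaces are treated as infinite (cylinder) or complete (sphere/ellipsoid)
obstacles; `half_length` is descriptive. One obstacle acts per straight
segment (the first assigned surface that engages).

## Moment arms, sweeps, normalization

`r = −dL/dθ` is evaluated by a central finite difference with step 0.25°.
The default stencil is 5-point (fourth order): with the 3-point stencil the
O(h²) truncation error at 0.25° is ~3e−6 relative, too coarse for the 1e−6
oracle agreement this package promises; the 5-point stencil reaches ~1e−8
while remaining a central difference. Both step and order are arguments.

Sweeps run on a 1° grid across fixed ranges of motion: hip FLEXEX −45…65°,
hip ABAD −45…0°, hip LAR −30…+30°, knee −90…10°, ankle 0…90°, MTP fixed at
0°. Non-swept DoFs sit at locked defaults — hip ABAD −15° (limb clearance of
the belly), hip LAR 0°, hip FLEXEX 0° (femur vertical) — for every sweep,
extending the stated FLEXEX-sweep convention to ABAD and LAR sweeps; the
defaults are overridable per sweep. The curve is reduced to its unweighted
grid mean (the source reduction is stated only as "a mean"), divided by the
reference length of the femur (hip), tibiotarsus (knee) or tarsometatarsus
(ankle). Two-headed muscles (IT2 generally; PIFI2 in crocodylians; ITC in
dinosaurs) contribute the arithmetic mean of their sub-head means.

## Ancestral states under Brownian motion

For a trait vector x over the n = 13 tips, the ML state at an internal node
is the GLS mean `â = (1ᵀV⁻¹1)⁻¹1ᵀV⁻¹x` with V the Brownian covariance of
the tips for the tree re-rooted at that node; V is built from pairwise path
lengths as `V[i,j] = (d(node,i) + d(node,j) − d(i,j))/2`. Confidence
intervals follow the re-rooting estimator convention of the comparative-
methods literature: node variance `(1ᵀV⁻¹1)⁻¹ × Σcontrasts²/(n−1)` (the
squared-contrast sum equals the GLS quadratic form and is invariant to the
rooting), interval `â ± 1.96 sd`. The implementation reproduces the
reference R routine for this estimator to printed precision (a frozen
cross-check lives in the test suite), and matches a brute-force explicit
re-rooting GLS oracle to 1e−8 on all small test trees. The reported global
rate σ² is the ML (1/n) estimator.

A known calibration limitation, measured rather than hidden: with the rate
estimated from only 13 tips, the normal-quantile interval behaves like a
t₁₂-based pivot, so the true node state falls inside the nominal 95% CI in
≈92.4% of Brownian simulations on the study tree. This is a property of the
estimator convention itself (P(|t₁₂| ≤ 1.96) ≈ 0.926), not of the
implementation; the acceptance script reports the measured coverage.

Lost muscles enter trait vectors as 0 (matching the downstream treatment of
losses as zero leverage); a missing-data mode exists but is off by default.
The ITC — an innovation of Dinosauromorpha — takes the crocodylian IF/IFE
value in taxa that predate it (policy `copy_ife`, configurable), so the
trait is defined back to the root.

The punctuated sensitivity variant sets every branch length to 1 and reruns
the identical machinery.

## The study tree fixture

The packaged Newick encodes the 12 named internal nodes (Archosauria →
Phasianidae main line, Dromaeosauridae off Eumaniraptora) and 13 tips with
branch lengths in Ma. Topology follows the text-derivable structure of the
study phylogeny; divergence and tip dates are round literature values and
the file is plain text, deliberately editable — every computation takes the
tree as input rather than assuming these dates.

## Trend statistics

Direction membership is decided per node by the sign of the muscle's ACE
there, so a switching muscle migrates between the opposing sums — the only
reading consistent with annotating switches at all. Ratios: H1 hip
extension/flexion, H2 knee flexion/extension, H3 hip medial LAR/abduction
(numerator and denominator from different DoF families). Internodal changes
are `(Rᵢ₊₁−Rᵢ)/Rᵢ × 100` along the main line, with Dromaeosauridae compared
against its parent and reported separately; the overall change runs
Archosauria → Phasianidae. Thresholds are applied to unrounded values at
≥20% (reliable) and ≥10% (notable); reliable implies notable. Zeros in
switch detection inherit the nearer nonzero neighbour's sign (earlier node
on ties); extrema tie-break toward the earlier node and are flagged.
Verdicts: H1 "constant" iff no reliable main-line change; H2/H3 "supported"
iff the overall change has the predicted sign and at least one reliable step
in that direction exists.

## Synthetic data: what it emulates, and what it does not

The generator produces the three inputs the pipeline needs with closed-form
answers recorded in sidecar files (never derived from the engine under
test):

- **Pulley muscles** — attachments on the joint's sagittal axis plane and a
  mandatory-side wrap cylinder keep the tendon fully wrapped across the
  entire range of motion, so |r| equals the wrap radius exactly; the default
  radius is 0.1421 × femur length, the proportion knee wrap surfaces follow
  across the real model set. The hip pulley is exact only in the sagittal
  configuration (ABAD = LAR = 0): the −15° ABAD lock moves the attachments
  out of the cross-section plane and `r = R·planar/L < R`, so exactness
  claims at the hip are tested with ABAD overridden to 0, and programmed
  clade trends ride on the knee/ankle pulleys, which proximal joint posture
  cannot perturb.
- **Straight-line muscles** — ground truth from the perpendicular-distance
  (axis · cross-product) formula.
- **Clade schedules** — per-tip multipliers on pulley wrap radii program
  exact leverage trends (a 50% linear decline by default), and wrap-side
  mirroring programs action switches.
- **Brownian simulation** — root-to-tip Gaussian increments with variance
  σ² × branch length, true internal states retained, fully seed-driven.

Default geometry uses theropod-ish proportions (femur : tibiotarsus :
tarsometatarsus = 1 : 1.1 : 0.6) — cosmetic only. What passing tests show is
that the engine, estimator and trend logic are correct against analytic
truth; they do not show that any real taxon's leverage was recovered — real
anatomy (scan-derived attachment sites, manual wrap placement) is exactly
the input the synthetic models replace.

One consequence worth naming: an ancestral estimate is a weighted average,
so a trend programmed linearly across the *tips* is recovered shrunken at
the *nodes* (the mock clade's programmed −50% decline is recovered as
≈−43%). The end-to-end test budget of ±10 percentage points covers this
regression-to-the-mean, not engine noise (which is ~1e−8).

## Problem sizes

Default analysis and acceptance runs use the 13-tip study tree, a 1° sweep
grid, a 0.25° differentiation step, 50 randomized straight-line oracle
muscles and 2,000 Brownian replicates — sizes at which every quantity above
is reproduced in seconds while Monte Carlo error on the coverage estimate
stays below ±1 percentage point.

## Known limitations

- Joints are ideal (fixed centres, no translations, 1-DoF hinges distally);
  muscle force, activation and dynamics are out of scope by design.
- Ellipsoid geodesics are approximate (discretized relaxation); cylinders
  and spheres are exact.
- One wrapping obstacle acts per path segment; stacked obstacles on a single
  segment require an intermediate via point.
- The CI coverage of the ancestral estimator is inherently ~92–93% at
  n = 13 (see above); treat the intervals as the reference convention, not
  as exactly calibrated probability statements.
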