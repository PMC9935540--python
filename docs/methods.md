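# Methods

This note documents the models, conventions and numerical choices behind
clawfsa, in the order data flows through the pipeline, and states what the
synthetic benchmarks do and do not demonstrate.

## Coordinate and unit conventions

All meshes live in a local claw frame: +x proximodistal (distal positive),
+z dorsoventral (dorsal positive), +y mediolateral.  Units are fixed as
mm / N / MPa (1 N/mm² = 1 MPa); Young's modulus entered in GPa is converted
by ×1000.  Internal node/element indices are 0-based; the INP and MSH
dialects are 1-based on disk.  Boundary facets are stored with outward
orientation.

## Meshes and measurement

`TetMesh` stores nodes, positively oriented tetrahedra, the oriented
boundary triangulation, and named regions: `articular` (nodes; the fixed
joint facet), `ventral` (boundary facets), `tip` (nodes).  INP `*NSET`
blocks populate node sets; a facet set of the same name is derived as all
boundary facets whose three nodes lie in the set (the writer inverts this
convention).  Degenerate (zero-volume) tets are rejected at read time
rather than repaired, because silent repair corrupts the per-element
volumes that the intervals method weights by; inverted tets are repaired
by a logged vertex swap.

Claw measurements: L is the extent along the first principal axis of the
node scatter — for curved claws a chord-like extent, not arc length, since
no axis convention for fossil claws is standard.  D and W are measured at
the claw base, in the basal cross-section's own plane: the `articular`
node set when present, else the end slab spanning 10% of the axial span at
whichever end has the larger cross-section (claws taper distally).  D is
the in-plane axis whose unit vector has the largest |z| component, ties
broken toward +z.  Measuring depth/width at the articular end follows
standard claw morphometrics and, unlike global extents, is immune to
centerline-curvature sagitta, which otherwise inflates the depth of a 60°
claw by ~10%.  Volume is computed by the divergence theorem over the
oriented boundary and equals the sum of signed tet volumes for closed tet
meshes; for open surfaces the volume is reported absent with a warning.
The bound volume ≤ L·D·W holds for distally tapering claw-like shapes
(whose basal section is maximal), not for arbitrary geometry.

Scaling to a common surface area (factor s = sqrt(target/current), about
the node centroid) precedes cross-specimen FE comparison so equal total
forces are comparable; volumes scale by s³.

## FE solver

4-node constant-strain tetrahedra, isotropic linear elasticity
(default E = 20.49 GPa, ν = 0.40, cortical bone), direct sparse LU of the
reduced system.  Constraints: the articular nodes are fixed in all three
translations — the simplest well-posed reading of "constrained at the
articulation", matching common claw-FEA practice; per-component masks are
also supported (the patch test uses rollers).

Scenario loads are defined so the resultant magnitude equals the requested
total force exactly: per-facet vectors area × inward unit normal are
rescaled globally by F/|resultant| and spread equally over facet corners.
Directions are a modelling choice (only locations are conventional):
substrate reaction along inward (dorsal-pointing) normals for the two
ventral scenarios, and the proximally directed distal tangent of the claw
axis for piercing.  The tip is the distal 5% of the axial parametric
coordinate by default (configurable); a facet belongs to the tip if it
touches that region, so coarse meshes still load a non-empty patch.  On
meshes without parametric coordinates the `tip` region set is used, and
the piercing direction falls back to the first principal axis oriented
distally.

Validation: the uniaxial patch test reproduces vm = F/A to ~1e-14; rigid
rotation of mesh+loads leaves vm unchanged to <1e-6; doubling the force
doubles vm exactly; scaling geometry by s with fixed force scales vm by
s⁻² to <1e-9.  The cantilever benchmark (100×10×10 mm, 200 N end load)
recovers tip deflection within 5% of FL³/3EI and root-fiber bending stress
within 10% of FLc/I on a 40×8×8 lattice.  Two numerical choices matter
there: (i) the lattice is split 24 symmetric tets per hex (face+body
centers) because the biased uniform 6-tet split is ~3× stiffer in bending
at this resolution (14.5% deflection error, 10.5% even at ν = 0) and would
mask solver correctness with discretization stiffness; (ii) the bending
stress is recovered by regressing σxx on fiber height in the second
element layer and extrapolating linearly to the surface fiber and the root
section — element-centroid stresses sit inside the section and a one-layer
offset avoids the Poisson-restraint concentration at the clamp.  The
residual deflection gap also contains real shear deflection (~0.8% at
L/h = 10) absent from the Euler–Bernoulli reference.

## Intervals method

Pipeline order is fixed as trim → bin → log → standardize → PCA.
(Standardizing before the log, which one could read into the phrase
"normalised … then log-transformed" in the intervals literature, is
ill-defined for the non-positive values standardization produces; the
implemented order is the numerically meaningful one.)

* **Trim**: whole elements are removed in descending stress order while
  the removed volume stays ≤ the trim fraction of total volume (default
  2%, allowed 0–5%).  Trimming by volume with whole elements keeps the
  remaining field a valid element set.
* **Bin**: 50 equal-width intervals (default) over [0, pooled post-trim
  maximum across the batch].  A shared global upper bound is required for
  cross-model comparability; per-model bounds would make the vectors
  incommensurable.  Interval i accumulates element volume with stress in
  [eᵢ, eᵢ₊₁), last interval closed; stresses above an imposed global bound
  are accumulated into the last interval with a warning.  Percentages are
  relative to the pre-trim volume, so sum + trimmed = 100 exactly.
* **Log**: log(p + c) with c = 0.01 percentage points (configurable);
  empty intervals are common, so a plain log is undefined.
* **Ordinate**: zero-variance columns are dropped, the rest standardized
  to unit variance (correlation PCA), and all simulations from all
  specimens are ordinated jointly — triangles are only comparable within
  one ordination.  Deterministic signs: PC1 is flipped, if needed, to
  correlate non-negatively with the simulations' volume-weighted mean
  stress (giving quadrant semantics: low-stress quadrant II, high-stress
  quadrant I); every other component has its largest-magnitude loading
  made positive.

Choosing 50 intervals is an accuracy/speed balance: on 30-field synthetic
batches, 50- vs 100-interval ordinations give pairwise-distance matrices
correlated >0.99, so finer binning does not change the geometry of the
space.

## Functional triangles

Area by the shoelace formula; centroid as the vertex mean; side lengths
Euclidean in (PC1, PC2).  The sign of a directed side is +1 when the
terminal scenario's stress field is higher than the initial one's, −1 when
lower, 0 within 1e-9 MPa (configurable).  "Higher stress field" is
operationalized as the volume-weighted mean von Mises stress of the
underlying simulation: PC1 position is a proxy but depends on the
ordination, whereas the mean stress is intrinsic to the simulation.  Note
the sign convention's verbal reading is slippery — a positive
"A to B" side means B (the terminal function) performed *worse*; prose
descriptions that equate negative sides with "A shows lower stress than B"
invert this and should be checked against the rule, which this package
applies literally.  Quadrants use the half-open rule (0 counts as
positive) so axis-sitting points classify deterministically.

## Total evidence

`regress_ols` is ordinary least squares with optional log transforms
(default base 10 — the natural choice for allometric "log volume" axes;
the base is configurable and affects only slope/intercept, not R² or p).
R² is the squared Pearson correlation; p is the two-sided slope t-test
with n−2 df, undefined at n = 2.  Missing values are dropped pairwise per
regression.

The morphospace PCA is fitted on the log reference ratios only (covariance
PCA; component signs fixed by the largest-loading rule); study records are
projected as supplementary points, leaving reference scores untouched.
Since log(L/W) = log(L/D) + log(D/W) identically, the three ratios span a
plane: the third component carries zero variance and two components are
retained by default.  "Morphological divergence" is the Euclidean distance
from a designated baseline record in that plane (the baseline is an
explicit argument; no canonical choice exists).  "Functional divergence"
is intrinsic per record and emitted both as triangle area and as a named
signed side.

## Synthetic data generator

The generator emulates what CT-derived claw meshes provide to the
pipeline — a watertight tet mesh with articular/ventral/tip regions and
a stress field per scenario — with exactly known ground truth.

Geometry: a solid elliptical cross-section swept along a circular arc in
the sagittal plane (curving ventrally), tapered by (1−u)^taper toward an
apex node, with optional seeded per-section jitter.  Cross-sections are
structured grids mapped square→ellipse by x = p·sqrt(1−q²/2),
y = q·sqrt(1−p²/2) (boundary nodes lie exactly on the ellipse); hexes are
split with the uniform Freudenthal 6-tet template, which is conforming on
structured grids, and the tip closes with a pyramid fan.  The 6-tet
template was chosen over alternating-diagonal schemes for provable
watertightness; its directional stiffness bias is irrelevant here because
generated stress fields are drawn, not solved (FE-solved fields use the
fe module, and the validation benchmark uses the symmetric 24-tet split).
A 32×16 straight cone reproduces πr²L/3 within 0.2%; the self-intersection
bound (base half-depth < 0.95 × centerline radius) rejects over-tight
arcs.  Defaults — 50 mm length, 60° arc, 12×8 mm base section, taper 1 —
are a mid-sized, moderately curved theropod-like ungual.

Stress fields are i.i.d. per element (lognormal by default, gamma or
constant available) so distributional ground truth is exact; spatial
correlation of real FE fields is deliberately absent.  Benchmark cohorts
span linear D/W, arc and stress-scale gradients with per-scenario
multipliers; the manifest records every ground-truth value, and
`resample_fields` redraws fields on fixed geometry for replicate
experiments.  Lognormal sigma defaults to 0.5 (~50% coefficient of
variation, of the order seen across elements of solved claw fields).

All randomness flows from explicit seeds through `numpy.random.default_rng`;
equal seeds give bit-identical meshes, fields and CSV outputs.

## What the synthetic benchmarks show — and what they don't

Passing tests demonstrate that the machinery is correct and that the
pipeline recovers known orderings: imposed scenario multipliers reappear
as side signs (in ≥95% of seeded replicates at realistic noise), 2×
mean-stress separations are linearly separable on oriented PC1, and
imposed stress–shape couplings yield significant regressions.  They do not
validate biological conclusions: i.i.d. fields lack the spatial stress
gradients of real claws, generated geometries do not mimic particular
taxa, and absolute stress levels from the volumetric tet solver need not
match shell-element studies.  Keratin sheaths, contact, plasticity and
dynamic loading are out of scope.

## Problem sizes

Default test and acceptance runs use cohorts of 5–12 claws at 12×6
generator resolution (~2.6k tets each), 800–1500-element synthetic fields,
100-replicate recovery experiments, and the 40×8×8 cantilever (61k tets
after the 24-tet split) — sizes chosen so the whole validation suite runs
in well under a minute apart from the cantilever solve.
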