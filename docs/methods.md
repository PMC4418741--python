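# Methods

This note records the models behind each stage, the defaults and why they were
chosen, what the synthetic data does and does not emulate, and the numerical
choices a user should know before trusting a number.

## The synthetic phantom

The phantom is a capped cylinder (default: outer radius 10 mm, length 60 mm,
cortical shell 2 mm) whose interior carries concentric cancellous density
classes, decreasing inward — the axially concentric density pattern seen in
well-preserved long-bone fossils.  Default class densities are the
conventional four-class table (1.6, 1.4, 1.2, 1.1 g/cm³) with cortical bone at
2.06 g/cm³.  Greyscale is density × gain (100 grey per g/cm³) plus Gaussian
noise, default σ = 2% of the dynamic range.  Two defect types are planted:

* a **pathologic fracture**: a dark sheet ≈2 voxels thick on a paraboloid
  patch concentric with the cortical shell, strictly interior (default 0.8 mm
  beneath the inner shell surface, on the lateral side of the proximal end),
  with distal slip sense;
* **taphonomic cracks**: dark slabs 5 voxels wide that intersect the outer
  surface, placed in the distal half with entry points spread in angle so
  components stay separate.

Two imaging regimes are deliberately separated.  `generate_phantom` renders
*bulk densities* (each class one grey level): in this regime the analytic mass
(closed-form shell + annuli integral) and exact label recovery are meaningful
oracles.  `generate_trabecular_volume` renders *resolved microstructure*: a
Gaussian random field smoothed by an anisotropic kernel
(σ_axis/σ_transverse = anisotropy ratio; transverse σ = 1.5 voxels) and
thresholded at the (1 − BVF) quantile, so the realised bone volume fraction is
exact up to voxel-count rounding.  Real trabecular bone is a network of
plates and rods, not a thresholded random field; the generator reproduces the
*statistics* the MIL method measures (volume fraction, orientation, elongation)
but not trabecular connectivity or thickness distributions, so passing fabric
tests demonstrates estimator correctness, not biological realism.  The bone
volume fraction of the motivating fossil is unknown; the default BVF = 0.3 is
simply a mid-range mammalian-like value and is a free parameter, not a
reconstruction.

The tetrahedral phantom is a structured cube grid clipped to the capped
cylinder (cubes ranked by signed distance of their centres; the
round(V/h³) most-interior kept, so the mesh volume matches the analytic
volume to within half a cell) and split into six Kuhn tetrahedra per cube —
translation-invariant, hence conforming, with a 45° minimum dihedral angle.
The jagged lateral surface is the price of reproducibility without an external
mesh generator; loads are always distributed over node patches by tributary
area, which makes the staircase harmless in practice.  Elements take the
density of the class containing their centroid.

## Segmentation and crack classification

Bone/background uses iterative intermeans (ISODATA): the fixed point of
t ← (mean below + mean above)/2, started from the sample mean.  The original
workflow's "adaptive iterative thresholding" is a proprietary tool setting
with no published formula; ISODATA is our stated stand-in, not asserted to be
identical.  Class cuts default to equal-count quantiles of the within-bone
histogram — a reproducible replacement for a qualitative manual choice — and
can be overridden with explicit cuts.

The bone mask is the iso-threshold foreground closed morphologically
(26-neighbourhood, 3 iterations, computed on a padded array so the border is
not eroded) and hole-filled, so dark crack interiors stay inside the bone.
Crack voxels are those in the mask darker than mean − 2σ of the segmented
(bright) bone; components use 26-connectivity; component width is twice the
median Euclidean distance to the component exterior (for a planted 2-voxel
sheet this yields 2.0).  Surface contact is measured on the distance transform
of the mask (contact ⇔ within 2.5 voxels of the exterior) because the closing
can pad a crack mouth by a voxel or two.  Classification follows the field
rule: pathologic ⇔ width ≤ 2.5 voxels *and* surface contact over at most 1% of
the component (a real pathologic fracture may near the surface at a groove);
otherwise preservational.  All constants are keyword arguments.

With the default noise and the 0.1 g/cm³ gaps of the density table, the
per-voxel Bayes error between adjacent classes is not negligible; label
accuracy should therefore be assessed away from greyscale values within ±2σ of
a cut (the noise-blurred class boundaries).  The noiseless phantom segments
exactly.

## Fabric analysis

Orientations are a Fibonacci lattice on the upper hemisphere (z = (i+½)/n —
no two points collapse under antipodal identification), rigidly rotated by a
seeded random rotation.  Defaults mirror high-density practice: 2049
orientations, 2000 points; the studies in the test-suite use 129/300, which
recover a ratio-3 fabric axis to ~1°.

MIL line casting walks the voxel grid exactly (Amanatides–Woo traversal; ties
at cell corners advance z, then y, then x), counting bone↔void transitions
between consecutive visited voxels; chord length comes from the ROI box
intersection.  A scalar brute-force walker in the test suite must agree with
the vectorised implementation's crossing counts *exactly*.  MIL(n) = total
chord length / total crossings, in mm.  The ellipsoid fit nᵀHn = 1/MIL² is
linear least squares in the six tensor components; at least nine directions
spanning 3-space are required, and fabric magnitudes are 1/√eig(H).

DA of an isotropic phantom is biased slightly above 1 (it is a ratio of
extreme eigenvalues of a noisy tensor); at the test-suite sampling density the
bias stays below 1.05.  The estimator is validated by parameter recovery, not
against any particular specimen: a fossil's printed DA cannot be reproduced
without its scan.

## Materials

E = 0.001 ρ^1.3266 (GPa, kg/m³) for cancellous classes, rounded to the nearest
0.5 GPa when mapping a table; ν = 0.3.  Cortical bone is fixed at
ρ = 2.06 g/cm³, E = 20,000 MPa, ν = 0.4 — the regression is a cancellous-bone
fit and is not extrapolated to compact bone.  The reference table carries one
documented inconsistency: the 1.6 g/cm³ class is conventionally tabulated at
17,500 MPa, while the regression rounds to 18,000 MPa.  `reference_table()`
reports both and flags the row; nothing silently corrects it.
Homogenisation is Σρᵢvᵢ/Σvᵢ over cancellous classes.  Internally the FE stack
works in mm/MPa/N; densities convert at the interfaces.

## Finite elements

Constant-strain (4-node) tetrahedra with isotropic linear elasticity match the
low-order meshes of image-based bone FE.  CST passes the patch test exactly
and converges monotonically, but is stiff in bending: the slender-cantilever
verification (L/d = 10, 11×11×90 cells) underestimates the Euler–Bernoulli tip
deflection by ≈4%.  Quantities that compare two models on the *same* mesh
(the heterogeneous/homogeneous harness, the fracture-regime ranking) are
insensitive to this bias; absolute strains inherit it.

Solves use a sparse direct factorisation, reused across load cases with the
same restraint pattern, with prescribed (possibly nonzero) displacement
support.  Global equilibrium (Σ reactions + Σ applied) is checked on every
solve; residuals are at round-off (≤1e-10 relative).  Von Mises strain uses
the (1+ν)-normalised deviatoric form, so in any uniaxial state it equals
σ_vm/E — the convention assumed when comparing to a yield strain.  Stresses
are MPa, tension positive; strains are reported in με.

The five canonical regimes restrain translation at a small node set at the end
centres (all nodes within 2% of bone length of the end face and near its
centroid): compression/tension/torsion load the proximal face (torsion as an
exactly net-force-free tangential couple) with the distal centre fixed;
bendings apply a transverse midshaft surface load with both end centres fixed.
The articular-cartilage device used in the original workflow (a stiff-beam
tessellation) is replaced by tributary-area force distribution over the loaded
patch, which serves the same purpose — suppressing point artifacts — without
beam elements.  Mean von Mises "brick strain" per regime is the unweighted
element mean (SD alongside); the volume-weighted variant is also emitted
because the convention is ambiguous in the literature.

## Fracture-regime inference

The fracture surface is carried as analytically sampled points with outward
normals and in-plane slip directions (distal sense).  Two scores, each in
[0, 1], with combined score C1·C2:

* **C1 (strain localization).**  H = proximal-half elements with von Mises
  strain ≥ 50% of the proximal peak.  C1 = restriction × coverage, where
  restriction is the fraction of H within 3d of the surface and coverage the
  fraction of surface samples with an H element within d
  (d = 1.5 × mean element edge).  Defining H relative to the field's own peak
  makes the construction independent of mesh size and load magnitude.  Both
  factors are needed: restriction alone is saturated by a concentrated
  (bite-like) load sitting over one corner of the fracture, and coverage alone
  is saturated by diffuse bending fields.  On the recovery phantom the true
  distributed load scores ≈0.28 combined against ≈0.11 for a point load at the
  same location.
* **C2 (shear consistency).**  Over elements within d of the surface, the mean
  of three indicator fractions: angle(σ₁₁, plane) ≥ 45°; angle(σ₃₃, plane)
  ≤ 45°; angle(σ₂₂, plane) ≤ 30° and angle(σ₂₂, slip) ≥ 60°.  The thresholds
  encode "high angle / low angle / parallel / perpendicular", which the
  underlying field criteria leave qualitative; all four are parameters and are
  reported with results.  Elements with numerically degenerate principal
  values (hydrostatic states) are counted and reported as a degeneracy
  fraction.

The search replaces manual trial-and-error with a grid: angular sectors of the
proximal-third lateral surface (default 12 patches, half-width 1 rad) crossed
with a direction cone about the distal axis (15° rings to 45°; 25 directions).
The stiffness is factorised once; by linearity the magnitude (default 56.1 N)
cannot affect the ranking, which is asserted in tests.  Absolute C1/C2 values
are implementation-defined; the module's validation is recovery (the planted
regime must rank first) and negative controls (point loads, wrong-side
patches), never a printed score.

## Mechanics chain

All closed forms use g = 9.8 m/s² by default (configurable).  Exact values are
always computed; "printed" variants reproduce the quoting conventions of the
worked example this chain follows: force to 3 significant figures (1,122 →
1,120 N), equivalent mass to the kg, the free-fall distance rounded to 0.1 m
before adding the deceleration distance (0.836 → 0.85 m), and the
lighter-animal height to the nearest 10 cm.  For the lighter animal the
deceleration distance (body depth) is rescaled isometrically,
s_d ∝ m^(1/3) — the natural reading of "scaled to the smaller body", and the
one that reproduces the quoted ≈110 cm.  The inverse map
F = m·g·(s_h − s_d)/s_d round-trips with the forward chain to 1e-9.

## Problem sizes and determinism

The test-suite and demonstration runs use desk-scale sizes chosen as the
smallest at which each contract is comfortably observable: ~12–20k element
meshes (fossil-scale meshes run ~10⁶ elements), 64³ trabecular volumes,
129 orientations × 300 points for fabric, 8 patches × 9 directions for the
search.  Every stochastic stage takes an explicit seed; phantoms are
bit-reproducible for a fixed seed, and the tet mesh is fully deterministic
(geometry only).  The pipeline writes a manifest (config hash, seed, package
version, per-stage artifacts and timings) sufficient to reproduce a run.

## Known limitations

* CST stiffness bias (above); no geometric/material nonlinearity, contact or
  impact transients — the impact is handled by the quasi-static linear-scaling
  argument.
* The phantom's bulk-density regime has no partial-volume blur; real CT class
  boundaries are softer than the planted ones.
* Crack width from the median distance transform underestimates the drawn
  width of tilted slabs (staircase edges); classification is robust to this
  because surface contact dominates the rule.
* Isometric body-mass scaling assumes equal shape between the subject and the
  reference animal; the resulting masses are bounds, not estimates with
  uncertainties.
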