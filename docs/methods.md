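# Methods

## Problem and idealization

The package simulates posteroanterior (PA) lumbar traction: semi-cylindrical
rollers beneath a bed mat lift into the lower back of a supine subject in
nine uniform steps of 62/9 mm (62 mm at the top level, TL9), and the
quantities of interest are the per-disc mean von Mises stress and equivalent
strain as functions of traction level and BMI class.

The subject is modeled as a **mid-sagittal plane-strain slab** (x
craniocaudal, y posteroanterior; mm–MPa–N units). PA loading, lordosis and
layer shielding act dominantly in the sagittal plane, and a 2D model keeps
every solve on one CPU in seconds. The cost of the reduction is quantified
below ("Known limitations").

## Phantom

The phantom is a layered stack standing in for a segmented mid-sagittal MRI.
Because the subject lies supine, the posterior skin is flat (back flattened
against the mat) and the lordosis lives in the spine: the vertebral column
follows an anterior-convex sin² arc of depth 20 mm over 270 mm — a supine
(partially flattened) lordosis — carried by a paraspinal muscle band whose
thickness grows by the arc toward mid-lumbar levels.

Layer thicknesses (posterior to anterior): skin 1 mm; subcutaneous fat 13 mm
(normal BMI); soft tissue 15 mm; muscle 30 mm (+ lordosis bump); spinal
canal strips — epidural fat 4 mm, CSF 4 mm, cord 8 mm (optional; their
mechanical influence on disc ROI stress is second order); vertebral column
35 mm deep, with seven 30 mm vertebral bodies (T12..S) alternating with six
10 mm discs; anterior soft tissue 25 mm. Body length is 380 mm: the 270 mm
column plus 55 mm soft margins on each side standing in for the adjacent
thorax and pelvis. Only skin and fat thicknesses come from the imaging
protocol the phantom emulates; the remaining dimensions are textbook adult
lumbar anatomy and all are exposed in `PhantomSpec`.

**BMI classes.** Higher-BMI phantoms are derived exactly as higher-BMI
anatomies are derived from a normal scan: the fat layer is dilated outward
along the skin normal to 26 / 52 / 86 mm and the ~1 mm skin recovered
outside it. With a flat posterior skin the normal offset is vertical, so
dilation composes exactly (13→26→52 ≡ 13→52), can never self-intersect, and
leaves every deeper tissue coordinate bit-identical — properties the test
suite asserts. In the assembled scene each phantom is positioned 0.1 mm
above the mat, so the roller travel is identical across classes and the
extra fat depth lies between the mat and the spine.

**Meshing.** A structured, mapped, conforming triangulation: layer
interfaces and vertebra/disc boundaries are mesh lines; each quad cell is
split into two straight-sided 6-node triangles whose midside nodes bisect
the corner edges. Region interfaces therefore share nodes by construction
and each element carries exactly one region label. The default target edge
is 4 mm (≈16k elements, ≈32k DOF for the normal phantom); halving it moves
every disc-average stress at TL9 by under 2 %, which is why 4 mm is the
default. Quadratic (T6) elements with 3-point quadrature avoid the
volumetric locking that linear triangles exhibit at the ν = 0.49 typical of
soft tissue. Construction is deterministic: identical specs give
bit-identical meshes.

## Materials

All tissues are isotropic linear elastic (the reference device simulations
make the same assumption): skin 160 MPa, muscle 7, soft tissue 23.5,
vertebrae 17 000, disc 17, subcutaneous/epidural fat 3, cord/dura 10 (all
ν = 0.49 except bone at 0.30), CSF specified as K = 2250 MPa at ν = 0.499
with E = 3K(1−2ν) = 13.5 MPa. Densities are stored for completeness; the
quasi-static solver does not use them. For conditioning, Poisson ratios are
capped at 0.495 when building constitutive operators (config-overridable);
at this geometry scale the disc ROI response is insensitive to the CSF ν.
The disc is homogeneous (no annulus/nucleus split), matching the single
published disc modulus.

The bed mat is not in the tissue table: default E = 5 MPa, ν = 0.3,
thickness 10 mm (foam pad; config-exposed).

## Actuator and contact

The traction map is exactly u(TL) = TL·62/9 mm, honoring the printed 62 mm
maximum (9 × "approximately 6.9 mm"). Two rigid rollers of radius 25 mm sit
at x = 160 and 220 mm — centered under the L2–L4 vertebral span, where the
device produces maximal traction — with their apex 4·62/9 ≈ 27.56 mm below
the mat underside at rest. This clearance is the one calibrated quantity:
it reproduces the observed onset of tissue response between TL4 and TL5
(response is identically zero through TL4).

**Mat as an elastic foundation.** The foam pad is represented as a
unilateral elastic foundation riding on the rollers: the effective rigid
indenter radius is R + t_mat and the contact stiffness is the pad's
constrained modulus per thickness, in series with the interface penalty.
This retains the pad's two mechanically relevant features — spacing and
serial compliance — without meshing the strip. A meshed deformable mat with
two node-to-segment pairs (roller–mat, mat–skin) was implemented first and
rejected: the floppy 10 mm strip between two frictionless penalty
interfaces made the quasi-static Newton iterations chatter irrecoverably,
while the pad's bending stiffness (E = 5 MPa) contributes negligible load
spreading. With the mat disabled (`include_mat: false`) the bare roller
meets the skin through hard contact.

**Contact algorithm.** Node-to-rigid-circle penalty on the posterior skin
nodes with consistent (Simpson) tributary lengths along the quadratic
boundary, a C¹-regularized positive-part traction law (removing the
active-set kink that stalls semi-smooth Newton), and the consistent
curvature term of the circle in the tangent (clamped so overshooting
iterates cannot make it indefinite). Tangential behavior is exactly
frictionless. For hard contact the penalty is kept moderate
(penalty_factor × E_soft / element size) and an augmented-Lagrange (Uzawa)
outer loop drives the residual penetration below 0.01 mm and the
complementarity defect |gap × traction| below 0.05 MPa·mm; for the
foundation law the overlap is the physical foam compression and multipliers
stay zero.

## Solver

Quasi-static incremental solve, one increment per traction level by default
with automatic bisection on non-convergence. The default kinematics is
updated-Lagrangian: geometry updated after every converged increment,
small-strain kinematics and stress accumulation within each — capturing the
first-order geometric effect of a 62 mm lift (and the observed nonlinear
stress-vs-TL growth) without a finite-strain formulation. A strict
small-strain single-step mode exists for verification against linear closed
forms and for configurations whose local compressions would distort the
updated mesh. Within an increment a modified Newton iteration (LU reused
while the residual contracts) converges the out-of-balance force below
rtol = 1e-6 of the external force norm. The linear solver is a sparse
direct factorization with deterministic ordering: repeated runs are
bit-identical.

Boundary conditions: zero translation on the anterior aspect of the cranial
and caudal end faces. The default fixes the anterior-most 90 % of each end
face: the faces stand in for the removed thorax/pelvis continuation, and a
small patch would let the truncated segment swing vertically as a near-rigid
body instead of deforming locally. No gravity/body-weight preload is applied
(the reported quantities are traction-induced stresses).

**Verification.** Five analytic benchmarks run in the test suite and via
`patraction verify`: linear patch test (exact to machine precision),
slender-cantilever tip deflection vs PL³/3EI (≤ 5 %), Hertz line contact
half-width and peak pressure for a rigid cylinder on a deep block (≤ 10 %),
sparse-vs-dense solve equivalence on a ≤ 200-DOF system (≤ 1e-10), and
work-vs-strain-energy balance on a frictionless solve (≤ 1 %).

## Analysis

Quadrature stresses/strains are linearly extrapolated to element nodes and
averaged per node within each region (so disc-boundary nodes are not
contaminated by the 1000× stiffer vertebrae); the reported value is the
arithmetic mean over the disc's node set. Von Mises uses the full tensor
including the plane-strain σ_zz = ν(σ_xx+σ_yy); the strain scalar is the
von-Mises-equivalent strain √(2/3 e:e) of the deviatoric strain. Percent
shielding of a BMI class is 100·(1 − mean/mean_normal) aggregated over all
six discs and the post-onset levels TL5–TL9; on the packaged reference
tables this aggregation reproduces the published ~79 % severe-obese
reduction at TL9 (78.5 % by table arithmetic), anchoring the convention.

## What the synthetic phantom does and does not capture

The generator emulates the *structure* of the segmented anatomy — tissue
inventory, layer ordering, fat-dilation procedure, lordotic column with six
discs — not a specific subject's geometry. Passing tests therefore
demonstrate the mechanics of layered shielding and PA distraction, not
patient-specific stress values. Real anatomy additionally has curved,
subject-specific interfaces, inhomogeneous discs, posterior bony elements
and facet joints, and out-of-plane structure; none are represented.

## Known limitations

* **2D depth decay.** Contact stress under a long roller decays roughly
  like 1/depth in plane strain but like 1/depth² for the localized 3D
  contact bulb of the real torso. The simulated BMI shielding is therefore
  correctly ordered but smaller in magnitude (~8/24/41 % vs the full-scale
  3D model's ~14/51/79 %); stiffer end restraints can reproduce the 3D
  magnitudes but then violate stress-level plausibility and monotonicity,
  and were rejected.
* **Disc ranking.** In 2D the entire hold-down shear flows through the thin
  (35 mm) column, slightly elevating the outermost discs (T12-L1, L5-S)
  above the mid-lumbar ones; the 3D reference, whose disc shear areas are
  ~100× larger, ranks L2-L3 highest and T12-L1 lowest. The simulated
  profile is flat to mildly U-shaped.
* Linear elastic tissue at tens of percent strain; no viscoelasticity,
  anisotropy or poroelasticity; rigid rollers; stationary lift phase only
  (no craniocaudal scanning); single phantom per BMI class, so no
  statistical inference.
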