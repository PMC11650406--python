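# Methods

## Model and assumptions

PFA lesion formation is treated as a threshold phenomenon in the
instantaneous electric field: tissue with |E| above a lethal threshold
(default 600 V/cm) is electroporated. Because power and field are
instantaneous quantities, catheter designs can be compared without any
knowledge of pulse shape, width, repetition or train structure; only the
electrode geometry, its placement, and the vectoring (which electrodes
source and sink each delivery) enter the computation. All deliveries are
therefore modeled as independent static solves of the electro-quasistatic
volume-conductor equation ∇·(σ(|∇φ|)∇φ) = 0. Tissue capacitive effects at
PFA pulse time scales are neglected, as is electrode–electrolyte interface
impedance, Joule heating as a temperature field, and bubble/arc
electrochemistry (electrode current density serves as the conventional
proxy for the latter two).

The lesion of a sequence of deliveries is the union rule: per voxel, the
maximum |E| across deliveries is compared with the threshold. This is the
standard dose assumption for sequential identical pulse trains.

## Phantom

Real anatomy is replaced by two synthetic voxel phantoms (isotropic
spacing, voxel-centered coordinates; physical position = origin +
(index + 0.5)·spacing):

* **slab** — myocardial plate (default 2.5 mm) over connective background,
  blood above. Used for closed-form validation and single-panel field
  structure studies.
* **antrum** — a revolved profile: a cylindrical vein lumen (radius 10 mm)
  flaring through a cosine funnel into a blood chamber (radius 22 mm),
  everywhere wrapped by a myocardial shell of uniform 2.5 mm thickness,
  embedded in a 64 mm cube of connective background. The shell is
  constructed with a Euclidean distance transform of the blood pool
  (offset by half a voxel, since the transform measures to voxel centers),
  which makes the thickness uniform along surface normals, including the
  funnel and the chamber floor cap.

The target is the full-thickness wall inside a circumferential band,
6 mm axially × 47 mm of arc measured on the mid-wall circle (nominal
volume 6 × 47 × 2.5 = 705 mm³; the voxelized band matches this within one
voxel layer). The band subtends about 240° of the default vein, mirroring
a posterior-antrum target that covers most of the circumference.

What the phantom deliberately omits: patient-specific chamber shape,
esophagus, aorta, lungs and other discrete organs (a homogeneous
background absorbs them), wall-thickness variation, and non-ideal catheter
contact. Consequently the pipeline's absolute efficiencies and currents
are not comparable to values computed on CT-derived anatomy; the
meaningful outputs are cross-design *orderings* and arithmetic identities,
and the tests/acceptance script score exactly those.

## Conductivities

Defaults (S/m): blood 0.70, myocardium 0.20, connective background 0.10,
balloon insulator 1e-5 (a floor that keeps the discrete system
non-singular while making insulator current negligible). These follow the
standard tissue-property compilations; only the ratios drive the
comparison, and the table is overridable via YAML.

Field-dependent conductivity is a monotone sigmoid,
σ(E) = σ₀·(1 + A/(1 + exp(−(E − E_mid)/k))), defaults A = 2, E_mid =
500 V/cm, k = 80 V/cm, applied to myocardium only. The fold change A is
signed and configurable: the bulk-tissue electroporation literature
reports a conductivity *increase* upon membrane permeabilization, and
that is the default sign, but a decrease can be configured for
sensitivity studies. The comparison pipeline's default keeps all tissues
linear (A = 0): with a fixed field threshold and linear response, every
field map scales exactly with drive current, so one unit solve per
delivery determines all metrics, and the cross-design ordering is
unaffected. The nonlinear path (Picard iteration) is fully implemented
and exercised on slab cases in the test suite.

## Catheters and vectoring

Electrodes are rasterized in a band-surface chart (s = circumferential
arc on the endocardial surface, t = axial position, d = depth into the
blood pool), then clipped to blood voxels — ideal tangential contact with
no tissue displacement. Published dimensions are the parameter defaults:
circular 3 × 1.6 mm rings with 3.7 mm gaps (pitch compressed to close the
loop on the default lumen); penta-spline 4 × (1.3 × 3 mm) rings per
spline at 3/3/4 mm gaps, five splines, rings of a spline forming one
electrical node; flex/balloon 3.6 × 3.6 mm plates every 6 mm on 4 mm
splines; focal sphere 9 mm diameter with 0.127 mm struts, flattened to a
6 mm contact disc; one-shot sphere of six diamond-latticed panels in
conforming wall contact (renderings of these devices show them deformed
to the anatomy, so panel patches follow the wall). Thin struts that
cannot be resolved at 0.25–0.5 mm voxels become single-voxel chains; the
ECD denominator always uses the analytic strut/plate/cylinder area, never
the inflated voxel area.

Vectoring follows each device's published scheme: circular — one
interlaced bipolar delivery, alternating polarity around the loop;
penta-spline — bipole rotating spline-to-adjacent-spline five times per
application, two applications with an intervening rotation; flex/balloon
— wide-interlaced (alternating active polarity with inactive electrodes
between), two deliveries per application, two rotated applications;
spheres — monopolar, each placement/panel sequentially energized against
a 50 × 50 mm return patch on the boundary face opposite the target.

Accounting follows the ideal-deployment convention: only energy applied
by near-target electrodes is counted. A positive electrode is "on
target" when its center lies inside the band footprint (with a small
inset at the band edge); angular layout offsets are fixed so the default
deployment reproduces the published on-target vector counts — one-shot 3,
focal sphere 7, penta-spline 6, circular 3, flex/balloon 8. Off-target
deliveries are omitted from the solves: they neither reach the band nor
enter the accounting. When one delivery drives several simultaneous
vectors of which only some face the target (the circular loop: five
anodes, three on the band), its generator power enters the efficiency
denominator apportioned by on-target vectors / positive electrodes.

Multi-placement designs (7 focal placements; the rotated second
application of penta-spline and flex/balloon) live in one electrode set
with a placement index; masks from different placements may overlap in
space because they are never energized together, and electrodes not in
the active delivery are removed from the system entirely (a no-op rather
than a floating equipotential — a documented simplification). Disjointness
and ≥ 1-blood-voxel separation are enforced within each co-deployed group.

## Solver numerics

Finite-volume 7-point stencil on the uniform grid; face conductances use
the harmonic mean across material boundaries, making the scheme
conservative by construction. Active electrode voxels carry Dirichlet
values ±V/2; all outer boundaries are insulating (the return patch, when
present, is itself an electrode). Systems up to 40k unknowns are solved
by sparse direct factorization; larger ones by Jacobi-preconditioned
conjugate gradients (relative tolerance 1e-8). Joule power is computed
per face, g·(Δφ)², and attributed half to each adjacent voxel, so power
partitions over disjoint regions sum exactly to Σ I·V; electrode currents
are the face-flux integrals around each Dirichlet region.

Nonlinear runs use under-relaxed Picard iteration (relaxation 0.7,
σ evaluated at cell-centered |E|, convergence at max relative σ change
< 5e-3, at most 50 steps), wrapped in a secant iteration on the applied
voltage until the prescribed current is met within 0.1%. Linear runs
solve once at unit voltage and scale exactly. Degenerate inputs
(single-polarity deliveries, zero current, all-insulator paths,
unresolvable walls, footprints exceeding the phantom) raise before any
solve; Picard/secant non-convergence raises with the residual history.

Validated closed forms: parallel-plate uniform field (exact to solver
precision), sphere-in-concentric-shell spreading resistance
R = (1/a − 1/b)/(4πσ) — the finite-domain form of the classic 1/(4πσa),
which it approaches as b grows — with discretization error ~5.5% at
0.5 mm and decreasing under refinement, discrete current balance and
power conservation (machine precision by construction).

## Problem sizes and defaults

The comparison pipeline defaults to the 64 mm antrum phantom at 1.0 mm
voxels (262k cells, 21 counted-delivery solves across the six designs,
about half a minute total), a deliberate desk-scale operating point; the
phantom builder accepts 0.1–1.0 mm and the validation suite runs slabs
at 0.5 and 0.25 mm. Per-vector reference current 10 A; dose-current
search over 2–70 A by bisection to 1% relative width, with levels
unreached at 70 A reported as "not achieved" rather than raised. The
90% transmurality criterion counts voxel volume above threshold
(the literal volume rule, not per-column full-thickness columns).

## Known limitations

* The focal-sphere and one-shot panel metal areas follow from this
  package's parametric strut layouts (meridian/parallel mesh; ±45°
  diamond lattice) and are smaller than the published cage areas, whose
  finer lattice geometry is not public. ECD magnitudes for the two
  spheres inherit that difference; their orderings do not.
* Inactive electrodes are absent rather than floating conductors; a
  floating metal body would locally channel current and slightly
  redistribute near-electrode fields.
* One efficiency-adjacent pair (circular vs flex splines) sits within
  the phantom's geometric uncertainty and can swap with the published
  order; the rank correlation across the six designs remains ≥ 0.9.
* The balloon reaches 90% transmurality below the 2 A search floor on
  this phantom, so its reported dose current is the floor itself.
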