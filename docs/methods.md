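# Methods

This note documents the models, conventions and numerical choices behind
`ctmotion`, and what the phantom-based validation does and does not show.

## Measurement model

The pipeline measures the rigid displacement of objects between two CT
volumes of the same leg under opposite bending loads (valgus/varus). All
processing happens in world millimetres; volumes are scalar grids with an
affine index-to-world map (`world = origin + spacing · index`), right-handed
with the axial (distoproximal) direction along +z.

**Segmentation.** Objects are initialised by threshold-connected region
growing: the 26-connected component of voxels at or above an empirical
threshold (defaults ≈1600 intensity units for tibial cortex, ≈3500 for the
implant) containing a seed voxel. 26-connectivity is the permissive choice
for thin cortical shells. The cortex is grown with the (dilated) implant
mask excluded so the two objects remain separate where they touch. Both
masks are refined by a Laplacian level set (SimpleITK): the boundary,
initialised as a signed distance map, evolves toward zero-crossings of the
image Laplacian under curvature regularisation (weight 0.2, 30 iterations
by default, applied in passes of at most 15; ITK's expansion direction is
reversed to match the inside-negative initialisation). A refinement must
stay a refinement: each pass must overlap its input with Dice > 0.8, and
an empty result is an error. The short passes matter when the threshold
mask starts well inside the true edge (the implant threshold sits high on
the blurred metal edge): the total evolution is large but every pass is a
bounded boundary move.

**Meshing.** Surfaces come from marching cubes on a Gaussian-smoothed
(σ = 0.8 voxel) copy of the mask, which removes staircase normals; masks
under 27 voxels are meshed unsmoothed. Vertex normals are area-weighted
face normals, oriented outward by probing the mask along the normal.

**Double contour.** Each mesh vertex spawns two sample points at ±0.3 mm
along its normal; the gray values interpolated from the segmentation
(valgus) image at those points are stored with the contour. Base points do
not contribute gray values — the informative samples straddle the edge.
Trilinear interpolation is used throughout; points outside a grid are
flagged invalid and excluded rather than clamped, because clamping would
bias the metric toward poses that push points off the volume.

**Registration.** An object's displacement into the varus image maximises
the Pearson correlation between the stored contour grays and the target
grays sampled at the transformed points. The search space is
(tx, ty, tz, φx, φy, φz), translations in mm and rotations in degrees so
simplex steps are comparably scaled; the rotation matrix convention is
R = Rz(φz)·Rx(φx)·Ry(φy) about fixed axes (sequence y, x, z), isolated in
`params_to_matrix`/`matrix_to_params` so it can be swapped. The optimiser
is Nelder–Mead (tolerance 1e-4 on parameters and metric, at most 2000
evaluations per pass). Two routes run from the initialisation — a 1 mm/1°
simplex, and a wide 4 mm/4° pass followed by a 1 mm/1° refinement — and
the better optimum is kept, because the narrow simplex can stall when the
start is several steps off while the wide one can escape to a distant
basin on a near-converged problem; seeded random restarts (default 3)
perturb the incumbent. Non-convergence is flagged, never silent. Rotations are
parameterised about the contour centroid to decouple them from
translations; the reported matrix is centre-independent.

Because repositioning between scans can reach tens of mm and ~10°, far
outside the simplex basin, registration can start from a coarse
pre-alignment: centroids and dominant principal axes of the supra-threshold
voxel clouds fix four degrees of freedom, and the roll about the long axis
— ill-determined by moments for a near-tubular bone — is resolved by
scanning the correlation metric over 15° roll candidates (both axis signs).
The whole-bone contour is used for this scan: a tibial tray alone is nearly
symmetric under 180° roll and cannot disambiguate.

**Kinematics.** With absolute displacements `Mi`, `Mj` from registration,
the relative displacement is `M(i,j) = Mj⁻¹·Mi`, exact matrix algebra with
no re-orthonormalisation beyond 1e-12 cleanup. Any common rigid motion of
the specimen cancels in this product — the property that makes the method
insensitive to patient positioning. Displacements are reported in an
implant-anchored frame: a downward axial ray grid (spacing = voxel size)
is cast over the implant mesh; first hits sample the plateau; the hit
centroid is the origin and centre of rotation; the inertia tensor's
largest-eigenvalue eigenvector is the plateau normal (local z, oriented
away from the bone), the smallest in-plane eigenvector is the long
medial–lateral axis (local x, signed lateral using the declared side of
the leg, +x for right in standard orientation), and y = z × x. Near-equal
in-plane eigenvalues (ratio > 0.95) make the axes meaningless and raise an
error. `M_local = M_CS⁻¹ M M_CS`; parameters come from the same y, x, z
Euler decomposition, with magnitudes √(Δx²+Δy²+Δz²) and √(Δφx²+Δφy²+Δφz²).
Translations depend on the origin choice (plateau centroid); rotations do
not.

**Scalar metrics.** mTRE is the mean and MTPM the maximum of |M·p − p|
over the implant mesh vertices. Both conflate geometry and motion — MTPM
grows linearly with object size under pure rotation — so they complement,
not replace, the decomposed parameters. Surface-distance maps are
vertex-to-vertex nearest-neighbour distances.

**Segment clipping.** The tibia's long axis is the principal axis of its
vertex cloud (the mesh must be elongated: dominant variance ≥ 4× the
next). Length runs from the implant-plateau level (plateau centroid
projected on the axis; the most proximal vertex if no implant is given) to
the most distal vertex. The proximal and distal segments are the end
portions of 20% of that length (configurable), cut by planes perpendicular
to the axis; "whole tibia" is everything below the plateau level. 20%-long
end segments (rather than "everything beyond the cut") are the default
reading of clipping at 20%.

## The phantom

The generator emulates the imaging situation, not the mechanics: the
bending moment's *geometric* effect is imposed directly.

Geometry (canonical frame, bone axis on z from 0 to L = 260 mm): a
cortical shell of constant 4.5 mm thickness around a trabecular interior;
outer radius 12 mm at mid-shaft flaring smoothly to 34 mm proximally
(metaphysis) and 17 mm distally (toward the ankle); a 7% three-fold radial
modulation (the tibia's triangular section) and a 4 mm lateral bow of the
centreline. The implant is an elliptical plateau (halfwidths 33 mm ML ×
22 mm AP, 4 mm thick) on the tibial cut plus an intramedullary stem
(radius 6.5 mm, length 40 mm) offset (2, 3) mm from the plateau centre,
with an optional cement sheath. The asymmetries (bow, triangular section,
offset stem) are anatomy-inspired and necessary: a perfectly axisymmetric
tube or a centred ellipse has discrete roll symmetries under which
intensity registration has multiple equivalent optima, which real bones do
not.

Intensities: background 200, trabecular 600, cortex 1900, cement 2400,
implant 3800 — chosen so the pipeline's standard thresholds (1600/3500)
apply unchanged. Default isotropic spacing is 0.45 mm (the target scan
protocol); validation runs use 0.9 mm (half resolution) to fit desk-scale
budgets, and all accuracy criteria are stated in voxel units so they scale.

**Rendering.** Each voxel centre is classified by the implicit solids
(priority implant > cement > cortex > trabecular; the cavity left by a
displaced implant is background). Voxels on class boundaries are
supersampled 3³ for partial-volume realism. A Gaussian scanner PSF
(σ = 0.45 mm) is then applied — a sharp reconstruction kernel; without a
PSF the phantom would have one-voxel step edges no scanner produces, and
sub-voxel registration would be starved of gradient information — followed
by additive Gaussian noise (default SD 100) from a seeded generator. The
grid auto-fits the posed specimen with a 12 mm margin, origin snapped to
the spacing, so repeated renderings are bit-identical and arbitrary
repositioning (default U(−20, 20) mm, U(−10°, 10°)) never crops the bone.

**Bending.** The load-induced deformation is a rotation-field warp about a
y-parallel (coronal) axis through the distal 20% boundary: each point
rotates by an angle that is zero below the distal 20% boundary, ramps
linearly with axial position across the shaft, and saturates above the
proximal 20% boundary. Both end segments therefore move exactly rigidly —
deformation is concentrated in the shaft, reaches the proximal side, and
the prox-vs-distal ground truth is an exact rigid transform (the net
bend). The true spatial distribution of deformation in a loaded tibia is
not known in detail; this profile is one admissible choice, made so that
ground truth is exact where the measurement model assumes rigidity. The
warp is inverted by fixed-point iteration on the canonical axial
coordinate (8 iterations; the angle is ≤ a few degrees, so convergence is
far below numerical noise). Bends above 10° are rejected (outside the
small-deformation regime). The valgus state bends by +θ and the varus
state by −θ, so the net relative bend is 2θ; a fixed implant rides rigidly
with the proximal bone, and a loose implant additionally moves by a given
rigid transform relative to the proximal bone, applied in the varus state.
With those conventions the ground-truth relative displacements in the
implant frame are exactly `CS₀⁻¹·R(−2θ)·CS₀` (prox vs. distal) and
`CS₀⁻¹·D·CS₀` (implant vs. prox), independent of the specimen poses.

**What the phantom does not model:** metal artefacts (streaks, photon
starvation), beam hardening, anisotropic PSFs, soft tissue and the femur,
trabecular texture, cement–bone interdigitation, and any constitutive
bone mechanics. Passing the phantom experiments therefore shows the
*analysis chain* is correct and precise under controlled imaging physics;
it does not certify performance on artefact-laden clinical scans.

## Validation experiments and problem sizes

All validation runs use the 0.9 mm desk resolution, noise-free unless a
noise level is the point of the experiment (the rigid-recovery check also
runs at noise SD 100; a noise-ladder property test checks that pose error
grows monotonically with noise). Registration uses 2 restarts and contour
subsampling (≈1500 points implant, ≈2200 whole tibia, ≈1400 per segment);
these sizes keep a full registration at a few seconds without measurable
accuracy loss at this resolution.

- **Rigid recovery:** a re-posed (≤5 mm/5°) phantom is recovered to
  <0.1 voxel / 0.1° noise-free and <0.3 voxel / 0.3° at noise SD 100.
- **Zero-displacement null:** 4 repeat scans under full repositioning
  jitter; mean apparent displacement magnitudes stay below 0.1 mm / 0.1°
  for all three object pairs. Relative displacements are markedly more
  accurate than the individual registrations because common-mode
  registration bias cancels in Mj⁻¹·Mi. With N scans the procedure yields
  N(N−1) apparent displacements per pair (12 at the desk N = 4; 90 at the
  protocol's N = 10, which is exercised on a miniature phantom).
- **Deformation recovery:** an imposed 0.64° net bend is recovered from
  the prox-vs-distal pair to ±0.1°, with x-translation and y-rotation
  dominant (the coronal bending directions).
- **Deformation inflation:** across ten seeded specimens with fixed
  implants and net bends drawn near 0.64° ± 0.25°, the apparent implant
  translation against the whole tibia exceeds that against the proximal
  tibia in ≥9/10 specimens (sign test p < 0.05) — the mechanism that
  motivates the proximal reference.
- **Oracles:** the simplex optimum agrees with an exhaustive coarse-to-fine
  grid search (±2 mm/±2° box, 0.1 resolution) within grid resolution;
  exact Mann–Whitney and Wilcoxon p-values match full-enumeration oracles
  for n ≤ 7.

## Statistics

Group comparisons assume nothing about normality: Mann–Whitney U between
independent groups (exact p for n ≤ 25 without ties, tie-corrected normal
approximation otherwise) and Wilcoxon signed-rank for paired comparisons
(zeros dropped; all-zero differences return p = 1 by convention). The
significance level is α = 0.05 with no multiple-testing correction. Both
one- and two-sided alternatives are exposed; comparisons against the
methodological error use the one-sided "greater" alternative.

## Known limitations

- The correlation metric's optimum carries a sub-voxel resampling bias
  (~0.05–0.15 voxel per registration at desk resolution, largest for the
  compact implant); it largely cancels in relative displacements — which
  is what the method reports — but bounds absolute accuracy.
- The metric has no signal beyond ~1–2 mm from the optimum for compact
  thin-shell objects, so those must start from the coarse pre-alignment;
  only large objects (the whole tibia) can be registered from an
  uninformed identity initialisation after a few mm of repositioning.
- The local frame's lateral sign needs the leg side declared; it is not
  inferred from anatomy.
- MTPM/mTRE are computed over marching-cubes vertices; their values depend
  (weakly, via vertex distribution) on mesh density.
- The Euler decomposition is undefined at |φx| = 90° (gimbal); the
  convention (φy absorbed into φz) is flagged on results, and displacement
  magnitudes are unaffected. Load-induced displacements are orders of
  magnitude below this regime.
- Volumes with non-identity direction matrices (oblique acquisitions) are
  not supported.
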