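# ctmotion

CT-based measurement of load-induced tibial implant displacement after
total knee arthroplasty (TKA), with a synthetic CT phantom generator for
validating the whole measurement chain against exact ground truth.

## The problem

A loose tibial component is the most common reason for knee-replacement
revision, but plain radiographs and nuclear imaging detect it poorly. A
non-invasive alternative is to CT-scan the leg twice — once under a valgus
and once under a varus bending moment — and measure how far the implant
moves relative to the tibia between the two scans. The catch: the applied
load also *deforms* the tibia itself. A deformed bone registers to a
compromise pose, which inflates the apparent implant displacement when the
whole tibia is used as the reference object. Measuring the implant against
only the **proximal** tibia segment reduces this deformation artefact and
sharpens the separation between fixed and loose implants.

`ctmotion` implements that measurement pipeline and the experiments that
quantify each error source:

1. **Segmentation** — threshold-connected region growing (≈1600 intensity
   units for cortex, ≈3500 for the implant) refined by a Laplacian
   level set; marching-cubes surface meshes.
2. **Double-contour registration** — mesh points offset ±0.3 mm along the
   surface normals carry gray values from the valgus image; the rigid
   transform into the varus image maximises the Pearson correlation with
   the target grays (Nelder–Mead over tx, ty, tz, φx, φy, φz; rotation
   sequence y, x, z).
3. **Kinematics** — for objects i and j with absolute displacements
   `Mi`, `Mj`, the relative displacement is

   ```
   M(i,j) = Mj⁻¹ · Mi
   M_local(i,j) = M_CS⁻¹ · M(i,j) · M_CS
   ```

   where `M_CS` is an implant-anchored coordinate system (origin at the
   plateau centroid; z distoproximal, x lateral, y posterior–anterior)
   built automatically from the inertia axes of the ray-projected plateau.
   `M(i,j)` is invariant to specimen repositioning, which is why the leg
   needs no fixation in the scanner.
4. **Metrics** — decomposed translations/rotations with root-sum-square
   magnitudes, mean target registration error (mTRE), maximum total point
   motion (MTPM), and nearest-neighbour surface-distance maps.
5. **Phantom** — an analytic tibia + implant model (flared triangular
   cortex, bowed shaft, elliptical plateau with offset stem) rendered into
   CT-like volumes with partial-volume supersampling, a scanner PSF and
   Gaussian noise; coronal-plane bending and loose-implant micro-motion
   produce valgus/varus pairs with exact ground-truth displacement
   matrices.

## Worked example

```python
from ctmotion import PhantomSpec, generate_load_pair
from ctmotion.experiments import ExperimentConfig, analyze_pair
from ctmotion.kinematics import decompose

# a 0.64 deg net coronal bend between valgus and varus, fixed implant
spec = PhantomSpec(voxel_spacing=0.9, noise_sd=0.0, seed=11)
valgus, varus, truth = generate_load_pair(spec, bend_angle=0.32)

out = analyze_pair(valgus, varus, ExperimentConfig())
for name, r in out["results"].items():
    print(name, f"|t| = {r.translation_magnitude:.3f} mm,",
          f"|rot| = {r.rotation_magnitude:.3f} deg")
print("true net bend:", decompose(truth.true_M_prox_distal_local).rotation_magnitude)
```

prints (machine-dependent in the last digit):

```
prox_vs_distal |t| = 2.395 mm, |rot| = 0.639 deg
implant_vs_whole |t| = 0.152 mm, |rot| = 0.095 deg
implant_vs_prox |t| = 0.013 mm, |rot| = 0.039 deg
true net bend: 0.64
```

Reading: the proximal tibia moved 0.639° relative to the distal tibia
(the imposed 0.64° bend, recovered to 0.001°). The implant is fixed, yet
against the **whole** tibia it appears to move 0.152 mm — the
deformation artefact — while against the **proximal** tibia the apparent
motion drops to 0.013 mm, correctly reading "fixed".

A thin CLI wraps the same functions:

```bash
ctmotion simulate --out run/ --bend-deg 0.64 --seed 7
ctmotion analyze --valgus run/valgus.nii.gz --varus run/varus.nii.gz --out run/results.csv
```

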