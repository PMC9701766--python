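# spinereg

Rigid 2D–3D registration of supine-CT-derived lumbar vertebra meshes to
biplanar standing radiographs — so that a patient-specific 3D spine model
carries the *standing* sagittal alignment (lumbar lordosis) instead of the
supine one it was scanned in.

CT gives exact vertebral geometry but depicts the spine unloaded and
supine; standing radiographs capture physiologic sagittal alignment but
only in projection. `spinereg` closes the gap: each vertebra (L1–L5 and
the sacrum) is moved rigidly until its projected silhouette matches
target contours traced on a calibrated frontal + sagittal radiograph
pair. Angles are then measured on the midsagittal section of the
registered model the same way they are read off a sagittal radiograph.
The package is aimed at spine biomechanics groups building
subject-specific finite-element or alignment models from retrospective
CT + radiography data, and it ships a full synthetic-spine test bed so
the whole pipeline is verifiable without patient data.

## Method

For each vertebra with surface $S$ and pose $T = (R, t) \in SE(3)$:

* **Projection.** Each calibrated view has a point source and a detector
  plane; a world point $p$ maps to detector coordinates by central
  projection, with magnification $\mathrm{SID}/\mathrm{SOD}$ at the
  object plane. The two detectors are mutually orthogonal.
* **Initialisation.** A coarse pose aligns the projected silhouette
  centroid with the target-contour centroid in both views (least squares
  over the two ray constraints) and matches 2D principal axes per view —
  the stand-in for manual alignment.
* **Refinement.** Iteratively: project the silhouette outline in both
  views; match every densified target sample $q_i$ to its nearest
  silhouette point (pairs beyond a 10 mm cap are dropped); anchor that
  silhouette point to the 3D surface point $x_i$ projecting onto it; and
  update the pose by a damped Gauss–Newton step minimising

  $$\sum_i w_{v(i)}\,\bigl[\hat n_i^\top(\Pi_{v(i)}(R\,x_i + t) - q_i)\bigr]^2 ,$$

  where $\Pi_v$ is view $v$'s projection and $\hat n_i$ the local
  silhouette normal (point-to-tangent residuals). Steps that would
  increase the true pooled point-to-silhouette cost are halved until the
  cost is non-increasing; iteration stops when the pooled RMS residual
  changes by less than 0.01 mm.
* **Measurement.** Lumbar lordosis LL is the angle between the cranial
  endplate of L1 and the cranial endplate of S1 (lordotic positive);
  intersegmental angles use the caudal endplate of the upper and the
  cranial endplate of the lower vertebra. Both are measured on the
  midsagittal section (the cut by the sagittal mid-plane between the
  left and right vertebral margins) or directly on the meshes.
* **Agreement metrics.** Dice similarity $2|X\cap Y|/(|X|+|Y|)$ on
  0.6 mm voxelisations; one-sided mean surface distance
  $E_m(S_1,S_2) = \tfrac{1}{|S_1|}\int_{S_1} e(p, S_2)\,ds$ with exact
  point-to-triangle distances; symmetrised maximum (Hausdorff) distance;
  and two-way mixed-effects absolute-agreement ICCs — ICC(A,1) for
  intra-rater and ICC(A,2) for inter-rater style comparisons — with
  F-based 95% confidence intervals.

## Worked example

Register one synthetic vertebra to its own biplanar silhouettes from a
perturbed starting pose:

```python
import numpy as np
import spinereg as sr

env = sr.default_environment()                      # SID 1800, SOD 1400 mm
mesh = sr.make_vertebra(sr.default_shape_set(0)[2]) # an L3-like vertebra

truth = sr.RigidTransform.from_axis_angle([1, 0, 0], 6.0, [3.0, -4.0, 8.0])
targets = {name: sr.silhouette_contour(mesh, truth, view, 0.5)
           for name, view in env.views.items()}

model = sr.VertebraRegistration(mesh, targets, env)
init = sr.RigidTransform.from_axis_angle([1, 0, 0], 5.0, [4.0, 0.0, -3.0]) @ truth
result = model.fit(init)
print(result.summary())

err = result.final_pose.invert() @ truth
print(f"pose error: {err.rotation_angle_deg():.3f} deg, "
      f"{err.translation_norm():.3f} mm")
```

Output:

```
Registration result [L3]
  converged        : True
  iterations       : 7
  rms residual     : 0.0348 mm
  frontal  residual : 0.0406 mm  (552 pairs)
  sagittal residual : 0.0269 mm  (489 pairs)
pose error: 0.122 deg, 0.047 mm
```

The residual is the pooled RMS distance between the target contour
samples and the registered silhouette in detector millimetres; the final
pose is within about a tenth of a degree and a twentieth of a millimetre
of the true standing pose.

The same pipeline is scriptable from the shell:

```bash
spinereg simulate --cases 1 --seed 3 --outdir sim/
spinereg register --case-dir sim/case000 --out reg/
spinereg measure  --meshes reg/ --out angles.csv
spinereg validate --cases 20 --seed 1 --outdir validation/
```

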