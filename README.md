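# tbiq — CT quantification for acute traumatic brain injury

`tbiq` is an automated pipeline that computes, from a non-contrast head CT,
the three quantities that drive acute management of traumatic brain injury:

- **acute intracranial lesion volume** (epidural/subdural hematoma,
  contusion, intracerebral hemorrhage — hyperdense, ~50–90 HU), segmented
  by a patch-based 3D U-Net with a two-stage *false-lesion* retraining
  scheme that teaches the network to ignore normal blood-containing
  structures (venous sinuses, falx edges);
- **basal cistern volume**, from atlas-prior EM tissue segmentation
  followed by constrained morphology (compressed cisterns signal raised
  intracranial pressure);
- **midline shift (MLS)**, measured geometrically on each axial slice
  between the foramen of Monro and the roof of the lateral ventricles as

  ```
  shift(z) = | B/2 − C |,        MLS = max over slices z
  ```

  where `B` is the maximal left–right inner-skull width on the slice and
  `C` the distance from the inner table (on the side opposite the shift)
  to the midpoint of the frontal part of the lateral ventricles, both along
  the same left–right line. A shift > 5 mm is a conventional surgical
  decision threshold.

The package is aimed at researchers developing or validating quantitative
CT pipelines for TBI. Clinical CT cohorts with expert annotations are
access-restricted, so `tbiq` ships a first-class **phantom module**:
synthetic head CTs (egg-shaped skull shell, GM/WM/CSF tissue, ventricles with
frontal horns, basal cisterns, hyperdense lesions of requested volume, a
falx decoy, noise, and a *known induced midline shift*) plus a synthetic
atlas, giving exact ground truth for every stage. The entire test suite
validates the pipeline against these phantoms.

## Worked example

```python
from tbiq import PhantomSpec, generate_atlas, generate_phantom
from tbiq.pipeline import PipelineConfig, run_pipeline

atlas = generate_atlas(PhantomSpec(seed=0), n_subjects=3, seed=100)
case  = generate_phantom(PhantomSpec(seed=11, induced_shift=8.0))

report = run_pipeline(case.ct, atlas, PipelineConfig())
print(f"cistern volume: {report.cistern_volume_ml:.2f} mL "
      f"(truth {case.cistern_volume_ml():.2f} mL)")
print(f"midline shift:  {report.mls_mm:.2f} mm (induced {case.truth_mls:.1f} mm)")
```

prints

```
cistern volume: 7.56 mL (truth 7.90 mL)
midline shift:  8.24 mm (induced 8.0 mm)
```

i.e. the pipeline recovers the induced 8 mm shift to within a quarter of a
millimetre and the constructed cistern volume to within ~5 %, on a noisy
phantom it has never seen. The same objects expose every intermediate
(brain mask, subject-to-atlas affine, tissue posteriors, ventricle/cistern
candidates, per-slice `B`, `C` and shift values).

A command-line interface mirrors the library:

```bash
tbiq phantom --config spec.yaml --out cases/ --n 10 --seed 42
tbiq atlas   --config spec.yaml --out atlas/ --n-subjects 5
tbiq run cases/case000_ct.nii.gz --atlas-dir atlas/ --out results/
tbiq mls cases/case000_ct.nii.gz --atlas-dir atlas/
```

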