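# Methods

`tbiq` quantifies three CT features of acute traumatic brain injury from a
non-contrast head CT: total acute intracranial lesion volume, basal cistern
volume, and midline shift (MLS). The pipeline has four stages: (1)
pre-processing — brain extraction, intensity normalization, affine
registration to an atlas, and EM tissue segmentation with atlas priors,
which also localises the lateral ventricles and basal cisterns through
binary structure priors; (2) cistern segmentation by constrained
morphology; (3) patch-based 3D U-Net lesion segmentation with a two-stage
false-lesion retraining scheme; (4) geometric MLS measurement over the
axial slice range between the foramen-of-Monro plane and the roof of the
lateral ventricles. Because the clinical cohorts this class of method is
validated on are access-restricted, the package ships a synthetic phantom
module that generates head-CT-like volumes with exact ground truth; all
quantitative claims in the test suite are made against those phantoms.

## Synthetic phantoms and atlas

A phantom is built in world millimetres on a grid whose centre is the
origin: an egg-shaped skull shell (1000 HU, 6 mm thick, outer semi-axes
0.9x the grid half-extent with a 10 % anterior taper — real crania are
narrower frontally, and an exact ellipsoid would make affine registration
ill-posed, since any rotation of a quadric is reproducible by a symmetric
strain), a cortical grey-matter rim (10 mm, 42 HU) over
white matter (30 HU), paired lateral ventricles with frontal horns (CSF,
8 HU), basal cisterns forming an annulus around a brainstem cylinder near
the skull base, hyperdense lesions (70 HU) of configurable volume and
location, an optional 1-voxel parasagittal falx sheet at 60 HU (a "false
lesion" decoy), and additive Gaussian noise (default sigma 8 HU, typical of
soft-tissue kernels). Defaults: 113 x 127 x 72 voxels at 1.5 x 1.5 x 2.0 mm
— an odd x-dimension makes the zero-shift phantom exactly mirror-symmetric
about the mid-sagittal plane. Slice thickness is configurable over the
0.4–5 mm acquisition range seen clinically.

Cistern and lesion volumes are hit by bisection on the defining radius of
the voxelized shape, so the truth masks match the requested volume to
within a few percent (tests assert 5%). The midline shift is induced by a
rigid lateral translation of the ventricular system; a biomechanical
deformation is deliberately out of scope — the rigid model gives an exact
known MLS, which is the property the estimator is validated against.

The synthetic atlas is the voxelwise average of unshifted phantoms:
template = mean CT, tissue priors = class frequencies smoothed by a 3 mm
Gaussian (emulating the soft boundaries of a population atlas — important,
because perfectly crisp priors would overrule intensity evidence wherever
anatomy is displaced), binary ventricle/cistern priors = majority votes,
and two axial landmark planes read off the ventricle extent.

What the phantoms do **not** emulate: beam hardening and streak artifacts,
partial-volume effects at thin structures, anatomical variability of the
ventricular system, subarachnoid CSF, isodense or heterogeneous (mixed
hyper/hypodense) lesions, and real falx/tentorium geometry. Passing the
suite therefore demonstrates the internal consistency and parameter
recovery of the algorithms under controlled conditions, not clinical-grade
accuracy.

## Pre-processing

The reference brain extractor is morphological: HU window [-20, 100],
binary opening, largest connected component, hole fill. It is exact on
phantoms and has no trained weights, so downstream tests do not depend on
training success. A slice-wise 2D U-Net extractor (same-padding, per level
two 3x3 convolutions with ReLU, 2x max pooling/upsampling, Adadelta) is
also provided and trained on phantom slices; its default width (five
levels, 64 first-level filters) matches the classic 2D architecture, while
tests train a reduced width. Intensities are normalized to zero mean and
unit standard deviation strictly inside the brain mask (the only choice
consistent with operating on "extracted brain" images); voxels outside the
mask are zeroed.

## Registration and EM tissue segmentation

Registration is a 12-dof affine over a 3-level multi-resolution pyramid
(SimpleITK backend; random sampling with a fixed seed keeps runs
deterministic). The default similarity is mean squares: template and
subject are the same modality (CT in HU), and on smooth synthetic heads
mutual information proved insensitive to exactly the rotation-versus-strain
trade-off that matters (it pools intensity co-occurrence and does not care
*where* residual mismatch sits, so the optimizer settles on a strain-only
alignment of the near-quadric head); mean squares penalizes any displaced
skull shell at ~1000 HU contrast and recovers rotations correctly. Mattes
mutual information remains available through the configuration for
multi-modal use. Two robustness devices handle strongly rotated subjects:
optional multi-start (six axis rotations added to the identity start, all
optimized, densely-evaluated best kept) and incumbent restarts (the
regular-step descent shrinks its step monotonically within a run;
re-running from the incumbent with a reset step escapes shallow ridges).
Affine-only is a deliberate simplification — phantom-scale geometry has no
nonrigid component — and if the optimum fails to improve on the identity
alignment the identity is returned with a provenance flag.

Tissue segmentation is a three-class Gaussian mixture (CSF/GM/WM) with
spatially varying mixing proportions given by the warped atlas priors,
fitted by EM on the normalized in-mask intensities. Numerical choices:

- **Prior relaxation.** Mass effect can displace the ventricles more than
  10 mm from their atlas location, where the warped CSF prior is ~0 and no
  intensity evidence could ever win. Three mechanisms compensate, each
  configurable: the CSF prior is raised to at least 0.35 inside a 14 mm
  halo around the binary ventricle/cistern priors; no class prior may
  exceed 0.75 (intensity always retains a vote); and all priors are mixed
  with a uniform distribution at weight 0.1. With relaxation disabled the
  strict prior-dominance limit holds exactly (a prior of 1 forces the
  posterior regardless of intensity), which the tests assert.
- **Initialization.** Class means start at robust intensity landmarks
  (0.5 % quantile for CSF, 85 % for GM, 45 % for WM) rather than
  prior-weighted statistics: displaced anatomy poisons prior-weighted
  means, and a mis-initialized rare class (CSF is ~2 % of brain voxels)
  drifts into a broad "background" Gaussian.
- **Convergence.** Relative log-likelihood tolerance 1e-5, at most 50
  iterations; the log-likelihood is checked non-decreasing at every step.
  Class variances are floored at 1e-6 (flagged when hit — e.g. on
  noiseless phantoms, where within-class variance is genuinely zero).
- **Ties** in the hard-label argmax break to the lowest class index
  (CSF < GM < WM).

Structure localisation intersects the CSF hard label with the warped
binary prior dilated by 2 voxels, then takes each CSF connected component
touching that intersection **whole**. Pure voxel intersection would
truncate a ventricle displaced beyond the dilation radius and bias the MLS
midpoint; component completion keeps the candidates a subset of the CSF
label (asserted) while tolerating arbitrary displacement. A component
claimed by both structures goes to the larger overlap; an empty
intersection returns an empty mask with a warning (the clinical reading:
obliterated cisterns).

## Cistern segmentation

Candidates are refined by: (1) constrained dilation — up to 3 one-voxel
dilations accepted only where the CSF posterior is at least 0.5; (2)
smoothing — morphological closing, then Gaussian smoothing of the mask
indicator at sigma = 1 voxel, re-thresholded at 0.5; (3) non-overlap —
voxels claimed by the ventricle mask are removed. The volume is voxel
count x voxel volume. The three parameters (acceptance threshold, dilation
count, smoothing width) are configurable; the defaults are conventional
values, as the operations themselves are standard but their parameters are
a free choice. Overlap statistics are reported for cisterns above 5 mL;
below that the phantom annulus is thinner than a voxel and voxelization
noise dominates any morphological decision.

## Lesion segmentation

The network is the classic volumetric U-Net: per resolution level two
valid 3x3x3 convolutions with ReLU; 2x2x2 max pooling on the analysis
path; on the synthesis path a 2x2x2 stride-2 up-convolution that halves
the channel count, crop-and-concatenate shortcuts from the same level, and
two further convolutions; a final 1x1x1 convolution with softmax. First
level filters are (32, 64), doubling per level; the synthesis path mirrors
the (a, b) pair of its level. At the reference configuration (four levels,
132^3 input) the output patch is 44^3 and the input-output margin is 88
voxels — the closed-form shape trace, the structural per-layer trace, and
an executed forward pass are checked against each other.

The stack is implemented directly in numpy (float32, explicit
backpropagation, convolutions as offset-sums of BLAS GEMM calls, gradients
verified against central differences in float64 to ~1e-7). Training uses
categorical cross-entropy, Adam, batch size one, and augmentation by
random flips, translations, rotations and Gaussian noise; patches are
sampled lesion-centred with probability 0.7, else uniformly. The final
classification layer starts with the non-background logits at the class's
approximate log base rate (-3): the initial prediction then matches the
rarity of lesion voxels, so short training runs spend their steps learning
the lesion appearance instead of first suppressing a half-probability
lesion channel everywhere (without this, desk-scale training failed on a
third of seeds).

**Two-stage scheme.** Stage 1 learns lesion-versus-background. Each
training case's false-lesion mask is then computed as the stage-1
prediction minus the ground truth (voxelwise set difference — on real data
this collects venous sinus, falx and tentorium edges; on phantoms, the
falx decoy and boundary errors), and stage 2 retrains with that mask as a
third class, warm-started from the stage-1 weights; the final classifier
keeps the trained background and lesion rows and only the new
false-lesion row starts fresh, so stage 2 begins exactly as calibrated as
stage 1 and retraining can only add suppression at the hard negatives. At inference the volume is tiled with non-overlapping output
patches (stride = output size, mirror padding for context and grid
completion, so every voxel is predicted exactly once) and only the
lesion-class probability is thresholded, at 0.7.

**Desk scale.** CPU training uses the reduced configuration from the
design: 60^3 input (output 44^3), depth 2, filters (8, 16). The validation
experiment trains on two decoy-falx phantoms (64 x 72 x 44 at 2.5 mm,
30-40 mL lesions) for 30 epochs per stage with one patch per case per
epoch, learning rate 3e-3 (the 1e-5 default matches the reference protocol
at full scale but cannot move a randomly initialized network in 60 steps),
and evaluates on a held-out phantom, repeated over 10 paired seeds. The
reference-scale configuration is constructible and shape-checked but not
trained in the test suite.

## Midline shift

On each axial slice between the landmark planes (mapped from atlas to
subject space through the inverse affine), the shift is |B/2 - C|: B is
the maximal left-right inner-skull width on the slice (inner table edges
at the row of the ventricle midpoint), C the distance from the inner table
— starting on the side opposite the shift, as in the manual protocol — to
the midpoint of the frontal part of the ventricles. The frontal part is
the anterior third of the slice's ventricle pixels; with two or more
connected components the midpoint of the two largest components' centroids
is used (the second must be at least 25 % of the largest, so a noise speck
cannot masquerade as a horn), otherwise the centroid of the single merged
component. Slices whose ventricle cross-section is below half the in-range
maximum are skipped: the thin end-caps of the ventricles do not support a
reliable bilateral midpoint, mirroring the manual instruction to measure
where the shift is well visualized. The patient-level MLS is the maximum
per-slice shift, ties breaking to the most inferior slice; if no slice is
measurable (fully effaced ventricles) an error is raised rather than a
guess. Measurements are made in native voxel space with spacing-aware
millimetre arithmetic — centroids are sub-voxel quantities, so resampling
to 1 mm isotropic first adds cost without accuracy.

## Agreement metrics

Dice = 2TP/(2TP+FP+FN), sensitivity = TP/(TP+FN), precision = TP/(TP+FP);
volume difference is reference minus prediction (positive =
undersegmentation); ICC is the two-way random, single-measure, absolute
agreement form ICC(2,1) computed from the ANOVA mean squares (tested to
1e-10 against an independently coded brute-force decomposition and against
pingouin); classification accuracy is the agreement fraction at a cutoff
(25 mL for lesion volume, 5 mm for MLS), with Cohen's kappa. Conventions
where the definitions are silent: two empty masks agree perfectly
(Dice = precision = sensitivity = 1); an empty reference against a
non-empty prediction gives sensitivity NaN, precision 0, Dice 0; values
exactly at a cutoff classify as "not greater"; kappa on a single-class
table is NaN with a warning. Cohort summaries report median and
interquartile percentiles with linear interpolation.

## Validation problem sizes

The test suite validates MLS recovery on 20 phantoms with shifts uniform
in [0, 12] mm (|error| <= 1 mm in at least 18/20 and 5-mm classification
accuracy >= 0.9), cistern recovery on 10 phantoms with 2–15 mL targets,
EM accuracy >= 95 % on noiseless phantoms, known-affine registration
recovery (10 trials, <= 10 mm / 10 deg / 10 % perturbations recovered
within 1 mm / 1 deg / 1 %), and the two-stage property over 10 paired
seeds. These sizes are chosen so the whole suite runs on a single CPU in
well under half an hour while keeping every statistical check meaningful.

## Known limitations

- Phantom realism bounds what the tests can show (see above); in
  particular the lesion network is validated on spherical, homogeneous,
  hyperdense lesions only.
- The affine-only registration cannot model nonrigid anatomy; on real
  data a deformable refinement would precede the prior warping.
- The EM model has no spatial regularization (no MRF); isolated voxel
  misclassifications are handled downstream by component logic rather
  than in the model.
- Subarachnoid hemorrhage, edema, and lesion subtyping are out of scope.
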