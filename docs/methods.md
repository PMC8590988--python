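# Methods

This note documents the models and procedures implemented in
`petbrainx`, the parameters that matter, and the design decisions taken
where the design was genuinely open.

## Synthetic whole-body phantoms

Real oncologic PET scans cannot be redistributed, so every experiment
in this package runs on seeded synthetic phantoms
(`petbrainx.phantom`). A phantom is a stack of ellipsoids on a
96×64×192 grid at 4 mm spacing (configurable): a torso (SUV drawn from
U[1.0, 2.2]), a head shell (U[1.2, 1.8]), a brain near the superior
end (U[6, 8]), legs for total-body coverage, a urinary bladder hotspot
(U[15, 30]) and, optionally, a one-voxel-wide venous "injection
artifact" streak along an arm (U[10, 25]). The palette follows the
clinical rule of thumb that almost all tissues stay below SUV 30
except urine. Reconstruction is emulated by a 5 mm FWHM Gaussian blur
followed by additive Gaussian noise (default SD 0.15 SUV, a plausible
soft-tissue noise level at this voxel size); values are clipped at 0.

*Ground truth* is computed from the unblurred brain label: the tight
3-D bounding box, the binary brain mask, and the lesion mask if any.
The "not containing entire brain" class is modeled by superior
truncation: the anatomy is shifted so that a stated fraction of the
brain's height lies beyond the top grid face, which is how torso
protocols actually miss the brain. `whole_brain_present` is true only
for truncation fraction exactly 0. Lesions are spheres inside the
brain whose SUV is multiplied by a factor < 1 (default 0.5, radius
12 mm), mimicking the hypometabolic edema around metastases; a lesion
center outside the brain label is rejected with the offending
coordinate.

Cohorts randomize anatomy per phantom (brain/torso radii, positions,
tissue SUVs, coverage, artifacts) from a single seed, and realize the
truncated fraction as an exact count (default 30%) at seeded random
positions. The truncation fraction of each truncated phantom is drawn
from U[0.25, 0.8].

What the phantoms do **not** model: attenuation, scatter, partial
volume beyond the PSF blur, anatomical texture (gyri, ventricles,
organs), inter-subject intensity correlations, or age effects. Passing
tests therefore demonstrate the pipeline's mechanics — detection,
geometry, registration and inference are wired correctly and behave as
specified — not clinical-grade performance on real scans.

The registration template is the voxelwise mean of 20 seeded canonical
brains (centered ellipsoids, 5 mm blur, no noise) on a fixed 80×88×72
grid at 2 mm.

## MIP views and network inputs

Anterior (max over y) and lateral (max over x) projections are
displayed with the superior end at row 0. Preprocessing zero-pads the
shorter image axis to a square — split evenly, the extra pixel on the
high-index side — resizes to 224×224 with bilinear interpolation
(pad first, then resize), and maps SUV v to `min(v, 30)/30·255`.
Values are clipped at SUV 30 before scaling so the bladder cannot
compress the contrast of everything else. Padding offsets and the
resize scale are retained, and pixel→voxel mapping inverts resize then
padding with round-half-up and clipping; the mapping is exact on
integer grids whenever the resize scale is ≥ 1 (true for all default
grids).

Training-time augmentation applies intensity multiplication
(U[0.8, 1.2]), gamma contrast (U[0.8, 1.25]), isotropic scaling about
the image center (U[0.9, 1.1]) and translation (±10 px). The two views
of a sample share the scale and vertical translation (they share the
z axis), and the normalized box target is carried through the same
affine maps.

## Box geometry

Boxes are min-corner + size, 0-based, half-open. A 3-D box is encoded
for regression as the 6-vector `(min, size)/grid_extent ∈ [0, 1]`;
decoding rounds half-up and clips to the grid, and rejects components
outside [−0.5, 1.5] as implausible. When merging the two annotated
views, x comes from the anterior box, y from the lateral box, and the
z extent is the union of the two views' z ranges: the union errs
toward inclusion, which is the right failure mode because the crop
feeds registration — a slightly loose crop is harmless, a tight one
loses cortex. 3-D IOU is computed by axis-wise interval intersection.

## The dual-view localizer

Both 224×224 views pass through one shared-weight convolutional
backbone: a 4× block-average pooling (so convolutions run at 56×56),
then four 3×3 conv blocks (8, 16, 32, 32 channels, ReLU, 2×2 max-pool
between the first three). The two 1568-D feature vectors are
concatenated and passed through a fully connected layer (default
4096-D; the desk-scale preset uses 256-D) feeding two heads: a sigmoid
existence probability and a sigmoid 6-vector of normalized box
coordinates. The network, backprop and Adam are implemented in numpy
inside the package; everything is float32 and seed-deterministic.

The loss is `α·BCE + β·Y·Σ(Δ)²` with α = 10, β = 1. The binary
cross-entropy is the standard negated form with probabilities clamped
at 1e-7; the squared box error is summed over the six normalized
components and gated by the existence label, so absent-brain samples
never contribute box gradients (tested directly).

**Training profiles.** The documented defaults (Adam, lr 1e-5, 150
epochs, batch 8, 10% validation holdout, augmentation on, best-
validation checkpoint returned) describe fine-tuning a large
pretrained backbone. Training the compact backbone *from random
initialization* at lr 1e-5 moves the weights by a negligible total
distance in 150 epochs, so the desk-scale profile
(`TrainConfig.desk_scale`) uses lr 1e-3 with 120 epochs; and because a
fully randomized synthetic cohort already supplies unlimited fresh
geometry, the profile disables augmentation, which at this scale is
redundant regularization that slows convergence. An `overfit` profile
(no best-validation restore) exists for memorization sanity checks.
The existence decision threshold is p ≥ 0.5.

## Extraction and normalization

Scans are resliced to 2 mm isotropic by trilinear interpolation
(exact on linear intensity fields, which the tests exploit); the
predicted box, carried from the original grid to the 2 mm grid, is
padded by 10 voxels per face, clipped, and cropped; the crop's NIfTI
origin is shifted so world coordinates are preserved.

Registration to the template is affine first (correlation metric,
3-level coarse-to-fine, metric evaluated on a seeded 25% voxel
subsample), then a diffeomorphic displacement-field refinement with an
ANTs-style neighborhood cross-correlation metric (radius 3, 30
iterations over 2 levels, Gaussian-regularized update and total
fields). Because global uptake differs across subjects (dose, body
weight, glycemia), the moving image is first scaled to the template's
brain reference intensity — the mean over voxels above half the 99th
percentile, a robust proxy for the bright brain compartment of a
crop. This scaling also puts the normalized volumes on a common
intensity scale for the group comparison, playing the role that
global-mean scaling plays in conventional SPM pipelines. If the
diffeomorphic stage fails to improve the cross-correlation, its output
is discarded and the affine result is kept, so similarity never
decreases across stages. The schedule is deliberately short: phantom
and PET brains are smooth, and the benchmark experiments need ~24
registrations per run; the config is exposed for heavier use.
Smoothing uses `σ = FWHM/(2√(2 ln 2))` per axis in voxel units with
nearest-neighbor boundary extension (10 mm FWHM default).

## Statistical mapping

One subject versus n controls is the pooled two-sample t with a
single-observation group: `t = (x̄_ctrl − x_subj)/(s_p√(1 + 1/n))`,
`df = n − 1`. At least 3 controls are required. Zero-variance voxels
(possible on synthetic data) get t = 0 and are counted in the map's
metadata rather than becoming ±∞. The default direction is one-sided
controls > subject, because the screening target is hypometabolism;
two-sided maps threshold |t| at p/2. The analysis mask keeps template
voxels above 20% of the template maximum. Thresholding uses the
one-sided Student quantile at uncorrected P < 0.001 (no
multiple-comparison correction by design), clusters form under
18-connectivity (6/26 configurable), and each cluster reports size,
peak T and peak coordinate, sorted by peak T. Lesion recovery is
scored as any cluster voxel touching the 1-voxel-dilated (26-neighbor)
true lesion mask. No global intensity normalization is applied before
the test; the registration pre-scaling is the only intensity
adjustment.

## Benchmark experiments and problem sizes

`petbrainx.workflows` fixes the benchmark conditions: 160 phantoms
(30% truncated), 120 train / 40 held out, desk-scale training profile;
an independent 24-phantom all-whole-brain cohort; and 4 lesioned
subjects (multiplier 0.5, radius 12 mm) versus 20 controls through the
full pipeline with a mean-of-20 template. All sub-seeds derive from
one integer. These sizes were chosen so the entire benchmark runs in
minutes on a single CPU while keeping the class balance and cohort
sizes of the experiments they mirror.

## Known limitations

- The phantom's geometric simplicity makes box regression easier than
  on real anatomy; reported IOUs should be read as pipeline
  verification, not as expected clinical accuracy.
- The registration schedule trades accuracy for speed and is tuned for
  smooth ellipsoidal brains.
- Controls and subjects are simulated from the same anatomy
  distribution; there is no age or disease confounding, so the t-map
  experiments probe calibration and sensitivity, not specificity
  against realistic biological variance.
- The VIA annotation reader supports rectangle regions only.
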