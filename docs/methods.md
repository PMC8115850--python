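# Methods

## Problem and model

`osteoage` estimates adult chronological age from post-mortem CT of two
skeletal age indicators, the mandible and the femur. Age estimation is
posed as regression: a 3D CNN backbone `F_theta` maps a fixed-shape bone
voxel `X` to a pooled feature vector, the binary sex code (0 = male,
1 = female) is embedded through a 32-wide fully connected layer, and a
linear head produces the prediction

    age_hat = fc( concat( F_theta(X), g(sex) ) ).

Training minimizes the mean squared error between predicted and true ages.
Modalities are combined three ways:

* **late fusion** — average of the two single-modality predictions,
  `age_hat = (age_hat_mandible + age_hat_femur) / 2`, with no learned
  parameters;
* **middle fusion** — one joint model: both backbones' pooled features are
  concatenated with the sex embedding before a single head, and gradients
  flow into both backbones;
* **early fusion** — both voxels are trilinearly resampled onto a shared
  grid and stacked as two input channels of one backbone. The taxonomy
  ("merge before the model") leaves the grid unspecified; a shared grid
  with channel stacking is the simplest reading that keeps a single model.

## Preprocessing

CT series are read per-directory from DICOM; slices are sorted by
ImagePositionPatient along the stacking axis, a missing SliceThickness is
repaired as the median inter-slice step, and stored values are converted to
Hounsfield units by `HU = slope * stored + intercept` (defaults 1 / -1024
when tags are absent, with a warning). Inter-slice steps deviating more
than 5% from their median are rejected as degenerate geometry. All arrays
are (z, y, x); spacings are quoted in the same order in mm.

Volumes are resampled to 1 mm isotropic spacing by trilinear
interpolation; output dimensions are `round(dim * spacing / target)`, so
physical extent is preserved to within one voxel per axis. A volume already
on the target grid is returned untouched (bit-for-bit).

* **Femur**: HU are mapped linearly onto [0, 1] over the 400–1000 HU
  cortical-bone window (400 -> 0, 1000 -> 1, clamped outside) and the
  region is center-cropped / symmetrically zero-padded to 112 x 128 x 128.
  With `region="auto"` the crop box is centered on the bounding box of
  voxels >= 400 HU.
* **Mandible**: per axial slice — center-fit to 256 x 256 (padding with
  air at -1024 HU so padding can never cross the bone threshold),
  threshold at 400 HU, morphological opening with a 3 x 3 square
  structuring element, 8-connected component labeling, retention of every
  component at least 10% the size of the largest (the largest always
  survives), and multiplication of the surviving mask into the HU slice.
  The 20 slices centered on the bone-bearing span are stacked and
  window-normalized with the same 400–1000 map as the femur. A 20 mm slab
  cannot hold a full mandible at 1 mm spacing; slab selection is therefore
  a package decision (central bone-bearing slices), and the mandible
  normalization mirrors the femur window because masked intensities must
  land in [0, 1] for the network either way.

Structuring element, connectivity, and the 10% retention fraction are
configurable; the defaults above are the package's choices where the
procedure is otherwise under-determined.

## Backbones

All backbones are depth-inflated 3D variants with isotropic 3^3 (or stem
7^3) kernels and global average pooling:

* `resnet34_3d`: basic residual blocks (conv–BN–ReLU x2 plus identity
  shortcut), stages [3, 4, 6, 3], widths 64·{1,2,4,8} — mandible default;
* `resnet50_3d`: bottleneck blocks (1-3-1 convolutions, expansion 4),
  stages [3, 4, 6, 3] — femur default; feature width 2048;
* `mobilenet_3d`: depthwise-separable blocks in the MobileNet-V1 layout;
* `squeezenet_3d`: fire modules in the SqueezeNet v1.1 layout.

Note that depth inflation inverts the familiar 2D parameter-count ordering:
3^3 kernels blow up the basic blocks, so the 3D ResNet-34 is *larger*
(~63M parameters) than the 3D ResNet-50 (~46M), consistent with published
3D ResNet sizes.

Downsampling strides adapt per axis: an axis shorter than 4 voxels stops
being strided, so the architectures run unchanged on desk-scale grids. A
`scale` factor multiplies all channel widths (minimum 2). Batch
normalization uses momentum 0.1 and frozen running statistics at
evaluation.

The networks run on a compact numpy engine written for this package
(convolution by kernel-offset contraction, manual backpropagation, Adam);
it is float32, single-threaded and bitwise deterministic given the
initialization seed.

## Training

Adam with first-moment coefficient 0.9 (the "momentum" of the optimizer —
Adam has no classical momentum term; beta2 = 0.999), weight decay 1e-4,
minibatch 16, learning rate 3e-4 reduced by a factor 0.8 when the
validation loss has plateaued for 10 consecutive epochs (relative
improvement threshold 1e-3), floored at 3e-5, for up to 50 epochs.
Augmentation is random cropping to 20 x 224 x 224 (mandible) and
112 x 112 x 112 (femur); evaluation uses center crops. The plateau count
is over validation *epochs* because validation loss exists only per epoch.
The checkpointed model is the epoch with the best validation MAE (earlier
epoch on ties). The head bias is initialized to the mean training age so
the optimizer starts from the baseline predictor rather than from zero.

Progressive input-size pretraining trains the same architecture on a
ladder of growing input shapes; every parameter whose name and shape match
is carried to the next rung, and shape-incompatible layers (e.g. a head
over a different feature width) keep their fresh seeded initialization.

## Evaluation protocol

Metrics use population (1/n) moments, matching their expectation-form
definitions: MAE, Pearson's rho, and Lin's concordance correlation
coefficient `CCC = 2 rho s_y s_yhat / (s_y^2 + s_yhat^2 + (mu_y -
mu_yhat)^2)`. Degenerate CCC cases are defined explicitly (two identical
constants -> 1; two different constants -> 0) instead of propagating NaN;
a zero-variance Pearson input raises rather than silently returning 0.

Cross-validation stratifies subjects by age decade x sex ("same
distribution" made concrete), deals shuffled stratum members cyclically
across k folds with the deal position carried between strata (so both
stratum-level and global fold sizes differ by at most one), trains one
model per fold, and reports per-fold metrics plus unweighted mean ±
population std across folds. Each fold's training pool is further split
90/10 (stratified, seeded) into the inner training and validation sets the
scheduler and checkpoint selection require; held-out fold subjects never
enter either (asserted at run time). Using an inner split avoids the
leakage that scheduling on the test fold would cause.

## Phantom cohorts

The generator emulates what the pipeline needs from real data, not
anatomy: two bone-bearing CT regions per subject whose intensity and
geometry carry a known age signal,

    density(age, sex) = h0 - beta * age + delta * sex   (HU)
    thickness(age)    = t0 - gamma * age                (mm)

with defaults h0 = 900 HU, beta = 4 HU/yr, delta = -25 HU (female),
t0 = 7 mm, gamma = 0.04 mm/yr, i.i.d. Gaussian voxel noise sd 30 HU, ages
from a truncated normal (mean 49.59, sd 11.80, range 20–70) and a 76% male
cohort — the demographic profile of the population the pipeline targets.
The defaults keep cortical bone inside the 400–1000 HU window across the
whole age range (validated on construction). The femur is a cortical-shell
cylinder plus a spherical head (the hip-adjacent confound); the mandible is
a per-slice U-shaped cortical arch plus a small disconnected "neck bone"
cylinder, sized below the 10% retention threshold by construction so the
component-retention rule has real work to do. An optional per-subject,
per-modality density jitter (`modality_jitter_sd`) gives the two bones
independent noisy copies of the age signal; that is the regime in which
multimodal fusion has something to average away (12 HU jitter ~ 3 years of
age-equivalent noise per modality).

Phantoms are emitted at 2 mm spacing on small grids so the 1 mm resampler
always runs its real interpolation path. What the phantoms do **not**
model: real anatomy, scanner artifacts, beam hardening, damaged or
fragmented bone, or nonlinear aging. Passing tests therefore demonstrate
that the pipeline recovers a linear density/geometry age signal end to end
— not clinical accuracy on real PMCT.

## Desk-scale study sizes

CPU-sized experiments use block-averaged voxels (femur 112x128x128 ->
14x16x16, mandible 20x256x256 -> 10x16x16), crops of 12x14x14 / 10x14x14,
backbones at 1/8 channel width, 3-fold cross-validation, and 30–35 epochs
at learning rate 0.02 (floor 2e-3, plateau patience 6) — the learning rate
is sized for the ~10^3-fold smaller parameter count and the short
schedule; the full-size defaults remain those listed under Training. The
age-recovery study uses 200 subjects (default phantom parameters, seed 7);
the fusion study uses 105 subjects with 12 HU modality jitter. These sizes
are the package's chosen study conditions for the built-in experiments and
are shared between the test suite and `scripts/acceptance.py`.

## Known limitations

* The numpy engine targets correctness and determinism, not throughput;
  full-size (112^3-crop, width-64) training is out of desk reach.
* The anatomical localization of mandible/femur regions inside a
  whole-body scan is manifest-driven (explicit boxes) or a bone-centroid
  heuristic; no learned localization.
* Phantom linearity means desk-scale results say nothing about the size of
  real-data errors, only about pipeline correctness.
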