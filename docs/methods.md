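# Methods

This note documents the models, conventions and numerical choices behind
`orgamri`, in the spirit of the methods documentation of packages like
scanpy or statsmodels: what each stage assumes, which knobs matter, and
what the synthetic phantoms do and do not establish about real data.

## The analysis problem

Cerebral organoids grown in culture tubes can be imaged non-invasively
with high-field T2*-weighted MRI (80 µm isotropic is the design
resolution). On that contrast, free fluid — the culture medium and the
fluid inside cysts — is bright, while compact organoid tissue is darker
and the air background is darkest. The pipeline exploits exactly this
intensity topology for three tasks:

1. **Organoid segmentation** (volume monitoring over time),
2. **Global cysticity classification** (is there any cyst? a quality
   label), and
3. **Local cyst segmentation** (where are the cysts?),

plus group statistics on DTI parameter maps (Trace, FA, three
eigenvalues), where fluid-rich cystic organoids show elevated diffusion.

## Conventions

- Axis 0 of every volume is the **coronal** axis; plane-wise operations
  (medium extraction) walk along it. The convention is explicit because
  orientation is generally not recoverable from the voxel grid alone.
- Spacing is carried in **µm**; NIfTI affines are written in mm.
  A file without usable spacing metadata falls back to 80 µm isotropic
  with a logged warning.
- All intensity-based analysis operates on per-volume **min–max
  normalized** images (values in [0, 1]). A constant volume normalizes
  to all zeros rather than raising, so degenerate inputs cannot abort a
  batch run.
- Masks are boolean grids aligned voxel-for-voxel with their volume and
  stored as 0/1 NIfTI.

## The phantom generator

`phantom.generate_phantom` renders the simplest geometry that reproduces
the intensity topology the pipeline depends on: a cylindrical tube of
bright medium along the coronal axis in dark background, a darker
organoid sphere inside it, and optional bright cyst spheres fully inside
the organoid. Intensities are population means (defaults: background
0.05, tissue 0.30, medium 0.85, cyst 0.82 in arbitrary units) plus
additive Gaussian noise (σ = 0.03 by default; an optional Rician mode
takes the magnitude of a complex signal with Gaussian channel noise).
Each volume is finally multiplied by a per-volume gain (jittered
U(0.8, 1.2) in cohorts) so tests catch any accidental dependence on the
absolute intensity scale. Cyst fluid is constrained to lie within ±10%
of the medium intensity — cysts are filled with medium-like fluid, which
is the physical premise of the compactness metric.

`generate_cohort` emulates a longitudinal study: each organoid has a
base radius (62–78% of the spec radius) and a per-day growth rate, so
radii grow monotonically with imaging day; the default design of 9
organoids over 5 imaging days yields 45 samples. A cystic organoid keeps
a fixed relative cyst layout across days: one dominant cavity (radius
45–60% of the organoid radius) plus up to two smaller satellites. The
dominant-cavity default matters: it makes every cystic phantom's
organoid-mean intensity markedly medium-like, which is what the
generator must guarantee for the separability property stated below.

**What the phantoms do not model:** organoid shape irregularity,
fragmented organoids touching the tube wall, bias fields / B1
inhomogeneity, susceptibility artifacts, partial-volume blur, or any
actual MR physics (no Bloch simulation). Passing phantom tests therefore
establishes correctness of the *computational pipeline* — not expected
performance on scanner data, where contrast is less clean and anatomy
less spherical.

## Segmentation

**Multi-Otsu baseline.** The volume histogram is split into three
classes by maximizing between-class variance; the middle class (tissue)
restricted to its largest connected component is the organoid candidate.
Deterministic, no training; it is the comparison baseline and the fast
path of the pipeline.

**3-D U-Net.** A compact encoder–decoder (three resolution levels, one
3×3×3 convolution + ReLU per level, 2× average pooling,
nearest-neighbour upsampling with 1×1×1 projections before skip
concatenation, 8 base channels by default, `model_scale` to shrink or
grow) implemented directly in numpy: convolutions run as im2col + BLAS
matrix products in float32, and the backward pass is hand-derived. The
training protocol is Adam (learning rate 10⁻³, weight decay 10⁻⁷),
batch size 1 over whole volumes, and the composite loss
`1·BCE + 10·(1 − softDice)` — the Dice-dominant weighting counters the
foreground/background imbalance. Validation Dice is evaluated every
`val_every` iterations and the best checkpoint is kept. The organoid
task defaults to 2000 iterations and the cyst task to 5000; the
desk-scale protocol used by the test suite and the acceptance script is
64³ phantoms, `model_scale 0.5`, 300 iterations for the
8-train/2-held-out experiment and 200/300 iterations for the
overfit-one-sample checks (≈ 0.8 s per iteration on one CPU core).
Spatial shapes must be divisible by 4; predictions on other shapes are
zero-padded and cropped back. Binarization is at probability 0.5 with no
morphological post-processing by default.

**Evaluation protocol.** Organoid-wise leave-one-out cross-validation:
one split per organoid, whose samples form the test set; the remaining
samples are shuffled into a random 80/20 train/validation split with a
per-split seed derived from the root seed. Aggregated Dice is reported
both over samples and over organoids (the two aggregations differ when
time series lengths differ; both are carried).

## Compactness

For a normalized volume `v` and organoid mask:

    compactness = | mean(int_org) − mean(int_medium) |

`int_org` are organoid-voxel intensities (ground-truth masks by default;
predicted masks give a fully automatic mode). `int_medium` is extracted
plane-wise: on every *interior* organoid-containing coronal plane a 2-D
Otsu threshold separates bright fluid from dark background, and the
plane's above-threshold voxels minus organoid voxels are medium. The
first and last organoid-containing planes are discarded as
edge-artifact-prone, so the organoid must span at least three planes.
Planes whose bright set is entirely organoid contribute nothing (logged).

The cystic-class score is **−compactness** (medium-like organoid ⇒ low
compactness ⇒ cystic), fed into ROC analysis. Computing compactness on
min–max normalized intensities makes values comparable across samples
despite gain differences; the metric itself is invariant under adding a
constant to the volume and scales linearly under multiplication.

On phantom cohorts at default contrast/noise the cystic and non-cystic
compactness distributions do not overlap, so the ROC AUC is 1.0 and the
two-group Welch t-test is significant far below 10⁻⁴ at 10 samples per
group; compactness decreases monotonically as the cyst volume fraction
grows.

## Cyst filtering and segmentation

Samples enter the cyst-segmentation task only with ≥ 1000 cyst voxels
(0.512 mm³ at 80 µm isotropic, printed as 0.51; "less than 1000"
excludes, exactly 1000 is included). The threshold is expressed in
voxels with the mm³ equivalent derived per-sample from spacing, so it
ports to other resolutions. Samples without cyst annotation are reported
as unevaluable rather than dropped. Prediction can optionally be
intersected with the organoid mask (off by default).

## DTI statistics

Parameter maps arrive as ready-made volumes (tensor fitting happens in
the scanner software). Per sample and map the summary is the mean over
the organoid mask; when the map grid differs from the mask grid
(thick-slice 2-D DTI), the mask is resampled by nearest neighbour with
grids aligned at the first voxel. Groups are compared per map with a
two-sided t-test — Welch by default, since group sizes and variances are
not guaranteed equal and the classical variant is available via
`equal_var=True` — and the five maps' p-values are adjusted with
Holm–Šídák: sort ascending, adjusted₍ᵢ₎ = max over j ≤ i of
1 − (1 − p₍ⱼ₎)^(m−j+1), clipped to 1. Under a 5-map null simulation
(both groups identical, 1000 replicates) the measured family-wise error
rate stays at or below α = 0.05 within binomial Monte-Carlo error.

The pipeline's simulated DTI maps give tissue a Trace of 1.0 and cyst
fluid 2.5 (medium 2.9) ×10⁻³ mm²/s with σ = 0.05 noise; FA and
eigenvalue maps are scaled variants. These are stand-ins with the right
group structure, not diffusion simulations.

## Numerical choices and degenerate inputs

- Dice with two empty masks raises (0/0); an empty prediction against a
  nonempty target scores 0. ROC ties count ½ (trapezoidal AUC); the
  stored operating threshold maximizes Youden's J but only the AUC is
  used for evaluation.
- Multi-Otsu on a volume with fewer distinct values than classes raises
  rather than returning degenerate thresholds.
- Training aborts on any non-finite loss with a diagnostic; fixed seeds
  reproduce loss trajectories bit-for-bit on one device.
- All randomness (phantoms, cohort layouts, split shuffles, weight
  initialization) flows from explicit integer seeds; one root seed
  derives per-stage seeds via SHA-256 so a full pipeline run reproduces
  from a single integer.

## Known limitations

- The numpy U-Net is CPU-bound and meant for desk-scale validation and
  small studies; it does not attempt GPU-scale training, augmentation,
  or the full 400×188×100 acquisition matrix (oversized volumes should
  be cropped to the tube region first).
- Phantom separability makes the classification tasks easy by
  construction; real cystic/non-cystic boundaries are fuzzier, and the
  phantom results are upper bounds by design, not performance claims.
- No bias-field correction is attempted; the compactness metric assumes
  approximate B1 homogeneity across the organoid and nearby medium.
- Whether medium voxels should be pooled across all tubes in a holder or
  restricted to the organoid's own tube is left to the mask/volume crop
  supplied by the user; the phantoms model a single tube.
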