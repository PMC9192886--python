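# Methods

`spectboost` synthesizes standard-scan-time bone SPECT from a fast scan
(3 s/projection, nominally 1/7 of the standard 20 s dwell) plus a
co-registered CT, and ships everything needed to exercise the method at desk
scale: a simulator for paired acquisitions, the generator network, the
lesion-attention training loss, and the quantitative evaluation protocol.

## Forward model (simulator)

The package operates on reconstructed volumes, so the scanner and its
iterative reconstruction are replaced by an image-domain surrogate:

1. an *activity* map A(x) in arbitrary concentration units,
2. Gaussian system-resolution blur with FWHM `psf_fwhm_mm`
   (default 8 mm, a typical LEHR collimator resolution at 10 cm;
   the desk preset uses 12 mm to match its 6 mm voxels),
3. independent Poisson counts per voxel with expectation

   `lambda = blur(A) * sensitivity * t_proj * n_proj + background_rate * t_proj * n_proj`.

This preserves the one property the enhancement network learns from — the
fast scan is a 3/20-expectation Poisson realization of the same underlying
image as the standard scan — without modelling projections, attenuation,
scatter, or detector response.  Consequences for interpreting results: noise
here is uncorrelated white Poisson noise, whereas reconstructed clinical
SPECT has spatially correlated noise and streak/ringing artifacts; passing
tests demonstrate noise suppression and structure recovery under ideal count
statistics, not robustness to reconstruction artifacts.

Absolute sensitivity is a free parameter (the activity unit is arbitrary);
the default `50/1200 counts per unit·s` puts the standard-scan background of
the phantom at 50 counts/voxel, a realistic bone-SPECT count level.
`background_counts_rate` defaults to 0 (no scatter floor).

### NEMA IEC phantom

A fillable cylinder (9700 ml; interior length fixed at the standard's
180 mm, radius solved from the volume → 131 mm) holds six spheres of
diameter 10–37 mm, centres on a 50 mm ring in a plane 70 mm below the top
face, filled at 12:1 relative to the background.  Spheres sit at 60°
spacing with sphere 1 (largest) at angle 0, numbered in descending diameter
— the numbering that makes the per-sphere SUV table decrease with sphere
index under partial-volume logic.  The pseudo-CT encodes air (−1000),
water-equivalent fill (0) and the plexiglass shell (+120) as constant
classes.

### Synthetic subjects

A torso-like ellipsoid (activity 1) with a spine-like posterior rod and
rib-like partial plates at 3× background uptake (bone tracer avidity), plus
a configurable number of hot ellipsoidal lesions at 8× background, placed
without mutual overlap (bounded retries, then an error).  The pseudo-CT
shares the geometry at CT contrast (bone +700, lesions +300).  These
subjects emulate the gross count statistics and the
structure-visible-in-CT/weak-in-SPECT situation of clinical bone SPECT/CT;
they do not emulate anatomy, tracer kinetics, patient motion, or
inter-subject variability beyond random geometry jitter.

## Preprocessing

Every volume is divided by its own mean over all voxels (zeros included);
the divisor is stored with the samples.  CT is shifted to non-negative
before normalization — a signed HU mean is a meaningless divisor.  At
inference only the fast scan's statistics exist, so outputs return to count
scale through the fast volume's divisor; comparisons against the standard
scan therefore happen either on the mean-normalized scale (the default in
the demo) or after multiplying by the known dwell ratio 20/3.  Training
samples are whole axial slices; fast SPECT is channel 0 and CT channel 1 of
the network input (the CT channel is dropped in the ablation arm).

## Generator

A two-level nested U-structure: six encoder stages (residual U-blocks of
heights 7, 6, 5, 4, then two dilated RS-4 blocks) and five decoder stages
(dilated RS-4, then RSU-4, 5, 6, 7), with 2× max-pooling between non-dilated
stages and bilinear upsampling in the decoders.  An RSU of height L applies
an input 3×3 convolution, an inner symmetric encoder–decoder of L−1 levels,
and adds the inner output back onto the input-convolution branch; the
dilated variant replaces pooling/upsampling with dilation rates 1, 2, 4, …
Every convolution is 3×3 + batch norm + ReLU (no conv bias — batch norm
makes it redundant), Kaiming fan-in initialized from a seeded generator.

Six side outputs (decoder stages 1–5 plus the deepest encoder) map features
to one channel via 3×3 convolutions and are bilinearly upsampled to the
input size.  The fusion head is a 1×1 convolution over the six side outputs
*plus the fast-SPECT input channel*, and the fast channel is added once more
after the convolution (the long skip).  Exposing the skip channel to the
fusion is essential: with the additive skip alone, side outputs that
approximate the target can never cancel the input's noise (the fusion's
optimum degenerates to zero weights and the final image is pinned at
fast-scan quality); with the skip channel among its inputs the head can
weight it toward −1 and substitute the side estimates.  With a zeroed
fusion head the model is an exact pass-through of the fast channel, which is
also how the head is initialized (identity start) — training can only move
the output away from the input where the loss demands it.  Outputs are
linear: intensities are unbounded normalized counts, so no saturating output
nonlinearity is applied, and side heads start from bias 1 (the DC level of a
mean-normalized target).

Desk-scale widths: `base_channels` scales all stage widths (64 = full
scale, 8 = desk preset); inner-RSU widths keep a floor of 4 channels — a
one- or two-channel inner U cannot carry multi-scale content.

Spatial contract: input sides must divide by 32 (five pooling levels);
non-dilated RSU-L blocks require divisibility by 2^(L−2).  Violations raise
a shape error naming the required divisor.

## Losses

Per output image, with alpha = 0.5:

    L = L1(pred, target) + alpha * (1 − mean local SSIM)

Local SSIM uses a uniform sliding window (default 11×11, valid positions
only, population moments) with the conventional stability constants
c1 = (0.01·R)², c2 = (0.03·R)², R = dynamic range of the target.  The
windowed means behind SSIM are computed with integral images, so window size
does not affect cost; the same code path produces evaluation SSIM values and
training gradients.

The lesion-attention loss with beta = 100 re-evaluates L over the
lesion-mask region (masked L1 = mean over mask-positive pixels; masked SSIM
= SSIM map averaged over window positions whose centre is mask-positive —
computing the full map first avoids window-boundary pathologies):

    l = L + beta * L|mask        (empty mask: second term 0)

and deep supervision sums l over the six side outputs and the final output
with unit weights by default:

    L_total = sum_i w_side_i * l(side_i) + w_final * l(final)

## Training and inference

Adam (lr 2e-4 full scale, divided by 10 after epoch 80 of 100; batches of 4
axial slices; seeded shuffling, drop-last off).  Training is single-process
and bit-reproducible given the seed.  A non-finite loss aborts with the
epoch/batch context.  The desk preset trains 12–20 epochs at lr 1e-3 — two
orders of magnitude fewer gradient steps than the full-scale schedule, so
the rate is raised proportionally.  Inference normalizes the input volumes,
runs each axial slice through the network in evaluation mode (batch-norm
running statistics), keeps only the final output, restores count scale with
the fast divisor and clamps negatives to zero.

## Evaluation

* PSNR = 10·log10(MAX_gt² / MSE), MAX from the reference volume; identical
  volumes report +inf.
* SSIM as above; volumes are scored per axial slice with a shared dynamic
  range and averaged.
* SUV = pixel value × weight[g] / dose[MBq].  For the phantom, weight =
  9700 g (water-equivalent fill) and the dose is the known total instilled
  activity, which puts the true background SUV near 1 and sphere SUVs near
  12 (minus partial-volume losses).  Count images calibrate to concentration
  by dividing by sensitivity × scan time of their acquisition (the enhanced
  volume lives on the fast count scale, hence fast calibration).
* Sphere ROIs come from the analytic geometry (voxel centres inside the
  nominal sphere).  Detectability is a Rose criterion: CNR =
  (mean_ROI − mean_bg)/sd_bg > 4, with the background sampled from a slab
  around the sphere plane, ≥12 mm inside the cylinder wall and ≥10 mm away
  from every sphere.  With a degenerate zero-variance background, positive
  contrast counts as detectable.
* Difference maps are gt − pred (signed), with a suggested symmetric display
  window.

## Desk-scale test conditions

The test suite exercises the full pipeline at: phantom and subjects on
(32, 64, 64) grids at 6 mm voxels, PSF 12 mm; one phantom (upper half
training, sphere-plane slab held out) plus two training subjects and one
held-out subject (≈80 training slices); `base_channels` 8; six epochs at
lr 1e-3 across five seeds per arm.  These sizes keep a fifteen-arm
(full / no-CT / beta-0 × 5 seeds) comparison tractable on one CPU.

## Known limitations

* At desk-scale step counts the deeply supervised side outputs are still far
  from the target; the measured held-out gain of the full method saturates
  near +0.6 dB PSNR with slightly reduced SSIM — far short of what
  full-scale training of this architecture achieves on clinical data.  The
  pipeline itself supports much
  larger gains — a plain 3-layer CNN trained on identical data reaches
  +6 dB within 200 steps — so the gap is the optimization cost of the
  nested-U with deep supervision, not the data or the training stack.
  Per-sphere SUV accuracy does improve consistently under the full method.
* The deep-supervision total loss has an architectural floor when
  overfitting a single slice: the 4×4 and 2×2 side heads cannot represent a
  64×64 target, so L_total plateaus near 30 % of its initial value rather
  than approaching zero.
* The adversarial discriminator mentioned alongside the optimizer settings
  has no corresponding loss term and is not implemented; a config hook
  (`adversarial: none`) reserves the spot.
* Orientation handling is identity-only; clinical DICOM geometry beyond
  simple series reading is out of scope.
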