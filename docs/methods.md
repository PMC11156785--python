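# Methods

## The problem and the model

Free-breathing liver DWI collects N co-registered images per slice
(repetitions x diffusion directions; the default N = 12 corresponds to 4
repetitions of 3 orthogonal directions at b = 800 s/mm²). Cardiac pulsation
causes intravoxel dephasing that erases signal in a random subset of those
images, almost exclusively in the left liver lobe; vessels, conversely, can
flash bright in single images from inflowing blood. Every method in this
package consumes the H x W x N stack of one slice plus five ROI masks
(left lobe R1, right lobe R2, vessels, lesions, background parenchyma) and
produces a single combined or predicted image.

The unprocessed baseline is the trace-weighted reference: the voxelwise
geometric mean over each direction triplet, arithmetically averaged over
repetitions. All quality claims are relative to it.

## Quality scoring

Four raw feature scores are computed per image (higher = better):

* PA = mean(R1) / mean(R2). Signal loss pushes it below 1.
* VD = mean(background) / mean(vessels).
* CNR = (mean(lesions) - mean(background)) / std(background).
* DC = max(0, 1 - mean|I - I_ref| over R2 / mean(I_ref) over R2).

PA, VD and CNR of a processed image are divided by the reference's own
values; DC is already relative to the reference. Qtotal is the arithmetic
mean of the four ratios. The VD, CNR and DC forms are fixed here as the
simplest expressions satisfying the published contracts (reference
normalizes to 1; DC penalizes deviation in the artifact-free lobe; the CNR
denominator collapses for a constant liver signal); any alternative with the
same contracts can be swapped behind the same signatures. All denominators
carry a 1e-12 guard with a logged warning — the CNR divergence mode (a
network flattening the liver to kill the denominator) is a known failure of
score-guided optimization and is additionally countered by the dispersion
loss term.

Scores are per slice. Aggregates over datasets are unweighted means over
slices; slices without a lesion ROI contribute to the PA/VD/DC means only
(their CNR and Qtotal are NaN and skipped).

## Conventional combination algorithms

All five operate voxelwise on the N original images (the geometric-mean
trace step is used only to build the reference, matching the network's
N-channel input):

* weighted average with weights I^beta; p-mean ((1/N) sum I^p)^(1/p);
  voxelwise percentile (linear interpolation).
* outlier exclusion: the variation map is the voxelwise coefficient of
  variation (std/mean; CV rather than raw std so the threshold thr = 0.3 is
  intensity-scale-free), box-filtered with a ks2 x ks2 kernel
  (edge-replicating). Where the smoothed map exceeds thr, each voxel drops
  its current minimum repetition value while it lies below mean - 1.0 x std
  of the retained values (population std), at most k times; the output is
  the mean of the retained values, the plain mean elsewhere. The exclusion
  criterion and box smoothing are isolated behind the function so they can
  be replaced. Defaults k = 10, ks2 = 21, thr = 0.3 are the published
  optimum of the Qtotal parameter search.
* exception set: per voxel, greedily remove the repetition whose removal
  most reduces the variance of the retained values; accept while the
  smoothing factor (variance reduction) x (retained count) / |E| exceeds a
  threshold. This is a per-voxel reduction of a global deviation-detection
  scheme; the greedy step is verified in the tests against stepwise
  enumeration of all candidate removals (greedy is *not* globally
  subset-optimal for variance, so the oracle enumerates candidates per step,
  not subsets).

The parameter search scores every grid point on every slice against the
trace reference and returns the argmax of the mean Qtotal, first-in-grid on
ties.

## Feature-guided loss

L = -0.5 DC - 1.5 CNR - PA - VD + 0.5 DI + 0.05 PA2 + 0.05 xi, with

* DI = population variance of (DC, CNR, PA, VD) — penalizes one score
  diverging at the expense of the others (sample vs population variance is
  unstated in the source method; population is fixed here for
  reproducibility);
* PA2 = mean(MIP) - mean(prediction) over R1, the left-lobe deficit against
  the brightest available voxels, so brightening R1 is favored over
  darkening R2 (which would also raise PA);
* xi = RMS deviation from the reference. RMS rather than an unnormalized
  L2 norm makes the 0.05 weight resolution-independent.

The loss uses **raw** scores, not reference-normalized ones: the published
weight magnitudes are calibrated on raw ratio scales, and a normalization
constant would be absorbed into the weights. Slices without a lesion ROI
contribute a CNR-free loss: the CNR weight is redistributed equally onto DC,
PA and VD and the dispersion is taken over the remaining three scores.
Batch losses are unweighted means over slices.

## Network and training

A symmetric U-Net (two 3x3 conv + ReLU per level, 2x2 max pooling,
nearest-neighbour upsampling with skip concatenation, 1x1 output conv;
channels double per level) maps the N normalized images to one output image.
The exact published per-level channel counts are not recoverable, so depth
and base width are configurable; defaults depth 4 / base 32 suit 128 x 128
slices, and the desk-scale tests use depth 3 / base 16 at 64 x 64.

Each slice is normalized to zero mean and unit std jointly over all N images
(one record per slice, reused to invert predictions; the same per-slice
convention applies at inference). The linear network output is
de-normalized and then passed through a softplus with sharpness 10/std —
near-identity over the tissue intensity range, smoothly clamping the
background at zero. Applying the nonnegativity map *after* de-normalization
is deliberate: a nonnegative map in normalized units would bound every
de-normalized output below by the slice mean and make dark background
impossible.

Training: Adam (beta1 = 0.9, beta2 = 0.999), MSE pretraining on the trace
references, then feature-guided epochs. The early-stopping rule is a pure
function of the monitored loss sequence: stop once the mean over the latest
`window` epochs is not lower than the mean over the `window` before that;
the weights with the lowest monitored loss (test-set loss when a test set is
supplied, else training loss) are restored. Two named profiles exist:
`paper` (batch 64, 3000 pretraining epochs, window 100, lr 1e-4) mirrors the
full-scale published run, `desk` (batch 8, 50 pretraining epochs, window 10,
lr 1e-3, max 150 epochs) is sized for a single CPU; the higher desk learning
rate is the usual choice when a small network must converge within tens of
epochs. Augmentation (one random translation up to ±10% and one scale factor
in [0.90, 1.05] per slice, applied identically to all images and masks,
masks re-binarized at 0.5) is available at dataset preparation.

The whole training stack runs on an in-package numpy reverse-mode autodiff
engine (`_autodiff`): broadcasting arithmetic, ReLU/softplus/abs/sqrt,
reductions and masked means, im2col convolution, 2x2 max pooling, 2x
upsampling, concatenation, and an Adam optimizer. Every operator and the
full network carry central-difference gradient checks in the test suite,
and the differentiable loss graph is asserted term-by-term against the
plain-numpy loss implementation.

## The phantom

The phantom renders a schematic liver — an ellipse split into a small left
and large right lobe — with 2-4 thin dark vessels (0.3 x parenchyma; at
least one crossing the left lobe), 1-2 bright lesion discs at 1.8 x
parenchyma (the first always in the left lobe, so artifact correction and
lesion contrast interact), and a static low-frequency multiplicative
parenchyma texture (sigma 15%, identical in all repetitions). The texture
supplies the biological background variability that the CNR denominator
measures; without it the raw CNR sits orders of magnitude above the other
scores and the dispersion loss term, which presumes scores of comparable
magnitude, dominates the training signal.

Per repetition, independently: with probability 0.4 a smooth multiplicative
retention field (a blurred Gaussian field min-max rescaled into [0.2, 0.7])
is applied over the left lobe — smooth rather than uniform to mirror
spatially varying pulsation loss and to exercise the low-pass-gated
correction; each vessel brightens 3x with probability 0.15; zero-mean
Gaussian noise of scale 0.05 x parenchyma mean is added and clipped at zero
(Gaussian rather than Rician: no score in scope depends on the noise
floor's distributional form). `dropout_log` records the mean applied
retention factor per repetition (1.0 when none), giving the Monte-Carlo
oracle E[log] = 1 - 0.4 x (1 - 0.45) = 0.78 used in the tests.

The background-parenchyma ROI is drawn well inside the right lobe (erosion
by 8% of the image dimension, away from vessels and lesions) — as a manual
ROI would be — because the smoothed variation map spills high air/boundary
variation a half-kernel into the organ, and a boundary-hugging ROI would
measure that rim effect rather than parenchyma.

What the phantom does **not** emulate: anatomical liver shape, breathing
motion, EPI distortion, Rician noise, through-plane coherence, and realistic
dropout-factor statistics (no published characterization exists; the
defaults are calibrated for directional tests only). Passing phantom tests
therefore demonstrates the mechanics and the qualitative trade-offs of the
algorithms, not clinical performance.

## Problem sizes and numerical choices

Desk-scale runs used throughout the tests and the acceptance script: the
conventional directional suite uses 20 phantom slices at 128 x 128; the
training suite uses 16 training / 4 held-out slices at 64 x 64, a depth-3 /
base-16 network (~120k parameters), 50 pretraining epochs and a 10-epoch
stopping window, repeated over three seeds. These sizes were chosen so the
full pipeline runs in minutes on one CPU; the `paper` profile preserves the
full-scale hyperparameters. The network trains in float32; gradient checks
run the identical code in float64. Patient-wise splitting always holds out
at least one patient (ceil(0.8 n), capped at n - 1). Ties in the Qtotal
parameter search resolve to the first grid entry; ties in max pooling route
the gradient to the first maximum of each 2x2 block.

## Known limitations

* The desk-scale network heavily over-corrects relative to the published
  full-scale run (held-out Qtotal far above 1, DC well below 1): phantom
  artifacts are much easier than patient data and the desk schedule trades
  fidelity for runtime. The qualitative signature — quality gain without
  vessel brightening — is the validated claim.
* The exact appendix definitions of VD/CNR/DC, the informed-RESTORE
  adaptation details and the published per-level channel counts are not
  available; the fixed choices above are documented interpretations kept
  behind stable interfaces.
* Whether combined images should be trace-combined before scoring is
  unspecified upstream; this package scores the combined image of all N
  repetitions directly.
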