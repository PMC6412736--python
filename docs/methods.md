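# Methods

This note documents the models and procedures implemented in `hsibrain`,
the assumptions behind the synthetic data, and the numerical choices made
where the underlying method description left the design open.

## Pre-processing chain

Raw pushbroom VNIR cubes (rows × cols × 826 bands, 400–1000 nm) pass
through three stages.

**Calibration.** Per-pixel, per-band reflectance in percent:
`C = (R − D)/(W − D) · 100`, with full white and dark reference images
(not averaged rows). The ratio is computed before the multiplication so
that a raw capture equal to the white reference yields exactly 100.0 in
floating point. Any element with `W − D ≤ 0` is a hard error naming the
pixel and band — a reference pair that fails there cannot calibrate
anything.

**Denoising.** A centered moving average along the band axis (default
window 5 bands, reflective ends) — the minimal reading of an unspecified
"smooth filter"; the window is exposed in configuration. Bands outside
the 450–900 nm operating range are dropped (the sensor is noisy at its
spectral extremes). The retained bands (619 on the default inclusive
grid) are partitioned into 128 contiguous groups whose sizes differ by at
most one and each group is averaged; the stored channel center is the
group-mean wavelength. The exact grouping used on the original
instrument is not reconstructible — under equal grouping channel 42 sits
near 595 nm rather than the printed 591.10 nm — so the channel
wavelengths are data, not constants, and can be overridden from
configuration when matching a specific instrument.

**Normalization.** Per-pixel min–max scaling to [0, 1]. This removes
amplitude differences caused by the non-uniform, curved brain surface:
classification then depends on spectral shape only (the operation is
invariant to positive affine rescaling of a spectrum, which is tested by
property fuzzing). Constant spectra (saturated glare) cannot be scaled;
they are zeroed and flagged in a degenerate-pixel mask rather than
raising, because such pixels are routine in real scenes.

## SAM labeling

Gold-standard maps are sparse: an expert picks a reference pixel of known
tissue, the tool computes the spectral angle of every pixel to that
reference, and a user-chosen threshold (radians; degrees in the CLI)
selects the similar set, which is then assigned a class. SAM is
scale-invariant, consistent with running on normalized spectra; all 128
channels are used. Overlapping assignments follow last-write-wins with a
reported conflict count, mirroring an interactive tool while keeping
sessions auditable (the CLI writes a JSON-lines action log). A 1e-7 rad
tolerance on the threshold comparison absorbs `arccos` round-off so a
zero threshold still selects exact positive multiples of the reference.

## Learnable components

No GPU framework is assumed: `hsibrain._nn` is a small seeded
forward/backward engine (dense, 3×3 convolution, average/max pooling,
nearest-neighbor upsampling, ReLU/sigmoid, inverted dropout, softmax and
binary cross-entropy, SGD and AdaDelta) in float32 NHWC. All randomness
— initialization, batching, dropout, subsampling — flows through named
`numpy.random.Generator` streams, so training is bit-reproducible on one
platform.

**Spectral 1D-DNN.** 128 → 28 → 40 → K with ReLU hidden units and a
softmax head, SGD at learning rate 0.1, 45 epochs binary / 40 multiclass.
The batch size is not part of the published description; at learning rate
0.1 small batches make plain SGD prone to dying-ReLU collapse (a
first-layer unit pushed permanently negative early in training), so the
package defaults to batches of 128 spectra, which is stable across seeds.
The loss is cross-entropy (the conventional choice; none is named).
Training data are class-balanced by random subsampling without
replacement to the smallest class.

**Patch 2D-CNN.** Three 3×3 'same' convolutions (64, 92, 128 filters),
one 3×3 'valid' average pool, flatten (for an 11×11×128 patch:
9·9·128 = 10 368), a 1000-wide dense layer with ReLU, and a softmax head;
sigmoid activations with 40% dropout on the convolutions; AdaDelta at
learning rate 1.0; batches of 12 patches expanded in-batch to 96 by the
eight dihedral variants (rotations by 0/90/180/270° with optional
vertical mirror). The printed per-layer channel sizes are internally
inconsistent; each row's input size is taken literally, which reproduces
the 10 368-feature flatten. A configuration switch replaces sigmoid with
ReLU: sigmoid convolutions stall badly at small problem sizes (near-zero
gradients through three saturating layers), and the desk-scale
experiments use the ReLU setting.

**Vessel detector.** The same topology with a single-channel input and a
two-class head, applied to patches of the grayscale image. No layer
table exists for this variant; the package default uses narrower layers
(the literal multiclass widths at 41×41 would give a ~195 M-parameter
dense layer, implausible for a component motivated by real-time use).
In the desk-scale experiments the patch is 11 px on 64×64 scenes (the
full-scale figure is 41 px on roughly eight-times-larger images), and
half of the negative training patches are drawn from a ring near the
vessels — hard negatives that teach center discrimination.

**Parenchyma segmenter.** A depth-3 U-Net-style encoder/decoder (one
3×3 convolution + ReLU per block, 2×2 max pooling, nearest-neighbor
upsampling, skip concatenations, 1×1 sigmoid output), trained with
binary cross-entropy and AdaDelta on the grayscale image against binary
parenchyma masks; the training set is augmented by exactly a factor of
eight with the dihedral group. Base width 16 filters (8 in the
desk-scale experiments). Images must be square with side divisible by 4.

## Framework composition

The grayscale image `I = 0.7·b₄₂ + 0.3·b₅₀ + 0.8·(1 − b₈₀)` (1-based
channel indices into the 128-channel signature) highlights vessels via a
hemoglobin absorption channel while separating background and markers.
The vessel mask is the patch-CNN argmax cleaned by close(r=1) then
open(r=1); the parenchyma mask is the segmenter output at threshold 0.5
cleaned by close/open with a large disk and hole filling (radius 35 px at
full resolution; the radius is configuration and the desk-scale
experiments use 5 px on 64×64 scenes — a 35 px disk would not fit).
Fusion: vessel pixels overwrite the spectral map to hypervascularized
(*positive mask filling in* read as overwrite-inside-mask), pixels
outside the parenchyma become background (*negative mask filling in*,
applied after, so it dominates — this ordering follows the prose order of
the pipeline description), and each class is finally opened with an r=1
disk. Openings of disjoint sets stay disjoint, and a pixel whose class
erodes away everywhere keeps its pre-open label, so the output remains
fully assigned; this also makes fusion idempotent. The disk structuring
element is `{(dx,dy): dx² + dy² ≤ r²}`, and outside the image counts as
background at every stage (checked exhaustively against a brute-force
set-definition oracle on all 4×4 masks).

## Density visualization

Hierarchical k-means is realized as bisecting 2-means on pixel spectra:
the cluster with the largest within-cluster sum of squared distances is
split (seeded scikit-learn 2-means) until 24 clusters, stopping early
when every remaining cluster is numerically homogeneous — zero-noise
cubes legitimately yield fewer clusters. Majority voting assigns each
cluster its modal class from the framework's final map (the final map,
not the raw spectral map, is the class source); ties break by the
overlay priority tumor > normal > hypervascularized > background, the
same order the threshold sliders use. Per-cluster class frequencies
become a three-layer probability cube (tumor, normal, hypervascularized;
background is never rendered), scaled to RGB and blacked out outside the
parenchyma. Threshold re-classification assigns each pixel the first
class in priority order whose probability meets its slider threshold,
else background; it is monotone in each threshold and replayable from
the stored probability cube.

## Validation statistics

Accuracy `(TP+TN)/(P+N)`, sensitivity `TP/(TP+FN)`, specificity
`TN/(TN+FP)`; a zero denominator yields NaN (undefined) rather than an
exception. ROC curves come from a threshold sweep with tied scores
grouped; AUC is the trapezoid integral, and the optimal operating point
maximizes Youden's J = sensitivity + specificity − 1 (the natural
formalization of "best combined performance"). The class-balanced
bootstrap finds the smallest class count m in the evaluated set, draws m
samples with replacement from every class per replicate, computes the
metrics on the balanced resample, and reports the mean with the 2.5/97.5
percentiles over 1000 replicates; multiclass sensitivity, specificity
and AUC are one-vs-rest per class then averaged, per-class "accuracy" is
that class's sensitivity, and overall accuracy is computed on the
balanced resample so every class contributes equally. Per-replicate AUC
uses the tie-aware Mann–Whitney rank statistic. Leave-one-patient-out
cross-validation keys folds on patient identifiers; all images of the
test patient are excluded from training.

## Synthetic data: what it emulates, and what it does not

Class signatures are smooth sigmoid-like reflectance baselines plus
Gaussian absorption dips — few parameters that reproduce the qualitative
shapes of measured tissue spectra. The hypervascularized class has its
main dip at 545 nm (inside the 500–590 nm hemoglobin window) and an
explicitly larger spread at long wavelengths, where vessels and
extravasated blood genuinely diverge; the background is a distinct
step-like family with a slight tilt (never exactly constant, so its
normalized shape is well defined). Patients differ by seeded
perturbations of baseline level, dip depth, and long-wavelength slope
(`patient_shift_sd`, default 0.05); images within a patient share the
perturbation exactly.

Scenes are an elliptical parenchyma in a background frame with circular
tumor blobs (placed first, painted last, so they remain intact connected
components), quadratic-Bézier vessel curves ~3 px wide, one
extravasated-blood blob, and rubber-ring marker annuli of background
class. Raw counts follow
`raw = dark + (white − dark) · reflectance · illumination + noise` with a
lamp-shaped gain, a smooth multiplicative illumination field (amplitude
0.15 by default), additive spectral noise in reflectance units (default
0.01), and rounding to 12-bit integer counts. With noise, illumination
gradient, and quantization disabled, calibration recovers the planted
reflectance exactly — the inversion property the tests exercise;
quantization is kept on by default precisely because it exposes
integer/float handling.

The generator does **not** model radiative transport, realistic tissue
optics, specular glare, motion, or label noise, and its class
separations are far cleaner than surgical data. Passing the end-to-end
tests therefore demonstrates that the pipeline's stages are implemented
correctly and compose correctly — not that the architecture reaches any
particular clinical accuracy.

## Desk-scale study conditions

The end-to-end study runs on a seeded cohort of six synthetic patients,
one 64×64 scene each, with the default noise and inter-patient
variation. Per fold the spectral net trains for 40 epochs, the vessel
net for 16 (ReLU convolutions, 6/8/12 filters, 48-wide dense layer,
50 vessel + 50 non-vessel patches per scene), and the segmenter for 8
epochs at base width 8; the parenchyma morphology radius is 5 px. These
sizes are the package's chosen desk-scale conditions: small enough to run
on one CPU in a few minutes, large enough that every stage — including
fusion and the density rendering — is exercised nontrivially. Under
them the leave-one-patient-out study reaches ~0.98 mean pixel accuracy
and ~0.99 parenchyma Dice, and on zero-noise scenes the density-map
color argmax reproduces the planted classes inside the parenchyma
exactly.

## Known limitations

- Sigmoid convolutions (the printed configuration) are retained as the
  default for the multiclass patch CNN but train poorly at small scale;
  the ReLU switch is the practical setting and the one the experiments
  use.
- The NumPy engine is single-device and unoptimized for large images;
  full-resolution intraoperative cubes (≈1000×1000×826) would need a real
  accelerator stack.
- Bootstrap confidence intervals are percentile intervals; no DeLong or
  BCa correction.
- The ENVI reader supports the common little-endian BIL/BIP/BSQ layouts
  with an in-header wavelength block only.
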