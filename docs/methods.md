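# Methods

`retro_t2` estimates quantitative prostate T2 maps (ms) from
conventional T1- and T2-weighted images with a 2D U-Net, using
mono-exponential fits of a multi-echo spin-echo (MESE) series as the
training reference. Because no public dataset exists for this problem,
the package includes a physics-based digital phantom that emulates the
study design end to end, so every stage — simulation, reference
fitting, preprocessing, training, evaluation, and the two-timepoint
active-surveillance (AS) analysis — can be exercised and verified at
desk scale on one CPU.

## Signal simulation

Each synthetic subject is a multi-slice stack of nested ellipses
(background tissue, muscle/body, transition zone, peripheral zone, a
tumor inside the peripheral zone, and a bladder), with per-subject
random axes/centers and a through-plane taper. Ground-truth property
maps are tissue-class means times `(1 + Gaussian jitter)` (default sd
3%) times a smooth multiplicative bias field (default amplitude 5%,
Gaussian smoothness 32 voxels). Class T2 defaults (ms): tumor **80.4**,
peripheral zone **106.8** (the tumor/non-tumor contrast level reported
for prostate-cancer cohorts), transition zone 90, muscle and background
40, bladder 800 (deliberately above the 400 ms extreme-value threshold,
as urine is in vivo). T1 values (900–4000 ms) are literature-typical
assumptions: patient-level T1 is rarely reported for this protocol, so
they are config-exposed and flagged as assumptions.

Three acquisitions are simulated per subject, with the protocol
parameters of a 3 T pelvic exam:

* **FLASH T1w** (TE 2.03 ms, TR 250 ms, flip 48°), Ernst equation
  `S = PD sinα (1−E1)/(1−cosα E1) exp(−TE/T2)`, `E1 = exp(−TR/T1)`;
* **TSE T2w** (TE 108 ms, TR 3000 ms),
  `S = PD (1−exp(−TR/T1)) exp(−TE/T2)`;
* **MESE** (TR 4980 ms, 8 echoes at 10.5–84.0 ms, step 10.5 ms), the
  same spin-echo equation per echo.

Mono-exponential decay is assumed; stimulated echoes, B1 errors, and
T2* effects are not modelled. This is the simplest physics consistent
with the mono-exponential reference fit, and it means the phantom
cannot probe the first-echo bias that motivates dropping echo 1 in real
MESE data — the pipeline still drops it, but on synthetic data this is
exercised as a contract, not as a physical correction. Magnitude noise
is Rician, `sqrt((S+n1)² + n2²)` with `n1,n2 ~ N(0,σ²)`, default σ=1.5
a.u. (SNR ≈ 20–40 in tissue, a realistic clinical range). Motion
between acquisitions is a smooth random in-plane displacement field
(Gaussian-filtered white noise scaled to a 3 mm maximum, smoothness 12
voxels), applied with linear interpolation; the true field is returned
so registration accuracy is measurable.

What the phantom does **not** emulate: real pelvic anatomy and its
inter-subject variability, partial-volume mixtures at boundaries,
through-plane motion, susceptibility/bias-field artifacts of real
scanners, and multi-focal or transition-zone tumors. Passing the
recovery experiment therefore shows the pipeline is correct and the
estimator can invert the (known) signal physics under noise and
misalignment — it does not certify clinical performance on real data.

## Reference T2 fitting

Per voxel, `S(TE) = S0 exp(−TE/T2)` is fitted to the MESE train with
the first echo dropped (standard relaxometry practice). The primary
fitter is log-linear weighted least squares with weights `S²`, which
undoes the log-domain noise distortion and is exact on noiseless data;
an optional vectorized Gauss-Newton polish refines the estimate in the
signal domain (this is what matches a brute-force signal-domain
grid-search to within 0.1 ms on noisy voxels). Voxels with any
non-positive retained echo are excluded (log undefined; such voxels
are background) rather than clamped. Fitted T2 has no upper clamp —
extreme values are handled downstream by the extreme-value mask, which
preserves the pipeline's order of operations.

## Preprocessing

1. **Resampling/cropping**: weighted images are linearly resampled onto
   the T2-map grid; crops must be shared across a subject's volumes and
   the network requires in-plane dimensions divisible by 16.
2. **Deformable registration**: per-slice multi-resolution (4/2/1)
   symmetric-forces demons, 60 iterations, displacement smoothing sd 2
   voxels, with Gaussian presmoothing (σ=1 voxel) of both images to
   suppress independent acquisition noise. The registration target is
   the MESE echo whose TE is closest to the T2w TE (84.0 ms for a
   108 ms T2w; ties break toward the larger TE). The T2w image is
   registered on histogram-matched intensities (similar contrast); the
   T1w image on gradient-magnitude images, because urine flips from
   dark (T1w) to bright (late echo) and monotone intensity matching
   cannot fix an inverted contrast, while edge locations are shared.
   A slice whose mean squared difference increases under intensity
   registration falls back to the unwarped slice with a warning flag.
   On phantoms deformed by a known 3 mm field, mean residual
   displacement inside the prostate is ≈0.8 mm.
3. **Bladder mask**: Otsu threshold on the dark (urine) mode of the
   T1w image, per-slice morphological opening (radius 2) and hole
   filling, then the largest connected component whose centroid lies in
   the anterior half of the image. A bimodality guard (the dark mode
   must sit at least 20% below the bright mode) returns an empty mask
   for bladder-free images. Manual correction is replaced by an
   optional mask override. The dark-urine assumption is invertible in
   config for protocols where urine is bright.
4. **Normalization**: each weighted volume is divided by
   `mean + 3·sd` over all non-bladder voxels (population sd, pinned for
   reproducibility); bright urine therefore cannot rescale the
   prostate.
5. **Scaling and extreme masks**: reference T2 maps are divided by
   **400 ms** (0–400 ms covers most pelvic tissue) to give
   dimensionless targets; voxels with reference T2 strictly above
   400 ms form the extreme-value mask, excluded from the training loss
   and from every evaluation metric.

## Estimator

A 2D U-Net maps the 2-channel normalized (T1w, T2w) slice to the scaled
T2 slice: four encoder stages (each two 3×3 convolutions with batch
normalization and ReLU, then 2×2 max pooling), a bottleneck, four
decoder stages (2×2 transposed-convolution upsampling — nearest+conv
available as a config alternative — skip concatenation, two 3×3
convolutions), and a final 1-channel projection. Channel width doubles
per stage from `base_width`. Convolutions are zero-padded "same", so
output size equals input size.

The network, its backward passes, the masked L1 loss and the Adam
optimizer are implemented directly on NumPy (NHWC float32, im2col +
BLAS matmul), which keeps the package dependency-light and exactly
reproducible; gradients are verified against central differences in
float64. Training minimizes mean |pred − target| over pixels outside
the extreme-value mask (bladder pixels stay **in** the loss by default
— they are excluded only from normalization and evaluation; a config
flag flips this). The best-validation-loss state is returned.
Inference is slice-wise; outputs are multiplied by 400 ms and clamped
at 0.

Splits are subject-level: a k-fold planner with fixed
train:val:test sizes (default 4 folds, 19:2:4 for a 25-subject cohort),
pairwise-disjoint test sets, and greedy placement of "must-test"
subjects (so e.g. every cancer patient is evaluated exactly once); it
errors when capacity cannot cover them. Because 4 folds × 4 test
subjects may undershoot a must-test list of 17, per-fold size overrides
are accepted.

## Evaluation

Global metrics are computed slice by slice over voxels outside the
bladder and extreme masks: PSNR (`20 log10(400/RMSE)`; fixed 400 ms
dynamic range for cross-slice comparability; a 0-RMSE slice reports a
300 dB sentinel with a flag), SSIM (11×11 Gaussian window, σ=1.5,
K1=0.01, K2=0.03; masked voxels zero-filled before the windowed pass
and only unmasked fully-interior window centers averaged, so the
metric is strictly blind to masked values), MPE (mean of
`|est−ref|/ref·100` over voxels with reference above a 1 ms floor; the
alternative |mean error|/mean-ref definition is config-selectable), and
Pearson r (reported both per-slice-averaged and pooled across voxels,
since either convention is defensible). ROI analysis reduces maps to
tumor / non-tumor peripheral-zone means compared with two-sided
paired/unpaired (Welch) t-tests at α=0.05 — raw p-values, no multiple-
testing correction, noted in the report — and Bland–Altman limits of
agreement (absolute or percent mode). For AS cohorts, deltaT2 =
timepoint-2 minus timepoint-1 tumor ROI mean; arms are compared by
Welch t-test and by the ROC AUC of the negated delta, computed with the
rank (Mann–Whitney) statistic, ties counting ½.

## Desk-scale defaults and problem sizes

The default recovery experiment uses 26 subjects of 128×128×12 voxels
(1.172×1.172×3 mm), one fold with a 20:2:4 split, `base_width` 8,
batch 8, learning rate 1e-2, 12 epochs. These sizes are chosen so the
whole experiment (simulation → fit → registration → training →
evaluation) completes in under ten minutes on a single CPU while still
recovering tumor-ROI T2 to a few ms; the full 24-slice protocol,
4-fold CV and wider networks are plain config changes. The learning
rate is higher than typical GPU-scale practice because the optimizer
takes only a few hundred steps at this scale; at 1e-3 the network is
visibly unconverged within the step budget.

Numerical conventions worth knowing: the through-plane axis is always
the last axis; weighted images carry arbitrary units and T2 maps ms,
with the units tag in a JSON sidecar; the extreme threshold is a strict
inequality (400 ms itself is kept); registration-target ties break to
the larger TE; the fit excludes rather than clamps non-positive
signals; every stage is a pure function of (config, seed), and the
config hash plus seed are logged for traceability.

## Known limitations

* The phantom's tumor contrast is, by construction, learnable from two
  weighted contrasts; real tissue heterogeneity, protocol drift and
  scanner differences are out of scope.
* The demons registration assumes in-plane motion; through-plane motion
  is neither simulated nor corrected.
* The gradient-channel registration for T1w relies on shared edges; it
  degrades when edges are sparse (e.g. very smooth anatomy).
* The NumPy estimator is CPU-bound and intended for desk-scale
  experiments, not clinical-volume training.
* DWI/DCE acquisitions, radiologist ROI drawing, T1 mapping, GAN or
  transformer estimators, and multi-scanner generalization are
  explicitly out of scope.
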