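# retro-t2

Retrospective quantification of prostate T2 from conventional weighted
MRI, with a physics-based digital phantom for end-to-end validation.

## The problem

Quantitative T2 maps separate prostate tumor from normal peripheral
zone (tumor T2 is lower) and can track progression under active
surveillance, but dedicated T2-mapping sequences are long and rarely
part of clinical protocols. This package implements the retrospective
alternative: estimate the T2 map directly from the T1-weighted (FLASH)
and T2-weighted (TSE) images every clinical exam already contains,
using a 2D U-Net trained against mono-exponential fits of a multi-echo
spin-echo (MESE) reference,

S(TE) = S₀ · exp(−TE/T2),

fitted per voxel with the first echo dropped. The surrounding pipeline
is the part that makes this work on pelvic data: deformable
registration of the weighted images to the MESE echo with the closest
contrast (TE = 84 ms), bladder masking, per-volume mean+3σ intensity
normalization, scaling of T2 by 400 ms, and extreme-value masks
(T2 > 400 ms, i.e. urine) excluded from loss and metrics.

Since clinical prostate cohorts are private, the package ships a
digital phantom: multi-slice elliptical pelvic anatomy with ground-truth
PD/T1/T2 maps (tumor 80.4 ms vs peripheral zone 106.8 ms), standard
FLASH/TSE/MESE signal equations, Rician noise, inter-acquisition
deformation with known fields, and two-timepoint active-surveillance
cohorts whose tumor delta-T2 distributions are Normal(−10.7, 14.2²) ms
for progressors and Normal(3.4, 14.5²) ms for non-progressors. Every
stage of the method is therefore testable against known ground truth.

## Worked example

Run the default desk-scale recovery experiment (26 synthetic subjects,
128×128×12 voxels, 20 train / 2 val / 4 test, ~8 min on one CPU):

```bash
retro-t2 experiment --config /dev/null --out out/
```

which prints (seed 0 is the default; the run below used `seed: 1`):

```json
{
 "mean_abs_tumor_error_ms": 5.554,
 "pearson_slice_mean": 0.939,
 "pearson_pooled": 0.942,
 "tumor_vs_nontumor": {"t": -25.276, "p": 0.000136, "significant": true}
}
```

Reading: on held-out test subjects the estimated tumor-ROI mean T2 is
within 5.6 ms of the phantom ground truth on average; estimated and
reference maps correlate at r ≈ 0.94 slice-wise; and the estimated
tumor T2 is significantly below the non-tumor peripheral-zone T2
(paired t-test), i.e. the network preserves the contrast that makes T2
clinically useful. `out/slice_metrics.csv` holds per-slice PSNR / SSIM
/ MPE / Pearson (computed outside the bladder and extreme-value masks)
and `out/roi_stats.csv` the per-subject ROI means.

Other stages are available individually:

```bash
retro-t2 simulate  --config c.yaml --out sim/          # phantom + acquisitions
retro-t2 fit       --echoes sim/sub-000 --te 10.5,21.0,31.5,42.0,52.5,63.0,73.5,84.0 --out t2.nii.gz
retro-t2 preprocess --subject sim/sub-000 --out pre/
retro-t2 evaluate  --est est.nii.gz --ref ref.nii.gz --out metrics.csv
retro-t2 as-analysis --seed 1 --n-per-arm 5000         # delta-T2 AUC study
```

All parameters live in one YAML config (see `retro_t2/config.py` for
the schema and defaults); an empty config file gives the defaults used
above.

## Layout

- `src/retro_t2/io_core.py` — NIfTI volumes/labels, units sidecars
- `src/retro_t2/config.py` — the YAML run configuration
- `src/retro_t2/phantom.py` — anatomy, signal models, noise, deformation, AS cohorts
- `src/retro_t2/t2fit.py` — reference mono-exponential fitting
- `src/retro_t2/preprocess.py` — registration, bladder mask, normalization, masks
- `src/retro_t2/nn.py`, `estimator.py` — NumPy U-Net, splits, training, inference
- `src/retro_t2/metrics.py` — masked PSNR/SSIM/MPE/Pearson, ROI stats, t-tests, Bland–Altman, AUC
- `src/retro_t2/experiment.py` — the end-to-end study
- `docs/methods.md` — models, assumptions, parameter choices, limitations
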