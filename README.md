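# shgfb

Forward/backward second-harmonic-generation (SHG) ratio quantification of
fibrillar collagen, and survival analysis of the resulting biomarker.

## The problem

Fibrillar collagen in tissue generates SHG without any staining, and the
ratio of forward-emitted to backward-emitted SHG intensity (**F/B**) reports
on the internal structure of individual collagen fibers — fibril diameter,
spacing and packing disorder. Because collagen organisation changes with
tumor progression, the average F/B of a biopsy is a candidate prognostic
marker: in lymph-node-negative breast cancer it can be measured on standard
pathology slides by a fully automated pixel analysis, no trained observer
required. This package implements that measurement chain and the downstream
prognostic statistics for people who want to run, test or simulate it:
microscopists quantifying F/B from paired-detector image stacks, and
analysts relating the marker to survival endpoints.

## What it computes

**F/B measurement.** Per imaged location, with 11-frame focal stacks
`F_k`, `B_k` and a closed-shutter noise stack `N_k`:

1. maximum-intensity projection: `F = max_k F_k`, `B = max_k B_k`
   (sections are one collagen layer thick, so this is an auto-focus);
2. background subtraction `F ← max(F − max_k N_k, 0)` (per-pixel by
   default; scalar mean optional);
3. binary masks `M_F = [F > T]`, `M_B = [B > T]` at a common threshold
   `T = 40` of the 4095-count (12-bit) range, multiplied into one
   forward×backward mask `M = M_F · M_B`;
4. the sample's F/B is the mean of the ratio image `F/B` over `M`,
   normalised by daily-standard (FITC) calibration factors that cancel
   detector-gain drift; multi-location samples average their per-location
   values. The analysis marker is `ln F/B`.

**Orientation anisotropy.** The R² of a line fitted to the bright pixels
(> 20 on an 8-bit scale) of the centred Fourier magnitude spectrum of the
forward image — near 1 when the fiber ensemble shares one (oblique)
orientation, near 0 when isotropic.

**Survival analysis.** Quartile stratification of `ln F/B` with
Kaplan-Meier curves, a 1-df log-rank test for trend across Q1–Q4, and
univariate/multivariate Cox proportional-hazards models (Breslow ties,
Wald CIs) for metastasis-free, overall and progression-free survival, with
the usual clinical covariates and complete-case handling of missing values.

**Synthetic data.** Everything is testable without microscope access:
generators produce paired fiber-field stacks with known per-pixel F/B,
von-Mises-controlled orientations, noise/calibration fixtures with
controllable gain drift, and cohorts whose hazard is log-linear in
`ln F/B`.

## Worked example

`examples/03_survival.py` simulates a 221-patient cohort whose metastasis
hazard falls with `ln F/B` in ER+ disease (log-HR −1.5 per unit) and runs
the full prognostic analysis on the ER+ subset:

```
ER+ subset: n = 123
ln F/B quartile cutpoints: 2.005 / 2.191 / 2.326
log-rank trend across Q1..Q4: chi2(1) = 6.05, p = 0.0139
univariate Cox, continuous ln F/B: HR = 0.18 (95% CI 0.06-0.53), p = 0.0021
multivariate Cox (adjusted)      : HR = 0.21 (95% CI 0.07-0.68), p = 0.0093; 2 patient(s) dropped for missing covariates
```

HR < 1 on the continuous marker means higher F/B predicts longer
metastasis-free survival; the trend test says the same thing across ordered
quartiles. The other examples cover the image pipeline
(`01_fb_ratio.py`), the anisotropy statistic (`02_anisotropy.py`) and an
end-to-end run from files on disk with a deliberate detector-gain mismatch
(`04_full_pipeline.py`).

There is also a thin CLI over the same functions:

```bash
shgfb simulate --out session/ --seed 1
shgfb compute --manifest session/manifest.json --out fb.csv
shgfb anisotropy --manifest session/manifest.json --out aniso.csv
shgfb survival --cohort session/cohort.csv --subset "er == 'pos'" --out report/
```

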