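# Methods

This note records the measurement model, the statistical procedures, the
conventions the package had to fix where the underlying method leaves them
open, and what the synthetic generators do and do not emulate.

## F/B measurement chain

Per imaged location the pipeline consumes one 11-frame stack per detector
(12-bit counts in a 16-bit TIFF container; a count above 4095 is treated as
an acquisition fault and rejected, never clipped). Tissue sections (~5 µm)
are comparable to the axial resolution, so the specimen is effectively a
single collagen layer and a maximum-intensity projection over frames acts
as an auto-focus. The closed-shutter noise stack is projected the same way
and subtracted; negative differences are clamped to zero so counts stay
non-negative and masks stay well defined.

A single threshold (default 40 counts of 4095) is applied to **both**
background-corrected channels; a pixel enters the analysis only if it
exceeds the threshold in the forward *and* the backward image (the
forward×backward mask). The sample's F/B is the arithmetic mean of the
pixel-wise ratio F/B over that mask; inside the mask the denominator is
> 40, so the ratio is always finite and positive. Multi-location samples
(three random fields for centimetre-scale sections, one central field for
0.5 mm TMA cores) average their per-location F/B values arithmetically.
`ln F/B` is the natural logarithm of that average.

Conventions this package fixes (the method's published description leaves
them open):

* **Threshold comparison is strict** (`> 40`, not `≥`), for determinism at
  the boundary.
* **Background is per-pixel by default** (the projected noise image is
  subtracted image-wise); a scalar mode (mean of the projection) is
  available since a single dark level is the other plausible reading.
* **Calibration is applied after masking**, as the multiplicative factor
  `f_F / f_B` on the ratio, where `f_c = reference_c / mean(projected
  calibration image_c)` from the daily FITC standard. The threshold is
  stated in raw detector counts, so masking must see uncalibrated counts;
  applying the factor to the ratio is algebraically identical to
  calibrating F and B separately and then dividing.
* **Zero-mask locations are excluded** (logged), never scored F/B = 0,
  which is not a valid ratio; a sample whose locations are all empty is an
  error for the caller to handle.

## Fourier anisotropy

The anisotropy statistic is the R² of an ordinary least-squares line
(row on column) through the coordinates of the bright pixels of the
centred 2-D magnitude spectrum of the forward image. Conventions, all
reconstructions rather than published facts:

* **Display scale.** The threshold of 20 presumes an 8-bit display scale.
  The default maps the magnitude **linearly** onto [0, 255] (the standard
  Matlab magnitude display); on a log(1+magnitude) scale — also provided,
  along with raw magnitudes — a threshold at 8 % of the range keeps
  virtually the whole spectrum plane of any realistic fiber image, because
  even the incoherent spectral floor of a fibrous field sits several
  e-folds above zero. Linear scaling keeps exactly the bright oriented
  band and produces the aligned/isotropic separation the statistic exists
  for, so it is the default.
* **DC exclusion.** The zero-frequency pixel carries no orientation
  information and would dominate both the scale normalisation and any
  threshold; it is zeroed before scaling and excluded from binarization.
* **Axis blind spot.** R² of a simple regression equals the squared
  correlation of the two coordinates and is therefore *symmetric in the
  regression direction*: an axis-parallel band of spectrum points (fibers
  parallel to an image axis) has correlation ≈ 0 no matter which variable
  is regressed on which, and scores low. `symmetrize=True` also evaluates
  R² on the point set rotated 45° about the spectrum centre and reports
  the larger value, which removes the blind spot; the default leaves the
  statistic in its plain form.
* Fewer than 3 points, or zero variance in the regressor, make the
  statistic undefined; such samples are flagged, not scored.

## Survival analysis

Endpoints are metastasis-free survival (event: confirmed distant
metastasis; deaths without metastasis censor at death — no competing-risks
model), overall survival (event: death; deaths without evidence of disease
censor at last follow-up, with an all-cause variant available in the
cohort generator), and progression-free survival under tamoxifen (event:
second-line treatment or death). Times are months, flags 0/1.

* **Quartiles** use linear interpolation between order statistics for the
  25/50/75 cutpoints (also for all IQRs); assignment is `value ≤ cut`
  going up, so ties share a quartile and a fully tied sample degenerates
  to Q1.
* **The log-rank trend test** weights each ordered group's
  observed-minus-expected event count by an equally spaced score (1..4 for
  quartiles); the squared weighted sum over event times divided by its
  hypergeometric variance is χ²(1). With two groups and scores {0, 1} it
  reduces exactly to the ordinary log-rank statistic, and on untied data
  it equals the Cox score test with the group score as covariate — both
  equalities are tested.
* **Cox models** maximise the partial likelihood with **Breslow** tie
  handling by default (Efron available), matching the convention of the
  statistics package the analysis mirrors. HR = exp(coef) with Wald 95 %
  CIs. Multivariate models adjust for age band, menopausal status, tumor
  size, tumor grade, PgR and HER2 (reference levels: ≤40 years,
  premenopausal, pT1, grade I, receptor-negative); ER status enters by
  subsetting, not as a covariate. Missing covariates cause complete-case
  deletion with the dropped count reported. A covariate level with no
  observed events yields a monotone likelihood for its dummy; the fit is
  kept and the term flagged (unbounded Wald interval), while a diverging
  coefficient (|coef| > 25) or a failed maximisation raises an error.
* **No multiple-testing correction** is applied; each endpoint/subset is
  tested two-sided at 0.05, matching field practice for a single
  prespecified marker.

## Synthetic data

The generators define the conditions every test runs under.

**Fiber fields.** Straight segments (length 180 px, width 4 px by default,
30 per 256×256 field) with von Mises orientations (κ = 50 ≈ aligned,
κ = 0 = isotropic), rasterised by 4×4 subpixel coverage sampling so
coverage is an exact multiple of 1/16. The backward channel carries
`coverage × intensity`, the forward channel `coverage × intensity ×
true_fb`; 11 frames attenuate by 0.6 per frame of defocus so maximum
projection recovers the in-focus plane exactly. Noise is Poisson (shot
noise) or Gaussian; offsets model the dark level. Straight fibers keep the
ground truth analytic — curvature, misregistration between detectors, and
physical emission modelling (deriving F/B from fibril structure) are
deliberately out of scope: true_fb is stipulated, not derived.

Quantization-aware choices: the default intensity 1600 is a multiple of 16
so noise-free counts are exact integers and the pipeline recovers
`true_fb` with zero error; `true_fb = 8` exceeds the 12-bit ceiling at
that intensity, so high-ratio tests use intensity 480 (and 496 under
noise). Gain sweeps use intensity 800 with gains on a 0.02 grid, keeping
`gain × count` integral — with arbitrary real gains, 12-bit re-quantization
alone injects ~1e-4–1e-3 relative error and an invariance test would
measure rounding noise instead of the calibration algebra.

**Cohorts.** `ln F/B ~ Normal(2.228, 0.416/1.349)` — the observed
population median and IQR under a normality assumption. Event times are
exponential with rate `0.004/month × exp(β·(ln F/B − mean))`;
administrative censoring at 120 months gives ~55–60 % censoring, with
optional uniform dropout. Per-endpoint defaults for ER+ patients follow
the reported continuous-marker effects: β = −1.5 (MFS, HR ≈ 0.22), −1.1
(OS), +1.2 (PFS, the tamoxifen reversal); ER− patients get β = 0, the
reported null. Overall survival mixes in an independent other-cause death
process (0.002/month) handled per the OS rule above. Covariates are drawn
independently at the observed prevalences, with ~2.7 % of grades missing.
What this does **not** emulate: correlation between the marker and
covariates (the real marker is higher in receptor-negative tumors),
non-proportional hazards, informative censoring, and per-patient imaging
noise on `ln F/B` — so passing tests certify the statistical machinery
under the stated model, not robustness to those violations.

## Problem sizes and determinism

All generators are pure functions of (spec, seed). The oracle-agreement
check uses 50 random 32×32 stack pairs against a pure-Python loop; noisy
recovery uses 20 seeds per ratio at 128×128; anisotropy separation uses 20
replicates at 256×256; Cox calibration uses 100 replicates of n = 500 per
β and 200 null replicates of n = 221; direction checks use 50 replicates
of n = 200, comparing quartile curves at the standard KM reporting grid
(24-month steps), which is where such curves are read in practice.

## Known limitations

* The anisotropy statistic ignores how *many* orientations are present —
  only collinearity of bright spectrum pixels; crossing fiber families at
  ±45° would produce an X-shaped spectrum and a misleadingly low R².
* The F/B measurement assumes perfect forward/backward registration.
* MFS treats death as censoring, which overestimates metastasis-free
  probability when mortality competes; a Fine-Gray model is out of scope.
* Wald CIs are used throughout; profile-likelihood intervals would behave
  better at small event counts.
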