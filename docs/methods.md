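# Methods

This note documents the models implemented in `aaapulse`, the choices made
where the design was genuinely open, and what the synthetic data can and
cannot show.

## Arterial transmission-line model

The systemic arterial tree is a rooted network of 55 uniform, linear,
lossy transmission lines closed by 3-parameter Windkessel loads. Per unit
length, a line with inner radius `r`, wall thickness `h` and Young's modulus
`E` carrying blood of density `rho` (1050 kg/m^3) and viscosity `mu`
(4 mPa s) has

* longitudinal impedance from Womersley theory,
  `Z' = (j omega rho / A) / (1 - F10(alpha))` with
  `alpha = r sqrt(omega rho / mu)` and `F10 = 2 J1(z)/(z J0(z))`,
  `z = i^{3/2} alpha`; the `omega -> 0` limit is the Poiseuille resistance
  `8 mu / (pi r^4)`;
* thin-wall elastic compliance `C' = 3 pi r^3 / (2 E h)`, implying the
  lossless wave speed `c = sqrt(2 E h / (3 rho r))`.

`F10` is evaluated through a cubic-spline tabulation of the exact Bessel
expression (relative error < 1e-8 over the physiologic range, with series and
asymptotic branches below alpha = 1e-4 and above 600); the tests compare it
against an independent power-series evaluation. Wall viscoelasticity of the
lines themselves is off: damping enters only through blood viscosity and the
cuff interface model below.

The periodic solve is exact per harmonic of the heart period: input
impedances are assembled leaf-to-root (`Z_in = Zc (Z_L + Zc tanh(gamma l)) /
(Zc + Z_L tanh(gamma l))`, daughters in parallel), the root pressure is
`Z_in * Q`, and pressures propagate root-to-leaf by forward/backward wave
decomposition with the distal reflection coefficient
`Gamma = (Z_L - Zc)/(Z_L + Zc)`. The mean component is solved on the
Poiseuille-resistance skeleton. Because the solution is constructed in the
frequency domain there is no settling transient; records are 2 s at 128 Hz
(256 samples), evaluated from up to 40 harmonics (capped below the Nyquist
frequency). The solver is validated against an independently coded
ABCD-matrix cascade to 1e-10 relative error.

### Anatomy and terminal loads

The packaged 55-artery table (`data/anatomy55.yaml`) follows the published
Avolio/Stergiopulos-type datasets in topology and dimensions; segment 31 is
the infrarenal abdominal aorta (the aneurysm host). Wall stiffness uses
elderly-range values (ascending aorta 0.6 MPa, muscular limb arteries
1.2 MPa, tibial/internal iliac 2.4 MPa), chosen so that the cohort's
carotid-femoral pulse wave velocity (cf-PWV) spans roughly 5-12 m/s across
the stiffness variability range and rises with age. Terminal resistances are
distributed proportional to `r^-2.2` and normalised to a net peripheral
resistance of 1.35e8 Pa s/m^3 (mean pressure ~89 mmHg at 87.5 mL/s cardiac
output); terminal compliances share a common RC constant of 1.3 s; the
proximal Windkessel resistance is 20% of the total, which approximately
matches the characteristic impedance of the feeding arteries. Everything is
overridable through the YAML table.

### Aneurysm model

The dilation multiplies the luminal area of the host segment by
`1 + (A_SL/2)(1 - cos(2 pi (x + 1/2)))` over a centred fraction `l_AAA` of
its length, and multiplies the wall stiffness there by `K_E`. The volumetric
severity index is `VSI = 100 (V/V0 - 1) / 2.625`, the exact integral of the
area profile normalised by its maximum (at `l_AAA = 1`, `A_SL = 5.25`). The
bump is discretised into 16 uniform sub-segments with midpoint radii; halving
the cell size changes site pressures by < 0.5% RMS, and the degenerate
parameters (`A_SL = 0`, `K_E = 1`) reproduce the healthy tree to floating-
point precision. Maximum-diameter severity, used as a comparison label, is
`100 (sqrt(1 + A_SL) - 1)` percent.

### Inflow

The ventricular ejection is a half-sine of duration
`T_sys = 0.3 sqrt(60/HR)` s with exact per-beat volume equal to the stroke
volume and zero diastolic flow. A sharper "physiologic" shape with an
end-systolic backflow notch was evaluated and rejected: it destabilised the
upstroke morphology that two of the waveform features depend on.

## Cohort synthesis

Ages are uniform on [40, 80] y. Age multipliers on the nominal parameters are
linear in age (1 at the reference age of 50): stroke volume -0.4%/y,
proximal-aorta length +0.4%/y, radii +0.2%/y, terminal compliance -0.8%/y,
terminal resistance +0.4%/y; wall stiffness is exponential,
`exp(0.022 (age - 50))`. The slopes are package calibrations (the source
formulas are not public) chosen so that cf-PWV, aortic systolic and pulse
pressure rise with age while aortic-to-brachial pulse-pressure amplification
falls, and the cohort cf-PWV occupies the stated 5-15 m/s band as far as the
stiffness range allows (in practice ~4.6-11.7 m/s).

Eight inter-individual variability (IIV) coefficients multiply heart rate,
stroke volume, lengths, radii, thicknesses, terminal resistances, terminal
compliances (all uniform 0.8-1.2; heart rate nominal 75 bpm so the range is
60-90 bpm) and wall stiffness (uniform 0.7-1.6). Severity is uniform on
[0, 100]% VSI; the bump extent is uniform on [max(0.4, VSI/100), 1] (the
lower bound keeps `A_SL <= 5.25` feasible); `K_E` is uniform on [1.25, 2.45],
independent of geometry. Subject height is `170 cm x` the length IIV
coefficient, which makes it a true waveform-affecting confounder for the
adversarial heads. Sample-to-sample variability multiplies every circulation
parameter by independent N(1, 0.01) draws per recording and re-draws the five
cuff constants from lognormals with median at the subject value and 1% CV.
Cuff-constant subject-level distributions are lognormal with medians
(E_B1, E_B2, eta_B, E_T, eta_T) = (1, 4, 0.2, 1, 0.1) in normalised units and
log-dispersion 0.2 — stand-ins, since the fitted patient distributions are
not public and the PVR scale is arbitrary.

## Cuff (PVR) model

Brachial: standard linear solid,
`H_B(s) = (E_B2 + eta_B s) / (E_B1 E_B2 + (E_B1 + E_B2) eta_B s)`;
tibial: Voigt body, `H_T(s) = 1/(E_T + eta_T s)`. Both are applied as exact
per-harmonic multiplications on the steady-state periodic record; a causal
bilinear-transform IIR variant is provided for streaming input and agrees
within 1% RMS on periodic records.

## Waveform features

* **cf-PWV**: tree path length (root-to-femoral minus root-to-carotid)
  divided by the mean foot-to-foot transit time; feet by the
  intersecting-tangent method (horizontal through the diastolic minimum
  intersected with the tangent at maximum upstroke slope). Beats are
  Fourier-upsampled 8x before landmark localisation.
* **CUI**: exhaustive split of the foot-to-peak upstroke minimising the sum
  of the two line-fit RMS errors (ties to the earlier index; closed-form
  running-sum least squares, identical to per-split fitting); CUI is the
  peak-to-intersection amplitude over pulse pressure. The pooled-total-RMSE
  split variant was evaluated and rejected (wrong severity direction).
* **CAR**: diastolic over systolic area above the diastolic minimum, split at
  the systolic peak (no incisura detector; configurable split).
* **COR**: spectral energy in 3-8x the fundamental over (0, 3x), computed on
  the mean-subtracted full 2-s record; the 3x boundary bin counts as high.

CUI, CAR and COR are amplitude-scale invariant; all four are time-shift
invariant. Features are averaged across complete beats.

On matched severity sweeps (everything fixed except the aneurysm) the
directions agree with the expected physiology: PWV falls and CUI, CAR, COR
rise with severity. Cohort-level correlations against VSI reproduce the
expected sign pattern (-, +, +, +), but the CUI and COR correlations are
weaker than reported for the source model family: this transmission-line
model driven by a half-sine ejection produces less 3-8 Hz reflection energy,
so upstroke-morphology features carry a smaller severity signature relative
to inter-subject variability. This is the main known limitation of the
generator.

## Severity-estimation network

Input: brachial and tibial waveforms (PVR or BP), each row z-scored, stacked
to (1, 2, 256). Feature extractor: five row-wise convolutions (kernel 5 then
3,3,3,3; stride 1; dilation 3; length-preserving padding; channels
96-192-288-288-288), batch norm (statistics and affine per channel-row, so
the rows never mix), ReLU; a skip connection from layer 2 into layer 4
through a 1x1 projection; CBAM attention after layers 3 and 5 (channel
attention pooled per row, reduction 16; temporal attention with kernel 7);
compression by 1x1 convolution to 32 channels and 4x average pooling to the
(32, 2, 64) latent. Three parallel heads (4096-64-64-1): severity, height,
age. The extractor holds ~810k parameters, each head 266,433.

Losses: MSE on severity (% units, labeled data only); for each adversary the
bounded loss `mean(log(1/(1 - tanh|e|)))` on z-scored targets, computed
through the exact identity `softplus(2|e|) - ln 2` (absolute error keeps the
loss nonnegative and symmetric; raw cm/years would saturate the tanh, hence
the z-scoring against training-pool statistics). Update laws: each head
minimises its own loss with its own Adam optimizer (severity on labeled,
adversaries on labeled + unlabeled, interleaved 1:1); the extractor minimises
`L_label - lambda (L_height + L_age)` — the gradient-reversal reading of the
adversarial objective, which matches the stated intent of making the
adversaries fail; the opposite (printed) sign is available behind
`adversarial_sign="printed"`. The label objective runs on a labeled-only
forward pass so that the `lambda = 0` trajectory is bit-identical to plain
supervised training (verified in the tests). Early stopping: patience 25 on
validation MSE, at most 100 epochs, best checkpoint restored.

The network runs on a small reverse-mode autodiff engine over numpy written
for this package (tape-based; dilated row convolution via im2col matmuls;
gradients verified against central finite differences). Default working
precision is float32; float64 is used for gradient checks. Per-modality Adam
hyperparameters (batch 16): PVR — betas 0.95/0.95, lambda 6.5e-4, learning
rates 1.2e-3 / 1.1e-3 / 7.0e-4 for extractor / severity head / adversaries;
BP — betas 0.989/0.970, lambda 7.3e-4, rates 2.2e-4 / 3.6e-5 / 5.5e-6.

## Evaluation

Regression: Pearson rho, MAE, RMSE, and mean predictions per true-severity
bin (5-15% ... 85-95%). Detection: truth is `VSI > labeling threshold`
(strictly), the call is `prediction > decision threshold` (default equal to
the labeling threshold); sweeps run at 20-80% in 10% steps. ROC and PRC are
built by sweeping the decision threshold over the predictions (no collinear
point dropping); areas are trapezoidal, the PR curve integrated in native
order; ROC-AUC is tested against the Mann-Whitney U statistic. Multi-model
aggregation reports mean and sample (n-1) SD; ROC curves are averaged
vertically over false-positive rate.

## Problem sizes

Defaults are scaled for single-CPU work: cohorts of 50 subjects x 20
recordings (`--paper-scale` switches to 200 x 100), feature cohorts of
10,000 independent subjects in the acceptance script, and reduced
convolution widths for the training runs exercised by the test suite (the
full-width network is the package default and is what the parameter-count
contracts check). The test suite's training check uses 500-subject
training/test splits (one recording each) and a narrow extractor; it demonstrates that the training machinery
learns severity from waveforms, not the headline accuracy of a full-scale
run.

## Known limitations

* The anatomy table, age-dependence slopes and cuff-parameter distributions
  are calibrated stand-ins for non-public sources; absolute feature values
  (especially CUI and COR levels) inherit that uncertainty.
* The aneurysm is an idealised axisymmetric cosine bump without intraluminal
  thrombus, tortuosity or asymmetry.
* No measurement noise, motion artifacts, comorbidities or sex differences
  are modelled; synthetic-to-real transfer is untested.
* The linear frequency-domain solver excludes nonlinear convective effects
  and pressure-dependent compliance.
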