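# Methods

`swqus` implements a five-parameter quantitative-ultrasound (QUS)
characterization of liver tissue driven by a simulated three-push
shear-wave sequence, a regression-tree fusion of the parameters into a fat
fraction, and the statistical machinery used to evaluate it. This note
records the models, the numerical choices and what the simulators do and
do not emulate.

## Physical model

### Shear wavefield (`wave_sim.simulate_shear_wavefield`)

The medium is a Kelvin–Voigt solid: shear modulus `mu = E/3` (Pa, with
Young's modulus `E` in kPa and near-incompressibility assumed) and shear
viscosity `gamma` (Pa·s). The forward model is 1-D lateral plane-wave
propagation synthesized per frequency from the Voigt dispersion relation

    c(w) = sqrt( 2 (mu^2 + w^2 gamma^2) / (rho (mu + sqrt(mu^2 + w^2 gamma^2))) )

which reduces to `c0 = sqrt(E / (3 rho))` at `w = 0`. A unipolar Gaussian
source pulse (width 1.2 ms, fixed) is delayed by `d / c(w)` per frequency
at each tracking-beam distance `d`, so the field's phase velocities are
exact by construction. Amplitude handling is deliberately decoupled from
the phase:

* lateral decay is a frequency-independent factor `exp(-alpha d)` with the
  tissue's configured shear attenuation `alpha` (Neper/m), so `alpha` is
  exactly the log-slope of the peak-displacement profile;
* the source amplitude scales as `I0 * exp(-2 sigma x_focus)` with
  `I0 = V0^2 / (2 c rho)`, the radiation-force absorption law the
  absorption estimator inverts.

The Voigt model's own intrinsic lateral damping is *not* additionally
applied: it would alias into the configured `alpha` and destroy the
ground truth the recovery tests rely on. The 1.2 ms pulse width was chosen
so that the spectral energy sits below ~150 Hz: this keeps the
time-to-peak speed close to `c0` in viscous media (the viscous bias on
recovered `E` stays at the few-percent level for liver-like
`gamma <= 2.5 Pa·s`) and keeps dispersion-induced pulse spreading from
contaminating the lateral decay, while the 50–300 Hz dispersion band
remains fully usable because noiseless DFT phases are amplitude
independent.

Tracking PRF (10 kHz) and beam count (8) are engineering defaults, exposed
in `SequenceConfig`. Push foci are 0.03/0.04/0.05 m with per-focus beam
spacings 0.0012/0.0013/0.0015 m; RF sampling is 40 MHz.

### RF speckle (`wave_sim.simulate_rf_pair`)

Echo frames follow the multiplicative power-spectrum model

    Sp(f, z) = G(f, z) * exp(-4 beta_np f z) * b f^n

with `G` a Gaussian pulse band around the 3.5 MHz center frequency times a
smooth seeded depth gain, shared exactly between target and reference
(the reference-phantom assumption), and independent speckle realizations.
Attenuation `beta` is stored in dB/MHz/cm and converted by
`beta_np = beta * ln(10)/20 * 100 / 1e6` Neper/Hz/m (`swqus.units`).

Speckle is synthesized block-wise: 128-sample depth blocks of white
Gaussian noise filtered to the model spectrum evaluated at the block
center. The expected periodogram of an aligned rectangular window then
equals the closed form exactly; Hann windows with 50% overlap (the
spectral-estimation default) introduce a small smearing bias across block
boundaries that is shared by target and reference and stays ~1–3% on the
recovered attenuation, well inside the method's operating accuracy.

What the simulators do not emulate: 2-D/3-D diffraction of the push beam,
transducer element geometry, depth-dependent focusing of the tracking
beams, frequency-dependent shear attenuation, or physiological motion.
Passing recovery tests therefore demonstrates the correctness of the
estimator mathematics under the stated signal model, not robustness to
every artifact of clinical acquisitions.

## Estimators

* **Echo attenuation** — log spectral ratio of beam-averaged windowed
  periodograms regressed (OLS) on `{1, ln f, f z}` over the pulse band
  (default 2–5 MHz, about the −6 dB band of the default pulse); the `f z`
  coefficient is `-4 (beta_tar - beta_ref)` in Neper units. The fit is
  joint over all (f, z) points rather than per-depth, which is more robust
  at small sample sizes. A published variant tunes this least-squares step
  with a learned optimizer; its internals are unpublished and plain OLS is
  used here.
* **Elasticity** — per-beam time-to-peak (3-point parabolic sub-sample
  refinement) regressed on beam distance; speed is the inverse slope and
  `E = 3 rho c^2` with `rho = 1.0 g/cm^3` by default. A flat or
  non-propagating profile raises `DegeneratePropagationError`.
* **Dispersion slope** — per adjacent beam pair, the unwrapped
  cross-spectrum phase gives `v(f) = 2 pi f delta_d / delta_phi`; pair
  velocities are averaged (pairs with non-physical in-band velocities are
  excluded) and the slope of a linear fit of `v(f)` over 50–300 Hz is
  returned, in m/s/Hz. No rheological model is fitted.
* **Shear attenuation** — `alpha` is minus the least-squares slope of
  `ln(MDR_i)` vs `d_i` over the first `near_region_beams` beams
  (default 5; the restriction to the near region of each push keeps
  diffraction effects negligible under the signal model).
* **Shear absorption** — each push contributes
  `y = S_max / (V0^2 / (2 c rho))` at its focus depth; `sigma` is half the
  negative log-linear slope of `y` vs focus depth. The exponential
  prefactor's own `sigma` dependence is ignored on purpose: the fit is a
  plain two-parameter exponential in the focus depth.

Per-push elasticity, dispersion and attenuation estimates are aggregated
across the three pushes by arithmetic mean (a declared package choice; a
per-depth reporting mode would be equally defensible). Absorption is a
single fit across the three pushes by construction.

## Fusion model and evaluation

The fusion model is a CART regression tree over the feature vector
x1..x5 = (shear_absorption, echo_attenuation, elasticity,
dispersion_slope, shear_attenuation), written in-package to pin down
behavior sklearn leaves unspecified: candidate thresholds are midpoints of
consecutive distinct values, features are scanned in ascending index
order, exact score ties keep the earliest candidate, and descent sends
`value < threshold` left (a value exactly at a threshold goes right).
Defaults `max_depth = 4, min_leaf = 3` suit a ~60-subject cohort; training
error is non-increasing in depth and leaf predictions always lie inside
the training-response range.

Evaluation utilities: Pearson correlation with Fisher-z 95% CI and a
two-sided t-test p-value; RMSE; ROC with trapezoid AUC (equal to the
normalized Mann–Whitney U with half-credit ties) and a Youden-optimal
cutoff (ties resolved toward the lowest cutoff). Disease labels use the
5% fat-fraction threshold. Parameters that decrease with fat
(shear attenuation/absorption) are scored with `positive_direction = -1`
so their AUC is ≥ 0.5 by convention. Repeated random holdout validation
(default fractions 5/10/15%, 10 repeats) reports per-repeat holdout CCs
plus a pooled CC over all holdout predictions; a per-repeat CC is NaN when
the holdout response is constant (possible at 3-subject holdouts), which
the pooled summary absorbs.

## Synthetic cohorts (`cohort_sim`)

Fat fractions follow a log-normal truncated to [2.0, 47.2]% with mean
9.1% (shape `log_sigma = 0.75`; the location is solved by Brent's method
from the closed-form truncated log-normal mean). Sampling is by inverse
CDF, so the configured bounds hold for every seed. Each parameter is a
linear function of fat fraction plus Gaussian noise with

    slope = cc * sd_param / sd_fat,   noise_sd = sd_param * sqrt(1 - cc^2)

calibrated against the analytic `sd_fat`, so the population Pearson
correlation equals the configured target and the marginal mean/SD match
the configured cohort statistics (echo attenuation 0.706 ± 0.121 dB/MHz/cm
rising with fat, CC +0.46; elasticity 9.46 ± 4.15 kPa and dispersion slope
3.82 ± 8.48 m/s/Hz essentially uncorrelated; shear attenuation
175.2 ± 46.3 Neper/m and absorption 58.9 ± 14.6 Neper/m falling with fat,
CC ≈ −0.25/−0.26). Elasticity draws are floored at 0.1 kPa to respect the
physical positivity constraint; at the configured noise level this clips
~1% of draws and shifts the sample CC by well under the test tolerances.
Parameters are conditionally independent given fat fraction: the generator
reproduces each parameter's relation to fat, not the unobservable residual
dependence among parameters, so fusion performance on these cohorts is
illustrative rather than a clinical claim.

## Problem sizes and determinism

Default simulations are small by design — 8 beams × 400 slow-time samples
per push and 64 beams × ~2000 depth samples per RF frame — because the
estimators are closed-form fits whose behavior does not change with larger
grids; recovery experiments average 20 speckle seeds and sweep 50 random
tissue models. All randomness flows through `numpy.random.SeedSequence`
children of a single user seed; identical inputs give bit-identical
fields, frames, cohorts and cross-validation splits.

## Known limitations

* The elasticity estimator measures the peak propagation speed; in
  viscous media this genuinely exceeds `c0`, so recovered `E` carries a
  physical upward bias growing with `gamma` (a few percent at liver-like
  viscosities with the default pulse).
* The dispersion slope of the simulated Voigt field is on the order of
  1e-3 m/s/Hz, the physical scale for liver-like parameters; the cohort
  generator instead uses the reported clinical marginal statistics
  directly. The two scales are not reconciled because the fusion stage
  consumes cohort tables, not wavefields.
* The regression tree is the only fusion model offered; ensembles are out
  of scope by design for a 60-subject regime.
* `track_displacement` assumes a common geometry and a single axial
  kernel per beam; it is exercised by shift-recovery tests, while the
  wavefield pipeline consumes simulator displacement directly.
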