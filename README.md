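# swqus

Shear-wave quantitative ultrasound tissue characterization for liver
steatosis. The package simulates a three-push acoustic-radiation-force
shear-wave sequence, estimates five acoustic parameters from it, fuses
them with a regression tree into a liver fat-fraction estimate, and
evaluates the result the way clinical QUS studies do.

It is aimed at QUS method developers who need a transparent, fully seeded
sandbox: every estimator can be run against a simulator whose ground
truth is known exactly.

## The model

For one acquisition, three focused pushes (foci 0.03/0.04/0.05 m) each
launch a shear wave observed by adjacent tracking beams. From the
tracking data the package estimates:

| parameter | units | estimator |
|---|---|---|
| echo attenuation β | dB/MHz/cm | reference-phantom spectral ratio: `ln RS(f,z) = ln(b_t/b_r) + (n_t−n_r) ln f − 4(β_t−β_r) f z`, fitted by OLS |
| elasticity E | kPa | time-to-peak speed c, then `E = 3 ρ c²` (ρ = 1.0 g/cm³) |
| dispersion slope SDS | m/s/Hz | slope of phase velocity `v(f) = 2πf·Δd/Δφ` over 50–300 Hz, no rheological model |
| shear-wave attenuation α | Neper/m | `MDR_i = exp(−α d_i)` log-linear fit over the near region |
| shear-wave absorption σ | Neper/m | `S_max/I₀ ∝ exp(−2σ x_focus)` across the three foci, `I₀ ∝ V₀²/(2cρ)` |

A CART regression tree over x1..x5 = (σ, β, E, SDS, α) maps the parameter
set to fat fraction (%), and the evaluation module provides Pearson CC
with Fisher-z 95% CI, RMSE, ROC/AUC with the Youden-optimal cutoff, the
5% fatty-liver threshold, and repeated random-holdout validation.

The forward simulators (Voigt plane-wave shear field; block-filtered
Gaussian RF speckle; truncated log-normal synthetic cohorts) are
first-class, tested components — see `docs/methods.md` for the physics
and their limits.

## Worked example

```python
import json
from swqus import (SequenceConfig, TissueModel, simulate_and_estimate,
                   CohortGeneratorConfig, synthesize_cohort,
                   fit_regression_tree, evaluate_predictions, cross_validate)
from swqus.fusion_eval import cohort_features

tissue = TissueModel(elasticity_E=12.0, shear_viscosity_gamma=1.0,
                     echo_atten_beta=0.72, shear_atten_alpha=180.0,
                     shear_absorption_sigma=60.0)
reference = TissueModel(echo_atten_beta=0.30)
params = simulate_and_estimate(tissue, reference, SequenceConfig(), seed=1)
print(json.dumps(params.to_dict(), indent=2))
```

prints

```json
{
  "echo_attenuation": 0.7019413831858743,
  "elasticity": 13.062188870260101,
  "dispersion_slope": 0.0006163109105855937,
  "shear_attenuation": 180.4304557030862,
  "shear_absorption": 59.999999999999986
}
```

— echo attenuation within 3% of the true 0.72 dB/MHz/cm (speckle noise),
elasticity slightly above the true 12 kPa because the time-to-peak speed
in a viscous medium physically exceeds the zero-frequency shear speed, a
positive dispersion slope at the physical scale of a Voigt liver, and the
two decay rates recovered essentially exactly. Continuing with a
synthetic 60-subject cohort:

```python
cohort = synthesize_cohort(CohortGeneratorConfig(seed=0))
model = fit_regression_tree(cohort)
pred = model.predict(cohort_features(cohort))
rep = evaluate_predictions(pred, cohort["fat_fraction"].to_numpy())
print(f"resub cc {rep.cc:.3f} rmse {rep.rmse:.2f} auc {rep.auc:.2f}")
cv = cross_validate(cohort, test_fraction=10, repeats=10, seed=0)
print(f"cv pooled cc {cv.pooled_cc:.3f}")
```

```
resub cc 0.742 rmse 4.73 auc 0.80
cv pooled cc 0.242
```

The gap between resubstitution and holdout CC is expected here: the
default generator gives each parameter only a weak, noisy linear link to
fat fraction (population CCs ≈ 0.46/0.03/0.04/−0.25/−0.26), so there is
little joint structure for the tree to exploit. When the five parameters
jointly determine fat fraction piecewise, fused holdout CC rises well
above every single-parameter correlation — that property is asserted in
the test suite.

## Command line

```
swqus simulate    --config cfg.json --out run.h5 --seed 1
swqus estimate    --in run.h5 --out params.json
swqus echo-atten  --target t.h5 --reference r.h5 --ref-beta 0.3 --band 2e6:5e6
swqus synth-cohort --out cohort.csv --seed 1
swqus fuse        --cohort cohort.csv --out report.json --cv 5,10,15 --repeats 10
```

`params.json` carries exactly the keys `echo_attenuation, elasticity,
dispersion_slope, shear_attenuation, shear_absorption`; cohort CSVs have
the header `subject_id, echo_attenuation, elasticity, dispersion_slope,
shear_attenuation, shear_absorption, fat_fraction`.

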