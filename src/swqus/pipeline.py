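"""End-to-end estimation: simulated acquisition -> AcousticParameterSet.

Per-push elasticity, dispersion slope and shear attenuation are aggregated
across the three pushes by arithmetic mean; shear absorption is a single
fit over the three push-focus peak records; echo attenuation comes from
the target/reference RF pair.
"""

from __future__ import annotations

import numpy as np

from .echo_atten import compute_power_spectrum, estimate_echo_attenuation
from .models import AcousticParameterSet, DisplacementField, RFFrame, SequenceConfig, TissueModel
from .shear_params import (
    DEFAULT_DISPERSION_BAND,
    DEFAULT_NEAR_REGION_BEAMS,
    estimate_dispersion_slope,
    estimate_elasticity,
    estimate_shear_attenuation,
    estimate_shear_absorption,
    make_push_peak_record,
)
from .wave_sim import simulate_rf_pair, simulate_sequence

DEFAULT_ECHO_BAND = (2.0e6, 5.0e6)  # ~-6 dB band of the default 3.5 MHz pulse


def estimate_parameter_set(
    fields: list[DisplacementField],
    seq: SequenceConfig,
    rf_target: RFFrame,
    rf_reference: RFFrame,
    ref_props: tuple[float, float, float],
    rho: float = 1.0,
    dispersion_band: tuple[float, float] = DEFAULT_DISPERSION_BAND,
    echo_band: tuple[float, float] = DEFAULT_ECHO_BAND,
    near_region_beams: int = DEFAULT_NEAR_REGION_BEAMS,
    spectrum_window: int = 128,
) -> AcousticParameterSet:
    """Estimate all five parameters from one acquisition."""
    elasticity = float(np.mean([estimate_elasticity(f, rho=rho) for f in fields]))
    sds = float(np.mean([estimate_dispersion_slope(f, band=dispersion_band) for f in fields]))
    alpha = float(
        np.mean([estimate_shear_attenuation(f, near_region_beams) for f in fields])
    )
    records = [make_push_peak_record(f, seq, rho=rho) for f in fields]
    sigma = estimate_shear_absorption(records)

    spec_t = compute_power_spectrum(rf_target, window_length=spectrum_window)
    spec_r = compute_power_spectrum(rf_reference, window_length=spectrum_window)
    fit = estimate_echo_attenuation(spec_t, spec_r, ref_props, band=echo_band)

    return AcousticParameterSet(
        echo_attenuation=fit.beta_target,
        elasticity=elasticity,
        dispersion_slope=sds,
        shear_attenuation=alpha,
        shear_absorption=sigma,
    )


def simulate_and_estimate(
    tissue: TissueModel,
    reference: TissueModel,
    seq: SequenceConfig,
    ref_props: tuple[float, float, float] | None = None,
    noise_level: float = 0.0,
    seed: int | None = None,
) -> AcousticParameterSet:
    """Convenience wrapper: simulate a full acquisition and estimate from it.

    ``ref_props`` defaults to the reference tissue's true (beta, b, n).
    """
    if ref_props is None:
        ref_props = (
            reference.echo_atten_beta,
            reference.backscatter_b,
            reference.backscatter_n,
        )
    ss = np.random.SeedSequence(seed)
    seed_wave, seed_rf = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    fields = simulate_sequence(tissue, seq, noise_level=noise_level, seed=seed_wave)
    rf_t, rf_r = simulate_rf_pair(tissue, reference, seq, seed=seed_rf)
    return estimate_parameter_set(fields, seq, rf_t, rf_r, ref_props, rho=tissue.density_rho)
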