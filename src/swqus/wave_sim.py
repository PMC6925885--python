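"""Forward simulation of the three-push shear-wave acquisition.

Two generators live here:

``simulate_shear_wavefield``
    Lateral shear displacement vs time at the tracking beams after one
    acoustic-radiation-force push. The medium is a Kelvin–Voigt solid; the
    field is synthesized per frequency from the Voigt dispersion relation
    (plane-wave solution of the viscoelastic wave equation), so phase
    velocities are exact by construction. Peak amplitude decays laterally as
    exp(-alpha d) with the tissue's configured shear attenuation, and the
    source amplitude scales with push intensity I0 * exp(-2 sigma x_focus),
    the mechanism the absorption estimator inverts.

``simulate_rf_pair``
    Matched target/reference tracking-echo RF frames whose expected power
    spectra follow Sp(f, z) = G(f, z) * exp(-4 beta f z) * b f^n with a
    shared system/beamforming factor G, realized as block-filtered Gaussian
    speckle.
"""

from __future__ import annotations

import numpy as np
from numpy.fft import irfft, rfft, rfftfreq
from scipy.fft import next_fast_len

from .errors import InvalidTissueError
from .models import DisplacementField, RFFrame, SequenceConfig, TissueModel
from .units import db_mhz_cm_to_np_hz_m

# Temporal source pulse: unipolar Gaussian. The width puts most spectral
# energy below ~150 Hz, which keeps time-to-peak speeds close to the
# zero-frequency shear speed and pulse-spreading bias on the lateral
# attenuation small; phases remain exact at all synthesized frequencies.
PULSE_WIDTH_S = 1.2e-3
PULSE_DELAY_S = 6.0e-3
_SOURCE_SCALE = 0.1  # maps V^2/(2 c rho) to metres of peak displacement


def voigt_phase_velocity(freq_hz, shear_modulus_pa, viscosity_pa_s, density_kg_m3):
    """Phase velocity c(f) of a Kelvin–Voigt solid, m/s.

    c(w) = sqrt( 2 (mu^2 + w^2 g^2) / (rho (mu + sqrt(mu^2 + w^2 g^2))) ),
    which reduces to sqrt(mu/rho) at w=0 and grows with frequency when the
    viscosity g is nonzero.
    """
    w = 2.0 * np.pi * np.asarray(freq_hz, dtype=float)
    mu = float(shear_modulus_pa)
    g = float(viscosity_pa_s)
    rho = float(density_kg_m3)
    mag = np.sqrt(mu**2 + (w * g) ** 2)
    return np.sqrt(2.0 * mag**2 / (rho * (mu + mag)))


def source_pulse(time_axis: np.ndarray) -> np.ndarray:
    """Unit-amplitude temporal displacement pulse at the push location."""
    t = np.asarray(time_axis, dtype=float)
    return np.exp(-0.5 * ((t - PULSE_DELAY_S) / PULSE_WIDTH_S) ** 2)


def push_amplitude(tissue: TissueModel, seq: SequenceConfig, push_index: int) -> float:
    """Peak source displacement for one push, metres.

    S_max is proportional to I0 * exp(-2 sigma x_focus) with
    I0 ~ V0^2 / (2 c rho); the proportionality constant is a fixed package
    scale since only ratios across pushes matter to the estimators.
    """
    v0 = seq.push_voltages[push_index]
    x_focus = seq.push_focus_depths[push_index]
    i0 = v0**2 / (2.0 * tissue.sound_speed_c * tissue.density_kg_m3)
    return _SOURCE_SCALE * i0 * np.exp(-2.0 * tissue.shear_absorption_sigma * x_focus)


def simulate_shear_wavefield(
    tissue: TissueModel,
    seq: SequenceConfig,
    push_index: int,
    noise_level: float = 0.0,
    seed: int | None = None,
    duration_s: float = 0.04,
) -> DisplacementField:
    """Simulate the lateral shear displacement ensemble after one push.

    Parameters
    ----------
    noise_level : float
        Standard deviation of additive Gaussian noise as a fraction of the
        peak displacement of the noiseless field.
    seed : int, optional
        Seeds the noise generator; identical inputs give bit-identical output.
    duration_s : float
        Slow-time record length. Must cover the transit of the pulse across
        the aperture for the softest media of interest.
    """
    if not isinstance(tissue, TissueModel):
        raise InvalidTissueError("tissue must be a TissueModel")
    if not (0 <= push_index < seq.n_pushes):
        raise IndexError(f"push_index {push_index} out of range for {seq.n_pushes} pushes")
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")

    spacing = seq.beam_spacings[push_index]
    distances = np.arange(seq.n_tracking_beams) * spacing
    dt = 1.0 / seq.track_prf
    n_t = int(round(duration_s * seq.track_prf))
    time_axis = np.arange(n_t) * dt

    n_fft = next_fast_len(2 * n_t)
    freq = rfftfreq(n_fft, dt)
    c = voigt_phase_velocity(
        freq, tissue.shear_modulus_pa, tissue.shear_viscosity_gamma, tissue.density_kg_m3
    )

    pulse = np.zeros(n_fft)
    pulse[:n_t] = source_pulse(time_axis)
    spectrum = rfft(pulse)

    # propagate: delay each frequency by d / c(f); attenuate amplitude by
    # exp(-alpha d), frequency-independent so the configured alpha is the
    # exact log-slope of the peak-displacement profile
    phase = np.exp(-2j * np.pi * freq[None, :] * distances[:, None] / c[None, :])
    disp = irfft(spectrum[None, :] * phase, n_fft, axis=1)[:, :n_t]
    amp = push_amplitude(tissue, seq, push_index) * np.exp(
        -tissue.shear_atten_alpha * distances
    )
    disp *= amp[:, None]

    if noise_level > 0:
        rng = np.random.default_rng(seed)
        disp = disp + rng.normal(0.0, noise_level * np.abs(disp).max(), disp.shape)

    return DisplacementField(disp, distances, time_axis, push_index)


def simulate_sequence(
    tissue: TissueModel,
    seq: SequenceConfig,
    noise_level: float = 0.0,
    seed: int | None = None,
    duration_s: float = 0.04,
) -> list[DisplacementField]:
    """Run all pushes of the sequence; one DisplacementField per focus."""
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(seq.n_pushes)]
    return [
        simulate_shear_wavefield(
            tissue, seq, k, noise_level=noise_level, seed=child_seeds[k], duration_s=duration_s
        )
        for k in range(seq.n_pushes)
    ]


# ---------------------------------------------------------------------------
# RF speckle simulation

RF_BLOCK_LEN = 128  # depth samples per stationary speckle block


def _system_power_spectrum(freq: np.ndarray, center_frequency: float) -> np.ndarray:
    """Pulse-echo system power response: Gaussian band around f_c."""
    sigma_f = center_frequency / 4.0
    return np.exp(-0.5 * ((freq - center_frequency) / sigma_f) ** 2)


def _depth_gain(z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth random depth-dependent gain shared by target and reference."""
    u = (z - z.mean()) / (z.max() - z.min() + 1e-30)
    coeffs = rng.normal(0.0, 0.15, size=3)
    return np.exp(coeffs[0] * u + coeffs[1] * u**2 + coeffs[2] * u**3)


def expected_power_spectrum(
    tissue: TissueModel, freq: np.ndarray, depth: float, system_power: np.ndarray, gain: float
) -> np.ndarray:
    """Closed-form expected Sp(f, z) = G * exp(-4 beta f z) * b f^n."""
    beta_np = db_mhz_cm_to_np_hz_m(tissue.echo_atten_beta)
    atten = np.exp(-4.0 * beta_np * freq * depth)
    backscatter = tissue.backscatter_b * freq**tissue.backscatter_n
    return system_power * gain * atten * backscatter


def _synthesize_frame(
    tissue: TissueModel,
    seq: SequenceConfig,
    rng: np.random.Generator,
    depth_axis: np.ndarray,
    gain: np.ndarray,
    center_frequency: float,
    n_beams: int,
    block_len: int,
) -> RFFrame:
    n_samples = depth_axis.size
    n_blocks = n_samples // block_len
    freq = rfftfreq(block_len, 1.0 / seq.rf_sampling_rate)
    sys_power = _system_power_spectrum(freq, center_frequency)

    noise = rng.standard_normal((n_blocks, n_beams, block_len))
    spectra = rfft(noise, axis=-1)
    for b in range(n_blocks):
        z_c = depth_axis[b * block_len : (b + 1) * block_len].mean()
        g_c = gain[b * block_len : (b + 1) * block_len].mean()
        target_power = expected_power_spectrum(tissue, freq, z_c, sys_power, g_c)
        spectra[b] *= np.sqrt(target_power)[None, :]
    blocks = irfft(spectra, block_len, axis=-1)
    samples = np.transpose(blocks, (1, 0, 2)).reshape(n_beams, n_blocks * block_len)
    return RFFrame(samples, depth_axis, center_frequency, seq.rf_sampling_rate)


def simulate_rf_pair(
    target: TissueModel,
    reference: TissueModel,
    seq: SequenceConfig,
    seed: int | None = None,
    center_frequency: float = 3.5e6,
    depth_span: tuple[float, float] = (0.02, 0.06),
    n_beams: int = 64,
    block_len: int = RF_BLOCK_LEN,
) -> tuple[RFFrame, RFFrame]:
    """Simulate matched target and reference tracking-echo RF frames.

    Both frames share the same system/beamforming factor G(f, z) (identical
    pulse band and identical seeded depth gain) while their speckle
    realizations are independent, exactly the situation the
    reference-phantom spectral-ratio method assumes.
    """
    for tm, name in ((target, "target"), (reference, "reference")):
        if tm.echo_atten_beta < 0 or tm.backscatter_b < 0:
            raise InvalidTissueError(f"{name} has negative beta or b")

    c = target.sound_speed_c
    dz = c / (2.0 * seq.rf_sampling_rate)  # echo round-trip depth per sample
    n_samples = int((depth_span[1] - depth_span[0]) / dz)
    n_samples -= n_samples % block_len
    if n_samples < block_len:
        raise ValueError("depth_span too short for one speckle block")
    depth_axis = depth_span[0] + np.arange(n_samples) * dz

    ss = np.random.SeedSequence(seed)
    rng_g, rng_t, rng_r = (np.random.default_rng(s) for s in ss.spawn(3))
    gain = _depth_gain(depth_axis, rng_g)

    frame_t = _synthesize_frame(
        target, seq, rng_t, depth_axis, gain, center_frequency, n_beams, block_len
    )
    frame_r = _synthesize_frame(
        reference, seq, rng_r, depth_axis, gain, center_frequency, n_beams, block_len
    )
    return frame_t, frame_r
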