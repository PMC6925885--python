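"""Reference-phantom spectral-ratio estimation of echo attenuation.

The backscattered power spectrum factors as
``Sp(f, z) = G(f, z) * exp(-4 beta f z) * b f^n`` where G collects system
and beamforming effects. Dividing the target spectrum by that of a
reference phantom acquired with identical settings cancels G, and the log
ratio is linear in the regressors {1, ln f, f z}:

    ln RS(f, z) = ln(b_tar/b_ref) + (n_tar - n_ref) ln f
                  - 4 (beta_tar - beta_ref) f z

An ordinary least-squares fit over the usable band therefore yields the
target attenuation relative to the known reference value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.fft import rfft, rfftfreq
from scipy.signal.windows import hann

from .errors import AlignmentError, FitError
from .models import RFFrame
from .units import np_hz_m_to_db_mhz_cm


@dataclass
class PowerSpectrumMap:
    """Beam-averaged power spectra on a [frequency x depth] grid."""

    power: np.ndarray
    freq_axis: np.ndarray
    depth_axis: np.ndarray

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freq_axis = np.asarray(self.freq_axis, dtype=float)
        self.depth_axis = np.asarray(self.depth_axis, dtype=float)
        if self.power.shape != (self.freq_axis.size, self.depth_axis.size):
            raise ValueError("power must be [frequency x depth]")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        for ax in (self.freq_axis, self.depth_axis):
            if ax.size > 1 and np.any(np.diff(ax) <= 0):
                raise ValueError("axes must be monotone increasing")


@dataclass
class AttenuationFit:
    """Result of the log-spectral-ratio regression."""

    beta_target: float  # dB/MHz/cm
    delta_n: float  # n_tar - n_ref
    log_b_ratio: float  # ln(b_tar / b_ref)
    residual_rms: float

    def __post_init__(self) -> None:
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be >= 0")


def compute_power_spectrum(
    rf: RFFrame, window_length: int = 128, overlap: float = 0.5, taper: str = "hann"
) -> PowerSpectrumMap:
    """Windowed, beam-averaged periodograms of an RF frame.

    Tapered depth windows of ``window_length`` samples with fractional
    ``overlap`` are periodogram-averaged across all beams; the resulting map
    is indexed [frequency x depth-window-center]. ``taper`` is "hann"
    (default, low leakage) or "boxcar".
    """
    n_depth = rf.samples.shape[1]
    if not (16 <= window_length <= n_depth):
        raise ValueError(
            f"window_length must be within [16, {n_depth}], got {window_length}"
        )
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    if taper not in ("hann", "boxcar"):
        raise ValueError("taper must be 'hann' or 'boxcar'")

    hop = max(1, int(round(window_length * (1.0 - overlap))))
    starts = np.arange(0, n_depth - window_length + 1, hop)
    taper = hann(window_length, sym=False) if taper == "hann" else np.ones(window_length)
    norm = (taper**2).sum()

    freq = rfftfreq(window_length, 1.0 / rf.sampling_rate)
    power = np.empty((freq.size, starts.size))
    centers = np.empty(starts.size)
    for j, s in enumerate(starts):
        seg = rf.samples[:, s : s + window_length] * taper[None, :]
        pg = np.abs(rfft(seg, axis=1)) ** 2 / norm
        power[:, j] = pg.mean(axis=0)
        centers[j] = rf.depth_axis[s : s + window_length].mean()
    return PowerSpectrumMap(power, freq, centers)


def estimate_echo_attenuation(
    target_spec: PowerSpectrumMap,
    ref_spec: PowerSpectrumMap,
    ref_props: tuple[float, float, float],
    band: tuple[float, float],
) -> AttenuationFit:
    """Fit the log spectral ratio and return the target echo attenuation.

    Parameters
    ----------
    ref_props : (beta_ref, b_ref, n_ref)
        Known acoustic properties of the reference phantom; beta_ref in
        dB/MHz/cm. Only beta_ref enters the returned attenuation — the
        backscatter terms are reported as ratios.
    band : (f_lo, f_hi)
        Frequency band of the fit, Hz; must contain at least 3 bins.
    """
    if target_spec.freq_axis.shape != ref_spec.freq_axis.shape or not np.allclose(
        target_spec.freq_axis, ref_spec.freq_axis
    ):
        raise AlignmentError("frequency axes differ between target and reference")
    if target_spec.depth_axis.shape != ref_spec.depth_axis.shape or not np.allclose(
        target_spec.depth_axis, ref_spec.depth_axis
    ):
        raise AlignmentError("depth axes differ between target and reference")

    beta_ref, _b_ref, _n_ref = ref_props
    f = target_spec.freq_axis
    in_band = (f >= band[0]) & (f <= band[1]) & (f > 0)
    if in_band.sum() < 3:
        raise FitError("band contains fewer than 3 positive-frequency bins")

    pt = target_spec.power[in_band, :]
    pr = ref_spec.power[in_band, :]
    fb = f[in_band]
    z = target_spec.depth_axis

    valid = (pt > 0) & (pr > 0)
    if valid.sum() < 3:
        raise FitError("fewer than 3 usable (f, z) points in band")

    y = np.log(pt[valid] / pr[valid])
    ff, zz = np.meshgrid(fb, z, indexing="ij")
    X = np.column_stack(
        [np.ones(valid.sum()), np.log(ff[valid]), ff[valid] * zz[valid]]
    )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef

    delta_beta_np = -coef[2] / 4.0
    beta_target = beta_ref + np_hz_m_to_db_mhz_cm(delta_beta_np)
    return AttenuationFit(
        beta_target=float(beta_target),
        delta_n=float(coef[1]),
        log_b_ratio=float(coef[0]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )
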