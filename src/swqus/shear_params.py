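"""Shear-wave parameter estimators: elasticity, dispersion slope, lateral
attenuation and push-depth absorption, plus RF displacement tracking.

All estimators work on a :class:`~swqus.models.DisplacementField` and are
ratio- or timing-based, hence invariant to a global scaling of the
displacement amplitude.
"""

from __future__ import annotations

import numpy as np
from numpy.fft import rfft, rfftfreq
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import next_fast_len

from .errors import (
    DegeneratePropagationError,
    EstimationError,
    InsufficientDataError,
    InvalidSignalError,
)
from .models import DisplacementField, PushPeakRecord, RFFrame, SequenceConfig

DEFAULT_DISPERSION_BAND = (50.0, 300.0)  # Hz
DEFAULT_NEAR_REGION_BEAMS = 5


def _parabolic_refine(y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample peak location and value via a 3-point parabola at index i."""
    if i <= 0 or i >= y.size - 1:
        return float(i), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(i), float(y1)
    offset = 0.5 * (y0 - y2) / denom
    offset = float(np.clip(offset, -0.5, 0.5))
    value = y1 - 0.25 * (y0 - y2) * offset
    return i + offset, float(value)


def peak_displacements(field: DisplacementField) -> np.ndarray:
    """Parabolically refined per-beam peak displacement magnitudes."""
    peaks = np.empty(field.n_beams)
    for b in range(field.n_beams):
        trace = field.displacement[b]
        i = int(np.argmax(trace))
        _, peaks[b] = _parabolic_refine(trace, i)
    return peaks


def time_to_peak(field: DisplacementField) -> np.ndarray:
    """Per-beam time of the displacement peak, seconds (sub-sample refined)."""
    dt = float(np.mean(np.diff(field.time_axis)))
    t0 = field.time_axis[0]
    ttp = np.empty(field.n_beams)
    for b in range(field.n_beams):
        trace = field.displacement[b]
        i = int(np.argmax(trace))
        loc, _ = _parabolic_refine(trace, i)
        ttp[b] = t0 + loc * dt
    return ttp


def estimate_elasticity(field: DisplacementField, rho: float = 1.0) -> float:
    """Young's modulus in kPa from time-to-peak shear speed, E = 3 rho c^2.

    The peak arrival time is regressed on beam distance; the inverse slope
    is the peak propagation speed. ``rho`` is in g/cm^3 (liver: 1.0), so
    with c in m/s the product 3*rho*c^2 is directly kPa.
    """
    if rho <= 0:
        raise ValueError("rho must be > 0")
    if field.n_beams < 3:
        raise InsufficientDataError("need at least 3 beams for time-to-peak regression")
    ttp = time_to_peak(field)
    slope = np.polyfit(field.beam_distances, ttp, 1)[0]
    if not np.isfinite(slope) or slope <= 0 or ttp[-1] <= ttp[0]:
        raise DegeneratePropagationError(
            "time-to-peak profile is flat or non-propagating"
        )
    c = 1.0 / slope
    return float(3.0 * rho * c**2)


def phase_velocity_spectrum(
    field: DisplacementField, band: tuple[float, float] = DEFAULT_DISPERSION_BAND
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frequency shear phase velocity averaged over adjacent beam pairs.

    For each adjacent pair the cross-spectrum phase gives the travel phase
    over the pair spacing: v(f) = 2 pi f * delta_d / delta_phi. Pairs whose
    in-band velocity is non-physical (non-positive or non-finite) are
    excluded; if every pair is excluded an EstimationError is raised.

    Returns ``(freqs_in_band, v_mean_in_band)``.
    """
    if field.n_beams < 2:
        raise InsufficientDataError("need at least 2 beams for phase velocities")
    dt = float(np.mean(np.diff(field.time_axis)))
    n_t = field.time_axis.size
    n_fft = next_fast_len(4 * n_t)
    freq = rfftfreq(n_fft, dt)
    in_band = (freq >= band[0]) & (freq <= band[1])
    if in_band.sum() < 2:
        raise EstimationError("fewer than 2 frequency bins inside the band")

    spectra = rfft(field.displacement, n_fft, axis=1)
    velocities = []
    for i in range(field.n_beams - 1):
        delta_d = field.beam_distances[i + 1] - field.beam_distances[i]
        cross = spectra[i] * np.conj(spectra[i + 1])
        delta_phi = np.unwrap(np.angle(cross))
        with np.errstate(divide="ignore", invalid="ignore"):
            v = 2.0 * np.pi * freq * delta_d / delta_phi
        v_band = v[in_band]
        if np.all(np.isfinite(v_band)) and np.all(v_band > 0):
            velocities.append(v_band)
    if not velocities:
        raise EstimationError("all beam pairs excluded (non-physical phase velocities)")
    return freq[in_band], np.mean(velocities, axis=0)


def estimate_dispersion_slope(
    field: DisplacementField, band: tuple[float, float] = DEFAULT_DISPERSION_BAND
) -> float:
    """Shear-wave dispersion slope, m/s/Hz: linear slope of v(f) on the band.

    No rheological model is assumed; the default band is 50-300 Hz.
    """
    f, v = phase_velocity_spectrum(field, band)
    return float(np.polyfit(f, v, 1)[0])


def estimate_shear_attenuation(
    field: DisplacementField, near_region_beams: int = DEFAULT_NEAR_REGION_BEAMS
) -> float:
    """Lateral shear-wave attenuation alpha, Neper/m.

    The maximum-displacement ratio of beam i to the first beam is modeled
    as MDR_i = exp(-alpha d_i); alpha is minus the least-squares slope of
    ln MDR_i vs d_i over the first ``near_region_beams`` beams (the near
    region of the push focus, where diffraction effects are negligible).
    """
    if not (3 <= near_region_beams <= field.n_beams):
        raise ValueError(
            f"near_region_beams must be in [3, {field.n_beams}], got {near_region_beams}"
        )
    peaks = peak_displacements(field)[:near_region_beams]
    if np.any(peaks <= 0):
        raise InvalidSignalError("non-positive displacement maximum in near region")
    d = field.beam_distances[:near_region_beams]
    mdr = peaks / peaks[0]
    slope = np.polyfit(d, np.log(mdr), 1)[0]
    return float(-slope)


def estimate_shear_absorption(records: list[PushPeakRecord]) -> float:
    """Shear-wave absorption sigma, Neper/m, from multi-focus peak records.

    Each push contributes y = S_max / I0_proxy at its focus depth; the model
    y = A exp(-2 sigma x_focus) is fitted log-linearly and sigma returned.
    The prefactor's own sigma dependence is deliberately ignored: the fit is
    a plain two-parameter exponential in the focus depth.
    """
    depths = np.array([r.focus_depth for r in records], dtype=float)
    if np.unique(depths).size < 2:
        raise InsufficientDataError("need records at >= 2 distinct focus depths")
    y = np.array([r.max_displacement / r.intensity_proxy for r in records], dtype=float)
    if np.any(y <= 0):
        raise InvalidSignalError("non-positive compensated displacement")
    slope = np.polyfit(depths, np.log(y), 1)[0]
    return float(-slope / 2.0)


def make_push_peak_record(
    field: DisplacementField,
    seq: SequenceConfig,
    sound_speed: float = 1540.0,
    rho: float = 1.0,
) -> PushPeakRecord:
    """Build the absorption-estimator record for one push.

    The peak displacement is read at the first tracking beam (adjacent to
    the push focus); the intensity proxy is V0^2 / (2 c rho) with rho in
    g/cm^3 converted to SI.
    """
    k = field.push_index
    v0 = seq.push_voltages[k]
    proxy = v0**2 / (2.0 * sound_speed * rho * 1e3)
    peak = peak_displacements(field)[0]
    if peak <= 0:
        raise InvalidSignalError("non-positive peak displacement at first beam")
    return PushPeakRecord(
        focus_depth=seq.push_focus_depths[k],
        max_displacement=float(peak),
        voltage=v0,
        intensity_proxy=proxy,
    )


# ---------------------------------------------------------------------------
# RF displacement tracking


def track_displacement(
    rf_ensemble: list[RFFrame],
    kernel_length: int,
    sound_speed: float = 1540.0,
    beam_spacing: float = 1.0,
    prf: float = 1.0,
) -> DisplacementField:
    """Axial displacement vs slow time by normalized cross-correlation.

    A kernel centered in the first frame is matched against every later
    frame per beam; the best lag (parabolically refined to sub-sample
    precision) maps to displacement through the echo round-trip convention
    delta_z = shift * (c/2) / f_s.

    ``beam_spacing`` (m) and ``prf`` (Hz) supply the lateral and slow-time
    axes of the returned field, since raw RF frames carry neither.
    """
    if len(rf_ensemble) < 2:
        raise InsufficientDataError("need at least 2 frames to track displacement")
    first = rf_ensemble[0]
    n_beams, n_samples = first.samples.shape
    for fr in rf_ensemble[1:]:
        if fr.samples.shape != (n_beams, n_samples):
            raise ValueError("all frames must share geometry")
    if not (2 <= kernel_length <= n_samples):
        raise ValueError(f"kernel_length must be within [2, {n_samples}]")

    p0 = (n_samples - kernel_length) // 2
    kernels = first.samples[:, p0 : p0 + kernel_length]
    dz = sound_speed / 2.0 / first.sampling_rate

    disp = np.zeros((n_beams, len(rf_ensemble)))
    for t, fr in enumerate(rf_ensemble[1:], start=1):
        for b in range(n_beams):
            kernel = kernels[b]
            kn = np.linalg.norm(kernel)
            if kn == 0:
                continue
            windows = sliding_window_view(fr.samples[b], kernel_length)
            norms = np.linalg.norm(windows, axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                ncc = windows @ kernel / (norms * kn)
            ncc = np.where(np.isfinite(ncc), ncc, -np.inf)
            i = int(np.argmax(ncc))
            finite = np.where(np.isfinite(ncc), ncc, np.min(ncc[np.isfinite(ncc)]))
            loc, _ = _parabolic_refine(finite, i)
            disp[b, t] = (loc - p0) * dz

    distances = np.arange(n_beams) * beam_spacing
    time_axis = np.arange(len(rf_ensemble)) / prf
    return DisplacementField(disp, distances, time_axis, push_index=0)
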