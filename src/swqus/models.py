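"""Domain containers: tissue/sequence descriptions and measured fields.

These are plain dataclasses with eager validation; arrays are converted to
float ndarrays at construction time so downstream numerics never need to
defend against lists or integer dtypes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, InvalidTissueError


@dataclass
class TissueModel:
    """Ground-truth acoustic and mechanical properties of a simulated medium.

    Parameters
    ----------
    elasticity_E : float
        Young's modulus, kPa. For nearly incompressible soft tissue the
        shear modulus is E/3, so the low-frequency shear speed is
        ``sqrt(E / (3 rho))``.
    shear_viscosity_gamma : float
        Shear viscosity of the Voigt solid, Pa·s. Zero gives a
        nondispersive medium.
    density_rho : float
        Density, g/cm^3 (liver is conventionally taken as 1.0).
    echo_atten_beta : float
        Effective echo (longitudinal) attenuation, dB/MHz/cm.
    backscatter_b : float
        Constant backscatter coefficient of B(f) = b * f^n.
    backscatter_n : float
        Frequency-dependence exponent of the backscatter coefficient.
    shear_absorption_sigma : float
        Shear-wave absorption coefficient, Neper/m: decay rate of the
        intensity-compensated push-focus peak displacement with focus depth.
    sound_speed_c : float
        Longitudinal sound speed, m/s (1540 for soft tissue).
    shear_atten_alpha : float
        Lateral shear-wave attenuation, Neper/m: exponential decay rate of
        peak shear displacement with propagation distance.
    """

    elasticity_E: float = 9.46
    shear_viscosity_gamma: float = 1.5
    density_rho: float = 1.0
    echo_atten_beta: float = 0.7
    backscatter_b: float = 1.0
    backscatter_n: float = 1.0
    shear_absorption_sigma: float = 58.9
    sound_speed_c: float = 1540.0
    shear_atten_alpha: float = 175.2

    def __post_init__(self) -> None:
        if not (self.elasticity_E > 0):
            raise InvalidTissueError(f"elasticity_E must be > 0, got {self.elasticity_E}")
        if not (self.density_rho > 0):
            raise InvalidTissueError(f"density_rho must be > 0, got {self.density_rho}")
        if self.shear_viscosity_gamma < 0:
            raise InvalidTissueError("shear_viscosity_gamma must be >= 0")
        if self.echo_atten_beta < 0:
            raise InvalidTissueError("echo_atten_beta must be >= 0")
        if self.backscatter_b < 0:
            raise InvalidTissueError("backscatter_b must be >= 0")
        if self.shear_absorption_sigma < 0:
            raise InvalidTissueError("shear_absorption_sigma must be >= 0")
        if self.shear_atten_alpha < 0:
            raise InvalidTissueError("shear_atten_alpha must be >= 0")
        if not (self.sound_speed_c > 0):
            raise InvalidTissueError("sound_speed_c must be > 0")

    @property
    def shear_modulus_pa(self) -> float:
        """Shear modulus mu = E/3 in Pa (E stored in kPa)."""
        return self.elasticity_E * 1e3 / 3.0

    @property
    def density_kg_m3(self) -> float:
        return self.density_rho * 1e3

    @property
    def shear_speed(self) -> float:
        """Low-frequency (gamma=0) shear speed sqrt(E / (3 rho)), m/s."""
        return float(np.sqrt(self.shear_modulus_pa / self.density_kg_m3))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TissueModel":
        return cls(**d)


@dataclass
class SequenceConfig:
    """Three-push shear-wave acquisition sequence.

    Defaults follow the clinical sequence: push foci at 0.03/0.04/0.05 m,
    tracking-beam spacings 0.0012/0.0013/0.0015 m per focus, and 40 MHz RF
    sampling. Tracking PRF and beam count are engineering choices exposed
    here as configurable defaults.
    """

    push_focus_depths: Sequence[float] = field(default_factory=lambda: [0.03, 0.04, 0.05])
    beam_spacings: Sequence[float] = field(default_factory=lambda: [0.0012, 0.0013, 0.0015])
    push_voltages: Sequence[float] = field(default_factory=lambda: [90.0, 90.0, 90.0])
    n_tracking_beams: int = 8
    rf_sampling_rate: float = 4.0e7
    track_prf: float = 1.0e4
    aperture_a: float = 0.01
    t0: float = 1.0e-4

    def __post_init__(self) -> None:
        self.push_focus_depths = [float(x) for x in self.push_focus_depths]
        self.beam_spacings = [float(x) for x in self.beam_spacings]
        self.push_voltages = [float(x) for x in self.push_voltages]
        n = len(self.push_focus_depths)
        if len(self.beam_spacings) != n or len(self.push_voltages) != n:
            raise ConfigError(
                "push_focus_depths, beam_spacings and push_voltages must have equal length"
            )
        if any(s <= 0 for s in self.beam_spacings):
            raise ConfigError("beam spacings must be > 0")
        if any(d <= 0 for d in self.push_focus_depths):
            raise ConfigError("push focus depths must be > 0")
        if not (self.rf_sampling_rate > 0 and self.track_prf > 0):
            raise ConfigError("sampling rates must be > 0")
        if self.n_tracking_beams < 2:
            raise ConfigError("need at least 2 tracking beams")

    @property
    def n_pushes(self) -> int:
        return len(self.push_focus_depths)

    def to_dict(self) -> dict:
        return {
            "push_focus_depths": list(self.push_focus_depths),
            "beam_spacings": list(self.beam_spacings),
            "push_voltages": list(self.push_voltages),
            "n_tracking_beams": self.n_tracking_beams,
            "rf_sampling_rate": self.rf_sampling_rate,
            "track_prf": self.track_prf,
            "aperture_a": self.aperture_a,
            "t0": self.t0,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SequenceConfig":
        return cls(**d)


@dataclass
class DisplacementField:
    """Lateral shear displacement ensemble following one push.

    ``displacement`` is [beam x time] in metres; ``beam_distances`` are
    lateral distances from the first tracking beam (first entry 0).
    """

    displacement: np.ndarray
    beam_distances: np.ndarray
    time_axis: np.ndarray
    push_index: int = 0

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.beam_distances = np.asarray(self.beam_distances, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.displacement.ndim != 2:
            raise ValueError("displacement must be 2-D [beam x time]")
        nb, nt = self.displacement.shape
        if self.beam_distances.shape != (nb,) or self.time_axis.shape != (nt,):
            raise ValueError("axis lengths do not match displacement shape")
        if nb >= 1 and self.beam_distances[0] != 0.0:
            raise ValueError("beam_distances must start at 0")
        if np.any(np.diff(self.beam_distances) <= 0):
            raise ValueError("beam_distances must be strictly increasing")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement must be finite everywhere")

    @property
    def n_beams(self) -> int:
        return self.displacement.shape[0]


@dataclass
class RFFrame:
    """One tracking-echo frame of raw RF data, [beam x depth-sample]."""

    samples: np.ndarray
    depth_axis: np.ndarray
    center_frequency: float
    sampling_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.depth_axis = np.asarray(self.depth_axis, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D [beam x depth-sample]")
        if self.depth_axis.shape != (self.samples.shape[1],):
            raise ValueError("depth_axis length must match samples")
        if np.any(np.diff(self.depth_axis) <= 0):
            raise ValueError("depth_axis must be monotone increasing")

    @property
    def n_beams(self) -> int:
        return self.samples.shape[0]


@dataclass
class PushPeakRecord:
    """Peak displacement bookkeeping for one push, for absorption estimation.

    ``intensity_proxy`` stands in for the push intensity I0 = P0^2/(2 c rho)
    with the transducer voltage V0 as the pressure proxy: V0^2 / (2 c rho).
    """

    focus_depth: float
    max_displacement: float
    voltage: float
    intensity_proxy: float

    def __post_init__(self) -> None:
        if not (self.max_displacement > 0):
            raise ValueError("max_displacement must be > 0")
        if not (self.intensity_proxy > 0):
            raise ValueError("intensity_proxy must be > 0")


@dataclass
class AcousticParameterSet:
    """The five tissue parameters estimated from one acquisition."""

    echo_attenuation: float  # dB/MHz/cm
    elasticity: float  # kPa
    dispersion_slope: float  # m/s/Hz
    shear_attenuation: float  # Neper/m
    shear_absorption: float  # Neper/m

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
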