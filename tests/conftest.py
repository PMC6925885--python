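import numpy as np
import pytest

from swqus import DisplacementField, SequenceConfig, TissueModel


@pytest.fixture
def seq():
    return SequenceConfig()


@pytest.fixture
def elastic_tissue():
    """Purely elastic 12 kPa medium: shear speed exactly 2 m/s."""
    return TissueModel(
        elasticity_E=12.0,
        shear_viscosity_gamma=0.0,
        density_rho=1.0,
        shear_atten_alpha=0.0,
    )


@pytest.fixture
def voigt_tissue():
    return TissueModel(
        elasticity_E=12.0,
        shear_viscosity_gamma=1.5,
        density_rho=1.0,
        shear_atten_alpha=0.0,
    )


def gaussian_pulse_field(
    speed=2.0,
    alpha=0.0,
    n_beams=8,
    spacing=0.0012,
    prf=1e4,
    duration=0.04,
    amplitude=1e-5,
    width=1.2e-3,
    delay=6e-3,
):
    """Analytic nondispersive pulse field: exact TTP line and exp decay."""
    d = np.arange(n_beams) * spacing
    t = np.arange(int(duration * prf)) / prf
    disp = amplitude * np.exp(-alpha * d)[:, None] * np.exp(
        -0.5 * ((t[None, :] - delay - d[:, None] / speed) / width) ** 2
    )
    return DisplacementField(disp, d, t, 0)
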