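"""Unit conversions used across the package.

The clinical literature reports echo attenuation in dB/MHz/cm while the
power-spectrum model uses a Neper/Hz/m exponent: the one-way amplitude loss
is ``exp(-beta_np * f * z)`` so the round-trip *power* loss at depth ``z`` is
``exp(-4 * beta_np * f * z)``.

1 dB = ln(10)/20 Neper (amplitude); 1 MHz·cm = 1e6 Hz · 1e-2 m.
"""

import numpy as np

NEPER_PER_DB = np.log(10.0) / 20.0

#: multiply a dB/MHz/cm attenuation by this to get Neper/Hz/m
#: (/1e6 Hz per MHz, *100 cm per m)
DB_MHZ_CM_TO_NP_HZ_M = NEPER_PER_DB * 100.0 / 1e6


def db_mhz_cm_to_np_hz_m(beta_db: float) -> float:
    return float(beta_db) * DB_MHZ_CM_TO_NP_HZ_M


def np_hz_m_to_db_mhz_cm(beta_np: float) -> float:
    return float(beta_np) / DB_MHZ_CM_TO_NP_HZ_M
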