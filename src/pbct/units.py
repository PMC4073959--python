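"""Physical constants and unit conversions.

Internal unit system: lengths in micrometres (µm). Centimetres (distances),
Ångström (wavelengths) and millimetres (ROI/profile specs) are converted at
the API boundary.
"""

from __future__ import annotations

import numpy as np

#: hc in keV·Å
HC_KEV_ANGSTROM = 12.39842

UM_PER_CM = 1.0e4
UM_PER_MM = 1.0e3
UM_PER_ANGSTROM = 1.0e-4


def wavelength_angstrom(energy_kev: float) -> float:
    """X-ray wavelength in Å for a photon energy in keV."""
    if energy_kev <= 0:
        raise ValueError(f"energy must be positive, got {energy_kev}")
    return HC_KEV_ANGSTROM / energy_kev


def wavelength_um(energy_kev: float) -> float:
    """X-ray wavelength in µm for a photon energy in keV."""
    return wavelength_angstrom(energy_kev) * UM_PER_ANGSTROM


def mu_from_beta(beta, wavelength_um_: float):
    """Linear attenuation coefficient µ = 4πβ/λ, in 1/µm."""
    return 4.0 * np.pi * np.asarray(beta) / wavelength_um_


def beta_from_mu(mu_per_um, wavelength_um_: float):
    """Absorption index β = µλ/(4π) from µ in 1/µm."""
    return np.asarray(mu_per_um) * wavelength_um_ / (4.0 * np.pi)
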