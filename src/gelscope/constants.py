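"""Physical constants and the probe-scale viscosity conversions.

The conversion between a probe relaxation time and a microscopic viscosity
uses the single named relation

    tau = 6 * pi * eta * R**3 / (kB * T)

(the time for a sphere of radius R to diffuse a distance comparable to its
own size).  It lives here, in one auditable site, because the choice of the
numerical constant in front of ``eta * R**3 / kB T`` is a convention: the
q-space relaxation time of the same sphere at wavenumber q is 1/(D q^2),
which differs by a dimensionless factor of order (qR)^2.  Both analysis
routes (real-space DVA and Fourier-space DDM) convert their fitted tau
through this same relation and the pipeline reports their ratio.
"""

from __future__ import annotations

import math

#: Boltzmann constant, J/K (exact, SI 2019).
KB = 1.380649e-23


def viscosity_from_tau(tau_s: float, radius_um: float, temperature_k: float) -> float:
    """Invert ``tau = 6 pi eta R^3 / kB T`` for the viscosity.

    Parameters
    ----------
    tau_s : relaxation time in seconds.
    radius_um : probe radius in micrometres.
    temperature_k : absolute temperature in kelvin.

    Returns
    -------
    float
        Microscopic viscosity in mPa*s.
    """
    r_m = radius_um * 1e-6
    eta_pa_s = KB * temperature_k * tau_s / (6.0 * math.pi * r_m**3)
    return eta_pa_s * 1e3


def tau_from_viscosity(eta_mpas: float, radius_um: float, temperature_k: float) -> float:
    """Forward relation: relaxation time (s) of a probe in a medium of given viscosity."""
    r_m = radius_um * 1e-6
    return 6.0 * math.pi * (eta_mpas * 1e-3) * r_m**3 / (KB * temperature_k)


def stokes_einstein_diffusivity(
    eta_mpas: float, radius_um: float, temperature_k: float
) -> float:
    """Translational diffusion coefficient D = kB T / (6 pi eta R), in um^2/s."""
    r_m = radius_um * 1e-6
    d_m2_s = KB * temperature_k / (6.0 * math.pi * (eta_mpas * 1e-3) * r_m)
    return d_m2_s * 1e12


def viscosity_from_diffusivity(
    d_um2_s: float, radius_um: float, temperature_k: float
) -> float:
    """Invert the Stokes-Einstein relation for the medium viscosity (mPa*s)."""
    r_m = radius_um * 1e-6
    eta_pa_s = KB * temperature_k / (6.0 * math.pi * (d_um2_s * 1e-12) * r_m)
    return eta_pa_s * 1e3
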