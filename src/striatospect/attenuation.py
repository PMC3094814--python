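"""Linear attenuation coefficients of aqueous sodium-iodide solutions.

The striatal-phantom chambers are filled with tracer dissolved in a 0.1 M
NaI carrier solution (the carrier suppresses adhesion of radioiodine to the
chamber walls).  For attenuation modelling we need the linear attenuation
coefficient of that solution at the I-123 photopeak (159 keV).  It is
computed by the standard mixture rule

    mu = sum_elements (mu/rho)_element(E) * partial_density_element

from a small embedded table of elemental mass attenuation coefficients
(photon cross sections including coherent scattering, after the standard
NIST/Hubbell-Seltzer compilations) for H, O, Na and I, interpolated
log-log in energy.  The solution density is approximated as water plus the
dissolved solute mass, which is accurate to well below a percent at the
molarities of interest (<= 1 M).
"""

from __future__ import annotations

import numpy as np

__all__ = ["mass_attenuation", "nai_solution_mu", "WATER_H_FRACTION", "WATER_O_FRACTION"]

# Elemental mass attenuation coefficients mu/rho in cm^2/g at the tabulated
# energies (keV).  Values follow the standard compilations for photon
# energies in the Compton-dominated regime relevant to I-123 imaging.
_ENERGIES_KEV = np.array([100.0, 150.0, 200.0])

_MU_RHO = {
    # Z = 1
    "H": np.array([0.2944, 0.2651, 0.2429]),
    # Z = 8
    "O": np.array([0.1551, 0.1361, 0.1237]),
    # Z = 11
    "Na": np.array([0.1512, 0.1313, 0.1190]),
    # Z = 53 (photoelectric still significant above the 33.2 keV K edge)
    "I": np.array([1.366, 0.494, 0.271]),
}

# Mass fractions of water.
WATER_H_FRACTION = 2 * 1.00794 / 18.01528
WATER_O_FRACTION = 1.0 - WATER_H_FRACTION

_NA_MOLAR_MASS_G = 22.98977
_I_MOLAR_MASS_G = 126.90447


def mass_attenuation(element: str, energy_kev: float) -> float:
    """mu/rho (cm^2/g) of *element* at *energy_kev*, log-log interpolated.

    Raises ``KeyError`` for an untabulated element and ``ValueError`` for an
    energy outside the tabulated 100-200 keV range.
    """
    table = _MU_RHO[element]
    e = float(energy_kev)
    if not (_ENERGIES_KEV[0] <= e <= _ENERGIES_KEV[-1]):
        raise ValueError(
            f"energy {e} keV outside tabulated range "
            f"[{_ENERGIES_KEV[0]}, {_ENERGIES_KEV[-1]}] keV"
        )
    return float(np.exp(np.interp(np.log(e), np.log(_ENERGIES_KEV), np.log(table))))


def nai_solution_mu(molarity: float, energy_kev: float = 159.0) -> float:
    """Linear attenuation coefficient (1/cm) of an aqueous NaI solution.

    Parameters
    ----------
    molarity:
        NaI concentration in mol/L (>= 0).  0 gives pure water.
    energy_kev:
        Photon energy in keV; must lie within the embedded table range
        (100-200 keV).  Default is the 159 keV I-123 photopeak.
    """
    if molarity < 0:
        raise ValueError("molarity must be non-negative")
    # Partial densities in g/cm^3: water assumed 1.0 g/cm^3, solute adds mass.
    rho_na = molarity * _NA_MOLAR_MASS_G / 1000.0
    rho_i = molarity * _I_MOLAR_MASS_G / 1000.0
    mu = (
        WATER_H_FRACTION * mass_attenuation("H", energy_kev)
        + WATER_O_FRACTION * mass_attenuation("O", energy_kev)
        + rho_na * mass_attenuation("Na", energy_kev)
        + rho_i * mass_attenuation("I", energy_kev)
    )
    return float(mu)
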