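"""Synthetic elemental photon mass-attenuation model.

The CT forward model needs elemental mass attenuation coefficients
(cm^2/g) at each tube's effective energy.  This module provides them
from a parameterized per-electron cross section:

    sigma(Z, E) = sigma_KN(E) + C_pe * Z^3.8 * E^-3.2 + C_coh * Z^1.9 * E^-1.9

i.e. exact Klein-Nishina incoherent scattering plus power-law
photoelectric and coherent terms, with the two amplitude constants
anchored so that water at 60 keV has approximately the accepted
photoelectric (0.0053 cm^2/g) and coherent (0.0233 cm^2/g) partial
coefficients.  This is a synthetic stand-in for measured/tabulated
cross sections: it preserves the Z- and energy-dependence that
dual-energy decomposition exploits (Compton ~ rho_e, photoelectric ~
Z^n) without claiming sub-percent elemental accuracy.  The photoelectric
and coherent exponents deliberately differ from the two-term exponents
used by the single-energy stoichiometric calibration (3.62 / 1.86), so
that calibration remains a genuine fit rather than an identity.

Energies are in keV throughout.
"""

from __future__ import annotations

import math

import numpy as np

from .physics import ELECTRON_REST_ENERGY_EV, MaterialSpec

__all__ = [
    "klein_nishina_cross_section",
    "electron_cross_section",
    "elemental_mass_attenuation",
    "material_mass_attenuation",
    "linear_attenuation",
]

AVOGADRO = 6.02214076e23
_R_E_CM = 2.8179403262e-13  # classical electron radius, cm

PHOTOELECTRIC_Z_EXPONENT = 3.8
PHOTOELECTRIC_E_EXPONENT = 3.2
COHERENT_Z_EXPONENT = 1.9
COHERENT_E_EXPONENT = 1.9

# calibration anchors: approximate partial mass attenuation of water at 60 keV
_ANCHOR_ENERGY_KEV = 60.0
_WATER_PHOTOELECTRIC_60KEV = 0.0053  # cm^2/g
_WATER_COHERENT_60KEV = 0.0233  # cm^2/g

# water per-gram electron-weighted moments used to solve for the amplitudes
_WATER_TERMS = (  # (Z, A, w)
    (1, 1.008, 0.1119),
    (8, 15.999, 0.8881),
)


def klein_nishina_cross_section(energy_kev: float) -> float:
    """Klein-Nishina total cross section per electron (cm^2)."""
    if energy_kev <= 0:
        raise ValueError(f"photon energy {energy_kev} keV <= 0")
    eps = energy_kev * 1e3 / ELECTRON_REST_ENERGY_EV
    t1 = (1.0 + eps) / eps**2 * (2.0 * (1.0 + eps) / (1.0 + 2.0 * eps) - math.log(1.0 + 2.0 * eps) / eps)
    t2 = math.log(1.0 + 2.0 * eps) / (2.0 * eps)
    t3 = (1.0 + 3.0 * eps) / (1.0 + 2.0 * eps) ** 2
    return 2.0 * math.pi * _R_E_CM**2 * (t1 + t2 - t3)


def _amplitude(target: float, z_exp: float, e_exp: float) -> float:
    moment = sum(AVOGADRO * w * Z / A * Z**z_exp for Z, A, w in _WATER_TERMS)
    return target * _ANCHOR_ENERGY_KEV**e_exp / moment


_C_PE = _amplitude(_WATER_PHOTOELECTRIC_60KEV, PHOTOELECTRIC_Z_EXPONENT, PHOTOELECTRIC_E_EXPONENT)
_C_COH = _amplitude(_WATER_COHERENT_60KEV, COHERENT_Z_EXPONENT, COHERENT_E_EXPONENT)


def electron_cross_section(Z: int, energy_kev: float) -> float:
    """Total per-electron cross section (cm^2) of element ``Z``."""
    return (
        klein_nishina_cross_section(energy_kev)
        + _C_PE * Z**PHOTOELECTRIC_Z_EXPONENT * energy_kev**-PHOTOELECTRIC_E_EXPONENT
        + _C_COH * Z**COHERENT_Z_EXPONENT * energy_kev**-COHERENT_E_EXPONENT
    )


def elemental_mass_attenuation(Z: int, A: float, energy_kev: float) -> float:
    """Mass attenuation coefficient mu/rho (cm^2/g) of an element."""
    return AVOGADRO * Z / A * electron_cross_section(Z, energy_kev)


def material_mass_attenuation(material: MaterialSpec, energy_kev: float) -> float:
    """mu/rho (cm^2/g) of a compound by elemental mixture additivity."""
    return float(
        sum(
            w * elemental_mass_attenuation(Z, A, energy_kev)
            for _, Z, A, w, _ in material.composition.entries
        )
    )


def linear_attenuation(material: MaterialSpec, energy_kev: float) -> float:
    """Linear attenuation coefficient mu (1/cm) at ``energy_kev``."""
    return material.density * material_mass_attenuation(material, energy_kev)


def attenuation_table(
    elements: dict[str, tuple[int, float, float]], energies_kev: list[float]
) -> "np.ndarray":
    """Matrix of mu/rho (cm^2/g), rows = elements (dict order), cols = energies."""
    return np.array(
        [
            [elemental_mass_attenuation(Z, A, e) for e in energies_kev]
            for Z, A, _ in elements.values()
        ]
    )
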