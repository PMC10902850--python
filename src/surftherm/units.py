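"""Physical constants, unit conversions, and shared scalar-parameter records.

Internal unit system
--------------------
Lengths in nm, areal densities in nm⁻², volume concentrations in nm⁻³, energies
in kJ/mol, temperature in kelvin.  Surface pressure is carried internally in
kJ/(mol·nm²) so that the ideal-monolayer law Π_id = k_BT·Γ is unit-consistent,
and is rendered in mN/m only at the reporting boundary.  Bulk concentrations
are converted to nm⁻³ at ingestion and reported in mol/L (M) at output; with
these choices every Boltzmann factor exp(−Δg/k_BT) and every product v·c is
dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidParameterError

#: Molar gas constant, kJ/(mol·K).
GAS_CONSTANT = 8.31446261815324e-3

#: Avogadro constant, 1/mol.
AVOGADRO = 6.02214076e23

#: 1 mol/L expressed in nm⁻³.
MOLAR_TO_NM3 = AVOGADRO * 1e-24

#: 1 kJ/(mol·nm²) expressed in mN/m.
KJ_PER_MOL_NM2_IN_MN_PER_M = 1e24 / AVOGADRO


def thermal_energy(temperature: float) -> float:
    """Thermal energy R·T in kJ/mol for a temperature in kelvin.

    Raises
    ------
    InvalidParameterError
        If ``temperature`` is not strictly positive.
    """
    if not temperature > 0:
        raise InvalidParameterError(f"temperature must be > 0 K, got {temperature!r}")
    return GAS_CONSTANT * temperature


def molar_to_number_density(c: float) -> float:
    """Convert a concentration in mol/L to a number density in nm⁻³."""
    if c < 0:
        raise InvalidParameterError(f"concentration must be >= 0, got {c!r}")
    return c * MOLAR_TO_NM3


def number_density_to_molar(rho: float) -> float:
    """Convert a number density in nm⁻³ to a concentration in mol/L."""
    if rho < 0:
        raise InvalidParameterError(f"number density must be >= 0, got {rho!r}")
    return rho / MOLAR_TO_NM3


def pressure_energy_to_mn_per_m(x: float) -> float:
    """Convert a surface pressure from kJ/(mol·nm²) to mN/m (factor ≈ 1.6606)."""
    return x * KJ_PER_MOL_NM2_IN_MN_PER_M


def mn_per_m_to_pressure_energy(x: float) -> float:
    """Convert a surface pressure from mN/m to kJ/(mol·nm²)."""
    return x / KJ_PER_MOL_NM2_IN_MN_PER_M


@dataclass(frozen=True)
class ThermoState:
    """Temperature and the derived thermal energy shared by all modules.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin, strictly positive.
    """

    temperature: float = 300.0

    def __post_init__(self):
        if not self.temperature > 0:
            raise InvalidParameterError(
                f"temperature must be > 0 K, got {self.temperature!r}"
            )

    @property
    def kt(self) -> float:
        """Thermal energy R·T in kJ/mol (≈ 2.494 kJ/mol at 300 K)."""
        return GAS_CONSTANT * self.temperature


@dataclass(frozen=True)
class SurfactantSystem:
    """Molecular-scale parameters of one surfactant species.

    Parameters
    ----------
    volume_v : float
        Surfactant molecular volume v in nm³; the normalizing coefficient of
        the ideal chemical-potential terms.
    delta_s : float
        Effective thickness δ_s of the attractive interface potential in nm
        (the z-range the adsorbed surfactant explores; ≈ 0.5 nm for C12EO6 at
        a decane/water interface).
    b2_3d : float or None
        Second virial coefficient of free surfactants in water, nm³.  May be
        negative, zero, or absent; used only for the ideality diagnostic.
    """

    volume_v: float
    delta_s: float
    b2_3d: float | None = None

    def __post_init__(self):
        if not self.volume_v > 0:
            raise InvalidParameterError(f"volume_v must be > 0, got {self.volume_v!r}")
        if not self.delta_s > 0:
            raise InvalidParameterError(f"delta_s must be > 0, got {self.delta_s!r}")
        if self.b2_3d is not None and not math.isfinite(self.b2_3d):
            raise InvalidParameterError(f"b2_3d must be finite, got {self.b2_3d!r}")
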