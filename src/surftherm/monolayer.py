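"""Monolayer thermodynamics: equation of state, Π-integration, and the
adsorption and surface-pressure isotherms.

The adsorbed Gibbs monolayer at an oil/water (or air/water) interface is
characterized by the surface coverage Γ (nm⁻²) and the surface pressure
Π = γ₀ − γ.  The equation of state (EoS) is a polynomial with the ideal
two-dimensional-gas leading term pinned,

    Π(Γ) = k_BT·Γ + C₂Γ² + ... + C_pΓ^p      (default order p = 5),

and the coverage-dependent transfer free energy follows from integrating the
Gibbs adsorption relation dΠ = Γ·dμ_s over the EoS ("Π-integration"):

    Δg_s(Γ) = Δg_s(0) + (Π − Π_id)/Γ + ∫₀^Γ (Π − Π_id)/Γ′² dΓ′,

which for the polynomial EoS has the closed form
Δg_s(0) + Σ_k C_k·k/(k−1)·Γ^{k−1}.  Chemical-potential equality between the
monolayer and the bulk gives the self-consistency condition

    Γ = δ_s·c₁·exp(−Δg_s(Γ)/k_BT),

whose root Γ(c₁), composed with the monomer/total relation c₁ = min(c₀, CMC),
yields the adsorption isotherm Γ(c₀) and, through the EoS, the pressure
isotherm Π(c₀).  Both plateau exactly above the CMC.

Internal units: Γ in nm⁻², energies in kJ/mol, Π in kJ/(mol·nm²); the
:class:`Isotherm` record reports concentrations in mol/L and pressures in mN/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import PchipInterpolator

from .errors import (
    AmbiguityError,
    ExtrapolationError,
    InvalidParameterError,
    OutOfRangeError,
    UnderdeterminedFitError,
)
from .units import (
    SurfactantSystem,
    ThermoState,
    molar_to_number_density,
    pressure_energy_to_mn_per_m,
)

_REL_SLACK = 1e-9  # tolerated relative overshoot of the validity range


def pressure_from_tension(gamma0: float, gamma: float) -> float:
    """Surface pressure Π = γ₀ − γ (mN/m), with γ₀ the bare-interface tension."""
    return gamma0 - gamma


def area_per_molecule(gamma: float) -> float:
    """Area per adsorbed molecule Γ⁻¹ in nm² for a coverage in nm⁻²."""
    if not gamma > 0:
        raise InvalidParameterError(f"coverage must be > 0, got {gamma!r}")
    return 1.0 / gamma


@dataclass(frozen=True)
class EquationOfState:
    """Polynomial monolayer equation of state with a pinned ideal term.

    Parameters
    ----------
    coefficients : numpy.ndarray
        Virial-like coefficients (C₂, …, C_p) of the Γ², …, Γ^p terms, in
        kJ/mol·nm^(2k−2).  The linear coefficient is fixed at k_BT.
    thermal_energy : float
        k_BT in kJ/mol.
    gamma_max : float
        Upper end of the validity interval [0, Γ_max] in nm⁻²; evaluating
        beyond it raises :class:`ExtrapolationError`.
    """

    coefficients: np.ndarray = field(repr=False)
    thermal_energy: float
    gamma_max: float

    def __post_init__(self):
        coeffs = np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        object.__setattr__(self, "coefficients", coeffs)
        if not (2 <= self.order <= 7):
            raise InvalidParameterError(
                f"polynomial order must be in [2, 7], got {self.order}"
            )
        if not self.thermal_energy > 0:
            raise InvalidParameterError("thermal_energy must be > 0")
        if not self.gamma_max > 0:
            raise InvalidParameterError("gamma_max must be > 0")

    @property
    def order(self) -> int:
        """Polynomial order p (highest power of Γ)."""
        return self.coefficients.size + 1

    @property
    def powers(self) -> np.ndarray:
        """Powers k = 2 … p of the non-ideal terms."""
        return np.arange(2, self.order + 1)

    def _check_range(self, gamma):
        g = np.asarray(gamma, dtype=float)
        if np.any(g < 0) or np.any(g > self.gamma_max * (1.0 + _REL_SLACK)):
            raise ExtrapolationError(
                f"coverage outside EoS validity range [0, {self.gamma_max:g}] nm^-2"
            )

    def pressure(self, gamma):
        """Π(Γ) in kJ/(mol·nm²); Π(0) = 0 and dΠ/dΓ|₀ = k_BT exactly."""
        self._check_range(gamma)
        g = np.asarray(gamma, dtype=float)
        excess = sum(c * g**k for c, k in zip(self.coefficients, self.powers))
        out = self.thermal_energy * g + excess
        return float(out) if np.ndim(gamma) == 0 else out

    def pressure_mn_per_m(self, gamma):
        """Π(Γ) in mN/m."""
        return pressure_energy_to_mn_per_m(self.pressure(gamma))

    def excess_pressure(self, gamma):
        """Π − Π_id in kJ/(mol·nm²) (the non-ideal part alone)."""
        g = np.asarray(gamma, dtype=float)
        out = sum(c * g**k for c, k in zip(self.coefficients, self.powers))
        return float(out) if np.ndim(gamma) == 0 else out

    def excess_transfer_free_energy(self, gamma):
        """Closed-form Π-integration increment Σ_k C_k·k/(k−1)·Γ^{k−1}, kJ/mol."""
        self._check_range(gamma)
        g = np.asarray(gamma, dtype=float)
        out = sum(
            c * (k / (k - 1.0)) * g ** (k - 1)
            for c, k in zip(self.coefficients, self.powers)
        )
        return float(out) if np.ndim(gamma) == 0 else out


def fit_eos(
    gamma,
    pi,
    thermo: ThermoState,
    sigma=None,
    order: int = 5,
) -> EquationOfState:
    """Fit the polynomial EoS to (Γ, Π[, σ]) data in internal units.

    The ideal term k_BT·Γ is pinned, so the fit is linear least squares on
    Π − k_BT·Γ with zero intercept and regressors Γ², …, Γ^order (inverse-
    variance weighted when ``sigma`` is given).  The validity range is
    recorded as [0, max Γ in the data].

    Parameters
    ----------
    gamma : array
        Coverages in nm⁻², all ≥ 0, including low-coverage points.
    pi : array
        Surface pressures in kJ/(mol·nm²).
    """
    gamma = np.asarray(gamma, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if gamma.shape != pi.shape or gamma.ndim != 1:
        raise InvalidParameterError("gamma and pi must be 1-D arrays of equal length")
    if np.any(gamma < 0):
        raise InvalidParameterError("coverages must be >= 0")
    n_free = order - 1
    n_distinct = np.unique(gamma[gamma > 0]).size
    if gamma.size < max(5, n_free) or n_distinct < n_free:
        raise UnderdeterminedFitError(
            f"need >= {max(5, n_free)} points with >= {n_free} distinct positive "
            f"coverages for an order-{order} fit"
        )
    powers = np.arange(2, order + 1)
    design = gamma[:, None] ** powers[None, :]
    target = pi - thermo.kt * gamma
    if sigma is not None:
        w = 1.0 / np.asarray(sigma, dtype=float)
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise InvalidParameterError("uncertainties must be > 0 and finite")
        design = design * w[:, None]
        target = target * w
    coeffs, *_ = np.linalg.lstsq(design, target, rcond=None)
    return EquationOfState(
        coefficients=coeffs, thermal_energy=thermo.kt, gamma_max=float(gamma.max())
    )


@dataclass(frozen=True)
class AdsorptionFreeEnergyCurve:
    """Coverage-dependent interface transfer free energy Δg_s(Γ).

    ``excess`` maps Γ (nm⁻²) to Δg_s(Γ) − Δg_s(0) in kJ/mol with
    ``excess(0) = 0``; ``source`` records whether the curve came from
    Π-integration of an EoS or from tabulated thermodynamic-integration data.
    """

    dgs0: float
    excess: Callable = field(repr=False)
    gamma_max: float
    source: str = "pi_integration"

    def __call__(self, gamma):
        """Δg_s(Γ) = Δg_s(0) + excess(Γ) in kJ/mol."""
        if np.any(np.asarray(gamma) > self.gamma_max * (1.0 + _REL_SLACK)) or np.any(
            np.asarray(gamma) < 0
        ):
            raise ExtrapolationError(
                f"coverage outside curve validity range [0, {self.gamma_max:g}] nm^-2"
            )
        out = self.dgs0 + self.excess(np.asarray(gamma, dtype=float))
        return float(out) if np.ndim(gamma) == 0 else np.asarray(out)


def pi_integrate(
    eos: EquationOfState, dgs0: float, method: str = "analytic"
) -> AdsorptionFreeEnergyCurve:
    """Build Δg_s(Γ) from the EoS by Π-integration, anchored at Δg_s(0) = dgs0.

    ``method="analytic"`` uses the closed form for the polynomial EoS;
    ``method="quadrature"`` evaluates (Π − Π_id)/Γ + ∫₀^Γ (Π − Π_id)/Γ′² dΓ′
    by adaptive quadrature, using the analytic limit (Π − Π_id)/Γ′² → C₂ at
    the lower endpoint (no epsilon offset needed).
    """
    if method == "analytic":
        excess = eos.excess_transfer_free_energy
    elif method == "quadrature":
        c2 = float(eos.coefficients[0])

        def integrand(g):
            if g == 0.0:
                return c2
            return eos.excess_pressure(g) / g**2

        def excess(gamma):
            def one(g):
                if g == 0.0:
                    return 0.0
                integral, _ = quad(integrand, 0.0, g, limit=200)
                return eos.excess_pressure(g) / g + integral

            g_arr = np.asarray(gamma, dtype=float)
            if g_arr.ndim == 0:
                return one(float(g_arr))
            return np.array([one(g) for g in g_arr])

    else:
        raise InvalidParameterError(f"unknown method {method!r}")
    return AdsorptionFreeEnergyCurve(
        dgs0=float(dgs0), excess=excess, gamma_max=eos.gamma_max, source="pi_integration"
    )


def curve_from_ti_table(gamma, dg) -> AdsorptionFreeEnergyCurve:
    """Δg_s(Γ) curve from tabulated thermodynamic-integration data.

    Interpolated with a monotone-preserving cubic (PCHIP) so that a monotone
    data set cannot acquire spurious oscillations that would create multiple
    roots in the adsorption self-consistency equation.  The table must start
    at Γ = 0 (the anchor Δg_s(0)); extrapolation beyond the tabulated range is
    forbidden.
    """
    gamma = np.asarray(gamma, dtype=float)
    dg = np.asarray(dg, dtype=float)
    order = np.argsort(gamma)
    gamma, dg = gamma[order], dg[order]
    if gamma[0] != 0.0:
        raise InvalidParameterError(
            "tabulated transfer-free-energy data must include a zero-coverage row"
        )
    if np.unique(gamma).size != gamma.size:
        raise InvalidParameterError("duplicate coverages in tabulated data")
    interp = PchipInterpolator(gamma, dg - dg[0], extrapolate=False)
    dgs0 = float(dg[0])

    def excess(g):
        out = interp(g)
        return out

    return AdsorptionFreeEnergyCurve(
        dgs0=dgs0, excess=excess, gamma_max=float(gamma[-1]), source="tabulated_TI"
    )


def coverage_of_monomer(
    c1: float,
    curve: AdsorptionFreeEnergyCurve,
    system: SurfactantSystem,
    thermo: ThermoState,
    rtol: float = 1e-12,
) -> float:
    """Solve the self-consistency equation Γ = δ_s·c₁·exp(−Δg_s(Γ)/k_BT).

    Parameters
    ----------
    c1 : float
        Free-monomer concentration in nm⁻³ (≥ 0).

    Uses bisection on a bracket grown geometrically from the Henry-limit
    estimate Γ_H = δ_s·c₁·exp(−Δg_s(0)/k_BT); for a nondecreasing excess the
    root is unique and lies in (0, Γ_H].  A non-monotone curve with several
    fixed points raises :class:`AmbiguityError` listing all roots; if no
    bracket exists inside the curve's validity range an
    :class:`OutOfRangeError` is raised.
    """
    if c1 < 0:
        raise InvalidParameterError(f"c1 must be >= 0, got {c1!r}")
    if c1 == 0.0:
        return 0.0
    kt = thermo.kt

    def f(g):
        # fixed-point residual; f(0+) > 0, f > root < 0 for monotone curves
        return system.delta_s * c1 * np.exp(-curve(g) / kt) - g

    henry = system.delta_s * c1 * np.exp(-curve.dgs0 / kt)
    hi = min(henry, curve.gamma_max)
    # grow the bracket geometrically in case the curve decreases somewhere
    while f(hi) > 0:
        if hi >= curve.gamma_max:
            raise OutOfRangeError(
                "no self-consistent coverage within the curve validity range "
                f"[0, {curve.gamma_max:g}] nm^-2 (c1 too high?)"
            )
        hi = min(2.0 * hi, curve.gamma_max)

    # scan for multiple sign changes (non-monotone excess)
    grid = np.linspace(0.0, hi, 513)
    vals = np.array([f(g) for g in grid])
    sign_changes = np.nonzero(np.diff(np.sign(vals)) < 0)[0]
    brackets = [(grid[i], grid[i + 1]) for i in sign_changes]
    if not brackets:
        brackets = [(0.0, hi)]

    roots = []
    for lo, up in brackets:
        a, b = lo, up
        fa = f(a)
        for _ in range(200):
            mid = 0.5 * (a + b)
            fm = f(mid)
            if fm == 0.0 or (b - a) <= rtol * max(mid, 1e-300):
                a = b = mid
                break
            if (fa > 0) == (fm > 0):
                a, fa = mid, fm
            else:
                b = mid
        roots.append(0.5 * (a + b))
    if len(roots) > 1:
        raise AmbiguityError(
            f"{len(roots)} self-consistent coverages found (non-monotone "
            "transfer-free-energy curve)",
            roots=roots,
        )
    return float(roots[0])


@dataclass(frozen=True)
class Isotherm:
    """Tabulated adsorption/pressure isotherm with its CMC annotations.

    ``c0_grid`` in mol/L, ``gamma`` in nm⁻², ``pressure`` in mN/m (None until
    composed with an EoS); ``gamma``/``pressure`` are nondecreasing and sit
    exactly at their CMC values for c₀ ≥ CMC.
    """

    c0_grid: np.ndarray = field(repr=False)
    gamma: np.ndarray = field(repr=False)
    cmc: float
    gamma_cmc: float
    pressure: np.ndarray | None = field(default=None, repr=False)
    pressure_cmc: float | None = None


def adsorption_isotherm(
    c0_grid: Sequence[float],
    curve: AdsorptionFreeEnergyCurve,
    cmc: float,
    system: SurfactantSystem,
    thermo: ThermoState,
) -> Isotherm:
    """Adsorption isotherm Γ(c₀) on a sorted grid of total concentrations (mol/L).

    Each grid point is mapped through c₁ = min(c₀, CMC) and the coverage
    self-consistency equation; above the CMC the coverage plateaus exactly at
    Γ_CMC.
    """
    c0_grid = np.asarray(c0_grid, dtype=float)
    if np.any(c0_grid < 0):
        raise InvalidParameterError("total concentrations must be >= 0")
    if np.any(np.diff(c0_grid) < 0):
        raise InvalidParameterError("c0_grid must be sorted ascending")
    gamma_cmc = coverage_of_monomer(
        molar_to_number_density(cmc), curve, system, thermo
    )
    gamma = np.empty_like(c0_grid)
    for i, c0 in enumerate(c0_grid):
        if c0 >= cmc:
            gamma[i] = gamma_cmc
        else:
            c1 = molar_to_number_density(monomer_of_total_molar(c0, cmc))
            gamma[i] = coverage_of_monomer(c1, curve, system, thermo)
    return Isotherm(c0_grid=c0_grid, gamma=gamma, cmc=float(cmc), gamma_cmc=gamma_cmc)


def monomer_of_total_molar(c0: float, cmc: float) -> float:
    """min(c₀, CMC) in mol/L (monomer pinning above the CMC)."""
    from .micelle import monomer_of_total

    return monomer_of_total(c0, cmc)


def pressure_isotherm(iso: Isotherm, eos: EquationOfState) -> Isotherm:
    """Compose an adsorption isotherm with the EoS: Π(c₀) = Π(Γ(c₀)) in mN/m."""
    pressure = np.asarray(
        [eos.pressure_mn_per_m(g) for g in iso.gamma], dtype=float
    )
    pressure_cmc = eos.pressure_mn_per_m(iso.gamma_cmc)
    return Isotherm(
        c0_grid=iso.c0_grid,
        gamma=iso.gamma,
        cmc=iso.cmc,
        gamma_cmc=iso.gamma_cmc,
        pressure=pressure,
        pressure_cmc=float(pressure_cmc),
    )


def reduced_isotherm(
    eos: EquationOfState,
    gamma_cmc: float,
    thermo: ThermoState,
    gamma_grid: Sequence[float],
) -> np.ndarray:
    """Reduced pressure isotherm (c₀/CMC, Π/Π_CMC) directly from the EoS.

    Subtracting the adsorption equilibrium at the CMC from itself at a general
    sub-CMC concentration eliminates Δg_s(0) and the absolute free-energy
    scale:

        k_BT·ln(c₀/CMC) = k_BT·ln(Γ/Γ_CMC) + [Δg_s(Γ) − Δg_s(Γ_CMC)],

    where the bracket is the Π-integration increment evaluated purely from
    the EoS.  The endpoint Γ = Γ_CMC maps to (1, 1) exactly.

    Returns an array of shape (len(gamma_grid), 2) with columns c₀/CMC and
    Π/Π_CMC.
    """
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    if np.any(gamma_grid <= 0):
        raise InvalidParameterError("gamma_grid must be strictly positive")
    if np.any(gamma_grid > gamma_cmc * (1.0 + _REL_SLACK)):
        raise InvalidParameterError("gamma_grid must not exceed gamma_cmc")
    kt = thermo.kt
    ex_cmc = eos.excess_transfer_free_energy(gamma_cmc)
    ex = eos.excess_transfer_free_energy(gamma_grid)
    c_ratio = (gamma_grid / gamma_cmc) * np.exp((ex - ex_cmc) / kt)
    p_ratio = eos.pressure(gamma_grid) / eos.pressure(gamma_cmc)
    return np.column_stack([c_ratio, p_ratio])
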