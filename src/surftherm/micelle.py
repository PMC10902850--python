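"""Micellization thermodynamics: transfer-free-energy model, mass-action size
distribution, and the critical micelle concentration (CMC).

The micelle phase is described by the transfer free energy Δg_m(n) for moving
one surfactant from bulk water into a micelle of final aggregation number n.
Under the law of mass action (chemical-potential equality between a free
surfactant and one bound in a micelle of each size) the micelle concentrations
obey the recursion

    c_n = c_{n-1} · (v·c₁) · exp(−Δg_m(n)/k_BT),       c₁ = free monomers,

where v is the surfactant volume.  The series of aggregate populations
converges only while c₁ is below the critical value

    c₁^CMC = (1/v) · exp(Δg_m(∞)/k_BT),

which is, to excellent approximation, the CMC itself.  Δg_m(n) is parameterized
by a double exponential that is exactly zero at n = 1 and saturates at the
infinite-cylinder value Δg_m(∞):

    Δg_m(n) = Δg_m(∞) · [1 − A·e^{−α₁(n−1)} − (1−A)·e^{−α₂(n−1)}].

All concentrations are carried in log space: at the CMC the cumulative
exponents reach magnitudes of order 300 and would underflow otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import logsumexp

from .errors import (
    DivergenceError,
    FitFailureError,
    InvalidParameterError,
    UnderdeterminedFitError,
)
from .units import SurfactantSystem, ThermoState, number_density_to_molar

DEFAULT_N_MAX = 10_000


@dataclass(frozen=True)
class MicelleFreeEnergyModel:
    """Double-exponential parameterization of the micelle transfer free energy.

    Parameters
    ----------
    dg_inf : float
        Asymptotic transfer free energy Δg_m(∞) in kJ/mol (the infinite
        cylindrical micelle limit).  Negative for micelle-forming surfactants.
    amp_a : float
        Mixing amplitude A of the fast exponential, dimensionless, in [0, 1].
    alpha1, alpha2 : float
        Decay rates of the two exponentials, dimensionless, strictly positive.
        By convention ``alpha1 >= alpha2`` (fast mode first).
    """

    dg_inf: float
    amp_a: float
    alpha1: float
    alpha2: float

    def __post_init__(self):
        if not (0.0 <= self.amp_a <= 1.0):
            raise InvalidParameterError(f"amp_a must be in [0, 1], got {self.amp_a!r}")
        if not self.alpha1 > 0 or not self.alpha2 > 0:
            raise InvalidParameterError(
                f"decay rates must be > 0, got {self.alpha1!r}, {self.alpha2!r}"
            )
        if not math.isfinite(self.dg_inf):
            raise InvalidParameterError(f"dg_inf must be finite, got {self.dg_inf!r}")

    def __call__(self, n):
        return transfer_free_energy(self, n)


def transfer_free_energy(model: MicelleFreeEnergyModel, n):
    """Evaluate Δg_m(n) in kJ/mol for aggregation number(s) n ≥ 1.

    The functional form forces Δg_m(1) = 0 exactly.  ``n`` may be a scalar or
    array and may be real-valued (continuous extension) or ``inf`` (returns
    ``dg_inf``).
    """
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 1):
        raise InvalidParameterError(f"aggregation number must be >= 1, got {n!r}")
    m = n_arr - 1.0
    with np.errstate(over="ignore"):
        value = model.dg_inf * (
            1.0
            - model.amp_a * np.exp(-model.alpha1 * m)
            - (1.0 - model.amp_a) * np.exp(-model.alpha2 * m)
        )
    if np.isscalar(n) or n_arr.ndim == 0:
        return float(value)
    return value


def cmc(
    model: MicelleFreeEnergyModel,
    system: SurfactantSystem,
    thermo: ThermoState,
) -> float:
    """Critical micelle concentration in mol/L.

    Limiting-ratio condition of the mass-action recursion (c_n = c_{n−1}):
    c₁^CMC = (1/v)·exp(Δg_m(∞)/k_BT).  Depends only on ``dg_inf`` and the
    surfactant volume, not on the shape parameters A, α₁, α₂.
    """
    return number_density_to_molar(cmc_number_density(model, system, thermo))


def cmc_number_density(
    model: MicelleFreeEnergyModel,
    system: SurfactantSystem,
    thermo: ThermoState,
) -> float:
    """Critical micelle concentration as a number density in nm⁻³."""
    return math.exp(model.dg_inf / thermo.kt) / system.volume_v


@dataclass(frozen=True)
class MicelleSizeDistribution:
    """Mass-action micelle-size distribution at fixed free-monomer concentration.

    Attributes
    ----------
    c1 : float
        Free-monomer concentration in nm⁻³ (equals the n = 1 entry).
    log_cn : numpy.ndarray
        Natural logarithms of the micelle concentrations c_n (nm⁻³) for
        n = 1 … n_max.
    n_max : int
        Truncation size of the distribution.
    converged : bool
        True iff c1 is strictly below the CMC, i.e. the infinite series of
        aggregate populations converges.
    """

    c1: float
    log_cn: np.ndarray = field(repr=False)
    n_max: int
    converged: bool

    @property
    def sizes(self) -> np.ndarray:
        """Aggregation numbers 1 … n_max."""
        return np.arange(1, self.n_max + 1)

    @property
    def concentrations(self) -> np.ndarray:
        """Micelle concentrations c_n in nm⁻³ (may underflow to 0 for display)."""
        return np.exp(self.log_cn)


def size_distribution(
    c1: float,
    model: MicelleFreeEnergyModel,
    system: SurfactantSystem,
    thermo: ThermoState,
    n_max: int = DEFAULT_N_MAX,
    hypothetical: bool = False,
) -> MicelleSizeDistribution:
    """Micelle-size distribution from the mass-action recursion, in log space.

    ln(v·c_n) = n·ln(v·c₁) − Σ_{k=2}^{n} Δg_m(k)/k_BT.

    Parameters
    ----------
    c1 : float
        Free-monomer concentration in nm⁻³, strictly positive.
    n_max : int
        Largest aggregation number retained (default 10⁴).
    hypothetical : bool
        Allow c1 above the CMC (a deliberately unphysical, diverging
        distribution).  Without it, c1 > CMC raises :class:`DivergenceError`.
    """
    if not c1 > 0:
        raise InvalidParameterError(f"c1 must be > 0 nm^-3, got {c1!r}")
    if n_max < 2:
        raise InvalidParameterError(f"n_max must be >= 2, got {n_max!r}")
    c1_cmc = cmc_number_density(model, system, thermo)
    converged = c1 < c1_cmc
    if c1 > c1_cmc * (1.0 + 1e-12) and not hypothetical:
        raise DivergenceError(
            f"c1 = {c1:.4g} nm^-3 exceeds the CMC ({c1_cmc:.4g} nm^-3); the "
            "size distribution diverges. Pass hypothetical=True to build it anyway."
        )
    n = np.arange(1, n_max + 1)
    dg = transfer_free_energy(model, n)  # dg[0] = Δg(1) = 0
    log_vc1 = math.log(system.volume_v * c1)
    # ln c_n = ln c1 + (n-1)·ln(v c1) − (1/kT)·Σ_{k=2}^{n} Δg(k)
    cum_dg = np.cumsum(dg)  # Σ_{k=1}^{n} Δg(k); Δg(1)=0 so equals Σ_{k=2}^{n}
    log_cn = math.log(c1) + (n - 1) * log_vc1 - cum_dg / thermo.kt
    return MicelleSizeDistribution(
        c1=c1, log_cn=log_cn, n_max=int(n_max), converged=bool(converged)
    )


@dataclass(frozen=True)
class TotalConcentration:
    """Total surfactant concentration c₀ = Σ n·c_n with its truncation bound."""

    value: float  # nm⁻³
    truncation_bound: float  # nm⁻³, upper estimate of the neglected tail

    def __float__(self):
        return self.value


def total_concentration(
    dist: MicelleSizeDistribution, allow_divergent: bool = False
) -> TotalConcentration:
    """Total concentration c₀ = c₁ + Σ_{n≥2} n·c_n up to n_max, in nm⁻³.

    The truncation bound estimates the neglected tail from the geometric decay
    of the last two retained terms.  A distribution built above the CMC has a
    divergent tail and raises :class:`DivergenceError` unless
    ``allow_divergent`` is set (the truncated sum is then reported with an
    infinite truncation bound).
    """
    log_terms = np.log(dist.sizes) + dist.log_cn
    value = float(np.exp(logsumexp(log_terms)))
    ratio = math.exp(log_terms[-1] - log_terms[-2]) if dist.n_max >= 2 else 0.0
    if ratio < 1.0:
        bound = math.exp(log_terms[-1]) * ratio / (1.0 - ratio)
    else:
        bound = math.inf
    if not dist.converged and ratio >= 1.0 and not allow_divergent:
        raise DivergenceError(
            "total concentration diverges for c1 > CMC; pass allow_divergent=True "
            "to accept the truncated sum"
        )
    return TotalConcentration(value=value, truncation_bound=bound)


def micellar_fraction(
    dist: MicelleSizeDistribution, allow_divergent: bool = False
) -> float:
    """Micellar mass fraction (c₀ − c₁)/c₀ ∈ [0, 1).

    c₀^mic ≡ c₀ − c₁ = Σ_{n≥2} n·c_n is the concentration of surfactants bound
    in aggregates; at the CMC it is ~10⁻⁵ of the total for C12EO6-like
    parameters.
    """
    c0 = total_concentration(dist, allow_divergent=allow_divergent).value
    return max(0.0, (c0 - dist.c1) / c0)


def monomer_of_total(c0: float, cmc_value: float) -> float:
    """Free-monomer concentration c₁ for a given total concentration c₀.

    Below the CMC essentially all surfactants are free (c₁ = c₀); above it the
    monomer concentration stays pinned at the CMC and the surplus is consumed
    by long cylindrical micelles: c₁ = min(c₀, CMC).  Units are the caller's
    (consistent between the two arguments).
    """
    if c0 < 0:
        raise InvalidParameterError(f"c0 must be >= 0, got {c0!r}")
    return min(c0, cmc_value)


def ideality_threshold(system: SurfactantSystem) -> float:
    """Concentration c* = 1/(2·|B₂|) in mol/L above which the free-surfactant
    solution can no longer be treated as ideal.

    At c* the second-virial correction to the log-activity reaches order one.
    With B₂ absent or zero the solution is ideal at all concentrations of
    interest and ``inf`` is returned.
    """
    if system.b2_3d is None or system.b2_3d == 0.0:
        return math.inf
    return number_density_to_molar(1.0 / (2.0 * abs(system.b2_3d)))


def cylinder_volume(radius: float, linear_density: float) -> float:
    """Effective surfactant volume v = π·R*²/(dN/dl) in nm³ from the geometry
    of an infinite cylindrical micelle.

    Parameters
    ----------
    radius : float
        Effective cylinder radius R* in nm.
    linear_density : float
        Linear number density of surfactants dN/dl along the cylinder, nm⁻¹.
    """
    if not radius > 0 or not linear_density > 0:
        raise InvalidParameterError(
            f"radius and linear_density must be > 0, got {radius!r}, {linear_density!r}"
        )
    return math.pi * radius**2 / linear_density


@dataclass(frozen=True)
class MicelleFitResult:
    """Result of fitting the double-exponential transfer-free-energy model."""

    model: MicelleFreeEnergyModel
    residuals: np.ndarray  # kJ/mol, model − data at the finite-n points
    cost: float  # half sum of squared (weighted) residuals


def _canonical(dg_inf, amp_a, alpha1, alpha2) -> MicelleFreeEnergyModel:
    # tie-break the α₁/α₂ exchange degeneracy: fast mode first
    if alpha1 < alpha2:
        alpha1, alpha2, amp_a = alpha2, alpha1, 1.0 - amp_a
    return MicelleFreeEnergyModel(
        dg_inf=float(dg_inf),
        amp_a=float(min(max(amp_a, 0.0), 1.0)),
        alpha1=float(alpha1),
        alpha2=float(alpha2),
    )


def fit_transfer_free_energy(
    n,
    dg,
    sigma=None,
    *,
    fix_asymptote: bool = True,
    n_starts: int = 5,
    seed: int = 0,
) -> MicelleFitResult:
    """Fit the double-exponential Δg_m(n) model to (n, Δg[, σ]) data.

    Rows with ``n = inf`` are cylindrical-limit data.  By default
    (``fix_asymptote=True``) such a row pins Δg_m(∞) as a hard constraint and
    only (A, α₁, α₂) are fitted; with ``fix_asymptote=False`` the asymptote
    row enters the least squares as an ordinary point.  Weights are
    inverse-variance when ``sigma`` is supplied, uniform otherwise.  The
    bound-constrained least squares is restarted from ``n_starts`` seeded
    initial decay-rate pairs to avoid the α₁/α₂ exchange degeneracy; the
    returned model orders α₁ ≥ α₂.

    Raises
    ------
    UnderdeterminedFitError
        Fewer points than free parameters.
    FitFailureError
        No restart converged.
    """
    n = np.asarray(n, dtype=float)
    dg = np.asarray(dg, dtype=float)
    if n.shape != dg.shape or n.ndim != 1:
        raise InvalidParameterError("n and dg must be 1-D arrays of equal length")
    if np.any(n < 1):
        raise InvalidParameterError("aggregation numbers must be >= 1")
    w = np.ones_like(dg)
    if sigma is not None:
        sigma = np.asarray(sigma, dtype=float)
        if np.any(sigma <= 0):
            raise InvalidParameterError("uncertainties must be > 0")
        w = 1.0 / sigma

    inf_mask = np.isinf(n)
    fin_n, fin_dg, fin_w = n[~inf_mask], dg[~inf_mask], w[~inf_mask]

    dg_inf_fixed = None
    if fix_asymptote and inf_mask.any():
        wi = w[inf_mask]
        dg_inf_fixed = float(np.average(dg[inf_mask], weights=wi**2))

    n_free = 3 if dg_inf_fixed is not None else 4
    if fin_n.size < n_free:
        raise UnderdeterminedFitError(
            f"need at least {n_free} finite-n points, got {fin_n.size}"
        )

    def unpack(theta):
        if dg_inf_fixed is not None:
            a, a1, a2 = theta
            return dg_inf_fixed, a, a1, a2
        g, a, a1, a2 = theta
        return g, a, a1, a2

    def predict(theta, n_values):
        g, a, a1, a2 = unpack(theta)
        m = n_values - 1.0
        return g * (1.0 - a * np.exp(-a1 * m) - (1.0 - a) * np.exp(-a2 * m))

    def resid(theta):
        r = (predict(theta, fin_n) - fin_dg) * fin_w
        if dg_inf_fixed is None and inf_mask.any():
            g = theta[0]
            r = np.concatenate([r, (g - dg[inf_mask]) * w[inf_mask]])
        return r

    dg_inf_guess = dg_inf_fixed if dg_inf_fixed is not None else float(dg[np.argmax(n)])
    if dg_inf_guess == 0.0:
        dg_inf_guess = float(np.min(dg)) or -1.0

    rng = np.random.default_rng(seed)
    # seeded multi-start over decay-rate pairs spanning two decades
    starts = []
    base_pairs = [(0.5, 0.03), (1.0, 0.1), (0.2, 0.01), (2.0, 0.3), (0.1, 0.005)]
    for i in range(n_starts):
        if i < len(base_pairs):
            a1, a2 = base_pairs[i]
        else:
            a1 = 10.0 ** rng.uniform(-1.5, 0.5)
            a2 = 10.0 ** rng.uniform(-2.5, -0.5)
        starts.append((max(a1, a2), min(a1, a2)))

    lo_rate, hi_rate = 1e-8, 1e3
    best = None
    for a1_0, a2_0 in starts:
        if dg_inf_fixed is not None:
            x0 = [0.5, a1_0, a2_0]
            lb = [0.0, lo_rate, lo_rate]
            ub = [1.0, hi_rate, hi_rate]
        else:
            x0 = [dg_inf_guess, 0.5, a1_0, a2_0]
            lb = [-np.inf, 0.0, lo_rate, lo_rate]
            ub = [np.inf, 1.0, hi_rate, hi_rate]
        try:
            sol = least_squares(
                resid, x0, bounds=(lb, ub), xtol=1e-15, ftol=1e-15, gtol=1e-15
            )
        except Exception:  # singular Jacobian etc.; try the next start
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitFailureError(
            "double-exponential fit failed to converge from all starts",
            details={"n_starts": n_starts},
        )
    model = _canonical(*unpack(best.x))
    residuals = transfer_free_energy(model, fin_n) - fin_dg
    return MicelleFitResult(model=model, residuals=residuals, cost=float(best.cost))
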