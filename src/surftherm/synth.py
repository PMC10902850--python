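"""Synthetic-data generator: ground-truth-known stand-ins for MD/TI output.

Every fit and pipeline stage in this package consumes tables that, in a real
study, come from molecular-dynamics free-energy calculations (micelle transfer
free energies, equation-of-state samples, surface-tension time series).  The
generators here produce such tables from known ground-truth parameters plus
seeded additive Gaussian noise, so that parameter-recovery and full-pipeline
tests have an exact reference.

Default parameters are the C12EO6/decane-water study conditions: the
double-exponential micelle model (Δg_m(∞) = −38 kJ/mol, A = 0.5, α₁ = 0.48,
α₂ = 0.026) sampled at the micelle sizes for which free energies are
typically computed, with σ = 2 kJ/mol error bars; and a fifth-order EoS whose
synthetic coefficients are chosen so that the adsorption pipeline, anchored
at the study's Δg_s(0) = −63.5 kJ/mol, reaches the study's coverage scale
Γ_CMC ≈ 1.5 nm⁻² at its CMC.  The true EoS coefficients of that system are
not published, so the EoS defaults are qualitative stand-ins, not a
reproduction (in particular the resulting pressure scale, Π_CMC ≈ 47 mN/m,
is set by this choice, not fitted to the study).

Determinism: each generator draws from ``numpy.random.default_rng(spec.seed)``
only — identical specs (including seed) give bitwise-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .micelle import MicelleFreeEnergyModel, transfer_free_energy
from .monolayer import EquationOfState
from .units import ThermoState, pressure_energy_to_mn_per_m

#: Study-condition micelle-model ground truth (kJ/mol and dimensionless).
DEFAULT_MICELLE_PARAMS = {
    "dg_inf": -38.0,
    "amp_a": 0.5,
    "alpha1": 0.48,
    "alpha2": 0.026,
}

#: Micelle sizes at which transfer free energies are "measured".
DEFAULT_MICELLE_GRID = (2, 4, 6, 9, 13, 19, 27, 39, 55)

#: Synthetic EoS ground truth C₂…C₅ in kJ/mol·nm^(2k−2).  Chosen once so that
#: the full pipeline with Δg_s(0) = −63.5 kJ/mol and the micelle-model CMC
#: reproduces the study's coverage scale, Γ_CMC ≈ 1.5 nm⁻².
DEFAULT_EOS_COEFFS = (0.5, 0.8, 1.2, 2.2)

#: Default coverage grid for EoS sampling, nm⁻².
DEFAULT_EOS_GRID = tuple(np.round(np.linspace(0.0, 1.6, 13), 6))

#: Bare decane/water interfacial tension of the study model, mN/m.
DEFAULT_GAMMA0 = 54.1


@dataclass(frozen=True)
class SyntheticSpec:
    """Specification of one synthetic data set.

    Parameters
    ----------
    kind : str
        One of ``micelle_dg``, ``eos_points``, ``tension_series``.
    params : dict
        Ground-truth parameters; missing keys fall back to the study-condition
        defaults of each generator.
    noise : float
        Additive Gaussian noise scale (kJ/mol for micelle data, mN/m for
        EoS/tension data); must be ≥ 0.
    grid : sequence or None
        Sample grid (micelle sizes n, coverages Γ, or time points); generator
        default when None.
    seed : int
        Seed for the generator's private RNG.
    """

    kind: str
    params: dict = field(default_factory=dict)
    noise: float = 0.0
    grid: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.kind not in {"micelle_dg", "eos_points", "tension_series"}:
            raise InvalidParameterError(f"unknown generator kind {self.kind!r}")
        if self.noise < 0:
            raise InvalidParameterError(f"noise must be >= 0, got {self.noise!r}")


def generate_micelle_dg(spec: SyntheticSpec) -> pd.DataFrame:
    """Synthetic (n, Δg, σ) table from the double-exponential micelle model.

    Emulates a set of TI measurements of micelle transfer free energies,
    including (by default) the infinite-cylinder row ``n = inf`` whose value
    is the asymptote Δg_m(∞).  Noise is additive Gaussian with the spec's
    scale; the reported σ column carries that scale.
    """
    p = {**DEFAULT_MICELLE_PARAMS, **spec.params}
    include_inf = p.pop("include_inf", True)
    model = MicelleFreeEnergyModel(**p)
    grid = np.asarray(
        spec.grid if spec.grid is not None else DEFAULT_MICELLE_GRID, dtype=float
    )
    rng = np.random.default_rng(spec.seed)
    dg = transfer_free_energy(model, grid)
    dg = dg + rng.normal(0.0, spec.noise, size=grid.shape) if spec.noise else dg
    n_col = list(grid)
    dg_col = list(np.atleast_1d(dg))
    if include_inf:
        n_col.append(math.inf)
        tail = model.dg_inf + (rng.normal(0.0, spec.noise) if spec.noise else 0.0)
        dg_col.append(tail)
    sigma = [spec.noise] * len(n_col)
    return pd.DataFrame({"n": n_col, "dg": dg_col, "sigma": sigma})


def eos_from_params(params: dict, thermo: ThermoState) -> EquationOfState:
    """Ground-truth EoS object from a generator parameter dict."""
    coeffs = np.asarray(params.get("coefficients", DEFAULT_EOS_COEFFS), dtype=float)
    gamma_max = float(params.get("gamma_max", max(DEFAULT_EOS_GRID)))
    return EquationOfState(
        coefficients=coeffs, thermal_energy=thermo.kt, gamma_max=gamma_max
    )


def generate_eos_points(spec: SyntheticSpec, thermo: ThermoState | None = None) -> pd.DataFrame:
    """Synthetic (Γ, Π, σ) table in nm⁻² and mN/m from the polynomial EoS.

    The Γ = 0 row is always exactly Π = 0 (the bare interface is the
    measurement reference, not a noisy sample).
    """
    thermo = thermo or ThermoState(float(spec.params.get("temperature", 300.0)))
    grid = np.asarray(
        spec.grid if spec.grid is not None else DEFAULT_EOS_GRID, dtype=float
    )
    if np.any(grid < 0):
        raise InvalidParameterError("coverage grid must be >= 0")
    eos = eos_from_params(
        {**spec.params, "gamma_max": spec.params.get("gamma_max", float(grid.max()))},
        thermo,
    )
    pi = pressure_energy_to_mn_per_m(np.asarray(eos.pressure(grid)))
    if spec.noise:
        rng = np.random.default_rng(spec.seed)
        pi = pi + rng.normal(0.0, spec.noise, size=grid.shape)
    pi = np.where(grid == 0.0, 0.0, pi)
    return pd.DataFrame({"gamma": grid, "pi": pi, "sigma": np.full_like(grid, spec.noise)})


def generate_tension_series(spec: SyntheticSpec, thermo: ThermoState | None = None) -> pd.DataFrame:
    """Synthetic surface-tension time series (t, γ) at fixed coverage, mN/m.

    Emulates the instantaneous surface tension of an interfacial MD run:
    γ(t) = γ₀ − Π(Γ) plus Gaussian fluctuations.  Reduce with
    :func:`surftherm.tableio.block_average`.
    """
    thermo = thermo or ThermoState(float(spec.params.get("temperature", 300.0)))
    gamma0 = float(spec.params.get("gamma0", DEFAULT_GAMMA0))
    coverage = float(spec.params.get("coverage", 1.0))
    n_samples = int(spec.params.get("n_samples", 500))
    eos = eos_from_params(
        {**spec.params, "gamma_max": spec.params.get("gamma_max", max(coverage, 1.0))},
        thermo,
    )
    mean_tension = gamma0 - pressure_energy_to_mn_per_m(eos.pressure(coverage))
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(
        spec.grid if spec.grid is not None else np.arange(n_samples, dtype=float)
    )
    tension = np.full(t.shape, mean_tension)
    if spec.noise:
        tension = tension + rng.normal(0.0, spec.noise, size=t.shape)
    return pd.DataFrame({"time": t, "tension": tension})


def write_xvg(path, df: pd.DataFrame, title: str = "surface tension") -> None:
    """Write a (time, value) series in the GROMACS XVG dialect."""
    cols = list(df.columns)
    with open(path, "w") as fh:
        fh.write(f"@    title \"{title}\"\n")
        fh.write("@    xaxis  label \"Time (ps)\"\n")
        fh.write("@    yaxis  label \"(mN/m)\"\n")
        for _, row in df.iterrows():
            fh.write(" ".join(f"{row[c]:.17g}" for c in cols) + "\n")
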