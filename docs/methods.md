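# Methods

## Scope and assumptions

`surftherm` converts surfactant transfer free energies — into micelles,
Δg_m(n), and onto an interface, Δg_s(Γ) — into concentration-domain
observables. The framework assumes:

- **Ideal bulk solution.** The excess chemical potential of a free
  surfactant in water is concentration-independent. The package computes the
  concentration c\* = 1/(2|B₂|) at which the second-virial correction to the
  log-activity reaches order one; for a typical nonionic surfactant
  (B₂ ≈ −0.1 nm³, c\* ≈ 8 M) this is many orders of magnitude above the CMC,
  so the assumption is safe throughout the relevant range.
- **Non-interacting micelles.** The mass-action treatment regards micelles
  as independent solutes; it breaks down only at very high concentrations.
- **Uniform monolayer.** The interface is a single 2D phase fully
  characterized by Γ — no in-plane phase coexistence or clustering. This is
  the observed behavior for C12EO6-type surfactants at oil/water interfaces,
  where effective in-plane repulsion keeps the layer homogeneous; it is
  *not* generally true at air/water interfaces.
- **Nonionic surfactants.** No electrostatic double-layer physics.

## Units

Internal units are nm, nm⁻², nm⁻³, kJ/mol, K; surface pressure is carried
as kJ/(mol·nm²) so Π_id = k_BT·Γ needs no conversion factor, and is
rendered in mN/m (×10²⁴/N_A ≈ ×1.6605) only at the reporting boundary.
Concentrations enter in mol/L and are converted to nm⁻³ on ingestion
(×N_A·10⁻²⁴); with the normalizing volume v in nm³ every occurrence of v·c
is dimensionless.

## Micellization

The double-exponential parameterization
Δg_m(n) = Δg_m(∞)[1 − A e^{−α₁(n−1)} − (1−A) e^{−α₂(n−1)}] is zero at
n = 1 by construction, bounded below by Δg_m(∞) < 0, and captures the two
empirical regimes of micelle growth: a fast decay (α₁) as the first shell
assembles and a slow approach (α₂) to the cylindrical limit.

The mass-action recursion is derived from chemical-potential equality with
ideal terms k_BT·ln(v·c): c_n = c_{n−1}·(v c₁)·exp(−Δg_m(n)/k_BT). Its
limiting-ratio condition c_n = c_{n−1} gives the critical monomer
concentration c₁^CMC = (1/v)·exp(Δg_m(∞)/k_BT), which depends only on the
asymptote and v — not on A, α₁, α₂ — and is, to excellent approximation,
the CMC itself (the micellar mass fraction at that point is only ~10⁻⁵).

Numerics: concentrations are accumulated in log space
(ln c_n = ln c₁ + (n−1)ln(v c₁) − Σ₂ⁿ Δg_k/k_BT); at the CMC the cumulative
exponents reach magnitude ~300 and a direct product would underflow. Sums
Σ n·c_n use log-sum-exp, default n_max = 10⁴, and report a geometric-tail
truncation bound. c₁ above the CMC is an error unless the caller passes
`hypothetical=True` (the diverging distribution is a useful illustration,
not a physical state); c₁ = CMC exactly is permitted — the series is
marginally divergent in principle but numerically negligible below n_max.

Fitting: bound-constrained `scipy.optimize.least_squares` on
(Δg_inf, A, α₁, α₂) with 0 ≤ A ≤ 1 and positive rates, inverse-variance
weights when uncertainties are given, and five seeded starts spanning two
decades of rate pairs to avoid the α₁/α₂ exchange degeneracy; ties are
broken by ordering α₁ ≥ α₂. An `n = inf` (cylindrical-limit) row pins the
asymptote as a hard constraint by default (`fix_asymptote=True`); passing
`fix_asymptote=False` instead treats it as an ordinary data point, since
how such a datum should be weighted is a genuinely open choice.

## Monolayer

The EoS is a polynomial with the ideal term pinned at k_BT (exact
2D-ideal-gas limit at Γ → 0); the order is 5 by default, configurable from
2 to 7. Because the ideal coefficient is fixed, the fit is *linear* in
C₂…C₅ and uses weighted `numpy.linalg.lstsq` on Π − k_BT·Γ with zero
intercept. The validity range is recorded as [0, max Γ in the data];
evaluation beyond it raises an extrapolation error rather than silently
extrapolating a high-order polynomial.

Π-integration of the Gibbs adsorption relation gives
Δg_s(Γ) = Δg_s(0) + (Π − Π_id)/Γ + ∫₀^Γ (Π − Π_id)/Γ′² dΓ′. For the
polynomial EoS this has the closed form Σ_k C_k·k/(k−1)·Γ^{k−1}, which is
the default path; an adaptive-quadrature path exists for non-polynomial
input and uses the analytic limit (Π − Π_id)/Γ′² → C₂ at the lower
endpoint, removing the spurious 0/0 without an epsilon offset. Tabulated
TI data are instead interpolated with a monotone-preserving cubic (PCHIP):
overshoot-prone interpolants can manufacture non-monotone Δg_s(Γ) and hence
spurious multiple roots in the adsorption equation. The zero-coverage
anchor Δg_s(0) must come from an independent calculation (TI); the
integration determines only increments.

The coverage at given c₁ solves Γ = δ_s·c₁·exp(−Δg_s(Γ)/k_BT) by bisection
(relative tolerance 10⁻¹²) on a bracket grown geometrically from the
Henry-limit estimate Γ_H = δ_s·c₁·e^{−Δg_s(0)/k_BT}; for nondecreasing
Δg_s the root is unique and lies in (0, Γ_H]. A scan over the bracket
detects multiple fixed points (possible only for non-monotone curves) and
reports them all in an ambiguity error instead of silently picking one.

Isotherms compose c₁ = min(c₀, CMC) with the coverage equation, so Γ(c₀)
and Π(c₀) = Π(Γ(c₀)) are nondecreasing and sit *exactly* at (Γ_CMC, Π_CMC)
above the CMC. The reduced isotherm (c₀/CMC, Π/Π_CMC) is evaluated from
the EoS alone — subtracting the adsorption equilibrium at the CMC from
itself eliminates Δg_s(0), so the reduced curve probes only in-plane
interactions; the implementation is tested to be invariant (≤10⁻¹⁰) under
±10 k_BT shifts of Δg_s(0).

## Diagnostics

- TI-vs-Π-integration comparison: per-point differences against a stated
  tolerance, with offending points flagged. Both routes are mathematically
  exact, so disagreement indicates a numerical or bookkeeping error.
- Force-field mismatch ΔΔg = k_BT·ln(CMC_sim/CMC_exp), assuming equal v in
  simulation and experiment (no volume-correction term is applied).
- Interface concentration-scale shift, implemented as
  exp[(Δg_s(oil/water) − Δg_s(air/water))/k_BT] ≈ 6×10⁻⁶ for −63 vs
  −33 kJ/mol: the factor by which adsorption onset at an alkane/water
  interface sits below that at air/water. The sign convention is fixed by
  the physically meaningful direction (stronger binding ⇒ lower onset
  concentration), i.e. the factor is < 1 when the oil/water interface binds
  more strongly.
- Oil-phase concentrations are converted via the partition coefficient,
  c₀ = c_oil/K_p.

## Synthetic data and what it does (not) show

Generators produce the tables an MD/TI study would: (n, Δg, σ) micelle
tables, (Γ, Π, σ) EoS samples, and surface-tension time series (reduced by
block averaging, default 5 blocks). Noise is additive Gaussian with a
single scale — symmetric and homoscedastic, which real TI error bars only
approximate — and each generator draws from its own
`numpy.random.default_rng(seed)`, so identical specs give bitwise-identical
tables.

Defaults are the study conditions for C12EO6 at a decane/water interface at
300 K: micelle model (Δg_m(∞), A, α₁, α₂) = (−38 kJ/mol, 0.5, 0.48, 0.026)
sampled at n ∈ {2, 4, 6, 9, 13, 19, 27, 39, 55, ∞} with σ = 2 kJ/mol;
v = 0.76 nm³ (equivalently from cylinder geometry, πR\*²·dl/dN with
R\* = 2.55 nm, dN/dl = 27 nm⁻¹); δ_s = 0.5 nm; Δg_s(0) = −63.5 kJ/mol;
γ₀ = 54.1 mN/m.

The EoS ground-truth coefficients (C₂…C₅) = (0.5, 0.8, 1.2, 2.2)
kJ/mol·nm^(2k−2) are a choice, not a measurement: the real system's fitted
coefficients are not publicly available. They were fixed once by two
physical requirements — a near-ideal dilute monolayer (small C₂, so the
Henry regime is reached cleanly) and a coverage scale such that the full
pipeline, anchored at Δg_s(0) = −63.5 kJ/mol, reaches Γ_CMC ≈ 1.5 nm⁻²
(≈0.67 nm² per molecule) at its CMC. The resulting pressure scale,
Π_CMC ≈ 50 mN/m, is a consequence of that choice. A structural point worth
recording: for this EoS family the Π-integration increment satisfies
Δg_s(Γ) − Δg_s(0) ≤ 2·(Π(Γ) − Π_id)/Γ, so no pinned-ideal polynomial can
reproduce every printed CMC-point value of the reference system at once;
passing tests therefore demonstrate internal consistency of the framework
on realistic scales, not agreement with that system's unpublished EoS.

## Problem sizes

Tests and the acceptance script run the study-scale problems directly:
size distributions to n_max = 10⁴, isotherms on 10–25 point concentration
grids, 100 random EoS instances for the quadrature cross-check, and a
50-replicate Monte-Carlo fit-bias check. The whole suite completes in a few
seconds on one core.

## Known limitations

- Above c\* the ideal-solution assumption degrades; no activity model is
  provided.
- The piecewise c₁ = min(c₀, CMC) idealizes the crossover; the real c₁(c₀)
  rounds off over a width set by the micellar fraction (~10⁻⁵ here), which
  is far below any practical resolution.
- Polynomial EoS fits are untrustworthy outside the fitted coverage range;
  the package refuses to extrapolate rather than attempting a correction.
- Ionic surfactants (long-range electrostatics, counterion effects) are out
  of scope.
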