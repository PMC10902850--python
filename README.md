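# surftherm

Thermodynamics of surfactant micellization and interfacial adsorption, built
for simulators who compute transfer free energies (e.g. by thermodynamic
integration in atomistic MD) and want to turn them into experimentally
comparable observables: the critical micelle concentration (CMC),
micelle-size distributions, and adsorption and surface-pressure isotherms at
oil/water or air/water interfaces.

Surfactants with intermediate alkyl chains (~C7–C16) exchange between bulk,
micelles, and interfaces far too slowly for brute-force MD, so the adsorption
equilibrium cannot be simulated directly. The way around is thermodynamic:
compute the excess chemical potentials of a surfactant in each environment
separately, and connect the environments by chemical-potential equality.
`surftherm` implements that connection.

## The model

Three environments, one chemical potential:

- **Free surfactants** at concentration c₁ (treated as ideal; the validity
  threshold c\* = 1/(2|B₂|) is computed from the second virial coefficient).
- **Micelles** of aggregation number n, entered with transfer free energy
  Δg_m⁽ⁿ⁾. The law of mass action gives the recursion
  c_n = c_{n−1}·(v c₁)·exp(−Δg_m⁽ⁿ⁾/k_BT), evaluated in log space.
  Δg_m(n) is parameterized by a double exponential
  Δg_m(n) = Δg_m(∞)·[1 − A e^{−α₁(n−1)} − (1−A) e^{−α₂(n−1)}],
  which is 0 at n = 1 and saturates at the infinite-cylinder value Δg_m(∞).
  The aggregate series converges only below
  **CMC = (1/v)·exp(Δg_m(∞)/k_BT)**, and above the CMC the free-monomer
  concentration stays pinned there: c₁ = min(c₀, CMC).
- **The adsorbed monolayer** at coverage Γ, with equation of state
  Π(Γ) = k_BT·Γ + C₂Γ² + … + C₅Γ⁵ (ideal term pinned) and transfer free
  energy obtained from the Gibbs adsorption relation by Π-integration:
  Δg_s(Γ) = Δg_s(0) + (Π − Π_id)/Γ + ∫₀^Γ (Π − Π_id)/Γ′² dΓ′.
  Chemical-potential equality then fixes the coverage through
  Γ = δ_s·c₁·exp(−Δg_s(Γ)/k_BT), solved by bracketed bisection.

Composing these pieces yields Γ(c₀) and Π(c₀) — both plateau exactly above
the CMC — plus diagnostics: TI-vs-Π-integration consistency reports, the
force-field free-energy mismatch k_BT·ln(CMC_sim/CMC_exp), and the
air/water ↔ alkane/water concentration-scale shift.

## Worked example

Generate a noiseless synthetic transfer-free-energy table (study-condition
defaults), refit it, and compute the CMC; then fit the equation of state and
build the isotherms:

```console
$ surftherm synth micelle --seed 0 --out dg.dat
$ surftherm fit-micelle dg.dat
{
  "dg_inf": -38.0,
  "amp_a": 0.5000000000000001,
  "alpha1": 0.47999999999999976,
  "alpha2": 0.025999999999999992,
  "rms_residual_kJ_per_mol": 1.1842378929335002e-15
}
$ surftherm cmc --dg-inf -38 --volume 0.76 --temp 300
5.2866061e-07
$ surftherm synth eos --seed 0 --out eos.dat
$ surftherm fit-eos eos.dat --out eos.json
wrote eos.json (C2..C5 = 0.5, 0.8, 1.2, 2.2)
$ surftherm isotherm eos.json --dgs0 -63.5 --dg-inf -38 --volume 0.76 \
      --delta-s 0.5 --c-min 1e-9 --c-max 5e-6 --n-points 8 --out iso.dat
wrote iso.dat (Gamma_CMC = 1.499 nm^-2, Pi_CMC = 50.2 mN/m)
$ surftherm validate --cmc-sim 5.29e-7 --cmc-exp 8e-5 --dgs-aw -33 --dgs-ow -63
force-field mismatch: -12.52 kJ/mol
interface concentration shift: 5.979e-06
```

Reading the numbers: the fitted model reproduces the generator exactly
(residuals at machine precision); a −38 kJ/mol micelle-transfer asymptote
with v = 0.76 nm³ at 300 K puts the CMC at 5.3×10⁻⁷ M; the adsorption
pipeline reaches a coverage of 1.5 nm⁻² (≈0.67 nm² per molecule) at the
CMC and stays there above it; a simulated CMC two orders of magnitude
below an experimental one corresponds to ~12.5 kJ/mol of excess binding
affinity in the model; and moving the same surfactant from an air/water to
an alkane/water interface shifts the adsorption concentration scale by a
factor ~6×10⁻⁶.

Every subcommand is a thin wrapper over `surftherm`'s library API
(`surftherm.cmc`, `surftherm.size_distribution`, `surftherm.fit_eos`,
`surftherm.pi_integrate`, `surftherm.adsorption_isotherm`, ...), which is
the recommended interface for scripting.

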