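# Methods

## Scope and model structure

The package models a VFA-fed methanogenic chemostat as a four-guild trophic
cascade on a chemical-oxygen-demand (COD) basis: butyrate oxidizers
(products 0.8 acetate / 0.2 H₂ of non-biomass COD), propionate oxidizers
(0.57 / 0.43), acetoclastic methanogens and hydrogenotrophic methanogens
(both → CH₄). The cascade is acyclic, one guild per substrate; decayed
biomass leaves as soluble inert COD rather than being recycled through
disintegration/hydrolysis — in this feed regime that recycling is a
sub-percent effect on population biomass, and excluding it keeps the chain
algebraically solvable. COD is conserved exactly: at steady state
D·S_in = D·(S_residual + X + inerts) + CH₄-COD, checked to 10⁻⁶ relative in
every solution.

All internal state is kept in canonical units (gCOD L⁻¹, days, kJ, Cmol);
conversions happen only at I/O boundaries. Biomass is CH₁.₈O₀.₅N₀.₂
throughout: degree of reduction 4.2, hence 33.6 gCOD/Cmol, 24.6 g VS/Cmol
and 1.366 gCOD per gVS. We deliberately do **not** use the common 1.42
gCOD/gVS factor (which belongs to C₅H₇O₂N); a single composition must serve
every conversion or the maintenance equivalences below stop being exact.

## The three maintenance representations

**Herbert (reduced ADM1).** μ(S) = μ_max·S/(S+K_S) − k_dec. At steady state
a surviving guild sits at S* = K_S(D+k_dec)/(μ_max−D−k_dec) and its apparent
yield is Y_app = Y/(k_dec/D+1). Defaults are the ADM1 parameter set:
Y = 0.05/0.04/0.06/0.06 gCOD/gCOD (ac/pro/c4/h2), k_dec = 0.02 d⁻¹,
μ_max = k_m·Y with k_m = 8/13/20/35 d⁻¹ and K_S = 0.15/0.10/0.20/7·10⁻⁶
gCOD L⁻¹. pH inhibition, acid–base speciation and gas-phase dynamics of the
full ADM1 are omitted: the target regime runs at pH ≈ 7.45 with >99%
substrate conversion, where those terms are ≈ 1. Washout is a reported
state, not an exception, so a cascade with one dead guild still solves (its
substrate passes through to the effluent).

**Pirt / thermodynamic black box.** Y_app = Y_max/(1+m·Y_max/D). The
maintenance coefficient is a single energy figure m_g (kJ per Cmol biomass
per hour; 9.8 is the literature value for anaerobes at 37 °C), charged to
each guild's own catabolic substrate via
m = (m_g/|ΔG_cat|)·24·COD_mol/33.6 gCOD_S gCOD_X⁻¹ d⁻¹. Y_max comes from
the Gibbs-energy dissipation correlation
ΔG_dis = 200 + 18(6−C)^1.8 + exp[((3.8−γ_S)²)^0.16·(3.6+0.4C)] kJ/Cmol_X,
with Y_max = |ΔG_cat′|/ΔG_dis capped at 1 Cmol/Cmol (optionally
|ΔG′|/(ΔG_dis+|ΔG′|) to charge the assimilated carbon; both are exposed,
the uncorrected form is the default). For H₂, a carbon-free electron donor,
the correlation is evaluated for the CO₂ carbon source (C = 1, γ = 0, ΔG_dis
≈ 986 kJ/Cmol — the classic ≈ 1000 kJ/Cmol autotrophic figure) and the yield
is per mol H₂. Residual substrate defaults to zero (complete conversion) and
can be overridden with Herbert S* values.

The shipped catabolic energies are physiological-condition values (standard
conditions would make syntrophic oxidation endergonic and the constructor
refuses them): acetate −31 kJ/mol — the value implied by the equivalence of
120 µmol acetate gDW⁻¹ h⁻¹ with 0.09 kJ Cmol⁻¹ h⁻¹ — propionate −15,
butyrate −17.5, H₂ −8 kJ/mol H₂. They are configuration, not constants: the
compound table is a TSV input.

**dFBA.** Each guild is a 5–6 reaction network (uptake, catabolic ATP
generation, product export, biomass synthesis with growth-associated ATP
cost g, NGAM) with the published chemostat parameters: S_in equivalents
29.76 / 0.6227 / 2.445 / 9.251 g L⁻¹, v_max 9.78 / 2.5885 / 3.538 / 10.53
g gDW⁻¹ d⁻¹, K_S 0.2952 / 26.208·10⁻⁶ / 0.03185 / 5.022·10⁻³ g L⁻¹ and NGAM
2 / 2 / 0.14 / 0.14 mmol ATP gDW⁻¹ h⁻¹ for the acetoclastic /
hydrogenotrophic / propionate / butyrate guilds. Genome-scale
reconstructions are replaced by these calibrated toys: the chemostat-level
behaviour of interest (growth versus NGAM competition for catabolic energy)
is a function of only (Y_max, m), which the toys reproduce exactly, and an
import hook accepts externally supplied networks in the TSV format.

Calibration knobs the source models do not print, fixed once here: ATP per
mol substrate catabolized a = 0.5 (acetate), 0.125 (per mol H₂, i.e. 0.5 per
CH₄), 0.33 (propionate), 0.30 (butyrate); maximal-yield targets 0.065, 0.08,
0.06 gCOD/gCOD, and 0.0162 for butyrate. The growth ATP cost is then
g = a(1/Y_mol − σ) with σ the biomass carbon drawn from the substrate
(1/24.6 Cmol gDW⁻¹ spread over the chain length; zero for H₂, whose carbon
comes from CO₂). The butyrate network additionally enforces acetate-carbon
export = 97.9% of carbon influx through a pseudo-metabolite constraint row;
a pure butyrate → 2 acetate stoichiometry cannot satisfy that equality at
zero growth, so the network carries an oxidative side route (carbon leaving
as CO₂). The 97.9% equality caps the butyrate biomass at 2.1% of carbon
(≈ 0.023 g/g), and the yield target is set below that cap so ATP, not
carbon, limits growth — keeping the network exactly Pirt-reducible like the
other three.

The LP maximizes the biomass flux subject to S·v = 0, bounds, the NGAM lower
bound and the Monod uptake cap; degenerate optima are resolved by a
secondary minimization of total absolute flux. When ATP supply cannot meet
NGAM the state is "maintenance-infeasible": growth is zero, uptake runs at
the cap, and the population washes out at rate D (the starvation regime is
not otherwise specified by the approach; a death rate would be an
alternative). Structural infeasibility (bounds inconsistent even without
NGAM) is a distinct error.

## Numerics

*Steady-state cascade*: compounds are solved in topological order; exact
arithmetic, no iteration. *Dynamic chain*: LSODA with rtol 10⁻⁸, methane
stripped to gas instantaneously. *dFBA stepping*: explicit Euler with
initial step 10⁻⁴ d. A step that would drive a concentration negative is
rejected and the step halved; the step also never exceeds the explicit-Euler
stability limit 0.9/(D + v′(S)·X) of the substrate balance — without that
cap the hydrogenotroph (K_S = 26 µg/L) limit-cycles — and regrows by 1.25×
(bounded by dt_max = 1000·dt₀) while the per-step relative change stays
below 2%. Because the LP value functions μ(cap) and v_S(cap) are piecewise
linear in the single varying bound, they are tabulated once by recursive
probing of the LP solver and interpolated inside the loop; the final state
is always re-verified by a direct LP solve. Steady state is declared when
the relative rate of change stays below 10⁻⁷ d⁻¹ for ten consecutive steps,
which pins μ = D to ≈ 10⁻⁶ relative; refining a fixed step tenfold moves the
steady biomass by < 0.1%. *Fitting*: bounded Brent search (xatol 10⁻¹⁰) on
the sum of squared relative deviations of total biomass; absolute residuals
and SEM weighting are options. Endpoints of the bound interval are checked
explicitly because the bounded search never evaluates them. *Competition*:
the S* crossover is bracketed on a grid and polished by Brent's method.

## Synthetic data

The generator reproduces the statistical shape of the benchmark experiment,
not its biology: model steady state per dilution rate plus i.i.d. Gaussian
observation noise, truncated at zero (truncations are counted; at
paper-scale noise, sd 0.03 gVS/L on ≈ 0.9 gVS/L, none occur), means over n
replicates reported with SEM = sd/√n. The fixture uses n = 1 and sd = 0.03
so the reported SEM matches the published ±0.03 directly; the replicate
count behind the published SEMs is not stated, so n is configuration.
Time series come from the dynamic chain with optional feed-scaling windows
(emulating the feed-pump failure of the real run). What passing tests show:
the estimators recover known parameters from data with this noise structure.
What they cannot show: robustness to the correlated, non-Gaussian drift of
real reactor time series, or to VS measurements contaminated by residual
substrate.

## Cross-model identities used as test oracles

* Y_app(Herbert; k_dec = m·Y_max) ≡ Y_app(Pirt) exactly, for all (Y, m, D).
* Every linear toy network reduces to (Y_max = μ/v at NGAM 0,
  m = uptake at μ = 0), and its Euler steady state must match the Pirt
  closed form X = Y_app(S_in − S*) within 0.5%.
* The algebraic cascade must agree with the long-time ODE limit within 0.1%
  on randomized parameter sets.
* LP solutions equal brute-force vertex enumeration on the ≤ 6-reaction
  networks.

## Behaviour under the benchmark conditions

With defaults the three models bracket the observations: the reduced chain
over-predicts (≈ +114%/+82% at D = 0.18/0.07, predicted high/low ratio
≈ 18% above the experimental one), the TBA with m_g = 9.8 collapses to
≈ 0.28/0.13 gVS/L, and the toy dFBA community lands between
(≈ 0.80/0.59 gDW/L) — the printed NGAM of 2 mmol ATP gDW⁻¹ h⁻¹ alone caps
acetoclastic biomass near D·S_in/m ≈ 0.93 g/L at D = 0.18, and the 97.9%
carbon policy caps the butyrate oxidizer, so a toy calibration cannot
over-predict the way genome-scale simulations reportedly do. Setting
m_g = 0 with dissipation Y_max lands within ±15% of the observations, and
the best-fit m_g on the fixture is ≈ 0.24 kJ Cmol⁻¹ h⁻¹ — the package's
restatement of the central claim that maintenance at these dilution rates is
two orders of magnitude below the 9.8 kJ Cmol⁻¹ h⁻¹ literature value.

Problem sizes: all steady-state computations are closed-form; the dFBA
Euler runs use ≈ 10³–3·10⁵ accepted steps per guild and dilution rate, and
the noisy-recovery study uses 100 seeded replicates of a two-point fit.

## Known limitations

* One guild per substrate in the cascade; co-cultures on a shared substrate
  are handled by the R*-competition analysis, not the chain solver.
* The CH₄/COD factor is exposed (default 0.35 L/gCOD at 0 °C, 1 atm, with an
  optional T/273.15 correction) rather than inferred: published "theoretical
  maximum" rates at the two dilution rates imply two different factors.
* No temperature/ionic-strength/pH correction of Gibbs energies; the ΔG_cat
  table is the user's statement of physiological conditions.
* Guild dFBA populations are simulated independently (each with feed
  equivalents of its substrate), so dynamic cross-feeding and H₂ inhibition
  feedbacks are out of scope.
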