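# chemaint

Maintenance-aware chemostat models for anaerobic digestion of volatile fatty
acids (VFAs), built for reactor modelers and microbial ecologists who want to
ask one question quantitatively: **how strongly does the dilution rate shape
microbial biomass through cellular maintenance?**

In a continuous stirred tank reactor (CSTR) without biomass retention the
steady-state specific growth rate equals the dilution rate, μ = D. Whether a
digester run at D = 0.18 d⁻¹ should hold more biomass than one at
D = 0.07 d⁻¹ depends entirely on how maintenance is represented. This package
implements the three standard representations for the same four-guild VFA
degradation cascade (butyrate and propionate oxidizers feeding acetoclastic
and hydrogenotrophic methanogens):

* **Herbert / reduced ADM1** — maintenance as a biomass decay rate `k_dec`:
  μ(S) = μ_max·S/(S+K_S) − k_dec, with the steady-state apparent yield

      Y_app = Y / (k_dec/D + 1)

* **Pirt / thermodynamic black box (TBA)** — maintenance as a substrate
  (energy) consumption rate m, q(S) = μ/Y_max + m, giving

      Y_app = Y_max / (1 + m·Y_max/D),     X = Y_app·(S_in + Ṡᵢ/D − S)

  with m derived from a single Gibbs-energy coefficient (kJ per Cmol biomass
  per hour) via each guild's catabolic ΔG, and Y_max from the Gibbs-energy
  dissipation correlation.

* **Dynamic flux balance analysis (dFBA)** — maintenance as a non-growth
  associated ATP demand (NGAM) inside small calibrated metabolic networks,
  solved by LP with a Monod uptake cap at every Euler step of
  dX/dt = (μ−D)X, dS/dt = (S_in−S)D − v_S·X.

The two forms are algebraically linked — Eq. (Herbert) equals Eq. (Pirt)
exactly under `k_dec = m·Y_max` — and the linear toy networks reduce exactly
to Pirt parameters, which the test suite exploits as cross-model oracles.
A unit-conversion layer (COD ↔ Cmol ↔ VS ↔ ATP ↔ kJ, biomass CH₁.₈O₀.₅N₀.₂,
24.6 g VS/Cmol, 33.6 gCOD/Cmol) connects the three parameterizations, a
single-parameter fitting module calibrates any of them against steady-state
biomass observations, and a synthetic-data generator emulates the benchmark
experiment: two 6 L CSTRs at 37 °C, D = 0.18/0.07 d⁻¹, fed 37.2 gCOD/L of
45/45/10 acetic/butyric/propionic acid, observed biomass
0.92 ± 0.03 / 0.94 ± 0.03 gVS/L.

## Worked example

```console
$ chemaint simulate-herbert --d 0.18 --out run/h18
total biomass 1.967 gVS/L, methane 12.84 L/d -> run/h18
$ chemaint simulate-herbert --d 0.07 --out run/h07
total biomass 1.706 gVS/L, methane 5.02 L/d -> run/h07
$ chemaint simulate-tba --d 0.18 --m-g 9.8 --out run/tba
total biomass 0.279 gVS/L -> run/tba
$ chemaint fit --strategy y_scale --out run/fit
y_scale = 0.497571 (objective 1.323e-02) -> run/fit
```

Reading these numbers: with ADM1 default parameters the decay-based model
predicts 1.97 and 1.71 gVS/L — roughly double the observed 0.92/0.94 — and a
higher biomass at the higher dilution rate, which the experiment did not
show. The energy-based model with the literature maintenance coefficient of
9.8 kJ Cmol⁻¹ h⁻¹ collapses to 0.28 gVS/L, far *below* the observations: at
μ = D = 0.18 d⁻¹ almost all substrate would be burned for maintenance.
Scaling all ADM1 yields by the fitted factor ≈ 0.50 reconciles the
decay-based model with both reactors; fitting the TBA maintenance instead
drives it to a small value (≈ 0.2 kJ Cmol⁻¹ h⁻¹, two orders of magnitude
below the literature default). Each command leaves a `steady_state.tsv` (one
row per guild, gCOD/L and gVS/L) and a `run.yaml` provenance record.

The same machinery is available as a library:

```python
from chemaint import defaults, FeedSpec, ReactorConfig, steady_state_chain

feed = FeedSpec(37.2, {"acetate": 0.45, "butyrate": 0.45, "propionate": 0.10})
state = steady_state_chain(defaults.adm1_guilds(), feed, ReactorConfig(d=0.18))
print(state.total_biomass_gvs)   # 1.9667...
print(state.methane_rate)        # 12.84 L/d of the 14.2 L/d ceiling
```

## Layout

```
src/chemaint/
  units.py     COD/Cmol/VS/ATP/energy bookkeeping, dissipation yields
  herbert.py   reduced-ADM1 guild cascade: steady state, ODE, competition
  pirt.py      TBA yields, community biomass, Figure-style yield curves
  dfba.py      toy-network LP, Euler chemostat loop, Pirt reduction
  fitting.py   one-parameter calibration strategies + deviation reports
  synth.py     synthetic observations/time series, experiment fixture
  io.py        TSV/YAML readers and writers
  cli.py       `chemaint` command-line tool
docs/methods.md   model assumptions, parameter choices, limitations
```
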