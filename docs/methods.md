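# Methods

`nobsim` simulates competition among a small number of soil
nitrite-oxidizing bacteria (NOB) functional types and uses the resulting
steady states to (i) reconstruct each type's ecological niche across
nitrite, organic-carbon and oxygen gradients, (ii) predict community
composition and soil nitrite-oxidation rates under factorial
global-change treatments, and (iii) quantify how many functional types a
model needs to capture those responses.

## Functional types

The reference configuration resolves three types:

* **Nitrospira** — K strategist for NO2-: low half-saturation constants
  (K_m(NO2-) = 15 µM, K_m(O2) = 10 µM), slow growth
  (µ_max = 7×10⁻⁶ s⁻¹), low specific activity.
* **Chemolithotrophic *Nitrobacter*** — r strategist: high
  half-saturations, fast growth (µ_max = 1.6×10⁻⁵ s⁻¹), specific
  nitrite-oxidation activity more than an order of magnitude above
  *Nitrospira*.
* **Mixotrophic *Nitrobacter*** (*N. hamburgensis*-like) — oxidizes
  organic carbon (OC) in addition to NO2- and carries two *flexible*
  traits evaluated as piecewise-linear functions of the environment
  (constant beyond the outer anchors): µ_max rises from 6.9×10⁻⁶ s⁻¹
  without OC to 27.8×10⁻⁶ s⁻¹ at 150 ppm (5×10⁻³ M) CH2O, and K_m(O2)
  rises from 25.1 µM at 3.2 ppm O2 (1×10⁻⁴ M) to 125 µM at high O2
  supply (≥ 200 ppm). These four anchor values are published
  ecophysiological measurements and are treated as fixed.

Ablation configurations: 1 type (trait means of all three), 2 types
(*Nitrospira* plus the mean of the two *Nitrobacter*, which inherits a
halved — "weakly flexible" — OC response through anchor-wise averaging),
and 4 types (the reference set plus a near-neutral mixotrophic
*Nitrospira*: base kinetics with a weak µ_max response, ≤1.2× at high
OC, and modest OC oxidation).

## Dynamics

Per type *i*, with biomass B_i (M biomass-C) and internal Droop quotas
q_C, q_N (mol per mol biomass-C):

* Oxidation follows dual Monod kinetics in substrate and O2,
  V = V_max · [S]/(K_m+[S]) · [O2]/(K_m(O2)+[O2]) · B; mixotrophs sum
  NO2- and OC oxidation.
* Carbon fixation is Michaelis–Menten in available C with an
  energy-limited maximum: growth yield × total oxidation rate.
  Chemolithotrophs assimilate dissolved CO2 (fixed, non-limiting
  1×10⁻⁵ M by default); mixotrophs additionally draw on OC.
* Nitrogen acquisition is a fixed fraction f_N of oxidized NO2--N
  (default 0.003, the stoichiometric requirement implied by the default
  yields and a biomass C:N of ≈ 6.7). NO2- is therefore both energy
  source and sole N source; this single coupling is what starves
  mixotrophs at low NO2- regardless of how much OC is available.
* Growth: dB/dt = µ_max(OC) · min_e(1 − q_min,e/q_e) · B − D_eff · B;
  quotas follow dq/dt = uptake − µ·q. Minimum quotas: q_min,C = 1,
  q_min,N = 0.15.

### Boundary modes

Holding concentrations truly fixed admits no finite nonzero steady
state (per-capita rates carry no biomass feedback), so the simulator
makes the closure explicit:

* **clamped** (default; niche and scenario runs): concentrations fixed;
  mortality is density-dependent, D_eff = D(1 + B_tot/B_cap), a
  crowding closure. The steady state is finite, composition depends on
  the ambient concentrations (a non-equilibrium, r-vs-K outcome), and
  the survivor satisfies growth = realized mortality. It also admits a
  closed form used as an independent cross-check: with constant
  per-capita uptakes u_e the quota system reduces to
  µ_ss = µ_max/(1 + µ_max·max_e(q_min,e/u_e)); the type with the
  highest µ_ss survives at B_tot = B_cap(µ_ss/D − 1).
* **chemostat**: substrate pools relax toward ambient values at a
  supply rate (default 10⁻⁵ s⁻¹) while being consumed; mortality is
  constant. Equilibrium competition then follows resource-ratio (R*)
  theory — the type with the lowest break-even concentration wins —
  and is tested against the analytic Monod break-even
  S* = D·K_m/(µ_max−D).
* **batch**: closed pools plus a cumulative ledger (NO2- oxidized, N
  assimilated, N lost through mortality) for stoichiometric
  conservation tests.

Defaults: stiff-capable LSODA, rtol 10⁻⁸, biomass atol 10⁻¹⁴ M; equal
seeding 10⁻⁶ M biomass-C per type; extinction below 10⁻¹² M;
steady-state residual max|dB/dt|/B < 10⁻¹⁰ s⁻¹ within a 10-simulated-
year cap. Cells whose dominance contest is near-tied (growth-rate gap
≲ 5×10⁻⁸ s⁻¹) exclude slower than the horizon and are reported with
`converged=False` rather than silently accepted; on the default niche
grid this affects ~1% of cells, all on niche boundaries.

## Trait calibration

Beyond the four published anchors, absolute trait values (V_max values,
yields, the chemolithotroph's O2 half-saturation, f_N, B_cap) are
calibration knobs. They were set by analyzing the closed-form
steady-state growth rate against the qualitative structure the model
must reproduce — *Nitrospira* dominant at low NO2-/low O2 and in the
bulk compartment, chemolithotrophic *Nitrobacter* at high NO2-/O2,
mixotrophs rising with OC at high NO2- but excluded at low NO2-, and
the mixotroph peak under the CO2NW treatment — and then refining on a
coarse grid to maximize the smallest dominance margin (~20%). Two
choices deserve note:

* The chemolithotroph's K_m(O2) (1.8×10⁻² M) is scaled to the model's
  simulated aeration axis (10⁻⁴–10⁻² M, an index of soil O2 status
  reaching well above air-equilibrated solubility) rather than to
  dissolved-O2 culture measurements; what is preserved is the ordering
  *Nitrospira* ≪ mixotroph < chemolithotroph and the resulting O2-axis
  niche separation. On a culture-scale K_m (tens of µM) O2 would be
  non-limiting over the entire grid and no O2 niche structure could
  emerge.
* B_cap = 1.5×10⁻⁷ M biomass-C sets the absolute biomass scale so that
  predicted soil rates fall in the 10–30 ng-N g⁻¹ h⁻¹ range, the lower
  end of field potential-nitrite-oxidation measurements.

## Soil representation and drivers

Two homogeneous compartments: a resource-rich hotspot (5.5% of soil
mass) whose NO2-, OC and O2 track the measured drivers, and a bulk
compartment prescribed at low O2 (5×10⁻⁴ M), low NO2- (10⁻⁵ M) and
zero OC. All types are seeded in both; in practice only *Nitrospira*
persists in the bulk, which is why it dominates every simulated
community numerically while *Nitrobacter* drives the rate responses.

Empirical driver relations: NO2- = 2×10⁻¹⁶·(ammonification)^5.35;
OC = 10·respiration − 15.5; O2 = −0.019·ln(respiration) + 0.0137.
The OC and O2 relations are dimensionally fragile at realistic driver
magnitudes, so outputs are clamped to the simulated gradient ranges
(OC ∈ [0, 5×10⁻³] M; O2 ∈ [10⁻⁴, 10⁻²] M); an alternative log₁₀
reading of the OC relation is available as a configuration switch.
Soil-solution fluxes convert to soil rates via the water content
(0.21 L per kg dry soil) and the compartment mass fractions.

## Synthetic field campaigns

The generator emulates the structure of the field study: a 2×2×2
factorial (CO2 × N × W) with 6 replicate blocks (48 units). Treatment
driver means follow a multiplicative model around a baseline of
100 ng-N g⁻¹ h⁻¹ ammonification and 1.3 mg-C g⁻¹ h⁻¹ respiration,
with multipliers N ×1.8 on ammonification, W ×0.9 on ammonification
and ×1.15 on respiration, CO2 ×1.3 on respiration. These are
illustrative (per-treatment measurements are not available in a usable
form); the baseline respiration is placed just below the OC relation's
zero-crossing so that non-CO2 treatments map to OC ≈ 0 and CO2
treatments to the OC clamp — reproducing the observed low-OC
(CTRL/W/NW) vs high-OC (CO2 ×) contrast. Observations are the forward
model corrupted by mean-one lognormal noise (PNO, qPCR-like
abundances) and 30-clone multinomial libraries over the three *nxrA*
clusters (cluster A ↦ mixotrophic, B ↦ chemolithotrophic *Nitrobacter*,
C has no model counterpart). Truth is stored alongside, enabling exact
recovery checks at zero noise.

What the synthetic data do *not* emulate: split-plot error structure
(block and whole-plot variance components), spatial covariance,
measurement detection limits, and any mechanism the forward model
lacks — so passing recovery tests demonstrates pipeline correctness,
not field realism.

## Known limitations

* The clamped-mode crowding closure is a modeling choice, not a
  measured process; absolute biomasses and rates inherit its scale.
* Within one compartment the steady state is winner-take-all except at
  ties; observed continuous composition gradients arise only through
  compartment aggregation.
* In the 2-type ablation the averaged *Nitrobacter* grows more slowly
  at CO2NW than the mixotroph it replaces, so its predicted rate there
  is lower, not higher, than the reference run; the ablation's
  model-selection signal here is the low-resource rate collapse of the
  1-type run and the near-equivalence of the 4-type run.
* No NH4+/NO3- pool dynamics, no ammonia-oxidizer coupling, no
  temperature/pH dependence, no explicit spatial gradients.
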