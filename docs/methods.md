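# Model and methods

## Scope

`saladm` simulates the anaerobic digestion of a dried, salt-accumulating
fodder-grass biomass in a completely mixed mesophilic reactor under high
salinity, as a COD-based Gujer-matrix ODE system. The network extends the
ADM1 backbone in two ways: an oxalate release/uptake pathway (halophytes
store oxalate salts in their vacuoles) and eight sulfate-reducing guilds
(SRB) that compete with the methanogenic food web for fermentation
products when the salt system supplies sulfate. pH/ion speciation,
gas–liquid transfer resistance, temperature correction and the inorganic
C/N balances of full ADM1 are out of scope.

## State variables and stoichiometry

34 components: 13 soluble (monosaccharides, amino acids, LCFA, valerate,
butyrate, propionate, acetate, oxalate, dissolved hydrogen, methane,
sulfide, sulfate, soluble inerts) and 21 particulate (composite feed,
carbohydrate/protein/lipid polymers, particulate inerts, and 16 active
biomass guilds). All organics are carried in kgCOD·m⁻³ (numerically
g·L⁻¹); sulfide and sulfate are molar (kmol·m⁻³), interconverted at
64 kgCOD per kmol of H₂S (the electron equivalence of SO₄²⁻ → S²⁻).

37 processes: disintegration of the composite; three hydrolyses; nine
Monod uptakes along the methanogenic chain (oxalate, sugar, amino acids,
LCFA, valerate, butyrate, propionate, acetate, hydrogen); eight SRB
uptakes that mirror the methanogenic product splits with the hydrogen
share redirected to sulfide, mole-for-mole against sulfate; sixteen
first-order biomass decays returning dead cells to the composite pool.
Every process row balances to zero COD (sulfide counted at 64, sulfate at
0) within 1e-8 by construction, and assembly validates this.

Feed fractionation (reconciled so the split closes exactly): 60%
carbohydrate, 10.8% protein, 0.1% lipid, 1.1% oxalate, 27% particulate
inert, 1% soluble inert — the 1% soluble-inert carve-out is taken from
the carbohydrate pool. Sugar ferments to 0.67 acetate + 0.33 hydrogen
(acetate-type fermentation); amino acids to 0.26/0.27/0.07/0.33/0.07
valerate/butyrate/propionate/acetate/hydrogen; higher acids follow the
standard ADM1 splits (valerate → 0.54 propionate + 0.31 acetate +
0.15 H₂, butyrate → 0.8/0.2, propionate → 0.57/0.43, LCFA → 0.7/0.3).
The lipid hydrolysis split (f_fa,li = 0.95) is the ADM1 default, as no
value is tabulated.

## Rate laws

* First order, ρ = k·X, for disintegration (k_dis = 1.2 d⁻¹ under both
  salt systems) and hydrolysis (10 d⁻¹ each).
* Monod, ρ = k_m·S/(K_S+S)·X_B, for all uptakes; rates are expressed in
  COD of the electron donor. Valerate and butyrate share one degrader
  population (X_c4) with separate uptake kinetics.
* Propionate threshold inhibition I = K_Iⁿ/(K_Iⁿ + S_proⁿ) multiplies the
  propionate (K_I = 0.8 kgCOD·m⁻³, n = 5), acetate (K_I = 0.5, n = 1) and
  hydrogen (K_I = 0.5, n = 1) uptakes. The sharpened exponent n = 5 is
  tabulated within the propionate-degrader parameter block and is bound to
  that process; applying it to all three (the other defensible reading)
  drives the acetoclastic and hydrogenotrophic populations extinct at
  every reported operating point, which contradicts the observed reactors
  (see "Reproducibility limits").
* Decay, ρ = b·X_B, b = 0.06 d⁻¹ for every guild with a tabulated decay
  rate. No decay rate is tabulated for the acetate and hydrogen
  methanogens; they are treated as decay-free. This is the only reading
  under which hydrogenotrophic methanogenesis is viable at SRT 40 d under
  the calibrated k_m,h2 = 1.5 d⁻¹ and Y_h2 = 0.04 (Y·k_m = 0.06 d⁻¹
  barely exceeds washout 0.025 d⁻¹; any added decay extinguishes the
  guild).
* SRB uptakes additionally carry a sulfate saturation factor
  SO₄/(K_SO4 + SO₄), K_SO4 = 1e-4 kmol·m⁻³. The source rate expressions
  have no sulfate dependence, which would let reduction continue at zero
  sulfate; the factor caps reduction at the supply and is two orders of
  magnitude below operating sulfate levels, so it is inactive whenever
  sulfate is present.

Parameter presets: `NaCl` (saline calibration, SRB present but dormant,
k_m = 0), `Na2SO4_NaHCO3` (same chain kinetics except k_m,pro = 2 d⁻¹,
SRB kinetics populated: k_m = 2 d⁻¹ for most donors, 1 for LCFA, 8 for
hydrogen; K_S = 0.1 gCOD·m⁻³; b = 0.06 d⁻¹; yields mirroring the
methanogenic counterparts), and `default` (non-saline reference values).
Oxalate degrader kinetics are not tabulated; defaults mirror the sugar
degrader (k_m = 4 d⁻¹, K_S = 0.010 kgCOD·m⁻³, b = 0.06 d⁻¹, Y = 0.04).
Tabulated gCOD·m⁻³ values are converted to kgCOD·m⁻³ on load.

## Reactor model

A CSTR of 4 L working volume. The wasting procedure (daily withdrawal of
mixed liquor sized to SRT 40 d, centrifugation, supernatant discarded)
couples the hydraulic and solids residence times, so one retention time
1/SRT applies to every component. Feed enters entirely as composite
particulate COD at the scheduled OLR, plus sulfate at
OLR × (0.245 kmol/m³ ÷ 158 kgCOD/m³) in the sulfate system (34.84 mg
Na₂SO₄ per g of feed mixture at ≈1 kg/L). Produced methane and sulfide
are stripped instantly to cumulative gas ledgers; dissolved hydrogen
stays in the liquid and is consumed biologically. Cumulative ledgers
(methane, sulfide, COD fed, COD wasted, sulfate washed out, SRB
electron-donor flux) are co-integrated, making the COD closure audit

    fed = Δinventory + wasted + methane + 64·sulfide

exact to solver accuracy (measured residuals ~1e-13 of fed COD; the
acceptance threshold is 0.5%).

Integration: SciPy BDF with rtol 1e-6 and atol 1e-12 (the hydrogen
half-saturation is 7e-9 kgCOD·m⁻³, so the absolute tolerance must sit
below that scale), restarted at every OLR step. Inside the integrator,
negative excursions are clamped to zero during rate evaluation only
(never written back); the public rate API rejects states below −1e-8.
Default initial condition: 0.1 kgCOD·m⁻³ in each of the 16 guilds,
everything else zero, followed by a 200-day warm-up at the first
segment's OLR standing in for the reactors' long preliminary incubation.

Steady state is declared when max|dC/dt|/(C+1e-9) < 1e-6 d⁻¹ after at
least 20×SRT, with two refinements needed because several guilds sit
within ~1e-3 d⁻¹ of their washout point: (i) a monotonically declining
population below 1e-6 kgCOD·m⁻³ counts as settled; (ii) a guild whose
relative decline rate stays constant chunk-over-chunk (pure exponential
washout, as opposed to the shrinking rate of an equilibrium approach) is
jumped to its limit, zero, once the run has lasted 3×20×SRT. Without
these, formal convergence of an extinction tail can take 10⁴–10⁵ days.

## Operating schedules

Only the endpoints of the OLR staircases are reported; interior step
boundaries are package choices. NaCl: 0.58/0.8/1.0/1.2/1.5 g-COD·L⁻¹·d⁻¹
stepping up to day 289, feeding pause 289–320, 0.8 to day 330, then 0.75
to day 480. Sulfate system: 0.2/0.3/0.4/0.6/0.8 over 300 days with
time-average 0.39 (matching the reported overall OLR), at 0.8 from day
270.

## Capacity sweep

The sweep asks the largest sludge-specific loading (kg-COD per kg-MLSS
per day) at which steady methane conversion stays within one percentage
point of its low-load plateau. MLSS is identified with VSS and converted
from particulate COD at 1.19 gCOD/gVSS. For a target MLSS (default
10 g/L, the favourable low end of the studied 10–40 g/L range) and a
given loading, OLR = loading × MLSS × 1.19 and the SRT is root-solved
(bisection on log SRT, bracketing probes at a relaxed steady tolerance of
1e-4, the reported point re-solved at 1e-6) so the steady-state
particulate COD matches the target.

## Synthetic observations and calibration

`generate_observations` samples five channels (MPR, acetate, propionate,
soluble COD, particulate COD) every 5 days — the apparent cadence of the
measured series — and adds independent, seeded Gaussian noise per channel
(clipped at zero). Soluble COD excludes dissolved hydrogen and gases, as
a TOC-based measurement would. `fit_parameters` minimises the
1/sd²-weighted squared error with SciPy's trust-region-reflective least
squares, multi-started from the geometric mean of the bounds plus seeded
log-uniform jitters; parameters with near-zero Jacobian columns are
flagged as uninformative (structural non-identifiability, e.g. the
oxalate uptake rate with no oxalate in the feed). The synthetic data
share the model's structure exactly, so passing recovery tests
demonstrates estimator correctness and identifiability under the assumed
noise — not robustness to the structural mismatch, autocorrelated errors
or irregular sampling of real measurement campaigns.

## Reproducibility limits

The tabulated parameter set is internally inconsistent with the study's
reported outcomes, and the package reproduces the mechanism rather than
the headline numbers:

* **Propionate has no viable sink in the NaCl system.** With
  k_m,pro = 0.039 d⁻¹ and Y_pro = 0.04, maximum growth (0.0016 d⁻¹) is
  far below decay plus washout (0.085 d⁻¹), so propionate degraders wash
  out from any inoculum and propionate rises to production×SRT
  ≈ 0.58 kgCOD·m⁻³ at OLR 0.75 (production ≈ 2% of disintegrated COD,
  from the amino-acid split and the valerate pathway). Every methanogen
  behind a 0.5 kgCOD·m⁻³ inhibition threshold then runs at I ≤ 0.46, and
  the hydrogen pathway (a third of sugar COD) is marginal: the steady
  methane fraction tops out near 58–61% against the reported 66%.
* **Biomass recycling regenerates inerts.** Decay returns cells to the
  composite pool, whose redisintegration is 28% inert; at steady state
  the particulate-inert outflow is therefore ≈ 29% of fed COD, above the
  reported 27% (which equals the feed's inert content exactly), and the
  biomass washout fraction (≈ 5–7%) exceeds the reported 3%.
* **The sulfate budget caps sulfide at 9.9% of fed COD** (0.245 kmol/m³
  × 64 kgCOD/kmol ÷ 158 kgCOD/m³), slightly below the reported 12%, and
  caps the with/without-SRB methane gap at roughly 0.1 g-COD·L⁻¹·d⁻¹ at
  OLR 0.8 — the reported gap (0.62 vs 0.35) exceeds it. The reported
  SRB-free MPR of 0.62 at OLR 0.8 also exceeds the 72%-degradable ceiling
  (0.58).
* **The sulfate-system capacity claim (>2 kg-COD/kg-MLSS/d) implies
  SRT ≈ 2–4 d**, below the washout limit of the tabulated acetoclast
  kinetics (maximum growth 0.2 d⁻¹).

These gaps are properties of the published parameterisation; the
acceptance suite asserts the reported values at their stated tolerances
and records the discrepancies rather than adjusting printed parameters to
force agreement.

## Known limitations

* Sulfide toxicity, FeS precipitation and pH feedback are not modelled;
  sulfide is reported as produced COD-equivalent regardless of its
  experimental fate as FeS.
* Dissolved hydrogen accumulates without bound if the hydrogenotrophic
  guilds collapse (no gas stripping of H₂), which is physically
  unrealistic but keeps the COD ledger exact.
* Several guilds are near their washout point by construction, so steady
  states close to those bifurcations are sensitive to small parameter
  changes; the steady-state solver's extinction shortcut resolves the
  limit deterministically.
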