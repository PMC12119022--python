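# Methods

`pigch4` estimates methane emission from pig production as a chain of five
stages: diet composition, feed intake, digestion/excretion, enteric CH4, and
a dynamic simulation of CH4 from slurry in the barn pit and the outdoor
storage tank. This note documents the model equations, the parameters that
matter, the design choices made where the design was genuinely open, and the
limits of what the bundled fixtures and tests can show.

## Diet composition

A diet is a list of as-fed inclusion proportions over a feed table that
carries, per ingredient, dry matter (DM, g/kg as-fed) and concentrations per
kg DM of organic matter (OM), crude protein (CP), crude fat (CF), starch,
sugar, residual fiber (RF), indigestible NDF (iNDF), non-starch
polysaccharides (NSP) and soluble NSP (sNSP). Mixing happens on a DM basis:

    a_j = incl_j · dm_j / Σ_k incl_k · dm_k          (DM proportion)
    X_i = Σ_j a_j · x_{i,j}                          (diet concentration)

Residual fiber is the by-difference carbohydrate fraction

    RF = OM − CP − CF − starch − sugar  (g/kg DM),

computed either by mixing tabulated ingredient RF values (canonical route)
or by applying the rule to the mixed proximate fractions; the two differ
only through table rounding, and the validator treats a deviation of up to
2 g/kg DM as rounding noise. Protein-dense ingredients (fish meal) can have
CP + CF exceed OM in printed tables; a tabulated RF of 0 is then accepted
against the negative by-difference value (clamp convention).

Mineral carriers (monocalcium phosphate, calcium carbonate, salt, premix)
are pure ash. Crystalline amino acids carry a CP-equivalent of
purity × N-fraction × 6.25 from the molecular formula; to keep the
OM + ash = 1000 closure and RF = 0 simultaneously, their OM is set equal to
that CP-equivalent and the remainder is booked as ash. This is an accounting
convention, not a chemical claim; amino-acid inclusions never exceed 1.1% of
any bundled diet, so the effect on diet composition is negligible.

One bundled formulation column as printed sums to 99.84% rather than 100%;
the fixture closes the gap by raising the wheat inclusion 0.16 points, which
moves the reconstructed diet DM by less than 0.1 g/kg.

## Feed intake

Diets within a category are compared at equal net-energy intake, expressed
in Danish feed units (FUsv for growing pigs, FUso for sows) per kg as-fed.

* Growing pigs eat to a batch-cycle gain target:
  `feed (kg/d) = gain · feed_efficiency / fu_per_kg / cycle_days`.
  The bundled gain and efficiency constants (weaned: 21 kg over 54 days at
  2.09 FU/kg gain; grower-finisher: 84 kg over 84 days at 2.648 FU/kg gain)
  are calibration fixtures reproducing typical Danish daily intakes; they
  are not normative values and are meant to be edited.
* Sows consume a fixed yearly FU budget, split over production stages, on
  their feeding days only (285 days/year gestating, 80 lactating):
  `feed (kg/d) = Σ stages / feeding_days / fu_per_kg`. Dividing by feeding
  days rather than 365 is the only reading that reproduces reported daily
  intakes (to ≤ 0.4%), and is adopted here.
* Energy densities of the fiber-substituted diets are not public; the
  fixture back-derives them from the reported intakes of those diets
  (`fu = fu_avg · intake_avg / intake_diet`), exact under the equal-FU
  design. They are marked derived, not authoritative.

A fiber substitution lowers FU/kg, so as-fed intake rises to hold FU intake
constant — the central intake mechanism of the whole chain.

## Digestion and excretion

Apparent total-tract digestibility coefficients are applied per ingredient:
growing-pig coefficients for weaned and grower-finisher pigs, sow
coefficients for gestating and lactating sows; CF and starch+sugar
coefficients are shared across classes, and starch + sugar digest as one
pool (coefficient 0.999). The bundled coefficients are plausible defaults
(cereal OM 0.86–0.91, hulls/bran 0.62–0.70, fibrous by-products lower for
growing pigs than sows); the normative tables they stand in for are not
redistributable, so these values are explicitly non-authoritative and
editable in `digestibility.csv`.

Derived quantities, all in g/kg DM unless noted:

* digested RF = digested OM − digested CP − digested CF − digested
  starch+sugar (clamped at 0 with a warning);
* fermentable fiber FF: the same by-difference form, used as the substrate
  of the sow enteric regression (FF ≤ diet RF always);
* potentially degradable excreted RF = excreted RF − iNDF (iNDF passes
  through the gut unchanged and is fully excreted);
* feces DM (g/d) = excreted OM + excreted ash, with ash excretion at
  1 − 0.50 apparent ash absorption (own closure choice; feces ash is not
  reported separately);
* feces mass (kg/d) = 5.405 − 6.31·d_OM + 0.505·DMI for all categories
  except weaned pigs, which use feces DM / 0.25 (25% DM in feces);
* urine N (g/d) = −21.20 + 0.134·CP + 10.15·DMI; weaned pigs instead use
  the N balance intake − feces − retained, with retained N =
  25.6 g N per kg gain (configurable; the underlying normative constant is
  not printed anywhere accessible);
* urine volume = 2.0 (growing) or 2.5 (sows) kg per kg DMI; urea N = 75% of
  urine N; fecal VFA = 2.87 g per kg feces fresh mass.

The whole-diet OM digestibility entering the feces-mass relation is the
intake-weighted mean of the ingredient coefficients.

## Enteric CH4

Two empirical class regressions:

    growing:  CH4 (L/d) = −0.62 + 0.032·sNSP intake (g/d) + 0.025·BW (kg)
    sows:     CH4 (L/d) =  0.440 + 0.0206·FF intake (g/d)

Litres convert to grams at 0.716 g/L (CH4 at 0 °C, 1 atm; 0.654 g/L at
25 °C selectable — the conversion convention behind published g/d values is
not stated, so absolute g/d agreement is not asserted anywhere).
Annualization multiplies by 365 without occupancy correction, matching how
published per-place values relate to daily values.

## Manure CH4 simulation

A simplified anaerobic-digestion compartment model in COD currency.
Excreted nutrients map to pools with standard oxidation stoichiometry
(carbohydrate 1.19, protein 1.42, lipid 2.90, VFA-as-acetate 1.07 g COD/g;
methanogen biomass C5H7O2N at 1.42 g COD/g DM; 4 g COD per g CH4):

* degradable pools: CP, CF, degradable RF, and a fast starch+sugar pool
  (feed spillage feeds mostly into the last);
* iNDF → inert pool; fecal VFA → VFA pool; urea N rides along as a non-COD
  solute; urine, feces water, washing water and spilled-feed water carry the
  slurry mass.

Fresh excreta also carries live methanogens: 2% of feces DM enters as
biomass, split 80/15/5 over the three populations. Without this continuous
inoculation a weekly-emptied pit could never sustain methanogenesis; with
it, pit activity is limited by how much biomass has accumulated since the
last emptying — which is exactly the behaviour that makes barn emission
depend so strongly on removal interval.

Dynamics per pool X (g COD):  dX/dt = X_in − α(T)·X − R(T)·X, with
hydrolyzed COD entering the VFA pool and respired COD leaving the system
(surface respiration, rate R). Three Monod populations consume VFA:

    uptake_i = B_i · q_i(T) · C/(K_S,i + C) · I(C)
    I(C) = 1 / (1 + (C/K_I)²),   C in g VFA per kg slurry

Consumed VFA-COD splits into CH4 (emitted) and biomass growth by the yield;
decayed biomass joins the inert pool. Temperature responses: exponential
exp(0.08·(T − 20)) for hydrolysis and respiration (Q10 ≈ 2.2), Gaussian
around each population's optimum for uptake.

Defaults (all per `KineticParams`, editable):

| parameter | value | note |
|---|---|---|
| α20 starch+sugar | 0.20 /d | fast pool |
| α20 CP / CF / deg. RF | 0.012 / 0.006 / 0.006 /d | slow pools |
| respiration R20 | 0.002 /d | surface loss |
| q_opt | 3.5 / 5.0 / 7.0 g COD/g DM/d | at optima 28 / 38 / 45 °C, σ = 7 °C |
| K_S | 0.35 / 0.45 / 0.60 g VFA/kg | within the accepted 0.3–0.6 range |
| K_I | 20 g VFA/kg | shared product inhibition, exponent 2 |
| yield | 0.05 g DM/g COD | decay 0.02 /d to inert |
| residual pit fraction | 5% | inoculum left at emptying |

The kinetic constants of the reference parameter set this model is shaped
after live in an external package and are not printed in any source bundled
here; the values above are this package's own choices, calibrated so that
the simulation reproduces the reported *orderings and qualitative dynamics*
(category ranking, diet ranking within category, barn-vs-storage share as a
function of removal interval, spillage response and VFA inhibition) with
annual magnitudes in the right range. Absolute barn/storage values are
therefore not asserted in tests; conservation, monotonicity, ordering,
convergence and identifiability properties are.

Management: the pit runs at the category's constant barn temperature;
influent pauses while the section is empty between batches; washing water
is added once per cycle; every `removal_interval` days the pit empties to
the storage tank except for the residual fraction. The covered storage tank
(5.5 m × 36 m, no rain or evaporation) follows a monthly temperature series
and is emptied 80% on day 105 (spring) and 20% on day 288 (autumn), giving
a mean retention of about 4.5 months.

Integration is explicit Euler at dt = 0.05 day with non-negativity guards
and event handling at day boundaries; halving the step changes annual
emission by < 0.3%. Every COD flux is booked in the emission ledger, so
initial + influent = CH4 + respired + removed + standing closes to
floating-point accuracy (asserted < 0.1% in tests). Default scenario
horizon is 730 days — one spin-up year to reach the quasi-steady management
cycle, then one reported year; this size keeps a full scenario under one
second while the spin-up removes the empty-tank transient.

## Synthetic data

The generator emulates the *structure* of the real inputs: ingredients with
by-difference-consistent composition across a controlled RF range (fibrous
ingredients get lower digestibility and energy density), two-ingredient
diet blends solving for a target diet RF, sinusoidal monthly temperature
series, and randomized grower-style management configs. A single integer
seed drives one `numpy` generator in a fixed sampling order, so identical
specs give identical outputs. It does not emulate the statistics of any
national feed market, amino-acid supplementation practice, or multi-phase
feeding — passing pipeline-closure tests on synthetic scenarios shows the
chain is total and conservative on valid inputs, not that it predicts any
particular farm.

Parameter recovery: with the degradable-RF hydrolysis constant as the only
unknown, fitting the simulated daily barn CH4 series by bounded scalar
minimization recovers a known scale factor to well within 5%, showing the
constant is identifiable from ledger data of this kind.

## Known limitations

* Digestibility, growing-pig performance, and all kinetic constants are
  documented defaults, not sourced norms; absolute emission levels move
  with them (reported magnitudes are matched within roughly ±30–50%).
* No pH/ammonia chemistry, no N2O or NH3, no crust formation, no
  rain/evaporation for uncovered stores, no field-application emissions.
* The published whole-diet RF values for some diets cannot be reconstructed
  from the printed ingredient tables by either RF route (gaps of ~25 g/kg
  DM suggest the underlying formulation files differ from the printed
  summary); diet-level RF is therefore validated against its own arithmetic,
  not against those printed values.
* Enteric g/d values depend on an unstated litre-to-gram convention; only
  ratios and annualized relations are asserted.
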