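# Methods

`crewmet` is a deterministic, desk-scale model of the metabolic resource
footprint of a space-exploration crew: per-person and crew-level energy
expenditure, oxygen consumption, carbon dioxide and metabolic heat
production, and hydration water needs, as functions of body size,
countermeasure-exercise prescription and mission duration. This note
documents the model equations, the parameter choices, the numerical
conventions, and what the tests do and do not establish.

## The population model

Crew members are characterised by stature alone; everything else is
shared. The default shared parameters encode a male astronaut reference
population: age 40 y, BMI 26.5 kg/m² (the mean of a 30-astronaut cohort
with mean stature 1.755 m and mass 81.6 kg), relative VO₂max
43.4 mL/kg/min, resting VO₂ 3.3 mL/kg/min, respiratory exchange ratio
0.788 at rest and 0.898 at 75% VO₂max. Under **geometric similarity**,
body mass = BMI × stature², exactly; surface area follows Du Bois,
BSA = 0.007184 · height(cm)^0.725 · mass(kg)^0.425. The Du Bois formula
is sometimes quoted with height "in metres"; only the centimetre form
(the classical one) reproduces the reference surface areas, and that is
what is implemented. Geometric similarity is known to understate muscle
mass (and hence metabolism) in larger individuals; the model therefore
likely underestimates large-crew budgets.

## Resting metabolism

- RMR (kcal/d) = 88.362 + 13.397·mass + 4.799·height(cm) − 5.677·age
  (revised Harris–Benedict, males), converted at 4.1868 kJ/kcal. The
  4.1868 factor (IT calorie) reproduces the reference table at printed
  precision; 4.184 does not.
- NEAT = (PAL − 1) × RMR with PAL = 1.4 (sedentary, confined habitat,
  countermeasure exercise excluded).
- TEM (thermic effect of meals) is a flat 206 kcal/d (0.862 MJ/d),
  independent of body size and intake.
- Resting VO₂ = mass × 3.3 mL/kg/min; VCO₂ = RER × VO₂.
- Heat production Mprod (J/s) = VO₂(L/min) × k / 0.01433, where k is
  the thermal equivalent of O₂ at the prevailing RER (4.788 kcal/L at
  rest, 4.924 kcal/L during exercise). Some statements of this formula
  say VO₂ "in mL/min"; only L/min reproduces the reference values
  (e.g. 84.4 J/s at 1.70 m), and the constant 0.01433 is simply
  1/(69.78 J/s per kcal/min).

**A reproduced inconsistency.** Two independent routes to resting daily
energy — 86,400 s × basal Mprod vs the Harris–Benedict RMR — diverge
monotonically with stature (−1.7% at 1.50 m, +2.3% at 1.70 m, +5.9% at
1.90 m), because HB is affine in mass while the fixed per-kg VO₂ route
is proportional. Summed over the five-stature population they agree to
+2.6%. Both routes are part of the source model and both are kept; the
tests assert the population-level agreement and the documented
per-member divergence pattern rather than pretending the routes agree
everywhere.

## Exercise metabolism

Countermeasure exercise is steady-state aerobic work at 75% VO₂max for
30 min, twice a day (the second bout standing in for resistance
exercise, for which no validated energy equation exists), nominally
6 d/week. Warm-up/cool-down are excluded.

- VO₂ = 0.75 × VO₂max(abs); VCO₂ = 0.898 × VO₂.
- EE (kcal/min) = 3.94·VO₂ + 1.11·VCO₂ (Weir). As with Mprod, the
  L/min reading of the Weir inputs is the one that reproduces the
  reference energy rates (12.3 kcal/min at 1.70 m).
- EPOC adds 6% of in-bout O₂, CO₂ and energy to each bout (mean of
  reported 5.1%/6.8% values for 20/40 min at ~70% VO₂max). EPOC is
  **not** applied to heat or sweat: per-bout heat equals in-bout
  Mprod × 1800 s exactly (1,542 kJ at 1.70 m), which is the only
  accounting consistent with the reference bout table. Strictly,
  recovery occurs at the resting RER, so applying the flat 6% to CO₂
  slightly overstates recovery CO₂; the source model does the same.

## Thermoregulation and sweat rate

Steady-state partitional calorimetry over one bout:

- Mnet = Mprod × (1 − 0.20)/BSA, the 20% being external mechanical work
  on a cycle ergometer for non-cyclists.
- Dry loss = (Tsk − Ta)/[Icl + 1/(fcl·(hc + hr))], with mean radiant
  temperature equal to air temperature.
- Ereq = Mnet − dry loss.
- Emax = (Psat(Tsk) − RH·Psat(Ta))/[Re,cl + 1/(fcl·hc·LR)].
- Whole-body sweat rate = max(0, 147 + 1.527·Ereq − 0.87·Emax) g/m²/h
  × BSA (Gonzalez regression), with no sweating-onset lag.

Coefficients the source only cites, with this implementation's chosen
defaults (all exposed on `Environment`): hc = 8.3·v^0.6 W/m²/°C (forced
convection; 5.48 at the 0.5 m/s cabin airflow), hr = 4.7 W/m²/°C,
clothing area factor fcl = 1.1, Lewis relation 16.5 °C/kPa, mean skin
temperature 35 °C (conventional exercising value; not stated by the
source). Clothing: Icl = 0.06 m²·°C/W, Re,cl = 0.01 m²·kPa/W (shorts
and t-shirt). Saturation vapour pressure uses the Antoine equation,
log₁₀P(mmHg) = 8.07131 − 1730.63/(233.426 + T), accurate to <0.1% over
0–45 °C.

With these defaults the ISS-like cabin (22 °C, 55% RH) gives dry loss
≈ 87 W/m² and Emax ≈ 207 W/m² (both pinned as regression constants in
the tests), and predicted sweat rates of 9.3–15.6 mL/min across the
stature band — uniformly ~9% below the reference 10.1–17.1 mL/min row,
within the ±15% band that is all the unpublished coefficient choices
support. Note that Ereq (259–295 W/m²) exceeds Emax here, i.e. the
required wettedness proxy Ereq/Emax is 1.25–1.42: under this clothing
and coefficient set the Gonzalez regression is being used outside the
fully compensable region, and indeed *any* parameterisation of this
regression that reproduces the reference sweat rates implies
Ereq > Emax (matching them with Ereq < Emax would require a total
evaporative resistance below the clothing's own). The model reports
wettedness as a diagnostic and the tests bound it at < 1.5 rather than
asserting compensability.

## Water requirements

Basal need = IWN + UV600, where IWN = 0.4 × energy needs(kcal)/1000 and
UV600 = DSL/600 with DSL = protein/0.175 + 2(Na/23 + K/39) (mmol/d) at
ISS-menu intakes (95 g, 4,320 mg, 3,062 mg → DSL 1,075.5 mmol/d, UV600
1.79 L/d, identical across statures). Respiratory loss is assumed
balanced by metabolic water; there is no explicit transcutaneous term.

"Energy needs" is not pinned down by the source. The default here is
the **gas-exchange route**: resting Weir EE × 1440 min × PAL + TEM.
This reproduces the reference basal-fluid column (2.63–3.13 L/d) to
within 1% at every stature; the alternative Harris–Benedict route
(RMR × PAL + TEM, selectable via `energy_route="harris_benedict"`)
leaves a residual growing to −3.3% at 1.90 m. Exercise affects water
only through sweat replacement (bouts × bout sweat); the exercise
energy itself does not enter IWN — this is what the reference
exercise-day water rows require.

## Daily and mission aggregation

No-exercise day: TEE = RMR×PAL + TEM; O₂/CO₂ = resting rate × PAL ×
1440 min; **heat = basal Mprod × 86,400 s with no PAL factor** — an
asymmetry reproduced from the source (7.3 MJ = 84.4 J/s × 86,400 s at
1.70 m); `heat_variant="consistent"` applies PAL to heat for a
self-consistent variant. Exercise days add the per-bout totals on top
of the full resting day, without deducting resting metabolism during
the exercise minutes (again matching the reference accounting).

Mission totals are exactly linear: Σ over crew of daily budget ×
duration. Exercise is applied 7 d/week by default because the
reference mission aggregates require it (e.g. +306 MJ/month for the
small crew = 2 bouts × 1.276 MJ × 4 crew × 30 d); the nominal 6 d/week
schedule is honoured pro rata under `strict_schedule=True`.

The worst-case concurrent heat load (sessions performed back-to-back)
is one member's exercise Mprod plus the rest of the crew at basal
Mprod: 1,386 J/s for a 1.90 m crew of four (the reference prints 1,388
from inputs rounded to table precision).

Two cells of the reference 24-h table are internally inconsistent and
are handled explicitly: the with-exercise VO₂ row (494–792 L) matches
neither bout addition nor its own printed "+31%" brackets and is not
used as a comparison target; and the 1.50 m with-exercise TEE prints
11.9 MJ where both its "+29%" bracket and the bout arithmetic give
11.5 MJ — the reconstruction is used.

## Synthetic crews, determinism and problem sizes

The roster generator produces homogeneous fixed-stature crews (the
default, which is what the reference analysis uses) and uniform or
truncated-normal samplers over the agency band (1.495–1.905 m) for
sensitivity work; bounds outside the band warn rather than fail. All
sampling goes through `numpy.random.default_rng(seed)`, so equal seeds
give bit-identical rosters and downstream tables. The model itself has
no randomness.

The full reference grid is 5 statures × 6 durations (30–1,080 d) ×
{no exercise, exercise} = 60 scenarios with four-person crews; the
whole pipeline (all tables plus the grid) runs in well under a second,
and the test suite in a few seconds.

## What the tests show — and don't

The golden-value tests pin every printed digit of the reproducible
table rows (tolerance 0.6 × the printed unit-in-last-place, which
absorbs the source's own inconsistent rounding) and the mission-level
deltas; property tests cover linearity, monotonicity in stature, EPOC
identities, determinism and the +44%/+60% body-size ratios. Passing
them shows the arithmetic model is reproduced faithfully. It does not
validate the model against real spaceflight physiology: microgravity
effects on RMR, NEAT and gastrointestinal function are assumed away,
resistance exercise is approximated by a second aerobic bout, the
sweat prediction is a terrestrial regression used near the edge of its
compensable range, and geometric similarity understates large-body
metabolism. Female crews, surface operations, CO₂ ventilatory effects
and life-support hardware efficiencies are out of scope.
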