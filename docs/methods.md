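# Methods

## The population-dynamics core

Each stock (cod *c*, herring *h*, sprat *s*) is a two-pool biomass model:
an adult pool `B` (whose biomass is the spawning stock biomass, SSB) and a
juvenile pool `J`.  All biomasses are relative units, roughly 100 kt; all
rates are per year; the time step is annual.  Within a year the order of
operations is fixed, and results depend on it:

1. **Rates at the year's start.**  Predation, seal and feedback terms are
   evaluated at beginning-of-year biomasses.  This avoids any ordering
   circularity between production and mortality.
2. **Production.**
   `B' = B (1 + g_eff) + J`, where `g_eff` is the surplus-production
   (growth-efficiency) coefficient `g` modified by the variant's switches:
   * environmental forcing: `g ← g · growth_multiplier(year)`;
   * density dependence: `g ← g (1 − B/K)` (logistic self-limitation);
   * prey feedback on cod: `g ← g · min(cap, φ/φ_ref)` with
     `φ = (total available prey biomass)/B_c` the per-capita food
     availability and `φ_ref` its baseline value — a linear, capped
     response (the shape is an artifact choice; only "growth varies with
     food consumption" is structurally prescribed);
   * clupeid competition: `g ← g / (1 + γ (B_h + B_s))`, a saturating
     shared-resource penalty on both clupeids.

   Spawning produces a juvenile cohort `R(B)` (Ricker `aSe^{−bS}`,
   Beverton–Holt `aS/(b+S)` or hockey-stick `a·min(S,S*)/S*`, optionally
   multiplied by the recruitment forcing), which survives juvenile
   mortality `exp(−(M1_juv + M2_juv))` and is promoted to the adult pool
   after exactly one year.
3. **Mortality partition.**  Adult natural mortality is
   `M = M1 + M2 + M_seal`.  Two fishing conventions are implemented:
   * `harvest_rate` (annual catch/biomass): the catch is
     `C = F · B(start of year)` (a TAC computed from the assessed
     beginning-of-year stock), removed after production and capped at the
     post-production biomass; survivors then decay by `exp(−M)`.
     F is restricted to [0, 1].
   * `instantaneous`: fishing and natural mortality act concurrently via
     the Baranov catch equation, `C = F/Z (1 − e^{−Z}) B'` with
     `Z = F + M`; survivors are `B' e^{−Z}`.

   Biomass below 1e−9 is floored to zero with a collapse flag so extreme
   grid corners always complete.

Predation by adult cod takes one of two forms.  The *linear/declining*
form, `M2_p = c_p B_c / (D + Σ_q B_q)`, is linear in cod biomass and
declines with the total prey pool (a fixed ration shared across prey);
it is capped at a guard maximum, which is also returned if the denominator
is zero.  The *saturating* form,
`M2_p = m_p · B_c/(K_p + B_c) · B_p/(A_p + B_p)`, saturates in predator
biomass (bounded by `m_p`) and rises with the prey's own biomass.  Cod
cannibalism is predation on the juvenile-cod pool with the same functional
form and the prey set {herring, sprat, juvenile cod}.  Seal mortality is
either linear in seal biomass (unbounded) or saturating (bounded by its
per-stock coefficient), both increasing in prey biomass.

### The three ensemble members

The variants span the structural contrasts between a whole-food-web
simulator, an age-structured statistical model and a minimal multispecies
production model:

| assumption            | `ewe_like`                  | `gadget_like`       | `mspm_like`                 |
|-----------------------|-----------------------------|---------------------|-----------------------------|
| recruitment           | Beverton–Holt, env-forced   | hockey-stick        | Ricker (cod), B–H (clupeids)|
| cod predation         | saturating, incl. cannibalism| saturating, no cannibalism | linear in cod, declining in prey |
| prey feedback on cod  | growth × food availability  | none                | via cannibalism only        |
| clupeid competition   | yes                         | no                  | no                          |
| seal predation        | saturating (bounded)        | linear (unbounded)  | none                        |
| environmental forcing | growth+recruitment, all stocks | none             | growth of cod and herring   |
| density-dep. growth   | no                          | no                  | sprat                       |
| F convention          | harvest rate                | harvest rate        | instantaneous               |

The `ewe_like` recruitment is "complex and environmentally forced" in
spirit; within the three admissible analytic forms it is represented as
Beverton–Holt with recruitment forcing on all stocks.  The quarterly
resolution of age-structured models is emulated by the annual step (their
outputs would be aggregated to yearly means anyway).  Consequences of the
structure, all verified by tests: in `gadget_like` the cod trajectories
are *bitwise* independent of the clupeid Fs (no feedback channel exists),
so under the Piscivore Exploitation objective its clupeid F advice is "no
information"; in `ewe_like` the seal effect saturates and is nearly
neutral while in `gadget_like` it grows linearly with the seal population;
only `ewe_like` and `mspm_like` respond to the nutrient scenarios.

### Default parameters

Parameters were set analytically, once, from the equilibrium condition of
the annual map.  For a Beverton–Holt stock fished at harvest rate F the
unfished-balance condition is `a e^{−M_juv}/(b + B*) = e^{M1} − 1 − g + F`,
which was solved to place the stocks at Baltic-like relative biomasses
(cod 1, herring 7, sprat 8; juveniles at their equilibrium pipeline
values 0.6/2.6/4.4) under the 2011–2013 reference fishing mortalities
(0.5, 0.25, 0.3) and to put collapse Fs near or above the top of the
grid.  Growth coefficients are 0.10, residual adult mortality 0.2 (0.3
for sprat), juvenile mortality 0.3 (0.4 for sprat).  Cod's maximum
predation rate on herring is far below that on sprat (0.08 vs 0.25 in
`ewe_like`), reflecting their different vulnerability.  With these
defaults the F–cumulative-yield curves are dome-shaped or saturating for
every stock, variant and environment, and the BSAP nutrient scenario
yields more cod than BAU — the qualitative regime the ensemble is meant
to exhibit.

## Synthetic forcing

The generator replaces a hydro-biogeochemical hindcast with the minimal
structure the downstream analysis needs: label-specific deterministic
linear trends over 2014–2032 multiplied by `exp` of a stationary AR(1)
process (autocorrelation 0.6, marginal s.d. 0.05), which guarantees
strict positivity for every seed.  BSAP (nutrient-load reduction) tilts
cod growth/recruitment up to ×1.10 by 2032 and sprat slightly down; BAU
does the reverse.  Both seal futures are deterministic exponentials,
`B_seal(t) = (1+γ)^{t−2014}` with γ = 0.05 (LSE) or 0.10 (HSE).  Nutrient
multipliers depend only on (label, seed), so the two seal variants of a
nutrient scenario share identical multiplier tables.  What this generator
deliberately does *not* emulate: irregular saltwater-inflow events,
cross-correlation between stocks' forcing, climate trends beyond the
labelled means — so passing tests show the pipeline's machinery is
correct under controlled forcing, not that any real-ocean forcing is
reproduced.

The baseline state applies a small seeded log-normal jitter (3 %) to the
canonical biomasses; reference indicator means for SSB are the baseline
adult biomasses and for profits are computed by pricing the reference-F
harvest of the baseline at unit seal biomass.

## Economics

Yearly profit is landings × price − costs, with all catches treated as
landings.  Cod landings split 83 % BT / 17 % GN; each cod fleet pays
`F_c` times its cost coefficient (the total cod F — the fleet-resolved
partial F is not tracked).  Clupeid costs are per tonne landed, and the
pelagic-trawl profit is the sum of the herring and sprat profits.  Seal
damage discards `min(1, 0.02 · B_seal)` of the GN landings; the channel
is active only in variants that model seals.  Prices (1.5/0.3/0.2 per
tonne for cod/herring/sprat) and costs are relative: only differences
between scenarios are meaningful.  Objectives discount profits to net
present value at 3 % with 2014 (the first projection year) as base year;
*indicator* profits are undiscounted yearly values, since the indicator
compares each year against an undiscounted historical reference.

## Scenario engine

The F grid is the Cartesian product of per-stock values (default 0–1.4 in
steps of 0.2).  Harvest-rate variants cannot take F > 1 (more than the
whole annual biomass), so the grid is clipped to ≤ 1 for them; the
instantaneous-F variant uses the full range.  Selection is an exhaustive
argmax over the grid with ties broken toward the lexicographically
smallest (cod, herring, sprat) F vector — conservative exploitation.  At
the optimum, each F dimension whose objective's relative range across the
dimension is below 1e−6 is reported as "no information"; single-valued
dimensions cannot be assessed and are reported as informative.  The
Piscivore Recovery objective is the 2028–2032 mean of `B_c/(B_h + B_s)`
(total biomasses), with constraints `mean SSB > B_lim` over the same
window for both clupeids (B_lim defaults 3.5 and 4.0, direct
configuration inputs); if no regime satisfies them the selection is
reported explicitly infeasible.  Indicators are relative changes versus
the 2011–2013 reference means over 2020–2032 only — 13 yearly values per
indicator — with 2014–2019 excluded as a transition period.

When a selection has "no information" dimensions, indicators that cannot
be evaluated without the missing F are masked: a missing clupeid F masks
the clupeid SSBs, the pelagic-trawl profit and the total profit; a
missing cod F masks cod SSB, the BT profit and the total profit.

## Agreement statistics

Relative changes are binned into six categories with boundaries at ±10 %
and ±20 %: ±10 % belongs to the "within ±10 %" category (the band is
closed), and the ±20 % boundaries belong to the 10–20 % bands.  The A
index is `Σ_j N_j(N_j−1) / (N(N−1))`, the probability that two cases
drawn without replacement share a category.  By default the
"no information" category participates as an ordinary category — two
uninformative outputs count as agreeing — matching the factorial case
count of 12 that includes the uninformative model; an exclusion mode is
available (`include_no_information=False`) since the alternative reading
is defensible.  1/CV uses the absolute mean (so negative-profit
indicators stay defined) and the sample (n−1) standard deviation; yearly
indicator values are pooled across cases rather than averaged per model
first.  A sample s.d. at the level of float rounding noise (≤1e−12
relative) is treated as zero dispersion, returning the perfect-agreement
marker (∞), which propagates through item averaging.

## Numerical choices and degenerate inputs

* Collapse floor 1e−9 with a sticky-by-construction recovery path (zero
  SSB produces zero recruits).
* Linear predation's division guard returns the configured maximum rate
  when the prey pool and half-saturation are both zero.
* Grid values are rounded to 10 decimals so regime coordinates compare
  exactly across variants and reruns.
* The Schaefer verification uses a reduced variant (recruitment off,
  density-dependent logistic growth, no mortality besides fishing) whose
  annual map is exactly `B' = B + rB(1−B/K) − FB`, hence equilibrium
  yield `FK(1−F/r)` and optimum `F = r/2`.
* Default problem sizes: the shipped analysis uses the 0.2-resolution
  grid (512 regimes before clipping) over 19 years and 12
  variant × environment combinations; the test suite uses coarser grids
  and the closed-form checks use 150–250-year horizons for equilibrium
  convergence.

## Known limitations

* Structural forms are qualitative ports; no variant is calibrated to
  survey data, so absolute outputs (tonnes, currency) are only meaningful
  relative to each other and to the 2011–2013 reference.
* Constant-F regimes only; no closed-loop management with assessment
  error, no effort dynamics or market feedbacks.
* Annual resolution throughout; sub-annual processes (spawning timing,
  quarterly fisheries) are aggregated away.
* The environmental trend shapes are free parameters of the generator,
  not downscaled projections; conclusions about environmental sensitivity
  concern the machinery, not the Baltic.
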