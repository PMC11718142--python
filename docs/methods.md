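# Methods

## Scope and framing

`nlossrisk` scores the *relative* risk of nitrogen loss to water at block ×
month resolution as source × transport, with two flow paths (leaching past
1000 mm within two years; surface runoff within 30 days of input). Scores are
unitless and meaningful only as ranks: the validation machinery is rank-based
for exactly this reason, and nothing in the package converts a score to
kg N ha⁻¹ lost.

## Transport surrogate

National-scale implementations of this index family derive transport fractions
from long runs of a mechanistic farm-systems simulator over soil × climate ×
slope grids. This package instead ships a deliberately simple daily surrogate
so that the full pipeline is runnable and testable anywhere. The surrogate is
our own design; its job is to preserve the soil × climate × month × slope
contrasts the index needs, not to reproduce any particular simulator.

**Water balance.** A layered tipping bucket. Each layer carries water contents
at saturation, field capacity and wilting point and a saturated drainage
coefficient k ∈ [0, 1] (fraction of the water above field capacity that drains
to the next layer per day). Daily order of operations:

1. Infiltration-excess runoff = rain × c_eff × antecedent relative wetness,
   where c_eff = runoff_curve_parameter × slope multiplier (capped at 1) and
   wetness = (storage − WP)/(SAT − WP) over the whole profile. Runoff occurs
   only on rain days.
2. The remainder infiltrates and cascades down; water above saturation passes
   straight to the next layer (macropore bypass), then each layer drains
   k × (water − FC). Bottom-layer outflow is drainage below the profile.
3. Single-store evapotranspiration: PET × stress, drawn from the root zone
   (layers within the top 600 mm), stress linear in the root zone's
   plant-available water fraction.
4. Irrigation (if enabled, October–April): when end-of-day plant-available
   water falls below 50 % of capacity the profile refills to field capacity.

Water is conserved exactly by construction; the test suite asserts daily
closure of rain + irrigation = runoff + drainage + ET + Δstorage to 10⁻⁶ mm.

**Tracer.** A conservative solute moved by proportional displacement: water
draining from a layer carries the layer's mean concentration (drained fraction
of the layer's pre-drainage water). ET removes water only. Tracer passing the
bottom of the first layer whose base reaches 1000 mm counts as leached.
Because the tracer is conservative (no plant uptake, no immobilisation),
leaching fractions run high relative to what a full simulator with an actively
growing crop would give — on the freely draining archetype nearly all tracer
passes 1 m within two years. Contrasts between soils, months and climates are
preserved, which is what the index consumes.

**Protocol.** 450 kg N ha⁻¹ applied on the 15th of each calendar month, in
every simulated year that leaves a complete 730-day horizon inside the climate
series; leach fraction = leached/450 averaged over those years. Runoff
fraction = min(1, Σ runoff over 30 days / 200 mm), same averaging. The cap at
1 keeps the index scale bounded where a 30-day storm total exceeds the 200 mm
normaliser. Slope enters as a multiplier on the runoff curve parameter:
flat/rolling/easy/steep = 1.0/1.2/1.5/2.0 (configurable); slope classes are
0–7°, 7.1–15°, 15.1–25°, > 25°, with boundaries resolved downward (7.0° is
flat).

## Sources (kg N ha⁻¹ month⁻¹)

- **Excreta**: Σ(head × per-head monthly rate)/area, per stock class × age ×
  region; rates ship as illustrative defaults and are fully configurable —
  they are *not* the national inventory values. Dairy effluent is a separate
  field (milking cows × configured kg N cow⁻¹ month⁻¹) summed into the
  leaching-eligible pool.
- **Fertilizer**: applied mass × product N mass fraction, bucketed by month.
- **Residues**: released only when residue C:N < 25 (otherwise treated as
  microbially immobilised, no risk); releasable N spread equally over the
  three months after harvest (the within-window distribution is our choice).
  Belowground totals × 1.4 (shallow-rooting), × 0.7 (deep), × 1.0
  (intermediate — our addition for crops that are neither).
- **Cultivation**: first-order release from a mineralisable pool (defaults
  150 kg N ha⁻¹ for short (< 3 yr) pasture, 300 for long-term, × 0.8 for
  sheep & beef vs dairy) over a 6-month horizon; fallow months extend the
  horizon; the residual is folded into the final month so the pool is
  conserved exactly. This two-pool stand-in replaces an unpublished regional
  method; every constant is configurable.
- **Erosion**: estimated sediment (t ha⁻¹) = RUSLE-style cover factor ×
  land-use multiplier (defaults are placeholders in the 70–800 range);
  calibrated sediment = max(0, 0.92 × estimated − 15.7) — the floor is needed
  because the calibration line goes negative below ≈ 17 t ha⁻¹; N = calibrated
  × 1000 × soil total N mass fraction, split equally over the season's three
  months.

## Index

Leaching index = leach × (urine + dung + effluent + fert + belowground
residues + cultivation). Runoff index = runoff × (erosion + dung + fert +
aboveground residues); urine is assumed washed into the soil and unavailable
to runoff. The published equation pair prints leaching-fraction prefixes on
three runoff terms; we read that as a typographic slip and weight every
runoff-index term by the runoff fraction, keeping a `literal_equation` switch
that reproduces the printed form for comparison. Both indices are exactly
linear in sources at fixed transport, so multi-year averaging commutes with
scoring; aggregation offers per-block annual sums, area-weighted farm means
and pathway shares.

## Mitigation

Source deltas scale a category by (1 + δ), δ ≥ −1, floored at zero, then the
baseline is recomputed. Modifiers multiply a pathway score by
(1 − effectiveness); base effectiveness is adjusted multiplicatively for
climate/slope/soil class (factor tables default to 1.0; the adjusted value
must stay in [0, 1]). Modifiers are applied most-to-least effective with ties
broken by name; the final score equals baseline × Π(1 − eᵢ) and is therefore
order-invariant — the prescribed ordering matters only for the audit trail,
which records the score after every step. Modifiers are assumed independent
(no synergies/antagonisms) and optimally placed; the modifier library ships
empty and effectiveness values are user-supplied configuration.

## Validation

Risks and observed losses are rank-transformed (rank 1 = greatest; average
ranks for ties) and fitted by OLS (statsmodels), with t-based pointwise 95 %
confidence and prediction intervals; the result reports the count of points
outside the prediction band, and zero rank variance yields a degenerate-fit
flag with r² = 0. Sensitivity scales one source category at a time to 50 % and
150 % of baseline and reports the ratio of recomputed to baseline risk, split
by pathway — exactly 1.0 for a source absent from the block. The scale-factor
diagnosis fits risk-vs-loss slopes through the origin for a reference and a
focal cohort and reports reference/focal with a seeded 1000-resample bootstrap
interval; a cohort whose risk is attenuated ×6 yields a factor near 6.

## Synthetic data

The generator emulates the study conditions end to end: two-state (wet/dry)
Markov daily rain with gamma depths (shape 0.75) and winter-peaking wet-day
probability; sinusoidal summer-peaking PET (3.0 ± 2.2 mm day⁻¹); default
regime 1100 mm yr⁻¹, mean wet-day probability 0.30, seasonality amplitude
0.35 — a typical humid-temperate pastoral climate. Three soil archetypes
(stony-shallow, deep-fine, intermediate) each place a layer boundary at
1000 mm; land-use calendar templates (dairy at 2.8 cows ha⁻¹, sheep & beef,
cropping, vegetables, horticulture, forestry, deer) jointly exercise every
source category. Observation sets follow loss = 1.5 × risk × exp(N(0, σ))
with σ = 0.5 by default (moderate, right-skewed multiplicative noise, matching
the skewed loss distributions such data show); vegetable blocks generate their
loss from attenuation × risk (default 6), so the scale-factor diagnosis has a
known truth to recover. All randomness flows through NumPy's PCG64; a seed
fixes every output bit-for-bit.

What passing tests on these fixtures do **not** show: agreement with any real
observation database, realistic absolute transport fractions for actively
growing crops, preferential flow, frozen-soil lags, or spatial structure
(soils and climates are archetypes, not maps).

## Numerical choices and problem sizes

- Daily mass-balance closure asserted at 10⁻⁶ mm; index linearity at 10⁻⁹
  relative; residue/pool conservation at 10⁻⁹ absolute and 1 % respectively.
- Transport fractions are clamped to [0, 1] after averaging to absorb
  floating-point excursions at the boundaries.
- Randomised transport checks use 200 soil × climate fixtures with 3-year
  daily climates — the shortest length giving every calendar month a complete
  730-day tracer horizon (one application year per fixture).
- The rank-recovery check uses n = 96 observations; its expected r² band
  (0.64–0.88) was pre-computed from 200 replicate simulations of the same
  generator at σ = 0.5.
- Prediction-interval coverage is checked out-of-sample over 500 replicates of
  n = 20 (~95 % empirical coverage).

## Known limitations

- The transport surrogate has no plant N uptake, so leaching fractions are
  biased high on freely draining soils; use contrasts, not levels.
- Rate tables, cover factors and land-use multipliers are illustrative
  placeholders, to be replaced with regional values before any real use.
- Runoff risk is capped at 1; sites where 30-day runoff routinely exceeds
  200 mm saturate the scale.
- GeoTIFF rasterisation of transport tables is not provided; spatial output is
  GeoJSON property joins on block coordinates.
- The index is instantaneous: time lags between risk and measurable loss
  (deep vadose zones, frozen soils) are not modelled.
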