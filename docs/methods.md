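# Methods

## Model

`oxflux` solves a steady-state oxygen-atom budget for an animal over a
trailing measurement window. Every flux is expressed in moles of oxygen
atoms; each input draws on one of three isotopically distinct pools
(pre-formed water, atmospheric O₂, ambient vapour with which food
equilibrates), and each output draws on body water. Body-water ratios
are the quotient of the α-weighted input mixture and the α-weighted
output demand:

    R_bw(x) = Σ_i f_i α_i(x) R_x(source_i) / Σ_j f_j α_j(x),  x ∈ {17, 18}

with fractional contributions f computed within the input and the
output pool respectively. δ¹⁸O_bw and δ¹⁷O_bw follow from the two
ratios against VSMOW, and Δ′¹⁷O_bw = δ′¹⁷O − 0.528·δ′¹⁸O (per meg).
Δ′¹⁷O is always recomputed from the δ values, never stored, so the
defining identity cannot drift; it is provably insensitive to the
absolute VSMOW ratios adopted (tested to < 10⁻⁶ per meg), which default
to ¹⁸R = 2.0052 × 10⁻³, ¹⁷R = 3.799 × 10⁻⁴ and are configurable.

### Inputs

1. **Drinking water** — measured intake (leakage-corrected) / 18 g mol⁻¹;
   no fractionation.
2. **Food free water** — food mass × 55.56/(1−WC) × WC with water
   content WC = 0.09; carries the ambient-vapour composition; no
   fractionation.
3. **Oxidase water** — O₂ volume × 5.38 × 10¹⁹ O atoms ml⁻¹ / 6.03 × 10²³
   (these bookkeeping constants are kept verbatim from the tradition of
   this model family for reproducibility). Fractionated by
   α¹⁸ = (1000 + (δ¹⁸O_air − z)/(1 − OUF)) / (1000 + δ¹⁸O_air) with
   z-value 10.5 ‰, OUF 0.25, θ = 0.5179. This α (≈ 0.994) and its
   inputs dominate the Δ′¹⁷O prediction.
4. **Inhaled vapour** — lung ventilation (mol O₂/OUF/0.21 × 22.4 l) ×
   relative humidity × saturation pressure 10^(0.686+0.027·T) mmHg/760,
   converted at 22.4 l mol⁻¹. The empirical saturation exponent only
   yields physical pressures with T in °C (≈ 23 mmHg at 25 °C); a
   config flag retains the literal Kelvin reading for auditing
   parameter files that print it that way. Liquid–vapour equilibrium
   α¹⁸(T) = exp((11.36 × 10⁵/T² − 420/T − 2.07)/1000), θ = 0.529,
   applied as a multiplier on the source ratio as this model family
   does. The vapour's source pool is not dictated by the physics of the
   α alone; the default assigns the ambient-vapour (food-water) pool,
   with pre-formed water available by configuration.
5. **Condensation water** — food × carbohydrate fraction × 11.12 mol
   O/kg carbohydrate (2 of 6 glucose oxygens) × digestibility D ×
   energy-extraction E.
6. **Decarboxylation oxygen** — food × (f_carb × 22.24 + f_fat × 4 +
   f_protein × 6) × D × E; bound dietary oxygen reaching body water as
   CO₂ via carbonic anhydrase exchange.

Both bound-oxygen inputs are booked against the pre-formed-water pool
with the cellulose/pre-formed α¹⁸ = (1000 + δ¹⁸O_cellulose)/(1000 +
δ¹⁸O_preformed), ingredient-weighted (corn/wheat/soybean), θ = 0.525
applied per ingredient before weighting; this reconstructs the cellulose
ratio from the water it formed from, and keeps the food Δ′¹⁷O parameter
confined to the free-water pool.

### Outputs

Faecal bound oxygen is zero (undigested food does not exchange with body
water). Faecal water = food × (1−D)/(1−w) × w × 55.56 with faecal water
content w = 0.55. Transcutaneous loss = days × m^(2/3) × k × VPD ×
rate/1000 × 24/18 with Meeh constant k = 1100 cm² kg^(−2/3), a
taxon-specific skin evaporation rate of 0.025 mg cm⁻² h⁻¹ mmHg⁻¹ and
the Tetens vapour-pressure deficit; α¹⁸ = 0.982, θ = 0.5235. Exhaled
vapour is saturated at body temperature over the same lung ventilation;
half leaves orally (α¹⁸ = 1/α_eq(T_body)), half is routed nasally of
which half condenses back on the nasal epithelium, so a quarter of the
pool leaves nasally (α¹⁸ = 1/α_eq at the body/ambient mean temperature);
θ = 0.529 for both. Exhaled CO₂ carries 2 mol O per mol CO₂ with
α¹⁸ = exp((16600/T_body − 15.69)/1000) ≈ 1.038 and θ = 0.5248. Urea
oxygen = 12 × food × f_protein × D × E. Urinary water closes the
balance exactly: mice neither sweat nor pant under these conditions, so
the residual between inputs and the other outputs is assigned to urine
and allowed to grow as the animal drinks more.

A negative residual raises a mass-balance error naming the offending
magnitudes. The sensitivity sweep alone runs in a diagnostic mode that
permits a negative residual: a one-at-a-time range endpoint need not be
jointly consistent with the measured totals, and because urinary water
does not fractionate the prediction remains well defined (any
redistribution of moles among α = 1 outputs cancels identically — the
same invariance that makes the model exactly insensitive to faecal
water content).

### Parameters

All δ in ‰, Δ′¹⁷O in per meg, fractions in [0, 1], temperatures in °C
at interfaces, amounts in moles of O atoms. The base configuration is a
20 g mouse, 38 °C body temperature, 25 °C ambient, 45 % relative
humidity, low-salt chow (67.2 % carbohydrate, 25.4 % protein, 7.4 %
fat), drinking water at (−4.0 ‰, +20 per meg), atmospheric O₂ at
(24.046 ‰, −441 per meg), ambient vapour at (−16.41 ‰, +30 per meg),
and a 96 h window whose measured totals are 5582 ml O₂, 0.21417 mol
CO₂, 12.97 g food and 10.44 ml water. Where a printed parameter table
is internally inconsistent we resolved it once and exposed the choice:
the base ambient temperature is 25 °C (not the mislabelled 0.25); the
protein/fat fractions follow the base table (25.4/7.4 %), treating the
per-treatment table's transposed labels as swapped; the window is 4
days, consistent with the totals' magnitude against the measured daily
rates. CO₂ totals are accepted in ml or moles through an explicit
converter.

## Sensitivity analysis

One parameter (or fractionation component) at a time is moved to the
low and high end of its plausible range; the reported change is the
largest excursion of the prediction from the base model,
max(|f(low) − f(base)|, |f(high) − f(base)|), per response (δ¹⁸O_bw and
Δ′¹⁷O_bw). We chose the base-excursion form over the endpoint
difference |f(high) − f(low)| because ranges in this literature are
typically asymmetric around the base value and the excursion is the
quantity published sensitivity tables in this model family report;
for a symmetric range the two differ exactly by a factor of two.
Fractionation components (θ values, the transcutaneous α¹⁸, an oxidase
α¹⁸ override, the oral/nasal routing) are perturbed by direct override
rather than through the formulas that normally produce them. Ranks are
competition ranks (descending, ties share). The packaged 28-row design
ships with the published change magnitudes it was validated against;
26 of the 28 agree within the acceptance bar (±20 % relative or
±0.3 ‰ / ±8 per meg), the two exceptions being δ¹⁸O responses (OUF and
food-water δ¹⁸O) whose published values likely reflect an unstated
structural choice for the inhaled-vapour source pool; the Δ′¹⁷O
responses — the quantity this model exists for — agree on all 28 rows.

## Phenotyping QC

Gas exchange is sampled once per cage per 5 min; hopper masses step
down as the animal eats and drinks. Sensor gaps of 35–60 min are filled
at nominal cadence with the mean rate of the preceding 3 h of observed
records; longer gaps use the preceding 24 h (researcher presence
elevates metabolic rate, so a short lookback would bias high); gaps
under 35 min are left missing and integrate as zero-length, not
zero-rate. Fills never feed later fills, observed records are never
altered, and a fill is skipped (with a warning) when fewer than two
observed records exist in the lookback window. Daily water totals are
reduced by a bulk 10 % for drinker-nozzle leakage (flagged, hence
idempotent); days exceeding 12 ml water or 8 g food — far above
observed intake maxima (~6 ml, ~4.5 g) but well below the gross
spill/caching artefacts they target (25 ml, 30 g) — are replaced by the
cage's clean-day mean and flagged; both thresholds are configurable.
Window totals integrate rates × 5 min over [end − window, end) and sum
daily intakes for dates starting in the window, so day-aligned windows
are exactly additive.

## Analyzer-run correction

Each run is put on the VSMOW-SLAP scale per isotope by a two-point fit
through the outlier-screened mean raw values of two bracketing
reference waters: corrected = stretching × raw + offset, which maps the
reference means onto their known values exactly. Outlier screening is a
single pass removing injections more than 2 SD from the initial mean,
per quantity (Δ′¹⁷O screened independently of the δs), never more than
20 % of injections; the rule is configurable because the upstream
workflow leaves it to post-processing code rather than stating it.
Controls fail at |Δδ¹⁷O| ≥ 0.15 ‰, |Δδ¹⁸O| ≥ 0.3 ‰ or |ΔΔ′¹⁷O| ≥ 15 per
meg; a run is rejected when more than two controls fail. Distillation
replicates are averaged unweighted (more injections do not imply better
accuracy across runs), Δ′¹⁷O recomputed from the grand-mean δs, and a
replicate spread beyond 0.3 ‰ / 15 per meg warns without removing data.
Known reference/control values are configuration, not constants.

## Synthetic data

The generator emulates the study design, not mouse behaviour: per-mouse
daily means drawn from the treatment group's mean ± SD (four packaged
cells: low/high-salt diet × 25 °C/cold housing, with the cold cell
parameterized at 18 °C / 60 % rh); gas traces as AR(1) noise (φ = 0.9,
σ = 5 % of mean) around the daily mean with a 20 % sinusoidal diel
cycle; hoppers as monotone step functions at Poisson event times
(~30 drinking, ~12 feeding events/day) with lognormal sizes scaled to
the daily total; injected pathologies at known locations — tiny
(<35 min), fillable (35–60 min) and long (61–335 min) gaps, the 10 %
leakage bias, and optional 25 ml/30 g spill/caching days. "Measured"
body water is the model's own prediction for each mouse's true totals
plus noise: σ(δ¹⁸O) = 0.1 ‰ and σ(Δ′¹⁷O) = 8 per meg applied on the
(δ¹⁸O, Δ′¹⁷O) plane with δ¹⁷O derived, so the δ noise is strongly
correlated between isotopes, as on a real dual-isotope analyzer;
analyzer injections likewise use correlated noise (ρ = 0.9). What
passing tests show is therefore that the pipeline recovers what the
model itself implies under realistic noise and data pathologies — not
that the model is physiologically correct for real animals; circadian
feeding structure, growth, and thermoregulatory physiology beyond the
configured means are deliberately absent. All randomness flows from one
integer seed and regeneration is bit-identical.

Synthetic reference waters stand in for the USGS50/USGS47 pair and the
control set (one enriched, one strongly depleted, five controls
spanning the sample range); their assigned values are fabrications with
the right structure, not certified values.

## Validation pipeline

Per (mouse, sampling time): QC'd window totals → model prediction →
join against measured grand means → per-sample absolute differences,
group and overall MAD ± SD, and a flag at |ΔΔ′¹⁷O| ≥ 30 per meg.
Treatment contrasts use a paired t-test on per-mouse differences
(two-sided by default; one-sided available); a zero-variance nonzero
difference reports t = ±inf rather than an exception. Pooling of the
two cold temperatures and exclusion of duplicate baseline samplings are
configuration lists, not code.

## Problem sizes and numerical choices

Tests simulate 2–8 mice for 4–6 days at the 5-min cadence (~1700
records/mouse-day), sizes at which every stage's behaviour is already
asserted to tight tolerances; round-trip identities hold to 10⁻¹² ‰,
mass-balance closure to 10⁻¹² relative, reference-ratio invariance to
10⁻⁶ per meg. Ties in sensitivity ranks share the competition rank.
Degenerate inputs raise typed errors (non-positive ratios, OUF ∉ (0,1),
unmatched standards, empty joins) rather than propagating NaNs.

## Known limitations

Steady state only: growing, pregnant or lactating animals violate the
closure assumption. The z-value, OUF and the exhaled-CO₂ θ dominate the
Δ′¹⁷O prediction and are the least-constrained inputs; the model's
absolute δ¹⁸O_bw predictions are markedly less reliable than its
Δ′¹⁷O_bw predictions, mirroring the sensitivity table (skin evaporation
rate moves δ¹⁸O_bw by ~5 ‰ across its plausible range but Δ′¹⁷O_bw by
only ~4 per meg). The inhaled-vapour source-pool assignment is a
declared convention, not a measurement.
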