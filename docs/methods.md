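# Methods

## Headspace mass balance

A stream-water aliquot (volume V_w) equilibrates inside an N₂-preflushed
vial (total volume V_v, headspace V_h = V_v − V_w) at temperature T and
total pressure P. GC analysis yields the headspace N₂O mixing ratio x
(nmol mol⁻¹ of moist headspace gas at pressure P). All N₂O in the vial
came from the water, so

    C_obs · V_w / M_N = x·10⁻⁹·P · [ V_h/(R·T) + K₀(T)·V_w ]

with M_N = 28 g N per mol N₂O, R = 0.08205736 L atm mol⁻¹ K⁻¹ and K₀ the
Weiss–Price (1980) N₂O solubility. The moist-air-referenced coefficient
set is the default (appropriate when concentrations are referenced to
atmospheric mixing ratios); the dry-gas K₀ set is selectable. The vial
is assumed chemically inert after preservation (acid/ZnCl₂ additions
have no computational effect), and the equilibration temperature
defaults to the stream water temperature, overridable per sample.

Key properties, all tested: mass conservation to 1e-12 relative,
linearity in x, exact round trip (≤1e-9 relative) against an
independently solved partition equilibrium.

## Saturation and excess concentration

C_eq = K₀(T)·x_atm·P with x_atm = 330 ppb by default (configurable);
%sat = 100·C_obs/C_eq and ΔN₂O = C_obs − C_eq. Records below 100% are
retained everywhere and simply contribute negative excess (net uptake).
Land use is classified at region level (KRY/SES/SRC → forest,
SCA/UPP1/UPP2 → agricultural); the per-site land-use percentages remain
as model covariates only. Seasons follow the meteorological rule
(Dec–Feb winter, etc.), configurable.

The N₂O-N:NO₃-N ratio statistic uses TN directly as the nitrate proxy in
agricultural streams (where nitrate dominates TN) and a fixed nitrate
fraction of TN (default 0.18, the value measured in the one forest
region with nitrate data) in forest streams.

## Upscaling

Annual emission per stream-order × land-use stratum:
E = 365 · ΔN₂O · k_N₂O · A_S, with ΔN₂O in mg N L⁻¹ (≡ g N m⁻³), A_S in
m² and k_N₂O in m day⁻¹ obtained from the stratum's mean k₆₀₀ through
(Sc_N₂O(T)/600)^(−1/2). Defaults, each configurable:

* **Schmidt polynomial**: Wanninkhof 2014 freshwater coefficients
  (N₂O and CO₂); the 1992 sets are included and differ by <5% in k.
* **ΔN₂O pooling**: one pooled mean per land-use class
  (observation-weighted); a per-class × order option exists because the
  survey's saturation varies systematically with stream order.
* **Temperature**: the mean water temperature of the class's survey
  records; a fixed temperature can be configured instead. This choice
  is the dominant sensitivity of the budget (roughly ±15% across
  plausible temperature series, via both Sc and C_eq).
* **Reporting**: totals to 3 significant figures in the ×10⁶ g style;
  percentage shares to the nearest 10%.

The stratum table ships with the package: the non-alpine national
network, orders 1–4, with forest/agricultural water surface areas
(511/144 km² totals) and per-stratum k₆₀₀ mean, median and deciles.

## Monte Carlo uncertainty

Each iteration draws (i) a class mean ΔN₂O as a bootstrap mean of that
class's record-level excesses and (ii) a k₆₀₀ per stratum from a
lognormal matched to the stratum's published mean and p10–p90 ratio
(σ = ln(p90/p10)/2z₀.₉, µ = ln(mean) − σ²/2, so the published mean is
reproduced exactly). Areas and temperatures stay fixed. An outer loop
of repetitions averages the per-repetition 10th/90th percentiles; the
defaults are 10,000 × 10,000 with scaled-down counts (50 × 2,000) used
throughout the tests, where percentile standard errors over repetitions
quantify Monte Carlo noise. A degenerate specification (identical
excesses, p10 = p90 = mean) collapses the interval onto the point
estimate exactly; inverted deciles (p10 > p90) are rejected. Because a
single k₆₀₀ draw represents a whole stratum rather than an average over
its thousands of segments, the intervals are deliberately conservative
(wide); structural uncertainty in the network areas is out of scope.

## Mixed-effects models

ln(%sat) is modelled with fixed effects TN, DOC, pH, % agricultural
land, % wetland and water temperature, and a region random intercept,
fitted by REML (statsmodels MixedLM; BFGS with a Powell retry when the
optimizer returns a non-finite likelihood). Model significance is a
likelihood-ratio test against the intercept-only mixed model using ML
refits. Confidence intervals are normal-approximation (±1.96 SE);
degrees of freedom are reported as n − k because df conventions differ
across mixed-model implementations — estimates, standard errors and
signs are the stable quantities. Predictors enter untransformed and are
screened first with variance inflation factors (reject at VIF ≥ 10;
perfect collinearity reports an infinite, flagged VIF). Group
comparisons (land use, season, stream order) use the same structure
with a categorical fixed effect; pairwise contrasts are Tukey-adjusted
through the studentized-range distribution at the residual df. An AR(1)
within-site residual structure was considered and left out: the
package's surveys are sparse in time per site and the reference
analyses retained their conclusions after residual checks.

## Synthetic survey generator

The generator is the package's test bed and default input. Per region it
draws site-level Strahler orders and land-use percentages, visit-level
dates over the region's sampled months, a cosine seasonal water
temperature (peak July) with noise, barometric pressure ~N(1 atm,
0.012), lognormal TN and DOC, and truncated-normal pH. It then computes

    ln %sat = β₀ + β·x + ln(season multiplier) + ln(order multiplier)
              + b_region + ε,   ε ~ N(0, σ²)

and back-computes C_obs = C_eq·%sat/100 at the drawn temperature,
finally forward-simulating the vial partition so the table carries both
headspace and derived fields. Truth defaults: β₀ = 6.44, β_TN = 0.00023,
β_pH = −0.17 (the published saturation-model estimates, which recovery
tests target), small slopes for the remaining covariates, σ = 0.6,
season multipliers with an autumn peak in forest and a winter peak in
agricultural streams, and order multipliers decreasing (forest) or
increasing (agricultural) with order.

Region effects b_r are, by default, moment-matched so each region's
expected C_obs equals its configured target mean (1.3/1.6/0.8 µg N L⁻¹
for the forest regions, 0.9/2.0/1.4 for the agricultural ones),
conditional on the drawn covariates: b_r = ln(m_r) − σ²/2 − ln(mean of
C_eq·e^{Xβ}/100). This keeps the class-pooled concentration means at
their published values (the quantity the budget depends on) while
leaving the slope structure intact. With `calibrate_regions=False` the
effects are instead drawn N(0, 0.4²), giving a correctly specified
random-intercept model for coverage and type-I-error tests. Lognormal
shapes reflect the strong right skew of the published concentration
ranges; the distributions are univariate per covariate (no explicit
TN–pH correlation within region — between-region contrasts carry that
signal), so the generator emulates the survey's marginal structure and
region/season/order contrasts, not every joint feature of real data.
One emergent caveat: because season multipliers and temperature are
both season-driven, temperature is partially confounded with the
seasonal saturation signal, and its fitted coefficient on calibrated
surveys absorbs some of that seasonal variance — recovery tests
therefore target the chemistry slopes (TN, pH) on uncalibrated,
multiplier-free draws.

Every dataset ships with a JSON truth sidecar (all parameters, realised
region effects, seed); recovery tests read truth only from it. Same
seed ⇒ byte-identical output.

## What reproduction can and cannot show

The acceptance computation regenerates the ~1,000-record survey at the
published per-region means and upscales with the packaged stratum
table. The forest class total lands ~15–25% below the published
1,404×10⁶ g N₂O-N yr⁻¹, within the adopted ±25% reproduction band given
that the original excess-concentration pooling and temperature series
are unpublished. The agricultural total reproduces only to ~60–65% of
the published 380×10⁶ g: the published agricultural concentration
summaries (class mean 1.6 µg N L⁻¹ against an equilibrium of ~0.3–0.44)
bound the class mean excess near 1.2 µg N L⁻¹, whereas the published
total requires ~1.9 over the same k₆₀₀×area — no temperature in 0–20 °C
closes that gap. Intriguingly, expressing the excess in N₂O molecule
mass rather than N mass (×44/28) brings *all* published per-order and
class emissions into ~10% agreement; this package deliberately keeps
the stated N basis throughout. The national total and the ~80% forest
share are less sensitive and reproduce to ~20–25%. Sample sizes
everywhere are the survey's own (986 records; 100 replicates for
recovery; 50×2,000 for scaled Monte Carlo).

## Numerical notes and limitations

* Molar masses are fixed at 28 g N mol⁻¹ and 44 g N₂O mol⁻¹.
* Solubility fits are valid on −0.5–40 °C, Schmidt polynomials on
  0–35 °C; out-of-range temperatures raise rather than extrapolate.
* Salinity is fixed at 0 (fresh water) but remains a parameter.
* Generator temperatures are clipped to [0.2, 26] °C (flowing water),
  pH to [3.5, 9.5]; lognormal draws are floored at small positive
  values.
* CSV I/O is UTF-8, comma-separated, decimal point, header required;
  schema validation rejects negative concentrations, pH outside
  [0, 14] and Strahler orders outside [1, 8] with row numbers.
* Alpine strata (≈6.5% of national stream area) are not represented in
  the stratum table, mirroring its source.
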