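# Methods

## The measurement model

A POC determination starts from a known volume `V` of seawater filtered
through two stacked GF/F filters.  The upper (uPOC) filter retains
particles plus adsorbed dissolved organic carbon (DOC) plus any handling
biases; the lower (aDOC) filter sees the same water and handling but
essentially no particles, so it serves as a per-sample blank.  Both filters
are acid-fumed in a desiccator (removing inorganic carbon), dried, wrapped
in tin capsules and combusted in a CHN elemental analyser, whose response
`x` is converted to a carbon mass through a per-run calibration.

Per CHN run `k`, the calibration `M = m_k x + b_k` is fitted to pre-weighed
acetanilide standards by iteratively reweighted least squares with the
Tukey bisquare weight (the conventional tuning constant, c = 4.685), so a
single mis-weighed standard cannot tilt the line.  Calibration standards
(11, spanning 5–300 µg C) and stability standards (interleaved with the
samples) are pooled for the working fit.  The intercept is dropped, by a
single refit through the origin, when its robust p-value exceeds 0.05 —
pruning is not iterated, and it is applied only to the working fit (see
*Unstable runs* below).  The residual scale `σ_res` is the robust SD
(interpercentile, see below) of the mass residuals.

The uncertainty of a single predicted mass is the half-width of the 68%
prediction interval,

    σ_M = t_{0.84; n_S−2} · σ_res · √(1 + 1/n_S + (x − x̄)² / ((n_S − 1) s_x²)),

which is minimal at the mean standard response and widens towards the ends
of (and beyond) the calibrated range; predictions outside that range warn
rather than fail.

Blank corrections subtract the run's mean tin-capsule carbon and the
acidification increment (mean acidified minus mean non-acidified filter
blank, the acidified blanks taken from the sample's own desiccator):

    M*_uPOC = M_uPOC − M̄_cap − (M̄_ac − M̄_nac),   likewise M*_aDOC.

Because the paired filters share run and desiccator, the correction cancels
in the difference and the POC mass is computed directly as
`M = M_uPOC − M_aDOC`, making the algebraic identity with
`M*_uPOC − M*_aDOC` hold bit-exactly rather than merely to rounding.
Negative masses and concentrations are retained with a flag — clipping
would bias the medians — and filters below the detection limit are flagged,
never dropped.

## Uncertainty estimation

**Robust SD.**  Throughout, spread is measured as half the P84–P16
interpercentile range, with percentiles by linear interpolation between
order statistics (the interpolation rule is a declared choice; nothing
downstream is sensitive to it at the sample sizes used).  For Gaussian data
this equals the SD (z(0.84) ≈ 0.9945); it is insensitive to tails.

**Experimental route.**  Each station contributes one duplicate pair drawn
from the same bottle.  The scaled difference `Δ = (D₁ − D₂)/√2` estimates
the uncertainty of a *single* measurement (the pair's uncertainties add in
quadrature); because `Δ` scales with concentration, the relative difference
`Δ_r = Δ/D̄` is the quantity summarised.  The per-zone, whole-dataset
relative uncertainty is `σ_r = robust SD of Δ_r`, and each sample receives
`σ_C = σ_r·C`.  σ_r is deliberately a per-zone scalar, not a per-sample or
per-station quantity.  Pairs from unstable runs, and pairs with
non-positive mean concentration, are excluded (the latter logged).
Diagnostics report the correlation and fit line of |Δ| and |Δ_r| against
D̄, which show the scaling removed by the normalisation.

**Modelled route.**  Standard propagation of uncertainty gives three
per-sample components: volume (`σ_V = 0.010 L × √n_bottles`, half a
graduation mark per ~2.2 L bottle, so `σ_C(V) = M σ_V/V²`), calibration
(`σ_C(M) = √(σ²_M,u + σ²_M,a − 2 σ_M,u σ_M,a r)/V`) and contamination
(`σ_C(η) = √2 σ_η/V` with `σ_η` the SEM of the desiccator's three
acidified blanks; the uPOC and aDOC filters are assumed equally affected).
The correlation `r` between predicted uPOC and aDOC masses is estimated
empirically within each run (pooled across runs when a run has fewer than
three pairs) and clamped to [−1, 1].

**Budget.**  Relative contributions are `u_x = σ_C(x)/σ_C`.  The
unquantified remainder is reported under two conventions — linear
(`1 − Σu_x`, the budget-table arithmetic) and variance
(`√max(0, 1 − Σu_x²)`) — because shares are ratios of standard deviations
while closure arguments live on variances; the linear one is the default.
A separate `explained_variance_share`, `Σσ_C(x)²/σ_C²`, supports variance
closure checks and may legitimately exceed 1 when the prediction-interval
width over-covers the realised noise.

**Detection limits.**  From the pooled tin capsules of all runs
(`df = N − 1`, ordinary mean and SD — the robust qualifier applies
elsewhere, not here): `L_C = x̄₀ + s₀ t₀.₉₅;df`, `L_D = x̄₀ + 2 s₀ t₀.₉₅;df`.

**Unstable runs.**  In the absence of drift the calibration and stability
standard sets should give statistically indistinguishable coefficients.
Each run's two sets are fitted separately *without* intercept pruning
(pruning folds the intercept into the slope differently for the two mass
ranges and would mimic instability) and their slopes compared by a
Welch-style t-test at α = 0.05; the intercept comparison is available but
off by default.  Flagged runs are excluded from σ_r estimation and from the
reported summaries.  At α = 0.05 an occasional false flag on a stable run
is expected behaviour, not a defect.

## The synthetic cruise generator

The generator emulates the structure of a meridional Atlantic transect:
68 stations between 50°N and 45°S crossing six biogeographical provinces,
six depths in the upper 500 m, one duplicate pair per station (acidified in
a different desiccator), 16 CHN runs each with 11 calibration + 8 stability
standards, 3 capsules, and 3 acidified + 3 non-acidified blanks per
desiccator.  Key defaults and their rationale:

* **True POC field** `C(z) = f_st · (C₀ · g_prov · e^{−z/90 m} + 6 mg/m³)`
  with `C₀ = 26 mg/m³`, province factors 0.75–2.6 (gyres poor, temperate
  provinces rich) and a per-station lognormal factor (sd 0.35).  Chosen to
  put the productive-zone median near ~18 mg/m³ and the mesopelagic median
  near ~7 mg/m³ with realistic spatial spread.
* **aDOC adsorption** `A = 2 µg + 0.06·M`, giving corrected aDOC/uPOC mass
  ratios around 10% and a strong positive aDOC–POC correlation.
* **Blanks**: capsules 2 µg (0.6 µg between runs, 0.4 µg within), clean
  filters +1 µg, acidification contamination +1 µg (sd 0.3 µg each) — the
  non-acidified/acidified blank medians then sit near 3 and 4 µg with
  σ_η ≈ 0.3 µg.
* **Instrument**: slope 2 µg per response unit, intercept 1 µg, small
  per-run jitter, and additive response noise of 0.4 response units
  (≈ 0.8 µg of mass).  The within-run response noise of a CHN analyser is
  not a published quantity; it is a free parameter, set so that σ_M lands
  at the µg scale and the capsule spread stays near 1 µg.
* **Duplicate noise**: every filter's true POC mass is multiplied by
  `(1 + ε)`, `ε ~ N(0, σ_r,zone)` with defaults 0.12 (productive) and 0.35
  (mesopelagic); the factor is floored at 0.05 to keep masses physical,
  which the percentile-based estimator does not feel.  A multiplicative
  model is used because duplicate differences scale with concentration
  while relative differences do not.
* **Volume rule**: `V = clip(40 µg / C_expected, 1–8 L)` rounded to 0.1 L,
  `n_bottles = ⌈V/2.2 L⌉`, with the *true* filtered volume perturbed by
  0.010 L per bottle; the expectation uses the climatological profile
  (the operator does not know the station factor).
* **Unstable runs** (default runs 4 and 12): stability standards generated
  with the slope ×1.3, response noise ×3, samples with a midpoint slope
  drift — enough for the detector's power to be ≈ 1.

One RNG stream per generated aspect (field, calibration, blanks, filters,
duplicates, volumes), all spawned from a single seed, so identical config
yields byte-identical CSV output.

What the generator does *not* emulate: advection and seasonality, real
province ecology, rare-particle patchiness beyond the lognormal duplicate
noise, instrument drift within a stable run, or operator effects.  Passing
tests therefore demonstrate that the estimators recover the stated
generating processes, not that field data obey those processes.

## Numerical and design notes

* Exactly collinear (noise-free) standards short-circuit the robust fit:
  the generating line is reproduced to machine precision and the intercept
  kept iff non-zero, so a zero-noise cruise closes through the entire
  pipeline to < 1e-9 mg/m³.
* The budget-closure property (modelled components explaining ≥ 90% of
  experimental variance when only volume/calibration/contamination noise is
  active) is validated on a spatially *flat* POC field: with a strongly
  varying field the within-run mass correlation — the declared estimator
  for `r` in the calibration component — reflects the spread of true
  masses rather than the correlation of prediction errors and overstates
  the cancellation.  This is a known limitation of estimating `r` from
  mass values; the flat-field test isolates the propagation arithmetic.
* Scenario percent differences (blank-reduction analyses, particle-loss
  correction) are computed per sample and then summarised as median ±
  robust SD; per-sample arithmetic is the only version that supports a
  meaningful robust SD.
* Problem sizes in the validation suite (24-station cruises for unit
  checks, 200 stations for budget closure, 200×500 pairs for σ_r recovery,
  10⁶ draws for the robust-SD oracle) were chosen so each estimate's
  Monte-Carlo error is several times smaller than the tolerance it is
  tested against.
* Cast-time grouping (pre-dawn vs noon collections) is available through
  the generic group keys of `summarise` on the `datetime` column; no fixed
  clock boundary is built in.

## Known limitations

* σ_r for a zone with ~20 duplicate pairs carries a sampling SD of roughly
  20% of its value; single-cruise estimates scatter accordingly.
* The Δ_r ratio estimator has a small positive large-sample bias at large
  σ_r (≈ +2.5% at σ_r = 0.35) because the pair mean in the denominator is
  itself noisy.
* The robust-fit p-values (for intercept pruning and stability testing) use
  the asymptotic RLM covariance, which is mildly anti-conservative for
  8-standard stability sets.
* No spatial/temporal covariance modelling of uncertainties and no
  hierarchical per-station model; σ_r is a per-zone scalar by design.
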