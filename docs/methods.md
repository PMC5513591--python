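# Methods

## The turnover model and its assumptions

The package models a lactating dam and her whole litter as two well-mixed
body-water pools connected by milk. Three first-order rate constants
govern tracer movement: `k_out_dam` (K₀₁, dam → environment),
`k_dam_to_litter` (K₂₁, dam → litter; the milk route) and `k_out_litter`
(K₀₂, litter → environment). K₀₁ excludes milk transfer — the dam's total
elimination rate is λ₁ = K₀₁ + K₂₁ — so that at steady state the absolute
flows balance as R₁₀ = R₀₁ + R₂₁ on the dam side and R₂₀ + R₂₁ = R₀₂ on
the litter side. Milk flow is R₂₁ = K₂₁ × TBW_d.

Assumptions, and where they bite:

- **Steady state of both pools.** Reasonable for the dam (body mass stable
  during established lactation); an approximation for the litter, which is
  growing. The model tolerates this by allowing the litter's non-milk
  input R₂₀ to go negative (flagged with a warning, not an error): a
  growing pool retains water that a strict steady state would excrete.
- **Pooled urine enrichment equals litter body-water enrichment with no
  delay.** Urine is sampled from the body-water pool directly; no bladder
  lag is modelled.
- **Single water pool per animal.** Deuterium exchange with non-aqueous
  hydrogen is not modelled; isotope-dilution pool sizes are therefore
  biased a few percent high relative to desiccation, and milk flow
  inherits that bias multiplicatively.

The closed forms are evaluated in a cancellation-safe `expm1` formulation
so the near-degenerate case K₀₂ → λ₁ is smooth; the exact degenerate point
uses the analytic limit D·K₂₁·t·e^(−λ₁t)/TBW_l. Correctness is pinned to
an independent numerical integration of the mass-balance ODEs (relative
agreement ≤ 1e−8, tracer conservation ≤ 1e−6 in the tests).

## Two-stage estimation

1. **Dam total body water.** OLS of log plasma enrichment on time; the
   exponentiated intercept is the concentration at injection, and
   TBW_d = purity·dose / C(0). The intercept's standard error propagates
   to the mass by the delta method. A log-linear fit is exact for the
   mono-exponential dam curve and nearly unbiased at 1 % multiplicative
   noise; non-positive enrichments (possible after baseline subtraction)
   are excluded with a warning.
2. **Rate constants.** Levenberg–Marquardt minimisation of
   Σ((yᵢ − ŷᵢ)/(cv·ŷᵢ))² over {K₀₁, K₂₁, K₀₂} jointly on the plasma and
   urine series. Weighting by the *predicted* value each iteration
   (iteratively reweighted, constant CV) matches a fractional-standard-
   deviation error model; `cv` defaults to 0.01 (FTIR ≈ 1 % relative
   error). Parameter SDs come from the covariance of the converged fit
   (chi-square–scaled), CVs as 100·SD/estimate.

Numerical choices: starting values K₀₁ = ln 2/24 ≈ 0.0289 h⁻¹
(a 24 h water half-life), K₂₁ = 0.01 h⁻¹, K₀₂ = 0.02 h⁻¹, which bracket
the plausible range; box bounds [1e−5, 1] h⁻¹ keep the rates physiologic
and positive; on a failed first attempt a 3×3×3 multiplicative multi-start
grid (×0.3/1/3 per rate) is searched and the best converged fit kept.
Non-convergence yields a flagged result (`converged=False`), excluded from
group summaries with a notice, never an exception. A parameter landing at
a bound raises a warning.

**Fixed vs free pools.** TBW_d is fixed from stage 1 (the fit then has
exactly three unknowns); TBW_l is fixed at 0.76 × litter mass, the rounded
combined median body-water fraction. Both can be freed
(`co_fit_tbwd`, `free_tbwl`) as sensitivity modes, but freeing TBW_l is
structurally weakly identified: the dam curve constrains only λ₁ and the
litter amplitude only K₂₁/TBW_l, so the four-parameter fit rides a ridge —
it reproduces the data and the identified combinations without unique
per-parameter values. This is why fixing the litter pool is the default,
and the test suite asserts exactly the identified quantities in that mode.

## Statistics

Kinetic and growth endpoints (n = 4–6 per group) use an exact two-sided
Mann-Whitney test: the p-value is the proportion of all C(n₁+n₂, n₁)
group assignments of the observed pooled values whose U lies at least as
far from n₁n₂/2 as observed. The implementation convolves over doubled
mid-ranks — algebraically identical to literal enumeration (the tests
verify this against a brute-force oracle) but O(n³·Σranks) instead of
combinatorial. Ties are handled naturally because enumeration operates on
the data's own mid-ranks; with heavily tied (e.g. noiseless synthetic)
data the attainable levels differ from the untied 2/C(n,k) ladder, which
is correct behaviour, not error. Pooled sizes above 25 fall back to the
tie-corrected normal approximation, flagged in the method label.

The WSW endpoint uses Welch's t with Welch–Satterthwaite degrees of
freedom, the replication unit being the litter (production is a per-dam
quantity; a per-pup reading of the sample size would pseudo-replicate).
Summaries are median/quartiles (linear interpolation — conventions differ
and one had to be chosen) with [min; max], matching small-sample practice.
Day-by-day WSW tests are reported raw, with no multiplicity correction.

## The synthetic generator: what it emulates, and what it does not

`generate_study` draws per-dam parameters from lognormal distributions
(median-parameterised, so group medians are preserved exactly) and pushes
them through the closed-form curves and the WSW session arithmetic:

| parameter | default | note |
|---|---|---|
| dose rate | 5 g/kg, purity 0.999 | reference protocol |
| plasma / urine times | 3/24/48/72 h, 24/48/72/96 h | reference schedule |
| measurement CV | 1 % multiplicative, truncated at 0 | FTIR error |
| baseline | 155 ppm, added then subtracted | exercises the correction path |
| NP group | n=4, mass 337.7 g, TBW 76.9 %, K₂₁ 0.01223 h⁻¹ | study medians |
| LP group | n=5, mass 308.3 g, TBW 72.9 %, K₂₁ 0.00980 h⁻¹ | study medians |
| K₀₁, K₀₂ centres | 0.012, 0.020 h⁻¹ | **assumptions** — not reported quantities; chosen so the dam water half-life (~28 h) keeps all scheduled samples informative |
| between-animal CV | 10 % rates, 5 % masses | chosen to give Table-1-like [min; max] spans |
| litter | 8 pups, 25 g each (5 % CV), water fraction 0.76 | PND-11-scale pups |
| WSW | PND 11–14, 1 h bouts, noise SD 1.5 g, weights on a 0.01 g grid | spread comparable to observed WSW SDs |

`inject_suckling_losses` subtracts a constant loss rate × duration from
each session's gain, reproducing the documented downward bias of WSW
(a loss rate of f/(1+f) × true flow makes the tracer method read a
fraction f higher than WSW; f = 0.24 reproduces a 24 % gap).

What the generator does **not** emulate: a growing litter pool (the
near-steady-state assumption is baked in, matching the analysis model —
so recovery tests cannot detect bias from litter growth), circadian or
day-to-day variation in milk flow, tracer recycling from pups back to the
dam (pup saliva/urine ingestion), deuterium exchange with non-aqueous
hydrogen, or assay drift. Passing recovery tests therefore demonstrate
estimator correctness *under the model*, not robustness to these
real-data violations. One deliberate mismatch is retained: the synthetic
median product K₂₁ × TBW_d (0.01223 × 0.769 × 337.7 ≈ 3.18 g/h) is a few
percent below the observed median milk flow of 3.30 g/h, because the
observed dam-mass and TBW medians come from different margins of the same
animals; the generator keeps the stated medians rather than retuning them.

## Design choices that were genuinely open

- **Two-stage TBW_d** (fixed from the intercept) rather than co-fitting:
  keeps the fit at three unknowns and makes the dilution step auditable on
  its own; co-fitting remains available as a config flag.
- **Degenerate-case handling** via `expm1` rather than branching on an
  epsilon: continuous to machine precision across K₀₂ = λ₁.
- **Exact-test definition** of the two-sided p as the symmetric-distance
  tail count: for untied data it coincides with the classical doubled
  one-tail exact p, and it remains well-defined under ties.
- **Whole-litter weighing** as the canonical WSW input; per-pup records
  should be summed on ingest. The estimator is algebraically independent
  of litter size given the litter total.

## Problem sizes

Default verification sizes: 100 replicates for the single-dam parameter
recovery study, 15 studies for the two-group separation check, 200 draws
for Monte-Carlo median checks, 2000–4000 sessions for WSW unbiasedness.
These give Monte-Carlo error comfortably below the tolerances asserted
while the full suite runs in a few seconds.

## Known limitations

- Milk-flow SD propagates K₂₁'s uncertainty only; TBW_d is treated as
  fixed in that product, so the reported SD slightly understates the
  total.
- The exact Mann-Whitney is limited to pooled n ≤ 25 before switching to
  the normal approximation.
- No mixed-effects/population kinetic modelling: fits are strictly per
  dam, summarised by group medians.
- Intercept-based TBW needs ≥ 2 strictly positive enrichments; with
  exactly 2 the standard error is reported as 0 (no residual degrees of
  freedom).
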