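# Methods

This note records the statistical model, the default parameters and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical design decisions.

## Model

### Intensity

A disturbance's intensity return period is the inverse of the annual
occurrence probability of a force value at least as harmful as the one
observed.

- **Aggregate force measures** (seasonal mean temperature, rainfall
  totals): the annual values are treated as i.i.d. and fitted with a
  normal law. If a Shapiro–Wilk test rejects normality of the raw values
  at α = 0.05 but not of their logarithms, a lognormal law is used
  instead. If both are rejected, no distribution is admissible and the
  estimate is refused — silently picking a worse-fitting law would bias
  the x-axis of everything downstream.
- **Extreme force measures** (annual maxima or minima such as peak
  significant wave height): a generalized extreme value (GEV) law fitted
  by maximum likelihood, the standard asymptotic family for block
  extremes with one-year blocks. Minima are negated and fitted as maxima.
- **Historical evidence** (events too rare for an instrumental series):
  return period = record length / number of recorded events.

The harmful tail is declared per measure; exceedance probabilities are
always taken in the harmful direction.

### Severity

For one population, annual log-abundance growth rates
r(t) = ln N(t+1) − ln N(t) are classified as the single
disturbance-year rate r_pd or as normal-condition rates r_n. Excluded
from the normal pool are years flagged for other known stresses and a
post-event recovery phase, removed by an iterative filter: while the
post-event abundance–year OLS regression is significant at α = 0.05 and
at least three points remain, drop the oldest post-event year. The
filter mirrors the intuition that a directional recovery trend is not
"normal variability"; when it exhausts the data the remaining two points
are retained untested, with a warning.

The effect size is the single-case standardized difference
ES = (r_pd − mean(r_n)) / sd(r_n) (sample sd, ddof = 1). Uncertainty is
a bias-corrected (BC) percentile bootstrap: resample the normal rates
with replacement (r_pd fixed), recompute ES, and correct the percentile
interval for median bias. Severity return period = 1 / Φ(ES).

### Meta-regression

Each event × species record contributes a point
(x, y) = (log₁₀ intensity RP, log₁₀ severity RP). After an inclusion
filter (intensity RP ≥ 20 years, so the event is rare relative to the
populations' dynamics; generation time 1–10 years, so annual censuses
resolve the response; spatial extent ≥ 10 km², so the event is a
population-scale press rather than a local accident), the mean of y is
modelled as a GLM in x. Candidates are {gaussian, gamma} ×
{identity, log}; the default and scientifically motivated choice is
gamma/log — the response is positive and right-skewed, and the log link
makes the mean curve exp(β0 + β1 x), whose intersection with the
identity line defines the crossover. AIC selects among candidates, BIC
is reported, and disagreement is flagged rather than resolved.

## Parameter defaults and rationale

| Parameter | Default | Rationale |
|---|---|---|
| Shapiro–Wilk α | 0.05 | conventional level; gates normal vs. lognormal |
| trend-filter α | 0.05 | conventional level; controls recovery removal |
| bootstrap iterations | 10 000 | percentile endpoints stable to ~0.01 at this size |
| bootstrap level | 95 % | conventional |
| inclusion: intensity RP | ≥ 20 yr | excludes events frequent on a population timescale |
| inclusion: generation time | 1–10 yr | annual censuses resolve the demographic response |
| inclusion: spatial extent | ≥ 10 km² | excludes local accidents |
| GLM candidates | {gaussian, gamma} × {identity, log} | positive skewed response; log link defines the crossover |
| zero nudge | 10⁻⁶ | gamma support requires y > 0; a 1-year severity RP gives y = 0 exactly |

The severity map 1/Φ(ES) assumes the normal-year rates are approximately
normal. A `small_sample` option replaces Φ with a t-distribution
(n − 1 df and an (n+1)/n variance inflation) for very short normal
records; it is off by default because the plain map is the framework's
defining equation and the t variant is strictly more conservative.

## The synthetic-data generator

`disturbkit.synthdata` simulates whole studies with known ground truth.
Defaults: 27 events, 50 species series of 30 annual censuses, intensity
return periods log-uniform on [20, 1000] years, and a true mean curve
exp(β0 + β1 x) with β1 = 1 and β0 = ln 1.8 − 1.8, which places the
up-crossing at x = 1.8 (≈ 63 years). These sizes are the package's own
choice of a realistic study shape: a few dozen events, ~50 usable
series, multi-decade spans.

Per series, log abundance follows a random walk with i.i.d. N(0, 0.2)
annual increments, except across the disturbance year, where the
increment is exactly mean + ES·sd — the inverse of the effect-size
standardization, so the injected ES is the estimand by construction.
Multiplicative lognormal observation noise (log-sd 0.05) is added to
each census. A Student-t option for the increments probes robustness to
heavy tails.

Events with true return period > 200 years are generated as historical
records (the return period is then known exactly, as it would be from a
long documentary record); climatic events get a 100-year instrumental
force series and the event value at the matching quantile. This split
mirrors real studies and also controls the errors-in-x problem: return
periods of several hundred years cannot be estimated accurately from a
few decades of instrumental data, and the resulting x-noise attenuates
the fitted slope.

What the generator does **not** emulate: density dependence, spatial
structure, observation error correlated across species, census gaps,
multi-year disturbances, and model misspecification of the force laws.
Recovery of the injected parameters therefore tests the estimators, not
robustness to every real-world complication (the heavy-tail option
excepted).

## Numerical design decisions

- **AIC/BIC from one likelihood.** Both criteria are computed from the
  same log-likelihood with k = 3 (intercept, slope, dispersion), so
  BIC − AIC = k(ln n − 2) exactly; library-specific variants are not
  mixed.
- **Prediction bands contain confidence bands.** The base PI is the
  response quantile (gamma or gaussian) at the fitted mean and Pearson
  dispersion; it is then widened elementwise to contain the mean CI so
  that coefficient uncertainty is never understated and CI ⊆ PI holds
  pointwise, including under extrapolation.
- **Crossover roots.** exp(β0 + β1 x) − x is positive as x → 0⁺ for any
  admissible fit, so a convex mean curve meets the identity at a
  down-crossing before the ecologically interesting up-crossing. The
  crossover op returns the smallest positive root per its contract, and
  `CrossoverResult.roots` lists every root (grid scan + Brent refinement
  to 10⁻¹⁰) so summaries can report the up-crossing too. When AIC
  selects a non-log link, the pipeline still reports the crossover from
  the canonical gamma/log fit, since the quantity is defined only under
  the log link.
- **Batch drop policy.** In a multi-event run, an event whose force
  series fails both Shapiro–Wilk gates is dropped with a logged reason
  rather than aborting the study — at α = 0.05 and ~27 events this
  happens by multiple testing alone about once per study even when every
  series is truly normal. The single-event CLI keeps the hard error.
- **Degenerate bootstrap resamples.** A resample with all values equal
  has sd 0 and an undefined ES; such resamples are redrawn. Detection is
  "all values equal", not sd == 0, because identical floats can give
  sd ≈ 10⁻¹⁷ through round-off and an ES of ~10¹⁶ instead of an error.
  If more than 15 % of resamples are degenerate the interval is refused:
  three distinct rates have an irreducible all-equal probability of
  1/9 ≈ 11.1 % (so n = 3, the smallest enumerable case, stays
  computable), while two rates (50 %) fail.
- **Reproducibility.** All stochastic stages take explicit seeds;
  derived seeds are drawn as integers below 2³¹. Floating-point output
  is fixed to 12 significant digits, so identical seeds give
  byte-identical files.
- **Extrapolation.** Band grids outside [0, max observed x + 1] trigger
  a warning; the bands are still computed, since the crossover often
  lies near the edge of the observed range.
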