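# Methods

## Classification trees and Δ+

A catalog row carries the four ranks in routine use for millipedes (order,
family, genus, species). Sub-ranks are rejected at parse time rather than
silently dropped: they are applied too inconsistently across groups for a
rank-based distance to mean the same thing everywhere. Duplicate
(order, family, genus, epithet) paths are an error, not a warning —
synonymy resolution is out of scope, and silently deduplicating would hide
data problems.

The tree places every species at depth four below the class root with four
equal inter-rank steps, scaled so the maximum species-to-species path is
`max_path` (default 100). The distance ω between two species is the summed
step length up to their lowest shared taxon: congeners 25, confamilial 50,
con-ordinal 75, cross-order 100. This "ascend-only" convention is fixed
because it reproduces the two boundary values any published table of this
kind prints — a two-congener order scores Δ+ = 25 and a singleton scores 0
(the singleton convention; there are no pairs to average, and 0 is what such
tables print). Variable step lengths (e.g. proportional to the drop in taxon
counts between ranks) are available via `step_lengths` but off by default:
published analyses rarely state which variant they used, and the equal-step
form is the canonical one.

Δ+ is computed by binning pairs at the rank where they split (genus, family,
order multiplicities), which is O(s) instead of O(s²); the test suite holds
it to an explicit double-loop oracle at 1e-9 on random catalogs. Species
without a family are pooled into a single `INCERTAE_SEDIS_<order>` family
per order *before* tree construction, making them mutually confamilial —
pooling deliberately deflates average distance, the conservative direction
when the alternative is inventing singleton families that would inflate it.

The Δ+ vs log₁₀(s) regression is ordinary least squares; groups with fewer
than `min_species` = 4 species are excluded by default (a two-species group
pins Δ+ at a single pairwise value and would act as pure leverage).
Overlay groups are placed against the fitted line without refitting;
|residual| ≤ 0.5 Δ+ units counts as "on" the line, a band wide enough to
absorb table-rounding noise in published Δ+ values (printed to 2 decimals)
yet far smaller than any residual of scientific interest on a 0–100 scale.

A caveat on replaying published tables: no single equal-step convention can
reproduce every printed per-order Δ+ simultaneously (e.g. a within-order
value of 96.7 exceeds the 75 ceiling implied by the same convention that
yields 25 for a two-congener order). Published within-order values were
evidently computed with distances spanning more of the hierarchy than the
order subtree alone. The bundled reference tables therefore carry the
*printed* per-group values, and the regression/overlay stages are replayed
from them; the tree pipeline computes Δ+ under the declared convention for
user catalogs.

## Productivity (x-intercept) estimator

Points are (C_{t−1}, d_t) from the second year of the record onward. The
declining phase is found from the *local slopes* of a degree-1 tricube
local-linear smooth (span 0.75 of points by default): the start index is the
beginning of the maximal trailing run of negative smoothed slope, i.e. the
last +→− sign change that persists to the end of the record. The smoother is
written in-package because the detection rule needs the fitted local slopes,
not just smoothed values. A record whose smoothed slope does not end
negative has no declining phase and is a hard error — extrapolating a rising
productivity curve to an x-intercept is meaningless. A calendar-year
override is provided because analysts sometimes fix the window by historical
judgement rather than by the detector.

The 95% CI is a percentile bootstrap (default 2,000 resamples, seeded) over
the (C, d) points of the analysis window. Resamples with nonnegative refit
slope or zero predictor variance carry no finite x-intercept and are
discarded; their count is retained in the estimate notes. An estimate below
the observed described total is possible (a steep late decline) and is
flagged rather than rejected. The estimator is exact on a noiseless linear
decline by construction, which the suite asserts to 1e-6.

## Bayesian NHPP estimator

Model: d_t ~ Poisson(N·[F(t+1; m, s_c) − F(t; m, s_c)]) with logistic F;
parameters sampled as (log N, m, log s_c). Priors: N log-uniform on
[observed total, 50× observed]; m ~ Normal(mid-record, 100 yr);
s_c ~ Half-Normal(50 yr). This is the minimal thinned-renewal instantiation
that supports both a finite-asymptote fit and an honest failure mode on a
record with no asymptote. Era-varying effort lives in the *generator* (the
thinning), not the default likelihood — fitting constant effort to a thinned
record is precisely the mismatch a user of such models faces, and the worked
example shows the resulting mild downward bias.

Sampling is Haario-style adaptive Metropolis: during burn-in a global scale
is tuned toward ~30% acceptance and the proposal covariance is the empirical
covariance of the chain history (2.38²/d scaling); after burn-in the
proposal is frozen. Defaults: 4 chains × (1,000 burn-in + 2,000 kept).
Full-covariance proposals matter here because on weakly identified records
the posterior is a ridge in (log N, m): only N·exp(−m/s_c) is determined by
a still-accelerating record. Convergence is checked with split R-hat
(arviz) on all three parameters, error above 1.1 — but only for fits that
claim a finite estimate; on flagged no-asymptote fits the ridge coordinates
are not jointly identified, mixing diagnostics along the ridge are
uninformative, and the flag itself is the result.

**No-finite-estimate flag.** The fit refuses a point estimate when more than
5% of posterior N mass lies above the geometric midpoint of the prior range
(≈7× the observed total at the default cap). Rationale: on a no-asymptote
record the posterior runs flat-in-log-N along the ridge toward the prior
cap, so any reported quantile would move if the arbitrary cap moved —
cap-sensitivity is the operational meaning of "the data cannot bound total
richness". A mass-at-the-very-top criterion (e.g. the top 1% of the prior
range) cannot detect this regime: a log-flat ridge puts ≤~1% of mass in any
1% slice by construction, and the midpoint prior tilts mass below the cap.
The two regimes separate cleanly in simulation (well-identified post-peak
fits: 0.000 mass above the cut; pre-peak fits: 0.55–0.85).

Forecasts draw, per posterior sample, a Poisson total with mean
N·[F(horizon+1) − F(last+1)] and report the median and 2.5/97.5 percentiles.
They remain valid under the flag: near-term output depends on the locally
identified rate, not on a bounded N.

## Ratio extrapolation

estimate = round(ref_global/ref_region, 2) × target_region. The ratio is
rounded to two decimals *before* multiplying, matching how such ratios are
conventionally reported and making printed products exactly reproducible.
No interval: the method is a deliberate back-of-envelope cross-check.

## Geography

Regressions are OLS on untransformed predictors by default (log-predictor
optional). The tropical stratum is percent_tropical ≥ 50, consumed as an
input column — no GIS is performed. The Welch t-test uses scipy's
unequal-variance form with Welch–Satterthwaite df. Named exclusions (e.g.
population outliers) must all exist in the dataset; nothing is dropped
silently. Species recorded from k countries count once in each of the k
countries' totals: per-country totals measure description effort, not a
partition of species, so they need not sum to the catalog's species count.

## Synthetic generators

*Catalogs*: species→genus, genus→family and family→order allocations are
independent two-parameter Pitman–Yor draws (probability of founding a new
taxon ∝ concentration + discount·k). Two parameters are necessary: a
one-parameter CRP cannot jointly match a ~68% fraction of ≤2-species genera
and ~4 species per genus, the imbalance observed in real millipede data.
Defaults (concentration 70, discount 0.45 at the genus step) land near both
targets at S = 3,000; the calibration surface brackets both, which the suite
asserts from opposite parameter corners.

*Histories*: each of N species draws a latent description year from
logistic(midpoint, scale); years inside the record are retained with the
era's effort factor in [0, 1] (thinning); everything else stays latent, so
described + latent = N exactly and estimator truth is exact, never
approximate. Default year range 1758–2007 (the span of the real catalog the
generator emulates).

*Country tables*: log-normal areas and populations; species ~
Poisson(exp(intercept + 0.5·log area + tropical effect + Normal noise));
zero-species countries dropped, matching the admission rule.

What the generators do **not** emulate: synonymy and taxonomic revision
(catalog sizes only grow), autocorrelated effort (wars are the only
structure), spatial ranges (country lists are random). Passing tests
therefore show the estimators are correct *under the stated model*, not that
real catalogs satisfy that model — the worked example's NHPP bias under
unmodelled thinning is the canonical illustration.

## Problem sizes and numerics

The suite's parameter-recovery checks use 20 replicates of N = 5,000
histories with 3 chains × (800 burn-in + 1,500 kept) per fit, and a 15,000-
species history for the productivity check — sizes at which the sampled
posteriors are stable across seeds. All stochastic operations take explicit
seeds; nothing reads global RNG state. Bootstrap and MCMC replicate counts
are configurable everywhere. Degenerate inputs (single-year series, all-zero
counts, zero predictor variance, empty strata) raise informative errors
rather than returning NaN.
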