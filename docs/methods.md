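# Methods

`numberline` analyses 0–100 number-line estimation (NLE) data from a
touch-screen task in which adults place two-digit Arabic numerals on a
1000-px line shown horizontally or vertically. The package covers the
full path from raw touch pixels to the model-based left-digit-effect
estimates, plus a generator that produces synthetic cohorts with the same
statistical structure.

## Preprocessing

The line spans axis coordinates −500 … +500 px, i.e. 10 px per
number-line unit. A touch is converted to a *placing position* on the
0–100 scale and direction-normalised: participants choose which end of
the line is the "small" end, so lines used in descending direction are
numerically turned around (position ↦ 100 − position). Horizontal and
vertical lines share one code path through a generic axis/off-axis
coordinate pair.

Exclusion rules, applied per response:

1. **timeout** — no response within the 2500 ms window; the trial carries
   no coordinates and is repeated at the end of its block;
2. **off the line axis** — the along-line coordinate lies beyond either
   line end;
3. **perpendicular deviation** — the off-axis coordinate deviates from
   the line by strictly more than 150 px.

Exclusion fractions are reported relative to all recorded touch
responses; timeouts are not part of that denominator (the deposit's
convention is not stated, so the package fixes one and reports raw
counts alongside). Exclusion is idempotent.

Line direction per participant × orientation is inferred from the sign of
the correlation between targets and touched axis coordinates (at least 10
usable trials; fewer flags the participant for manual review). A
sliding-window correlation (window 25 trials) flags direction switchers —
one window above +0.5 and another below −0.5 — who are removed before
analysis. The study protocol reports chosen directions but no inference
rule; the correlation rule is this package's choice, robust to noisy but
task-compliant responders.

## Bias metrics and omnibus tests

*Positioning bias* is placing position minus the target's true position;
*absolute positioning bias* takes absolute values per trial first
(equivalent to percent absolute error). Trial values are averaged within
participant × line dimension before any group statistic; all inference is
participant-level.

The omnibus analysis is a mixed ANOVA (between: language; within:
dimension), computed through `pingouin` and cross-checked in the tests
against a textbook sums-of-squares decomposition. Effect size is
generalized eta-squared (Olejnik–Algina), with a 90% CI by noncentral-F
pivot: the effect size is converted to the F value it implies,
noncentrality limits are solved from the noncentral-F CDF, and mapped
back through λ/(λ + df1 + df2 + 1). Pivoting on the implied rather than
the observed F keeps the interval on the generalized-eta-squared scale
and bracketing the point estimate; the interval collapses to [0, point]
for effects below the central lower quantile. A two-level within factor
needs no sphericity correction (Greenhouse–Geisser ε ≡ 1). Follow-up
contrasts compare language marginal means (participants averaged over
dimensions) with the studentized-range (Tukey HSD) adjustment on a pooled
one-way error term.

t-tests are Welch (independent groups; Welch–Satterthwaite df), paired,
or one-sample, all through `scipy.stats`. Cohen's d uses the pooled SD
for independent groups and the SD of the differences for paired and
one-sample tests; zero-variance inputs are flagged degenerate and handled
by convention (p = 1 when means agree). Significance threshold: 0.05.

## Intra-decade slopes (inversion effect)

Within each decade from 20 to 90, placing positions are regressed on
targets per participant (trial-level OLS, both orientations pooled — with
equal responses per target this equals target-mean-weighted OLS).
A slope of 1 is veridical; < 1 means the unit digit is underweighted.
Teens are excluded from the group tests because English teen number words
are themselves inverted. Decades with fewer than two distinct responded
targets are skipped, not imputed. Per-participant slopes are averaged
unweighted across decades; group comparisons are Welch tests — German >
English and German > Mandarin one-tailed (the inversion-effect
prediction), English vs Mandarin two-tailed.

Slopes are invariant to a constant shift of all placing positions, and on
noise-free model-generated data they are a deterministic, strictly
increasing function of the unit weight δ at fixed curvature β (verified
numerically over a δ grid).

## Pair analyses

* **Inverted pairs**: the 17 digit-reversal pairs with both members > 20.
  Placing positions are averaged per target within participant first;
  pair distances |mean(large) − mean(small)| are then averaged unweighted
  over pairs. For a veridical responder this equals 477/17 ≈ 28.06 units.
  Group test: one-tailed Welch, German < English.
* **Teens vs twenties**: per-participant mean bias over 13–19 vs 23–29;
  one-tailed paired t (teens relatively overestimated) plus one-sample
  tests of each decade's bias against 0.
* **Decade difference scores**: for stimulus pairs straddling a decade
  break — default (19, 21), (29, 31), (39, 41), (89, 91), the adjacent
  printed pairs with true distance 2; configurable — placed distance
  minus true distance, averaged per participant; positive values indicate
  boundary exaggeration (left-digit effect). Zero for any affine
  responder with unit slope.

## Cyclical power model

For a target x = x_d + x_u (decade part, unit digit), the transformed
magnitude is s = x_d + x_u^δ and the predicted placement is

    y = (s − LB)^β / ((s − LB)^β + (UB − s)^β) · (UB − LB) + LB

with segment bounds (0, 50) / (50, 100) chosen by the raw target value in
the two-cycle structure, or (0, 100) in the one-cycle structure. β > 0 is
the curvature index (β = 1: linear), δ = 1 is veridical unit weighting
and δ < 1 a left-digit bias. The closing factor is the half-range
(UB − LB) per segment: this is the unique reading that makes β = δ = 1
the identity and keeps predictions inside [0, 100] with fixed points at
the segment midpoints (25, 75). The language modifier λ gives a
comparison group its own effective unit weight δ_eff = δ + λ·L (L = 0
reference, 1 comparison); a λ significantly different from 0 is the
evidence that the unit digit's contribution is language-specific.

Model input is the median placing position per (language, target) over
targets > 20, pooled across all responses of all participants and both
orientations (each participant contributes eight responses per target, so
no response-level outlier trimming is applied). A
`per_participant_first` switch computes participant medians first and
takes the group median of those; pooled is the default as the group-level
curves are group aggregates.

Fitting is nonlinear least squares over the stacked group medians with
shared β and δ, starting values β = 1, δ = 1, λ = 0. β > 0 is enforced by
optimising log β and reporting natural-scale SEs via the delta method.
The trust-region solver runs with box bounds (log β ∈ [ln 0.01, ln 100],
δ, λ ∈ [−5, 5]) and tolerance 1e−10 on the residual norm; parameters
driven to a bound are flagged, since estimates there mean the model
cannot represent the data (see limitations). SEs come from the Jacobian
at the optimum, t = estimate/SE with n − k residual df, p two-sided.
If an optimizer excursion pushes s past a segment boundary (possible only
for δ_eff ≳ 1.09) it is clamped just inside with a diagnostic counter.
Cycle structures are compared by Gaussian BIC, n·ln(RSS/n) + k·ln(n).

## Synthetic cohorts

The generator reproduces the session design: 50 printed targets × 4
repetitions per orientation (400 experimental trials) plus training
trials (70, 30, 50) before each block; quasi-randomized order in which
consecutive targets never share a unit digit and differ by ≥ 10
(randomized greedy with restarts, deterministic per seed); timed-out
trials re-queued at block end, where the adjacency constraints may be
violated as in the real procedure.

Responses are drawn from the two-cycle model: latent position =
prediction under the group's (β, δ) + a group-level bias offset +
Gaussian trial noise on the 0–100 scale, clipped to the line, then
emitted as integer touch pixels under the participant's sampled line
direction (ascending with probability 0.98 horizontal / 0.80 vertical,
matching the observed direction choices). Perpendicular touch scatter is
N(0, 40) px, so a realistic small fraction of responses violates the
150-px rule. RT is a base plus a distance-to-anchor term (anchors at the
midpoint and upper end) purely so RT summaries have structure; no claims
attach to it.

Default group parameters follow the fitted study values: β = 0.9
everywhere; δ = 0.87 (German), 0.83 (English), 0.59 (Mandarin); bias
offsets −1.5/−1.6/−2.8 units (Mandarin underestimates most); trial noise
5 units; group sizes 80/78/76. Pixel emission quantizes positions to 0.1
units.

What the generator does *not* emulate — and hence what passing tests do
not show about real data:

* **The bias offset is outside the model's span.** Real NLE
  underestimation is not uniform across targets; the generator's additive
  offset is. Because the power model has no intercept, fitting it to
  offset-shifted synthetic data biases δ̂ downward and, for large offsets,
  drives λ̂ toward the x_u^δ → 0 plateau (caught by the bound flag).
  Parameter-recovery checks therefore run at zero offset; slope and pair
  analyses are shift-invariant and unaffected.
* **Model-implied slopes are steeper than empirical ones.** Real
  responders produce intra-decade slopes around 0.66–0.89 while data
  generated exactly from the model at the fitted (β, δ) imply flatter
  slopes (≈ 0.3–0.7): the model is a group-curve summary, not a complete
  trial-level response theory. The generator preserves the group
  *ordering* (German > English > Mandarin), which is what the slope tests
  assert.
* No per-participant parameter heterogeneity, sequence effects, or
  strategic anchoring beyond the model curvature.

## Numerical choices

* Median of an even number of responses: midpoint of the central pair.
* OLS slopes via `numpy.polyfit`; undefined slopes omitted.
* Noncentral-F pivot solved by bisection/brentq to 1e−10.
* Exclusion boundary is strict (exactly 150 px off-axis is retained).
* All randomness flows from `numpy.random.Generator`; cohort generation
  derives per-participant seeds from the master seed via `SeedSequence`,
  so a fixed config reproduces a dataset byte for byte.

## Problem sizes

The test suite exercises parameter recovery on 20 replicate cohorts of
80 participants per language at trial noise SD 3 (the package's recovery
benchmark), design validity over 100 seeds, and smaller 3–5 participant
cohorts elsewhere; the reproduction script uses study-sized groups
(80/78/76).
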