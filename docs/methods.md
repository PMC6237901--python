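# Methods

## The psychometric model

The response model is a 4-parameter logistic psychometric: the probability
of a category-2 response at continuum step `x ∈ {1..7}` is

    ψ(x) = γ + (1 − γ − λ) · S(x; m, w),
    S(x) = 1 / (1 + exp(−2·ln(19)·(x − m)/w)).

`m` is the threshold (category boundary), `γ` and `λ` are the deviations of
the lower and upper asymptotes from 0 and 1 (interpreted as lapse rates),
and `w` is the width, defined as the stimulus interval over which the
unscaled sigmoid rises from 0.05 to 0.95 — the convention of standard
psychometric toolboxes. Under this convention the slope of the full curve
at threshold is `(1 − γ − λ)·ln(19)/(2w)`, which makes width and slope
mutually convertible. Slope is the analysis quantity throughout, in units
of probability per continuum step.

Trial counts at each step are binomial in ψ, independent across steps; a
block contributes 10 trials at each of 7 steps.

## Bayesian fitting on a grid

The posterior is evaluated on a dense product grid with independent priors:

- threshold: uniform on [−2, 10] (the stimulus range widened by 50% per
  side), 41 uniformly spaced nodes by default;
- width: uniform on [0.5, 18] (half the step spacing up to three times the
  stimulus range), 41 nodes. The nodes are *geometrically* spaced with
  trapezoid-rule masses: the prior stays flat, but small widths — where the
  slope functional varies fastest — are properly resolved. A uniformly
  spaced width axis at this resolution produces several-percent
  discretization bias in slope;
- asymptotes: γ and λ each uniform on [0, asym_max] with 21 nodes;
  `asym_max = 0` collapses both axes to a point and reproduces the
  traditional 2-parameter fit.

Point estimates of m, w, γ and λ are marginal posterior means. The reported
slope is the **posterior geometric mean** of the slope functional
(equivalently `exp E[log slope]`, the Bayes estimator under squared
log-scale error). Slope is a positive scale-like quantity whose posterior
is strongly skewed by the `1/w` transform: the arithmetic posterior mean
overshoots by ~7% and the plug-in slope at the mean parameters undershoots
by ~14% at a representative operating point (true slope 0.66, 5% lapses,
70-trial blocks), while the geometric mean is nearly unbiased there. The
posterior-predictive mean curve `ψ̄(x)` at each step is retained for
held-out likelihood scoring.

Calibration of the slope estimator against truth (70-trial blocks, 5%
lapses, asym_max 0.1): essentially unbiased for true slopes up to ~0.8,
then progressively attenuated (≈0.73 of truth at slope 1.0, ≈0.5 at 1.5).
The attenuation is an information limit of the design, not of the
estimator: with steps spaced one unit apart and 10 trials per step, the
likelihood is nearly flat in width below the step spacing (steep curves
rise between adjacent steps, and endpoint errors can be carried by either
the width or the asymptote parameters). Unconstrained maximum-likelihood
fitting does not escape the limit — it explodes upward instead (×1.4–1.9),
which is the classic pathology of unconstrained slope estimation. Users
comparing groups whose true slopes exceed ~1 probability/step should expect
compression of the upper range. At large trial counts (≥200 per step) the
posterior outresolves the default width axis; raise `grid_points` (61+)
for such data.

Fit exclusion follows the threshold-validity rule: fits whose estimated
threshold falls outside the closed interval [1, 7] (the stimulus range) are
excluded with a recorded reason. The interval is closed because the rule's
purpose is to drop boundaries the stimulus range never bracketed, and an
estimate exactly at an endpoint is still bracketed.

## Cross-validated lapse-prior selection

The asymptote prior width is chosen from {0, 0.05, …, 0.5} by leave-one-out
cross-validation: for each block, each trial is held out in turn, the
remaining 69 trials are refit, and the model is scored by the
posterior-predictive probability of the held-out response. Because the
grid likelihood is a product over trials, the refit is computed exactly by
subtracting the held-out trial's log-likelihood contribution at every grid
node — an algebraic identity, verified against naive refitting in the test
suite. Scores are pooled across *all* blocks and trials jointly and
summarized by their median per candidate width; the width with the largest
pooled median wins, ties going to the smaller (more constrained) width.
Held-out likelihoods use the posterior-predictive mean ψ̄ rather than a
plug-in at the point estimate; the predictive distribution is the proper
scoring object for model comparison, and it lets a zero-width prior lose
the cross-validation legitimately (its predictive probabilities can reach
0 against an observed response) instead of crashing.

The sensitivity sweep refits every (ABX, by default) block at each
candidate width and tracks the Pearson correlations of per-subject mean
slope and combined lapse with the reading score, with percentile bootstrap
ribbons over subjects (the subject is the unit of analysis, so subjects —
not trials — are resampled).

## Curve-shape variables

Combined lapse is the arithmetic mean of the two asymptote deviations
(a lower asymptote of 0.1 and an upper asymptote of 0.9 are the same 10%
lapse rate). Repeated blocks within a subject × continuum × paradigm cell
(the two ABX blocks) are averaged parameter-wise before modeling; the
per-subject grand mean over all six blocks is the unit for group effect
sizes and discriminant classification.

The shape PCA standardizes (z-scores) the three columns slope, γ, λ before
extracting components: the columns live on incommensurate scales, so
correlation-matrix PCA is the defensible choice, and the aggregated
subject × continuum × paradigm record is the observation unit, matching
the mixed models. PC1 is sign-fixed so that slope loads positively; with
slope and lapses negatively coupled, PC1 reads as overall categorization
quality (steep, low-lapse curves score high).

## Mixed models and simplification

Shape outcomes are modeled with linear mixed-effects regressions: reading
score continuous, continuum and paradigm as deviation-coded (±0.5) factors
so main effects are evaluated at the grand mean, ADHD and nonverbal IQ as
covariates, and a random intercept per subject. Continuous predictors are
centered whenever interactions are present. Models are fit by maximum
likelihood (so nested models are LRT-comparable); coefficient p-values are
the Wald z-tests reported by the fitting routine. Backward elimination
repeatedly drops the least-useful term by likelihood-ratio test at α =
0.05, removing interaction terms before the main effects they contain and
never touching the random intercept; the full elimination trace is
returned.

Endpoint accuracy (steps 1 and 7 only, 20 endpoint trials per block) and
lapse are modeled on the identity link — a linear probability model — which
keeps coefficients in probability units per trial or per score point; the
mixed-model machinery is shared with the shape models.

Mediation follows the Baron–Kenny product-of-coefficients scheme with
identical covariates in all three regressions, so the identity
`a·b = c − c′` holds to numerical precision; the indirect effect's CI and
p-value come from a percentile bootstrap over observations (default 2000
resamples, seeded). Percent mediation is `100·a·b/c`, undefined (flagged)
when the total effect is ~0. Group comparisons use Cohen's *d* with the
(n−1)-weighted pooled SD; classification accuracy is leave-one-subject-out
LDA/QDA.

The correlation screen computes Pearson r for every (shape parameter, test
score) pair and applies Benjamini–Hochberg FDR across the entire matrix;
cells with a constant column are flagged rather than corrected.

## Reaction times

Trials with RT outside the closed interval [200, 2000] ms are removed
(boundary values kept: the rule targets responses *shorter* than 200 ms and
*longer* than 2 s). Per-subject RT profiles over steps use an orthogonal
quadratic polynomial basis built by Gram–Schmidt under the inner product
weighted by realized trial counts, so filtered, unbalanced designs keep the
columns exactly orthogonal; the quadratic column is oriented upward-curving,
making a negative coefficient the inverted-U (slow center, fast endpoints)
signature. Per-step central tendency uses the mode of a shifted, scaled
chi-square fit by maximum likelihood (mode = shift + (df − 2)·scale for
df > 2) — RT distributions are right-skewed, so the mean is a poor summary
and an unshifted chi-square is under-parameterized for millisecond-scale
data. The free (df, shift, scale) likelihood has trading-off parameters, so
the optimizer starts from moment-matched values; on failure the estimator
falls back to a kernel-density peak and flags the fit. The trial-level
mixed model regresses RT on the linear and quadratic basis, centered
reading score, and their interactions with a subject random intercept; a
negative quadratic × reading interaction means better readers slow down
selectively for ambiguous center stimuli.

## The synthetic cohort generator

The generator emulates the study design: each of 44 virtual subjects (6
blocks: 2 ABX + 1 single-interval per continuum; 70 trials per block, 10
per step) has a reading score drawn from a truncated normal (mean 100, SD
15, bounds [55, 145]) that drives their true psychometric shape:

- slope = −1.6 + 0.023·score + N(0, 0.15), floored at the design's
  expressible minimum (the width-prior ceiling, slope ≈ 0.08) and capped
  at 2.0. The intercept puts the cohort mean near 0.7 probability/step
  with a realistic spread (~0.1–1.4 across the recruited range); the floor
  is structural — real observers bottom out near chance rather than
  crossing zero — so a linear link over a 15-SD score distribution is
  necessarily a *floored*-linear law;
- lapse = 0.08 − 0.0004·score (+0.010 on the static-cue continuum)
  + N(0, 0.01), clipped to [0, 0.3]; lapses enter symmetrically
  (γ = λ = lapse) by default with an asymmetry knob. A config whose lapse
  link clips more than 10% of subjects raises an error;
- threshold ~ N(4, 0.5); width follows from slope and lapse;
- RT = 500 + 180·q(step)·g(score) + chi-square(4)·60 ms noise, where q is
  an inverted-U peaking at step 4 and g scales curvature up by 1% per score
  point; 9% of trials are replaced by spurious presses (< 200 ms) and 6%
  by long pauses (> 2 s), matching the filter's intended removal rates;
- covariates: ADHD flag (base rate 16%, more likely at low scores) and
  nonverbal IQ (correlated with reading) are generated with *zero* direct
  effect on the outcomes, so backward elimination should remove them — a
  meaningful null. Group labels follow the ±1 SD rule on the score
  (≤ 85 Dyslexic, > 100 Above Average, otherwise Below Average).

All randomness flows from one master seed through named substreams;
identical seeds give byte-identical cohorts. Ground-truth parameters are
emitted alongside the data for recovery testing.

What the generator does **not** emulate: response dependence across trials
(fatigue, sequential effects), paradigm-specific psychometric differences
(the ABX lapse increment defaults to 0), acoustic stimulus structure, and
the measurement error structure of real standardized test batteries. Tests
passing on these cohorts show the pipeline recovers what it assumes; they
cannot certify behavior under model misspecification.

## Problem sizes and numerical choices

The heavier validation runs are scaled to desk-size: the bias
demonstration uses 200 blocks at the default 41/21 grid; cohort-scale
simulations (cross-validation, sensitivity sweep, end-to-end recovery) use
20–44 subjects at a 25-node parameter grid (13 asymptote nodes), where the
grid-refinement check bounds point-estimate movement under doubling at
< 2%. Degenerate inputs: a posterior with numerically zero mass raises a
degenerate-fit error; predictive probabilities of exactly 0/1 against an
observed response yield a zero held-out likelihood with a flag rather than
an exception; empty aggregation cells are flagged, not fatal.

## Known limitations

- Slope attenuation above ~1 probability/step (see the calibration
  discussion above): between-group slope differences at the steep end are
  compressed, so effect sizes there are conservative. Consequently, an
  end-to-end regression of fitted slope on reading score recovers
  ~70–80% of a generative linear coefficient whose range extends beyond
  the identifiable band.
- Mixed-model p-values are Wald z-tests; small-sample degrees-of-freedom
  corrections (Satterthwaite/Kenward–Roger) are not provided by the
  fitting routine used.
- The LOO-CV fast path assumes the prior grid is fixed across refits
  (exact for this fitter by construction).
- The chi-square RT summary assumes unimodal, right-skewed step-level RT
  distributions; strongly bimodal data will be summarized by the taller
  mode.
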