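# lapsefit

Bayesian psychometric curve fitting with lapse-rate priors, cross-validated
prior selection, and the downstream statistics that link categorization
performance to reading ability.

## The problem

In phoneme-categorization experiments, a child hears synthesized syllables
drawn from a 7-step continuum between two phoneme endpoints (e.g. /ba/→/da/)
and labels each one. The probability of choosing the second category as a
function of continuum step — the *psychometric function* — is summarized by
its **slope** at the category boundary (how sharp the phoneme boundary is)
and its **lapse rate** (how often the listener errs even on unambiguous
endpoint stimuli, due to attention or motivation rather than perception).

Most of the developmental literature fits this curve with the asymptotes
fixed at 0 and 1 — a zero-lapse assumption. When listeners do lapse, that
assumption pushes the endpoint errors into the slope parameter and
**systematically underestimates slope**, and it does so most for exactly the
children (poor readers, children with ADHD) whose lapse rates are highest.
`lapsefit` implements the corrected analysis:

- a 4-parameter logistic psychometric
  `ψ(x) = γ + (1 − γ − λ)·S(x; m, w)`, with threshold *m*, width *w* (the
  interval over which S rises from 0.05 to 0.95, so the slope at threshold
  is `(1 − γ − λ)·ln 19 / 2w`), and asymptote deviations γ, λ;
- grid-posterior Bayesian fitting with a uniform prior of configurable
  width on the asymptotes (width 0 reproduces the traditional 2-parameter
  fit);
- leave-one-out cross-validation to choose that prior width by held-out
  trial likelihood;
- curve-shape summaries (combined lapse, threshold-validity filtering, a
  PCA composite of slope and asymptotes);
- linear mixed-effects models with deviation coding and backward
  elimination relating shape to a continuous reading score, plus Cohen's
  *d*, leave-one-out discriminant classification, an FDR-corrected
  correlation screen, and Baron–Kenny mediation with bootstrap inference;
- reaction-time analysis: range filtering, orthogonal-polynomial profiles
  over the continuum, shifted chi-square mode summaries, and the
  curvature × reading mixed model;
- a synthetic-cohort generator that emulates the full experimental design
  (44 subjects × 6 blocks × 70 trials, slope and lapse coupled to reading
  score) with ground truth retained, so every stage is testable without
  external data.

## Worked example: the zero-lapse bias

Simulate blocks from a listener with a true slope of 0.662 and a true 5%
lapse on each asymptote, then fit with and without lapse modeling:

```python
import numpy as np
from lapsefit import BlockData, PriorConfig, PsychometricParams, fit_block, slope_at_threshold
from lapsefit.simulate import simulate_block_responses

true = PsychometricParams(threshold=4.0, width=2.0, lower_asym=0.05, upper_asym_dev=0.05)
rng = np.random.default_rng(0)
slopes = {"2-param": [], "4-param": []}
for _ in range(50):
    trials = simulate_block_responses(true, n_per_step=10, seed=rng)
    block = BlockData.from_trials(trials, "demo", "dynamic_ba_da", "abx", 1)
    slopes["2-param"].append(fit_block(block, PriorConfig(asym_max=0.0)).slope_at_threshold)
    slopes["4-param"].append(fit_block(block, PriorConfig(asym_max=0.1)).slope_at_threshold)

print(f"true slope at threshold : {slope_at_threshold(true):.3f}")
for name, vals in slopes.items():
    print(f"mean {name} estimate  : {np.mean(vals):.3f}")
```

```
true slope at threshold : 0.662
mean 2-param estimate  : 0.378
mean 4-param estimate  : 0.636
```

The zero-lapse (2-parameter) fit underestimates the slope by ~43% — a 5%
rate of stimulus-independent errors is misread as a much fuzzier category
boundary — while the lapse-aware fit lands within a few percent of the
truth. Everything downstream (group effect sizes, slope–reading
correlations) inherits this difference.

## Command line

```bash
lapsefit simulate --seed 17 --out cohort/          # synthetic cohort CSVs
lapsefit run --sim-config cohort/sim_config.json --seed 17 --out artifacts/
lapsefit cv-prior --trials cohort/trials.csv --out cv.csv
lapsefit sweep --trials cohort/trials.csv --subjects cohort/subjects.csv --out sweep.csv
lapsefit report --artifacts artifacts/
```

`run` executes fit → shapes → mixed models → reaction times, writing every
intermediate CSV/JSON and a manifest with file digests for reproducibility.

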