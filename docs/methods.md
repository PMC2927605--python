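# Methods

## Prevalence-drift model

The deterministic model tracks a *fixed* binary risk factor (something that
cannot change at the individual level, like country of birth) through
repeated rounds of removal. Each step, the exposed and unexposed groups are
thinned by their retention probabilities and prevalence is renormalized over
the survivors:

- population: exposed retain `1 − RR_d·I_d`, unexposed retain `1 − I_d`;
- cohort: two independent removal processes act multiplicatively, so the
  exposed retain `(1 − RR_d·I_d)(1 − RR_a·I_a)` and the unexposed
  `(1 − I_d)(1 − I_a)`.

The update is implemented as this survivor-count ratio, and a property test
checks agreement with an explicit two-bucket computation to 1e−12. When the
exposed and unexposed retentions are equal (all `RR = 1`) the ratio is
algebraically the identity; the code applies that identity directly so the
fixed point is exact in floating point rather than accurate to an ulp.

**Assumptions.** The factor is fixed; incidences are per-step probabilities
(the step length is whatever period the incidences describe, typically a
year); removal processes are independent given exposure; the population is
large enough to treat the recursion as deterministic. Bias is stored signed
(`p_pop − p_cohort`), positive when the cohort under-represents the factor.

**Defaults.** The canonical scenario grid uses initial population prevalence
0.25 (cohort 0.20 in the initially-biased "B" variants), all incidences
0.10, `RR = 2` where an association is switched on, over 10 steps. The
behaviour of these scenarios is qualitative and robust: flat trajectories
with no associations, convergence under a shared death association (below
prevalence ½ — the direction reverses above ½, which a test demonstrates at
0.75/0.80), cohort-only decline under non-death attrition, divergence with
both. Construction rejects `RR·I > 1` (negative retention) rather than
clamping, and a step that removes everyone raises an error because
prevalence among zero survivors is undefined.

## Synthetic cohort generator

The generator emulates a five-wave survey of 12,432 women aged 70–75 at
recruitment, with five mutually exclusive end states per wave (respondent,
dead, frail withdrawal, other withdrawal, lost to follow up).

- **Baseline factors** are drawn independently from configured marginal
  distributions (seven factors: country of birth, highest qualification,
  BMI group, physical activity, alcohol, smoking, self-reported health).
  Only marginals are configured because only marginal/coefficient structure
  is needed for parameter-recovery experiments; a user can post-process the
  table to induce dependence.
- **Final status** is drawn from a multinomial logistic model: per-outcome
  linear predictors are an intercept plus summed log odds ratios for the
  participant's categories, softmax-normalized with respondent as baseline.
  The shipped coefficient fixture encodes the attrition odds ratios of the
  seven-factor analysis the package is designed to mirror.
- **Intercept calibration** makes the fixture's odds ratios coexist with
  target Survey-5 marginals (44.7/28.4/5.1/11.4/10.4%). Holding coefficients
  fixed, intercepts are updated by `log(target/achieved)` per outcome —an
  iterative-proportional-style search over the covariate distribution —
  until the worst marginal error is below 1e−6 (cap 500 iterations;
  non-convergence raises with the achieved marginals attached). Calibrating
  on the exact enumerated joint distribution (3,600 cells for the default
  factors) gives the infinite-sample intercepts in under a second.
  Simplex-corner targets are rejected: a finite intercept cannot put zero
  mass on an outcome.
- **Waves.** Two routes produce wave-resolved statuses. `expand_to_surveys`
  simulates forward from per-survey transition rates derived from a
  cumulative attrition table; since the four attrition states are treated as
  absorbing, the tabulated cumulative "lost" shares are monotonized with a
  running maximum and the respondent share re-derived as the complement
  (this also absorbs 0.1%-level rounding in tabulated rows, and preserves
  the Survey-5 marginals exactly). `assign_transition_surveys` instead
  back-fills exit timing conditional on a model-drawn final status, so one
  cohort can carry both the configured odds-ratio structure and plausible
  wave timing.
- **Missingness** is imposed completely at random per factor (defaults:
  BMI 11.0%, smoking 7.4%, country of birth 7.0%); real item non-response is
  unlikely to be MCAR, so recovery results under missingness are a
  best-case.
- **Weights** model intentional two-fold over-sampling of rural and remote
  strata: strata are drawn with probability ∝ population share × sampling
  fraction, weights are inverse sampling fractions normalized to mean 1.
  The over-sampling factor is configurable; two-fold is a plausible default
  for a design that needs reliable rural estimates.

What the generator does **not** emulate: factor dependence at baseline,
informative (MNAR) missingness, return from loss to follow up, wave-specific
covariate effects (the model targets cumulative Survey-5 status, not
per-wave hazards), and any recruitment/consent mechanics. Passing tests
therefore show that the analysis machinery is correct and well-calibrated
under these stated conditions, not that real attrition is MCAR or
independent.

## Attrition analysis

The five-outcome multinomial logit is fit by maximum likelihood
(statsmodels `MNLogit`, Newton iterations, parameter tolerance 1e−10) with
respondent as the reference outcome. Reference categories follow the
standard rule: modal category for nominal factors (ties break to the first
declared category, with a warning), declared best-survival end category for
ordinal factors (configuration, not inference, decides "best survival").
Confidence intervals are Wald intervals on the log-odds scale; a category is
flagged significant for an outcome when its 95% CI excludes 1. Empty
factor-by-outcome cells are detected before fitting and raised as a named
separation error; outcomes entirely absent from the data contribute no
equations. A two-outcome collapse with one binary factor is checked against
the closed-form `ad/bc` contingency odds ratio to 1e−8.

The retention screen runs in two stages — univariate fits first, then a
joint fit from which factors with no significant category are dropped — and
iterates the joint stage to a fixed point (cap 10 rounds, every drop
reported), because a single pass can leave factors that lost significance
when others were removed.

Under a null generator the screen's spurious retention rate is governed by
the family-wise Wald error across a factor's category×outcome tests
(≈ 1 − 0.95^k); tests assert consistency with that rate rather than a fixed
small bound, since "all odds ratios within 10% of 1" is not implied by
asymptotics for thinly populated cells (e.g. a 3% category crossed with a 5%
outcome).

## Population comparison

Cohort prevalence of a dichotomized factor is the weight-normalized mean of
the 0/1 indicator over non-missing records (invariant to weight rescaling;
all-missing input is an error). Named dichotomizations ship for non-English
country of birth and ever-smoking. Bias against an external series is
computed at explicitly matched calendar labels — no fuzzy matching of
"1995/6" vs "1996" — and reported signed, with a direction summary
(under-/over-representation). Percentages exist only at the display layer;
everything internal is a proportion.

## Problem sizes and determinism

Default experiment sizes were chosen so sampling error is well below the
effects of interest: marginal-calibration checks use n = 100,000 (binomial
SE ≤ 0.16 percentage points on a 28% share), odds-ratio recovery uses
n = 50,000 over 10 seeds (log-OR standard errors roughly 0.4× those of an
8,938-person complete-case fit, so estimates concentrate well inside the
generating model's published-width intervals), and screen behaviour uses
n = 20,000. All randomness flows through `numpy.random.SeedSequence` with
fixed spawn keys per operation, so a (configuration, seed) pair reproduces a
cohort byte-for-byte regardless of which operations ran before.

## Known limitations

- The deterministic model has no continuous-time hazard formulation and no
  time-varying risk factors; a factor that individuals can change blunts
  the divergence mechanism and is out of scope.
- Weighted prevalences carry no design-based variance estimates.
- The multinomial fit assumes independent observations; household or area
  clustering is not modelled.
- Remedial missing-data methods (multiple imputation, joint
  longitudinal-survival models, GEE) are deliberately out of scope: the
  package quantifies the bias, it does not correct it.
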