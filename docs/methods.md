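# Methods

## The measurement and its scales

The Randot Preschool stereotest yields an ordered categorical outcome over
seven categories: the six disparity levels 40, 60, 100, 200, 400, 800
arcsec (best first) and *nil* (failed the easiest plate). A child who
cannot engage with the test at all is *not testable* and carries no score.
All ranking operations (quantiles, correlations) order scores
40 < 60 < … < 800 < nil.

Analyses are done on log₁₀ thresholds, which are approximately normal
across observers. Two conventions matter:

- **Summary statistics** over score samples exclude nil from means/SDs
  (nil has no measured threshold) but include it in percentiles, ranked
  worst. All-nil samples have their moments flagged unavailable.
- **Agreement analyses** substitute a notional 1600 arcsec for nil — one
  log-level above the worst available score — so that every retested child
  contributes a difference. This substitution is owned by the
  repeatability module only.

## Lognormal threshold conversions (`threshold_stats`)

If log₁₀ threshold ~ Normal(M, S²), the threshold is lognormal with

    mean   μ = 10^M · exp(½ (S ln10)²)
    SD     σ = μ · √(exp((S ln10)²) − 1)
    median 10^M
    mode   10^(M − S² ln10)

and inversely M = log₁₀μ − ½ log₁₀(1 + (σ/μ)²),
S = √(log₁₀(1 + (σ/μ)²)/ln10). `log1p`/`expm1` keep the round trip exact
to ~1e-10 relative error even for σ/μ near zero. These conversions are
exact only under lognormality; applied to real (discretized, censored)
score samples they differ from directly computed sample moments, which is
expected and not an error.

Sample percentiles use the type 1 (inverse empirical CDF) definition:
Q(p) is the ⌈np⌉-th order statistic for p > 0, Q(0) the best score. A
small negative guard (1e-9) protects ⌈np⌉ against binary-float fuzz.

## The normative model (`normative`)

A proportional-odds (cumulative-logit) model:

    P(R ≤ L) = expit(α_L − βA − γ·male)

with six ordered cut-points α_L, an age slope β on a transformed age
covariate A, and a male effect γ (β < 0: scores improve with age; γ > 0:
boys score worse). Category probabilities are differences of adjacent
cumulative probabilities; P(nil) is the complement of the 800-arcsec
cumulative category. The sum telescopes to exactly 1.

**Age transform.** A is configurable: `log10_months` (default for the
bundled reference parameters), `log10_years`, or `identity_years`. The
source of the reference parameters describes A as log₁₀ years, but those
printed parameters reproduce the observed score distributions only when A
is log₁₀ months (e.g. they give P(score = 40) ≈ 0.71 for a 10-year-old
girl, matching the observed distribution, under months — versus ≈ 0.08
under years). We therefore evaluate the reference parameters under
`log10_months` and record the transform in every fit and parameter file;
users fitting their own data may choose either.

**Fitting.** The likelihood, analytic gradient and monotone
reparameterization (first cut free, subsequent gaps as exponentials of
unconstrained values) are implemented here; scipy's L-BFGS-B performs the
minimization (gradient tolerance 1e-8, three starts — one from the
empirical cumulative logits, two jittered — to guard against local
optima). Standard errors come from a central-difference Hessian of the
analytic gradient in the unconstrained space, mapped back by the delta
method; Wald p-values accompany each estimate. Degenerate situations are
surfaced, not hidden: non-convergence flags the result, a diverging
covariate effect (|coef| > 30) raises an explicit separation error, and
empty observed categories are listed in the result (their cut-points are
then only weakly identified).

**Sampling** is inverse-CDF on the per-child category distribution, fully
vectorized, driven by a caller-supplied seeded generator.

## Repeatability (`repeatability`)

For paired sessions, differences are d = (session-2 log threshold) −
(session-1 log threshold), so a negative bias means improvement on retest
(a practice effect). We report:

- bias = mean(d), tested against zero with a one-sample two-sided t test
  (the test choice is a package convention; only its significance is
  conventionally quoted);
- s = SD(d) (n−1 denominator) and the 95% limit of agreement L = 1.96·s,
  also expressed as a threshold factor 10^L;
- the 95% CI of L as L ± t₀.₉₇₅,ₙ₋₁·√(3s²/n). The t quantile uses n−1
  degrees of freedom: with a 20-child group and L = 0.71 this yields the
  conventional lower bound 0.42, which a normal quantile does not.
- The practice-effect bias is *not* subtracted before computing L; it is
  small relative to the between-session variability and folding it out
  would overstate the instrument's consistency.

Pass/fail agreement treats any numeric level as a pass (800 included) and
nil as a fail. Pearson correlations are computed on log thresholds after
the nil→1600 substitution and reported unavailable when a session is
constant (which legitimately happens in narrow age bands). Variance
comparisons between groups use a two-sided F test on the difference
variances; the age trend in reliability is additionally summarized by OLS
of |d| on age with a male indicator.

## Diagnostics (`diagnostics`)

Binocular-vision-problem classification applies four criteria in strict
precedence: parental questionnaire clearly indicating a problem
(**Parent**), heterotropia on the cover test (**CTFAIL**), worse-eye
acuity > 0.48 logMAR — the WHO moderate-visual-impairment cut-off, strict
inequality (**ModVI**) — and interocular acuity difference > 0.2 logMAR
(**IADonly**). Each category subsumes those after it. A missing
questionnaire means criterion one evaluates to "no"; such children stay
in the sample. The interocular threshold default is 0.2 logMAR
(consistent with the normative exclusion rule) but configurable, because
source descriptions of this cut-off disagree (0.2 in text, 0.3 in a
figure caption).

The stereotest screen counts nil as the only failure. Metrics are
sensitivity = 100·TP/(TP+FN), specificity = 100·TN/(TN+FP),
PPV = 100·TP/(TP+FP), NPV = 100·TN/(TN+FN); zero-denominator metrics are
reported unavailable, never 0 or 100. Display rounding is half-up to
integers (banker's rounding would mis-render e.g. 96.5 → 96); raw
fractions are always retained in machine-readable output.

Sample filters:

- **Normative**: testable, cover-test pass (missing cover data excludes),
  no parental report of a problem, not recorded as needing-but-not-wearing
  glasses; from age 4 (≥ 4.0 years — acuity is not measured in nursery
  settings below that) acuity must be present, ≤ 0.2 logMAR in both eyes,
  and within the interocular threshold.
- **Validity**: testable, cover test performed (either outcome — cover
  failures are the cases); from age 4, acuity measured in both eyes.

Both filters log every exclusion by its first triggering rule, so each
child is accounted for exactly once. Reporting bands are 2, 3, 4, 5, 6–7,
9–11 years for testability/norms and the coarser 2–3, 4–5, 6–7, 9–11 for
diagnostics, where cases are rare and groups need adequate size.

## Synthetic cohorts (`synth`)

The generator's defaults are the study conditions of the anchoring
characterization study:

| parameter | default | source of the value |
|---|---|---|
| n_children | 1005 | study cohort size |
| age bands (weights) | 2 (78), 3 (167), 4 (171), 5 (106), 6–7 (267), 9–11 (216) | recruitment table |
| sex ratio (male) | 488/1005 | cohort composition |
| testability logit | −3.938 + 1.823·age | band averages 65%/92%/99%/~100% |
| score model | reference cumulative-logit fit, log₁₀ months | published normative fit |
| BV-problem prevalence | 37/892 ≈ 4.1% | validity-sample case count |
| acuity means (4–5 / 6–7 / 9–11) | 0.10 / 0.07 / 0.01 logMAR | normative acuity table |
| acuity SDs | 0.055 shared + 0.045 per eye | reproduces per-eye SD ≈ 0.07 and IAD SD ≈ 0.065 |
| questionnaire logit | 2.094 − 0.203·age | ~83% at 2, ~44% at 11, ~54% overall |
| retest bias | −0.114 log₁₀ arcsec | observed practice effect |
| retest within-child SD | 0.227 log₁₀ arcsec | yields L = 1.96·0.227·√2 ≈ 0.63 |

The logistic-curve coefficients are chosen so the *band averages* (ages
uniform within each year band) match the anchor percentages, not the
point values at integer ages.

Scores are drawn from the ordinal model, then a continuous latent log
threshold is placed uniformly inside the scored level's bin (the 40-level
bin extends one log-step down, to log₁₀ 20); nil children get latent +∞
(stereoblind). Retest sessions add the practice bias and per-session
Gaussian noise to the latent value and snap back to the level grid — the
simplest mechanism that yields log-scale Bland–Altman geometry with
grid-quantized differences, a persistent-nil subgroup, and the apparent
improvement of repeatability with age through the floor effect (older
children sit below the 40 arcsec floor and repeat it trivially).

Case children (`case_latent_shift` = 0.6 log₁₀ arcsec added to the
latent, plus `case_nil_boost` = 0.2 extra probability of nil) carry an
observable marker drawn over Parent/CTFAIL/ModVI/IADonly (0.30/0.40/
0.20/0.10); acuity-based markers fall back to CTFAIL below age 4, where
acuity is unmeasured. No quantitative anchor exists for how much worse
case children score, so the two case parameters are free; the defaults
place the screen in the qualitative regime the instrument is known for —
specificity above 90%, sensitivity well under 60% — and are documented
here rather than tuned to any particular table.

**What the generator does not emulate**: the plate-level psychophysics
(2-of-4 guessing, crosstalk), refraction status, school-level clustering,
seasonal/testing-order effects, and any dependence of testability on case
status. Passing tests on synthetic cohorts therefore demonstrate that the
analysis pipeline is correct and internally consistent under the model's
assumptions — not that real cohorts satisfy those assumptions. In
particular, the ordinal model underpredicts nil rates in two-year-olds
relative to observed normative tables (~3% vs ~14%), a known lack of fit
of the published parameters at the youngest ages that the generator
inherits by design.

## Numerical and testing choices

- Category probabilities are clipped at 1e-300 inside the likelihood only
  to keep the optimizer finite; `ordinal_loglik` itself reports −∞ for
  truly impossible observations.
- Problem sizes in the test suite: Monte-Carlo moment checks use 10⁶
  lognormal draws (±1%); ordinal parameter recovery uses one 5,000-child
  cohort (±3 SE) and 120 replicate 1,000-child cohorts for estimator bias
  (<5% of |β|); repeatability calibration uses 10,000 retest pairs; the
  end-to-end pipeline check uses a 50,000-child cohort. These sizes make
  the Monte-Carlo error a small fraction of each tolerance.
- The independent cross-check for the ordinal fitter is statsmodels'
  `OrderedModel` (logit link) on simulated data; it is used only as an
  oracle in tests, never as the implementation.
- Scores are plain ints plus the string sentinels `"nil"`/`"NT"` rather
  than an enum, trading a little type safety for frictionless CSV/pandas
  round-tripping.

## Known limitations

- The fitted cut-point standard errors assume a locally quadratic
  likelihood in the unconstrained parameterization; with empty categories
  they become large and should be read as "weakly identified", not as
  precise uncertainty.
- The reference-parameter age-transform ambiguity (months vs years) is
  resolved pragmatically, not from raw data; fits on user data record
  their transform explicitly to avoid propagating the ambiguity.
- `abs_diff_regression` treats |d| as an unbounded continuous response;
  with heavy grid quantization its p-values are approximate.
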