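# Methods

## Absolute-risk model

The quantity estimated is the probability that a person of given age, sex,
race and risk-factor profile develops esophageal adenocarcinoma (EAC)
within 10 years, accounting for the competing possibility of dying first.
The construction is the classical attributable-risk projection used for
cancer risk calculators:

- **Population incidence → baseline hazard.** Incidence is taken from
  age/sex/race-specific rate tables (5-year age groups, 40–85+). The
  baseline hazard — the hazard of a person at the *lowest-risk level of
  every factor* — is incidence divided by the population-mean relative risk
  E[RR] = ∏_f Σ_l p_{f,l} RR_{f,l}. This is the population-attributable-risk
  identity: 1 − PAR = 1/E[RR]. Factors are assumed independent and
  multiplicative; joint exposure distributions are out of scope, and the
  assumption is least reliable at extreme combined profiles.
- **Time discretization.** Risk is accumulated in 1-year steps with hazards
  evaluated at mid-interval age (age + t + 0.5) and treated as constant
  within each step. For piecewise-constant hazards the per-step
  cause-allocation h/(h+m)·(1 − e^{−(h+m)}) is exact, so the annual sum
  equals the closed-form cause-specific cumulative incidence; the suite
  verifies this to 1e-12 against the constant-hazard closed form and to
  1e-8 against numerical quadrature of h(t)S(t).
- **Competing mortality** uses the all-cause hazard unadjusted for EAC
  deaths. EAC is a negligible share of total mortality at every age in the
  supported range, so subtracting it would change risks far below the
  precision of the inputs.

## Rate smoothing

Tabulated rates are smoothed with a cubic in age fitted by unweighted least
squares on the **log-rate** scale — the log guarantees positivity of every
evaluated rate, which a natural-scale cubic cannot. Age-group midpoints are
(lo + hi)/2 with the open-ended 85+ group closed at 89 (midpoint 87). Zero
rates (possible in sparse strata) are floored at half the smallest positive
rate in the table before the transform, and the flooring is logged. The fit
is performed in a scaled basis and converted back to raw-age coefficients,
so exact-cubic tables are recovered to ~1e-13. Evaluation clamps ages above
the fitted domain to its maximum (extrapolating a cubic beyond data is
unsafe) and refuses ages below 40, the bottom of the supported range.

## Barrett's-esophagus stratum

In persons with diagnosed BE, registry incidence is replaced by an anchored
progression model: 0.0031 events/person-year for white males at age 62 (the
midpoint of the 60–64 group, a typical age at BE diagnosis), scaled by
1.04 per year of age and by fixed sex/race multipliers (white women 0.4,
black males 0.75). The factor set changes too: segment length and dysplasia
dominate, family history and physical activity drop out, and the reflux
(sGERD) relative risks are the square roots of the general-population
values — i.e. half the trend coefficient on the log scale, the natural
scale for a multiplicative trend. Strata with no parameter rows (black
females, for whom reliable factor data do not exist) raise a
"stratum unsupported" error rather than extrapolate.

## Confidence intervals

Each selected level's log-RR standard error is read off its published 95%
CI: SE = (log ci_high − log ci_low)/(2·z₀.₉₇₅). The gradient of log AR with
respect to each factor's log RR is computed by central finite differences
(step 1e-4 on the log-RR scale), perturbing the factor's RR **both** in the
individual product and in E[RR] behind the baseline hazard, so uncertainty
flows through the attributable fraction as well. Factor estimates are
treated as independent; Var(log AR) is the sum of squared gradient×SE
terms, and the CI is log-normal around the point estimate. Against a
10,000-draw parametric bootstrap (log-normal RR draws, risk recomputed by
closed form) the CI width agrees within a few percent. Reference-level
selections have SE 0 and contribute nothing; a factor whose CI equals its
point estimate collapses the interval accordingly.

## Display conventions

Per-1000 risk is rounded to one decimal; "1 in N" is round(1000/per_1000)
(so 5.7 per 1000 reads as 1 in 175). The risk category uses fixed
log-spaced bins on the per-1000 scale — <0.5, 0.5–2, 2–8, 8–32, ≥32 —
chosen once for stability; only the log spacing, not the cut points, is
externally constrained. Comparator 10-year mortality probabilities (heart
disease, stroke, etc.) use the same competing-risk machinery with the cause
hazard against all-other-cause mortality; they are demographic averages,
not adjusted for the individual's factor selections, and an exhaustive
disjoint cause partition sums to the all-cause 10-year death probability.
BMI categories are WHO bins, left-closed (25.0 is "overweight").

## Discrimination pipeline

The evaluation emulates how pooled case-control data are prepared to study
a risk score:

- **Constrained assignment.** A factor unmeasured in the source studies is
  drawn for controls from external population prevalences and for cases
  from the RR-tilted distribution p₁ ∝ p₀·RR (for two levels this is
  exactly the odds relation p₁ = OR·q/(1+OR·q)), so empirical odds ratios
  converge to the targets.
- **Imputation.** Remaining missingness is hot-deck imputed within
  (case status, sex, 10-year age band) cells, m = 10 completions; cells
  without donors fall back to the marginal distribution (logged). Hot-deck
  within coarse strata is a deliberate simplification of fully model-based
  multiple imputation; per-record risks are averaged across completions
  before thresholding, which is deterministic given the seed.
- **Post-stratification.** Because study controls are frequency-matched to
  cases, control weights are reset to reference-proportion / sample-
  proportion per (age-group, sex) cell, renormalized to preserve the total
  control weight; the weighted control distribution then equals the
  reference exactly. Reference cells with mass but no sampled controls are
  an error, listed by cell.
- **Metrics.** Sensitivity and specificity are weighted tail fractions of
  cases and controls over every observed threshold. **PPV** has no natural
  definition in case-control data (no population prevalence), so it is
  computed as the weighted mean model-based 10-year risk among reweighted
  controls scoring at or above the threshold — the expected fraction of
  flagged population members who would develop the cancer. This is a
  documented choice, and it reproduces the qualitative behaviour that PPV
  stays low until thresholds of several per 1000. The AUC is the weighted
  probability that a random case outscores a random control (ties ½),
  computed by sorted accumulation but identical to exhaustive pairwise
  enumeration; its CI is a stratified percentile bootstrap (cases and
  controls resampled separately, 1000 reps) because analytic variance
  formulas do not accommodate the weights.

## Synthetic data and the packaged defaults

The generator draws control factor levels from prevalences and case levels
from the per-factor RR-tilted distributions — the same independent
multiplicative family the engine assumes — so parameter-recovery
experiments (logistic fits covering the generating log-ORs) test the
pipeline, not model misspecification. It does not emulate multi-study
heterogeneity, correlated exposures, or informative missingness; passing
tests therefore demonstrate internal consistency, not real-data
performance.

The packaged config CSVs are **synthetic placeholders**: rate tables are
Gompertz-shaped (incidence anchored at ~1.1e-4/person-year for white males
in their early 60s, ~6× lower for white females, ~4× lower for black
males; all-cause mortality with an ~8-year doubling time; cause-specific
mortality as fixed shares of all-cause), and the factor tables carry
literature-shaped RRs and prevalences (the statin pair — OR 0.57,
prevalence 33% — is the one value printed with its source in the public
record). Real registry rates and published meta-analytic RR tables should
replace them for any substantive estimate; the CSV schema is documented in
`eacrisk.parameters`.

## Problem sizes

The test suite and the acceptance script size their simulations for tight
oracle checks at interactive runtimes: 100,000 profiles for the
attributable-risk identity (agreement within 3 Monte-Carlo SEs), 10,000
bootstrap draws for the CI comparison, 50 replicates of 5,000 per arm for
logistic parameter recovery, 200,000 records for assignment-frequency
convergence, and a 495-case / 1376-control synthetic study (the size of
the pooled consortium data) for the end-to-end discrimination run.

## Known limitations

- US-population inputs only; factor independence assumed throughout.
- The general-population and BE factor sets cannot be mixed; a profile is
  scored under exactly one stratum.
- Comparator mortality ignores individual risk factors (a smoker's true
  lung-cancer mortality is higher than shown).
- The delta-method CI ignores uncertainty in the rate tables and
  prevalences; only RR uncertainty is propagated.
- With the synthetic default config the discrimination AUC (~0.66) reflects
  the synthetic effect sizes, not any published figure.
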