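# Methods

This note documents the statistical model behind `weightpatterns`: what
the synthetic-cohort generator simulates, how the default parameter
values were chosen, what the imputation and estimation machinery assumes,
and where the numerical edges are.

## Time grid and notation

Weigh-ins live on a fixed five-point grid — `baseline`, `w12` (12 weeks),
`m6`, `m9`, `m12` — defining four blocks of 12/13/13/13 weeks. "Loss" at
a time point is `baseline − weight` in kg; %TBW is `100 × loss /
baseline`. A block change within ±1.4 kg classifies as Maintenance (M),
below −1.4 kg as Loss (L), above +1.4 kg as Gain (G); the four symbols
concatenate into pattern labels such as `L|L|M|M`. The ±1.4 kg boundary
itself counts as maintenance, and classification adds a 10⁻⁹ kg epsilon
so that weights recorded at 0.1 kg precision whose difference lands
exactly on the band are not flipped by floating-point representation
error.

## Synthetic cohort generator

`generate_cohort(params)` draws, in a fixed stage order (see
*Reproducibility* below):

1. **Members.** Sex (83.1% female), age group, state and socioeconomic
   (SEIFA) quintile are categorical draws; starting weight is
   N(92.6, 19.2²) kg truncated to [40, 249]; starting BMI is
   N(33.1, 6.2²) truncated to [16, 60], with height derived as
   `sqrt(weight / bmi)`; paid membership duration is N(600, 356²) days
   truncated at ≥ 84. Small configurable fractions of members are planted
   as ineligible (test accounts, employer-paid, overseas, underage,
   underweight BMI, missing or invalid start weight) so the eligibility
   cascade has real work to do.
2. **Patterns.** Each member draws a trajectory class from a 15-class
   mixture: 14 named 4-symbol patterns (all beginning with a first-block
   loss, `L|L|M|M` the most frequent) plus an `other` class covering the
   remaining mass.
3. **Trajectories.** Given the pattern, each block change is a truncated
   normal confined to the symbol's region (means −4.2 / 0 / +1.8 kg for
   L/M/G, common SD 2.8 kg). `other`-class members draw unconstrained
   N(−1.0, 3.0²) block changes, rejection-sampled so their realized label
   is not one of the named patterns. Trajectories that would dip below
   15 kg are redrawn; members planted with physically implausible start
   weights get flat trajectories and are excluded downstream anyway.
4. **Engagement.** A member's weekly activity rate is
   `max(0, 60 + κ·z)`, where `z` is their cohort-standardized 12-month
   loss and κ the coupling constant; per-block totals are Poisson with a
   declining block multiplier (1.0, 0.52, 0.36, 0.27) and are split
   multinomially over seven activity streams (food diary, weigh-ins,
   menus, etc.).
5. **Dropout.** Missingness is monotone: a first-miss time is drawn from
   per-time-point hazards, and all later weigh-ins are blanked. The
   hazard at each of `m6`, `m9`, `m12` is multiplied by 1.6 when the
   member's *previous observed block* was a weight gain.

The pre-dropout weights and realized pattern labels are retained on the
`Cohort` object (`weights_premask`, `assigned_patterns`) as ground truth
for validation; file round-trips drop `weights_premask` deliberately.

### Why the dropout mechanism is missing-at-random

The gain multiplier applies to the hazard at time *t* based on the block
ending at *t−1*, which is fully observed for every member still at risk
at *t*. Dropout therefore depends only on observed history — informative
(gainers leave earlier, so available-case estimates are biased upward)
yet missing-at-random, which is exactly the regime in which a
correctly-specified conditional imputation model can recover the truth.
This is a deliberate design choice: it lets the package *demonstrate*
the available-case bias and *verify* MI's correction against ground
truth. Truly missing-not-at-random dropout (hazard driven by the
unobserved current block) is out of scope.

### Calibration of the documented constants

Two sets of defaults are calibrated rather than assumed:

- **Dropout hazards** `(0.2402, 0.0499, 0.2545, 0.1685)` were found by
  sequential bisection at n=200,000 so that, together with the 1.6 gain
  multiplier, marginal missingness at (w12, m6, m9, m12) lands at
  (25, 29, 50, 61)% — checked on an independent seed at
  (24.98, 28.92, 49.82, 60.69)%.
- **Engagement coupling** κ = 14.57 was found by bisection at n=100,000
  so that the complete-case Pearson correlation between weekly platform
  use and 12-month loss, computed on the *raw generated cohort*, is
  0.287 (independent-seed checks: 0.298, 0.290).

The calibration scripts were development tooling; the resulting constants
are hard-coded, documented defaults, and the test suite re-verifies both
targets at n=24,035 (±2 percentage points of missingness; ±0.05 in r).
Note that the same correlation computed after restricting to longer-term
members is substantially *higher* (≈0.55), because the ≥1-year
membership filter removes variation in the weekly-use denominator
(`total activity / membership weeks`); the documented 0.287 target refers
to the unfiltered cohort's complete cases.

## Eligibility cascade

Exclusions apply in a fixed order — pseudo-member, employer-paid,
overseas, underage (<18), underweight (BMI < 18.5), missing start weight,
invalid start weight (<13 or >250 kg) — each step reporting members
removed and remaining. *Longer-term members* then require a baseline and
12-week weigh-in and ≥365 days of paid membership; the *complete-case*
subsample requires all five grid points. The steps commute (each
predicate is intrinsic to the member), but the fixed order makes the
per-step counts reproducible.

## Multiple imputation

Missing losses are imputed by monotone sequential regression, one time
point at a time in chronological order. At each point, a normal linear
model regresses observed losses on reference-coded demographics
(age group, sex, state, SEIFA quintile), starting weight and BMI, and all
earlier-point losses. Proper (Bayesian) draws are used: residual variance
from its scaled inverse-χ², coefficients from their estimated
multivariate normal (SVD-based sampling for numerical robustness, with a
pseudo-inverse and symmetrization of X'X against near-collinear designs),
then predictive draws for the missing cells. Observed cells are never
overwritten, so non-monotone holes are also handled. Single-level
categorical covariates are dropped with a warning; a time point with
fewer observed rows than predictors raises a named error.

Pooling follows Rubin's rules: pooled estimate `q̄` = mean of per-dataset
estimates, total variance `T = W + (1 + 1/m)B` with `W` the mean
within-dataset variance and `B` the between-dataset variance (`ddof=1`;
snapped to exactly 0 when all estimates coincide, so degenerate pooling
returns the complete-data SE). Proportions use the binomial within-SE
and can optionally be pooled on the logit scale with a 0.5/n continuity
guard; the default pools on the proportion scale, which is adequate away
from 0 and 1 at the sample sizes involved.

The default `m = 20` imputations balance Monte Carlo error against
runtime; the suite checks that doubling `m` moves pooled means by less
than the Monte Carlo SE.

## Estimation approaches

The same estimands (mean loss kg, mean %TBW, proportions ≥5% and ≥10%
TBW) are computed three ways — multiply imputed, available-case (whoever
has a weigh-in at that point), complete-case — and the three coincide
exactly on fully observed data, which the suite asserts. Subgroup
summaries support member columns plus two derived groupings: WHO BMI
class at baseline and membership-duration bins (365–547, 548–730, >730
days). Reported values round half-up at 0.1 precision (`round_half_up`),
matching conventional clinical reporting rather than banker's rounding.

## Validation design

Beyond unit and property-based tests, the suite validates the package
end to end:

- **Worked arithmetic** at printed precision for %TBW and share
  computations, exact.
- **Closed-form pooling** identities, exact.
- **Calibration** of both documented constants at n=24,035.
- **Parameter recovery:** over 50 replicates (n=5,000) with informative
  dropout, the pooled 12-month mean must fall within 3 pooled SEs of the
  pre-dropout sample truth, and be no further from it than the
  available-case estimate, in ≥80% of replicates; over 200 MCAR
  replicates (n=600, gain multiplier 1, named-pattern-only mixture so the
  population mean has a closed form via truncated-normal moments), the
  nominal 95% pooled interval must cover the analytic truth 95% ± 4
  points of the time. Replicate counts were sized to keep the whole suite
  within a few minutes on one CPU while leaving the binomial noise of the
  pass-rate checks well inside the margins.
- **Oracle equivalence:** pattern and subgroup tables agree cell-for-cell
  with brute-force loop re-computations on 150-member fixtures, and the
  classifier reproduces 100% of generator-assigned labels on pre-dropout
  data.

## Limitations

- The generator is a *calibration target*, not a behavioral model: block
  changes are independent given the pattern, engagement does not feed
  back into weight, and no seasonality, re-enrollment or measurement
  error is modeled.
- Dropout is missing-at-random by construction (see above); the package
  demonstrates MI under MAR and cannot speak to MNAR sensitivity.
- The imputation model is normal-linear in loss space while true block
  changes are mixtures of truncated normals; coverage is verified
  empirically rather than guaranteed.
- Pattern analysis conditions on complete cases, inheriting that
  subsample's selection; this mirrors standard practice and is surfaced
  by reporting the complete-case fraction alongside.
- Absolute effect sizes in any one synthetic cohort are properties of the
  chosen defaults, not estimates about any real program or population.

## Reproducibility

All randomness flows from a single integer seed through
`numpy.random.SeedSequence.spawn`, with one child generator per stage
(members, patterns, trajectories, engagement, dropout), so adding or
re-ordering draws inside one stage cannot perturb another. Cohort CSVs
round-trip byte-identically, the pipeline manifest records a SHA-256
digest of every output, and re-running a config reproduces identical
digests.
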