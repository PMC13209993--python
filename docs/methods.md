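# Methods

## Scoring model

The DQS is an a-priori, food-based diet quality index: eleven components,
each a step function (a "band table") of mean daily intake, summed to a
0–100 total. Components follow three frameworks — adequacy (non-decreasing
in intake), optimal range (maximal only at the recommended amount, zero
above it), and moderation (non-increasing, maximum at zero consumption).
The plain-water and meat/alternatives tables are sex-specific; scoring
therefore requires a binary `scoring_sex` per participant and raises a
configuration error when it is absent rather than defaulting silently.

Band intervals are transcribed left-closed/right-open: "≥a to <b" maps to
[a, b). Where a published band reads "≥a to b" followed by "≥b to …", the
next band's ≥ wins, so the shared boundary belongs to the upper band (3
cups of water scores 6, not 2). The optimal-range peaks — grain 6.0 serves,
meat 2.5 (women) / 3.0 (men) — are printed as literal point values between
the 8-point band and the zero band, and are implemented as singleton bands
matched within an absolute tolerance of 1e-9; intake epsilon above a peak
scores 0, exactly as the table reads. Two deliberate escape hatches exist:

* `canonical_rules(widen_optimal_peak=True)` closes the preceding composite
  band at the peak with maximum points (grain [5, 6] → 10), for users who
  consider the printed cliff an artefact of tabulation;
* `score_component(..., proportional=True)` linearly interpolates points
  between band lower edges, a continuous variant suitable only for
  sensitivity analysis. The banded tables are the published framework and
  remain the default; totals under banded scoring are sums of tabled points
  and need no floating-point tolerance.

Band tables serialise to YAML (`rules_to_yaml` / `rules_from_yaml`) so the
framework can be re-banded for other guideline editions.

## Intake processing

Disaggregation is linear: 100 g of an item contributes its tabled per-100 g
serve content to each core food group, with no renormalisation for
multi-group items. Items carrying a moderation class (discretionary food,
SSB, alcohol) contribute nothing to core serves even if the source table
carries serve values for them — the discretionary flag is all-or-nothing —
and their energy is pooled per class and converted at 600 kJ per serve.
Mixed items that are flagged discretionary but contain core components are
therefore credited entirely to the discretionary pool; the flag's source
list makes that call, not this package.

Water is volumetric: intake events in cups (1 cup = 250 mL), scored in cups
and reported in litres as a convenience. Fruit/vegetable variety is the
number of distinct type identifiers consumed per day, averaged over
recorded days (fractional means are scored with the same [k, k+1) bands, so
2.5 types/day earns 2 points). A recorded day is any `day_index` with at
least one event; partial days count. All totals divide by recorded days;
records with fewer than 2 recorded days are excluded with reason
`insufficient_days` before any scoring.

## Misreporting screen

BMR uses the weight-only Schofield (1985) equations (sex × age band,
MJ/day), with band edges 30 and 60 both assigned to the 30–60 band; ages
below 18 are out of scope, matching the adult study range. EI:BMR is
(mean daily energy in MJ) / BMR. The "top and bottom 2.5%" trim is by rank:
`k = floor(0.025·N)` per tail, ties broken by participant id. The rank rule
is chosen over percentile interpolation because it is the only simple rule
whose arithmetic removes exactly 12 of 272 (interpolated percentiles leave
6-vs-7 per tail ambiguous). The screen always runs on the post-day-filter
sample, so that count is the percentile denominator.

## Construct-validity statistics

Index agreement is a paired t mean difference with a t-based CI plus
Spearman correlation. Bivariate associations use Spearman (average ranks)
for continuous covariates, a two-sample t-test (pooled variance by default;
`equal_var=False` gives Welch) for binary ones, and one-way ANOVA for
multi-level ones. Tertiles use average ranks cut at n/3 and 2n/3, so tie
groups share a tertile; an all-tied score vector is degenerate and assigned
tertile 1 with a warning. The poor-diet outcome is membership in the lowest
tertile under both indices (or under the DQS alone when no comparator is
supplied). The logistic model is a maximum-likelihood fit (statsmodels)
with dummy coding against declared reference levels, Wald CIs
exponentiated to odds ratios, Nagelkerke pseudo-R², and a classification
rate at the 0.5 probability threshold. Collinearity is screened by pairwise
|Pearson r| > 0.8 (configurable); correlated groups are formed by graph
connectivity and one representative is retained by declared priority.
Missing values are never imputed; every analysis is complete-case.

## Synthetic cohorts

The generator emulates the structure of a food-record validation study, not
any particular dataset: 280 participants by default, 4-day records with 8
planted single-day records, between-participant lognormal serve intakes
(medians: fruit 0.8, vegetables 2.8, grain 3.8, milk 1.2, meat 1.2
serves/day), gamma-distributed moderation energy (discretionary 1350, SSB
150, alcohol 120 kJ/day), truncated-normal water (4.5 ± 2 cups), and a
latent diet quality propensity driven by age and attention-to-diet so the
validity battery has real signal. Heavy (~×2.5) and light (~×0.2)
misreporting factors are applied to a 5% subset's amounts, planting them in
the EI:BMR tails. These defaults produce cohort mean totals near the
high-40s out of 100 with SD ≈ 9 — the moderate diet quality typical of
Australian adults — but matching any real score distribution is explicitly
not a goal.

Events are realised constructively: each participant-day's target serves
are converted to gram amounts through single-group reference items (plus an
explicitly-subtracted multi-group sandwich item on day 1), and variety
targets select that many distinct typed items. Amounts are left unrounded,
so with day-to-day noise disabled the aggregation chain recovers the
planted true means to 1e-9 — the package's end-to-end oracle. A
least-squares portion solver with gram rounding was considered and
rejected: rounding breaks the exact round-trip that anchors the test suite,
and the constructive allocation produces equally plausible records.

What the generator does **not** emulate: day-of-week (weekend) intake
shifts, correlated multi-item meals beyond the sandwich, portion-size
estimation error, item misidentification, or seasonal variety patterns.
Passing tests therefore demonstrate correctness of the scoring arithmetic
and pipeline plumbing on records of realistic magnitude — not robustness to
the measurement error structure of real image-based records.

## Numerical choices and limitations

* Singleton-band tolerance 1e-9 (absolute); all other band membership is
  exact floating-point comparison.
* Aggregation sums are plain float addition; permutation of events changes
  results only in the last ulps, and tests compare at 1e-12 relative.
* `tail_exclusion` on an all-tied ratio vector still removes k per tail
  (lowest ids first); the exact-count guarantee is only meaningful for
  distinct ratios.
* Quasi-complete separation in the logistic model raises a convergence
  error naming the suspect dummy columns (|coefficient| > 15) rather than
  reporting unstable odds ratios.
* The pipeline's exclusion order (day filter → tail screen → scoring) is
  fixed; running the screen on the pre-filter sample would change the
  trim denominator and is deliberately not offered.
* Scoring assumes adult serve targets; age-specific serve recommendations
  (children, adolescents) are out of scope.
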