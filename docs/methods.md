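# Methods

`pvsignal` implements post-marketing safety-signal detection for a single
drug of interest against the background of a spontaneous-report database in
the FAERS quarterly-extract dialect, together with a synthetic generator of
such extracts so every stage can be validated against known ground truth.

## Report cleaning

Spontaneous-report databases contain multiple versions of the same case:
follow-up submissions share a CASEID but carry new PRIMARYIDs and later
receipt dates (FDA_DT). We keep, per CASEID, the version with the latest
FDA_DT, breaking ties by the largest PRIMARYID. This rule subsumes the pure
max-PRIMARYID convention whenever follow-ups receive both later dates and
larger identifiers (which is how real resubmissions behave, and how the
generator emits them); `deduplicate(rule="max_primaryid")` switches to the
pure identifier rule. Deduplication runs across the whole loaded quarter
range because cases are resubmitted across quarters.

Target-drug identification matches DRUGNAME values against a synonym list
(brand, generic and trial-code variants) case-insensitively after collapsing
whitespace. Matching is exact by default — substring matching is available
behind a flag but risks combination-product false positives. The shipped
default list carries the twelve name variants under which tildrakizumab
appears in such databases, including the misspelt brand variant that occurs
in the published list.

The analysis set is restricted to reports where a matching drug has role
code PS (primary suspect). Handling-and-administration PTs that are not
adverse reactions ("Product dose omission issue", "Needle issue", …) are
removed from reaction lists, and "Product used for unknown indication" from
indication lists; a report left with no reactions is dropped and logged.
Exclusions are applied uniformly to the target set and the background —
the rule describes what counts as an adverse reaction, not a property of the
target drug — so denominators on both sides refer to the same event
universe. Cleaning-stage counts (raw rows, after dedup, after PS filter,
after exclusion) are recorded and are non-increasing by construction.

Demographic parsing keeps "unknown" as a first-class category: age uses
AGE_COD unit conversion (YR; DEC = decades; MON/WK/DY/HR scaled to years),
weight converts LBS to kg, and anything unparseable becomes unknown rather
than being dropped, because descriptive tables in this field report unknowns
inside the denominator.

## Contingency tables

For each term t (a MedDRA PT, or an SOC through a PT→SOC lookup) the 2×2
table counts **unique reports**: a = target reports with t, b = target
reports without, c = background reports with, d = background without. A
report listing a PT twice, or two PTs in the same SOC, counts once. The
background is every deduplicated report whose PS drug is not the target;
reports mentioning the target in a non-PS role stay in the background by
default (flag to drop them). Report-level counting matches how case counts
are presented in safety tables; an event-pair counting mode would be a
sensitivity analysis, not the default. Tables below the reporting threshold
(N < 3 by default) are still built, just flagged.

The PT→SOC map is a plain two-column table. The shipped map is a small
synthetic demonstration vocabulary (30 PTs over 10 SOCs); it is not a
licensed MedDRA dictionary, and real analyses must supply their own.

## Disproportionality estimators

With n = a+b+c+d and expected count E = (a+b)(a+c)/n:

- **ROR** = ad/bc, 95% CI exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
- **PRR** = [a/(a+b)]/[c/(c+d)] with the Pearson χ² statistic
  n(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)], uncorrected by default (Yates optional).
- **RRR** = a/E, the observed-over-expected ratio.
- **IC** = log₂(RRR) in bits. The default lower bound is the Norén
  closed-form approximation IC025 = IC − 3.3(a+0.5)^−1/2 − 2.0(a+0.5)^−3/2.
  A non-standard "fixed-width" mode (IC − constant, default 1.66) is provided
  only for matching outputs that subtract a constant from IC; published
  tables of this kind sometimes show a near-constant IC−IC025 gap that no
  standard interval reproduces.
- **EBGM** (simple surface) = RRR with a one-sided 5% log-normal bound
  EB05 = exp(ln RRR − 1.645·√(1/a+1/b+1/c+1/d)). This simplified form is the
  default because it preserves the identity IC = log₂(EBGM) that published
  row sets of this kind satisfy, making the Bayesian columns internally
  consistent with the IC column.

Algebraic facts used as test invariants: for ad > bc, ROR > PRR > RRR (with
equality at independence); IC ≡ log₂(RRR); doubling all cells leaves the
ratios unchanged and doubles χ².

**Full MGPS.** `mgps_full` implements the DuMouchel empirical-Bayes
gamma-Poisson shrinker: the rate multiplier λ has a two-component gamma
prior w·Γ(α₁,β₁) + (1−w)·Γ(α₂,β₂) (shape/rate), hyperparameters maximise
the marginal likelihood of a ~ Poisson(λE) (a negative-binomial mixture,
optimised by Nelder–Mead over log/logit-transformed parameters from the
conventional (0.2, 0.1, 2.0, 4.0, ⅓) start), and per-table values are the
posterior geometric mean EBGM = exp(E[ln λ | a]) and the 5th posterior
percentile (bracketed root of the posterior mixture CDF). Hyperparameter
fitting is only meaningful with tens of tables or more; the fit refuses to
return an optimum worse than its initial point. The full shrinker is an
option (`ebgm_mode="dumouchel"`), not the default surface, for the
consistency reason above.

**Zero cells** raise a degenerate-table error by default; a Haldane–Anscombe
0.5 correction is available behind a flag. Reporting requires a ≥ 3 anyway,
so zero-a tables never reach classification in the default pipeline.

**Signal rules.** ROR: N ≥ 3 and CI lower bound > 1. PRR: PRR ≥ 2, χ² ≥ 4,
N ≥ 3. BCPNN: IC025 > 0. MGPS: EB05 > 2. A term is *positive* when the ROR
criterion holds, *significant* when ≥ 2 criteria hold. "Significant" does
not require the ROR criterion to be among the two by default (a flag makes
it required); with these thresholds the distinction is rarely exercised
because ROR is the most sensitive of the four. All thresholds are
configurable. No multiplicity correction is applied — the criteria are
screening rules, not calibrated tests, and the end-to-end tests assert their
empirical operating characteristics (detection and false-positive rates on
synthetic data), not nominal error levels.

## Time to onset

TTO = event date − earliest fully-specified therapy start among PS entries
of the target drug, in days. Partial (YYYYMM/YYYY) or missing dates, and
negative intervals (event before therapy, i.e. data-entry errors), are
excluded with counted reasons; included + excluded always equals the input
count. One TTO per report; SOC-level comparisons reuse the report's interval
for each SOC its PTs map to.

Summaries are median and IQR (linear interpolation). Binning uses calendar-
free 30-day months and 90-day quarters, with the final bin absorbing the
remainder up to the 365-day year cutoff (inclusive) and an over-year bin
beyond it; counts always partition the input. Growth rates are
(N_t − N_{t−1})/N_{t−1} in percent to one decimal, undefined (None) after a
zero count.

The Weibull fit is maximum likelihood: the shape β solves the profile score
1/β + mean(ln t) − Σtᵝln t/Σtᵝ = 0 by bracketed root finding (computed on
t/max(t), which leaves the equation unchanged and avoids overflow), and the
scale is η = (mean tᵝ)^{1/β}. Zero-day intervals are shifted to 0.5 days
(event within the first day) and counted. 95% CIs come from the observed
information on (ln β, ln η) (central-difference Hessian, step 1e−5),
exponentiated back — parameters are positive, so the normal approximation
belongs on the log scale. β < 1 is labelled "early" onset (decreasing
hazard): most events cluster soon after therapy start; η is the time by
which 63.2% (1 − 1/e) of events have occurred, identically at t = η for any
β. Goodness of fit is the one-sample Kolmogorov–Smirnov test against the
fitted CDF, without a Lilliefors-type correction for the estimated
parameters — the standard practice in this literature, which makes the test
conservative (p-values biased upward). Kruskal–Wallis (tie-corrected, χ²
p on k−1 df) compares onset across groups, unadjusted for multiplicity.

## Sex-stratified signals and descriptives

Stratified analysis recomputes the full 2×2 and all four estimators inside
the female and male report subsets (unknown sex dropped from both), and
tests the between-stratum difference with z = (ln ROR_f − ln ROR_m)/
√(se_f² + se_m²), se recovered from the log-normal CIs; a Breslow–Day-style
alternative was considered but the z-test on the log difference is the
transparent default for exactly two strata. A term with no exposed cases in
a stratum yields a one-sided record with a note.

The demographics summary reports counts and percents (one decimal) per
category for sex, age (18–64 / 65–85 / ≥86, plus <18 when present), weight
(<50 / 50–100 / >100 kg), reporter occupation, country, serious outcomes,
indications and reporting year, with unknowns in every denominator.
Outcomes and indications are multi-valued per report, so those columns may
sum past 100%; the single-valued variables sum to the total exactly.

## Synthetic data generator

The generator emits "$"-delimited DEMO/DRUG/REAC/THER/INDI/OUTC/RPSR tables
plus a ground-truth ledger (per-case canonical version, target status, true
onset interval; per-PT true relative risk and exposed counts). Identical
config and seed give byte-identical files.

What it emulates, with defaults chosen to mirror the marginal structure of
a recent six-year single-drug slice of a spontaneous-report database:

- ~2% of reports have the target drug as primary suspect (`target_prob`;
  the scale of a niche biologic against a whole-database background, sized
  so a desk-scale run still yields hundreds of exposed cases);
- per-report drug counts ~ truncated geometric (p = 0.45, max 5), exactly
  one PS drug per report, other roles SS/C/I;
- PT occurrence: independent per-PT Bernoulli draws at configured baselines,
  multiplied by the injected relative risk (optionally sex-specific) when
  the target is PS; reports with no draw get one PT from the renormalised
  probability vector, so every report has ≥ 1 reaction. Because baselines
  sum to ≈ 0.35, this fallback fires often and most reports carry a single
  PT: marginal PT frequencies run ~3× their nominal baselines while
  relative risks between exposed and background are preserved — the
  quantity signal detection consumes. Injected defaults: relative risks 10,
  8, 5 and 4 on four PTs, everything else null;
- onset: event date = therapy start + round(Weibull(β = 0.89, η = 269.56
  days)) — an early-type law with ~16% of events in the first month and
  ~23% beyond a year;
- missingness at published-table rates (sex 16%, age 58%, weight 79%) and
  heavy date loss (40% each for event and therapy-start dates, plus 10% of
  surviving dates degraded to YYYYMM or YYYY partials), leaving ~30% of
  exposed reports with usable onset intervals;
- duplicates: 10% of cases get a second version with strictly larger
  PRIMARYID and later FDA_DT (clamped into the generated range), so the
  dedup rule has a unique correct answer;
- a handling-issue PT ("Product dose omission issue") injected into 5% of
  reports to exercise the exclusion filter;
- demographics sampled from categorical tables patterned on the published
  cohort (male-leaning sex ratio among knowns, consumer-majority reporters,
  US-dominated countries, mostly-absent outcomes).

What it does **not** emulate: reporting-delay dynamics and secular trends,
drug–drug interactions and the innocent-bystander effect, event-count
masking, correlated PT co-occurrence (PTs are conditionally independent
given exposure), real MedDRA coding beyond the flat PT→SOC lookup, and
free-text drug-name noise beyond the synonym variants. Passing tests
therefore demonstrate that the machinery recovers known associations and
known onset laws under clean spontaneous-report structure; they do not
certify performance against the confounding patterns of real data.

## Problem sizes and numerical conventions

The analysis scripts run 50,000 synthetic reports over eight quarters (~1,000
exposed cases); operating-characteristic tests use 50 replicates of 20,000
reports; Weibull recovery uses 200 replicates at the 335-interval sample
size with truth β = 0.89, η = 269.56 — sizes at which every documented check
is stable under reseeding. Estimates are reported to two decimals (growth
rates to one) with full precision retained internally. Root brackets:
shape ∈ [1e−3, 1e3]; posterior quantiles bracketed by component-gamma
extreme quantiles. The KS statistic uses the exact sup-distance as computed
by scipy; identical-valued Kruskal–Wallis groups short-circuit to H = 0,
p = 1 rather than erroring on zero variance.

## Known limitations

- The simplified EBGM surface is deliberately not a shrinkage estimator;
  with small counts it overstates EB05 relative to the full shrinker. Use
  `ebgm_mode="dumouchel"` when shrinkage matters.
- The Norén IC025 is an approximation to the BCPNN posterior interval,
  accurate for the moderate counts typical here but not exact.
- Signal criteria are screens; their false-positive behaviour is asserted
  empirically on synthetic nulls, and nothing corrects for multiplicity.
- The KS p-value ignores parameter estimation (anti-conservative rejection
  is not a risk; failure to reject is weaker evidence than it looks).
- Real-data idiosyncrasies (free-text drug names, partial-date conventions
  other than YYYYMM/YYYY, non-ASCII country codes) are out of scope beyond
  what the dialect reader normalises.
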