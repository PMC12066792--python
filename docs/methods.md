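# Methods

This note documents the statistical model, the algorithmic choices made
where the design was genuinely open, the synthetic-data generator's scope,
and known limitations.

## Cohort model and cleaning

A claim is one hospitalization: demographics, insurance type
(urban-employee vs urban-rural-resident), hospital level (primary /
secondary / tertiary), one of six charge grades, length of stay (LOS) in
days, total cost in unitless currency, an ICD-10 main diagnosis, and up to
seven positional ICD-10 secondary-diagnosis (CC) slots. Currency is never
converted; all cost statistics are on the raw scale.

Cleaning applies three filters with a fixed precedence so the audit counts
are well defined: incomplete record → LOS above the ceiling → cost above
the reimbursement cap. Defaults are a 60-day LOS ceiling and a 22,189 cost
cap, both **strict** comparisons (a 60-day stay or a cost exactly at the
cap is kept — the exclusion rules are read literally as "over" /
"exceeding"). Cleaning never raises on content; it drops, counts, and is
idempotent. Duplicate patient identifiers are allowed (readmissions).

## Stage 1: CC severity by cost impact

Per diagnosis slot *i* ∈ 1..7, OLS of **raw** cost on one 0/1 indicator per
distinct code observed in that slot plus one-hot controls (reference
levels: male, urban-employee, primary hospital, the lowest charge grade,
the youngest age bin, the shortest LOS bin). Raw cost — not log cost — is
the response because severity tiers are defined by ranking currency-scale
coefficients; a log-response option exists for sensitivity analysis only.
The slot reading of "seven models" is used: model *i* sees only the codes
occupying slot *i*.

Selection uses raw two-sided p < α (default 0.05) with no multiplicity
correction — deliberately, since the tiering rule is defined on the
selected set, not on inferential error rates. Within each model the
significant codes are ranked by coefficient, descending, ties broken by
code lexicographically (the ranking rule needs a total order). Tier
boundaries use ceilings on ranks: with J significant codes, ranks
1..⌈0.30·J⌉ are MCC and ranks up to ⌈0.60·J⌉ are mCC. Negative significant
coefficients sort to the bottom and can reach MCC/mCC only for tiny J. A
code significant in several models takes its **most severe** tier; the
retained evidence row is the tier-giving model with the largest
coefficient.

Patient typing: any MCC → type I, else any mCC → type II, else type III;
codes absent from the severity table count as non-CC, so typing is total.

Degenerate cases: a constant response yields all-zero coefficients with
p = 1 by convention; constant or aliased design columns are pruned with a
logged warning before fitting (never silently).

## Stage 2: variance-reduction tree

Classic ID3 splits categorical factors multiway on information gain, which
has no continuous-target form; the continuous-target analogue used here
splits on the reduction-in-variance fraction
(Var_parent − Σₖ (nₖ/n)·Varₖ)/Var_parent with **population** variances,
the same statistic used to evaluate whole schemes. Each factor is used at
most once per root-to-leaf path; gain ties go to the earlier factor in the
declared order; a node stops when its variance is zero, it holds fewer than
2·min_leaf cases, depth is exhausted, or no factor reaches min_gain
(default 0.001).

Default grouping factors are patient type, hospital level, age bin,
insurance and LOS bin — severity enters the tree only through the fitted
patient type, not as raw codes, which keeps the tree small and the groups
auditable.

Undersized leaves (default min_leaf = 200, the conventional floor for a
stable DRG) are merged smallest-first into the surviving group with the
nearest mean cost, recomputing merged means, until every group meets the
floor or one group remains. Nearest-mean absorption is chosen because
intra-group cost homogeneity is the method's objective. Final groups are
renumbered 1..K by ascending mean cost.

Assignment is total: a record with a factor level unseen in training
routes, at each such node, to the child whose training mean is nearest the
node's own mean (deterministic; ties to the lower mean). Hence enrollment
is always 100%.

Repeated trials: `run_trials` performs seeded random 70/30 train/test
splits (the split ratio is a package choice; the published-style final
scheme is refit on the full cohort since the published group sizes sum to
the whole cohort), reports per-trial test-set RIV, and flags whether all
trials agree on the group count and root factor. Consistency is reported,
never raised.

## Evaluation and payment arithmetic

Per group: sample (n−1) SD, CV = SD/mean on raw cost, quartiles by linear
interpolation between order statistics (the common statistics-package
default; the published tables' quantile rule is unstated, so quartile
values themselves are not asserted against them — only arithmetic derived
from printed values is), IQR = P75 − P25, weight = group mean / overall
mean of the analyzed cohort, ceiling = P75 + 1.5·IQR. Overuse is **strictly
above** the ceiling; the "times" ratio is overuse mean / normal mean and is
reported missing when a side is empty. LOS medians use the lower median for
even n. Projected full-control savings are Σ_g n_overuse·(mean_overuse −
ceiling), clamped at zero per group; this definition reproduces both
published savings totals from the published tables to the cent scale.

RIV is reported as a percentage and is bounded in [0, 100] by
construction. (The source tables print scheme RIVs above 100%, which no
variance-explained fraction can reach; the bounded standard definition is
implemented and no check is pinned to those printed values.)

## Synthetic cohorts

The generator emulates the structure the method assumes, not any real
cohort's joint distribution: categorical marginals matching the published
cohort composition (49.5/50.5 sex, 62.7/37.3 insurance, 19.6/32.7/47.7
hospital levels, six charge grades, five age bins dominated by 65+);
discretized log-normal LOS (≈38/21/41% below 9 / 9–12 / above 12 days,
capped at 60); log-normal baseline cost with **additive** currency-scale
CC and control effects plus Gaussian noise, truncated at zero (truncation
is logged; a multiplicative switch exists for robustness studies). The
additive form matches the linear cost model stage 1 fits.

CC occupancy is categorical per slot — each code's marginal prevalence is
exactly its catalog value and a slot holds at most one code. LOS is drawn
independently and carries an additive per-stratum cost effect; this plants
the positive LOS–cost dependence causally, so regressions that control for
LOS strata remain unbiased for the planted CC coefficients (a rank-coupled
LOS would instead be a descendant of cost and would attenuate them). The
default catalog plants 21 codes, three per slot, with well-separated
high/moderate/low effects (≈1,100–1,400 / 400–500 / 40–70) and an overall
mean cost near 1,560, matching the published cohort mean; the defaults were
fixed once from the published cohort description.

What passing tests on synthetic data show: that the implementation
recovers planted structure (coefficients within CIs, the planted top-cost
codes tiered MCC, the tree's root split matching exhaustive search) under
the model's own assumptions. What they do not show: performance under
model misspecification, miscoding, or the dependence structures of real
claims (e.g., CC co-occurrence, hospital–severity confounding), none of
which the generator plants.

## Benchmark grouper

The national-standard grouper is modeled as data: a severity lookup
(MCC/CC/nonCC; patient severity = maximum over their codes) plus an
ordered first-match-wins rule list with a guaranteed default label. The
bundled fixture assigns severity by *prevalence* in the default synthetic
catalog — deliberately misaligned with cost impact — and crosses it with
hospital level and insurance into up to 18 labels, giving the comparison
pipeline a realistic incidence-style strawman. Rule overlap is detected
and warned about, not rejected.

## Problem sizes and determinism

Default test and demonstration cohorts are 1,200–4,000 records; recovery
checks use 20,000 records and 20 replicates, sizes at which the planted
coefficient separation dwarfs its standard error. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`;
categorical levels are drawn in sorted order so semantically equal
configurations yield byte-identical cohorts, and fitted schemes serialize
to sorted-key JSON so reruns are byte-identical.

## Known limitations

* The 30/60 percentile tier cuts, ceiling-based rank boundaries, tie
  rules, and the nearest-mean merge direction are package choices where
  the method description is silent; all are documented above and fixed.
* OLS on raw, right-skewed cost is the method's own specification; its
  p-values are anti-conservative under heteroscedasticity. No robust or
  mixed-effects variants are provided.
* No ICD-10 validation beyond non-empty strings; no surgical-procedure
  axis; no reimbursement adjudication; no trimming re-estimation loops.
* The published per-group tables bundled for arithmetic verification
  contain two internal inconsistencies (one overuse row whose subgroup
  counts are off by nine, and scheme RIVs above 100%); they are transcribed
  faithfully and exempted from the corresponding checks, not imitated.
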