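# drgmix

Two-stage DRG (Diagnosis-Related Group) case-mix grouping for inpatient
claims, with the full payment-evaluation suite and a synthetic-claims
generator.

## The problem

Prospective hospital payment groups hospitalizations into DRGs — classes of
cases with similar clinical profile and resource consumption — and pays a
fixed rate per group. A grouping is only as good as its handling of
comorbidities and complications (CCs): national standards typically tier CC
codes by *incidence*, but common CCs are not necessarily expensive ones, so
in regions whose disease spectrum differs from the reference population the
resulting groups are heterogeneous in cost. `drgmix` implements a local,
cost-driven alternative in two stages:

**Stage 1 — CC severity by cost impact.** Seven ordinary-least-squares
regressions, one per secondary-diagnosis slot *i*, of raw hospitalization
cost on CC indicators and controls:

    y = Σⱼ βᵢⱼ xᵢⱼ + Σₙ γₙ controlₙ + e,   i = 1, …, 7

where xᵢⱼ ∈ {0,1} flags the *j*-th CC code in slot *i* and the controls are
sex, age stratum, length of stay stratum, hospital level, insurance type and
charge level. CCs significant at p < 0.05 in at least one model are ranked
within each model by coefficient; the top 30% are **MCC** (major), ranks
30–60% **mCC** (moderate), the rest non-CC. Patients are typed I / II / III
by their worst CC.

**Stage 2 — tree grouping by variance reduction.** An ID3-style multiway
decision tree on categorical factors (patient type, hospital level, age
stratum, …) splits each node on the factor maximizing the reduction in cost
variance, RIV = (Var_parent − Σₖ (nₖ/n)·Varₖ)/Var_parent. Leaves with fewer
than 200 cases merge into the nearest-mean group; final groups are numbered
by ascending mean cost.

**Evaluation.** Per group: mean, SD, CV = SD/mean, case-mix weight =
group mean / overall mean, and the boxplot-rule payment ceiling
P75 + 1.5·IQR. Cases above the ceiling form the "overuse" subgroup; under a
full-control policy the projected saving is Σ_g n_overuse·(mean_overuse −
ceiling). Scheme quality: number of groups, enrollment rate, share of
groups with CV < 1 and < 0.8, and RIV.

A rule-table benchmark grouper (CC severity from a user-supplied lookup,
first-match-wins rules) stands in for national-standard grouping, and a
synthetic-claims generator with planted cost effects makes every stage
testable by parameter recovery — the cohort behind the published results is
not publicly distributable.

## Worked example

```python
from drgmix import default_sim_params, generate_cohort, run_two_stage, PipelineConfig
from drgmix.stage2 import TreeParams

cohort = generate_cohort(default_sim_params(n=10_000, seed=1))
res = run_two_stage(cohort, PipelineConfig(seed=1, tree=TreeParams(seed=1)))

print("MCC tier:", res.classifier.severity_table_.codes_with_tier("MCC"))
print(res.stats.round(2).head(6).to_string(index=False))
print("groups:", res.grouper.n_groups_, "| RIV %.2f%%" % res.report.riv_pct,
      "| %%CV<0.8 %.0f%%" % res.report.pct_cv_lt_08, "| savings %.0f" % res.savings)
```

prints

```
MCC tier: ['A40', 'B37', 'B95', 'D46', 'F43', 'G97', 'T06']
 group_id   n   mean     sd   cv     p75    iqr  weight  upper_limit
        1 278 474.30 309.12 0.65  665.66 428.84    0.31      1308.92
        2 486 643.95 310.76 0.48  842.14 407.86    0.42      1453.92
        3 223 680.72 313.96 0.46  868.91 388.34    0.44      1451.43
        4 248 820.28 315.21 0.38 1008.01 383.98    0.53      1583.98
        5 390 877.81 331.47 0.38 1074.32 423.76    0.57      1709.96
        6 465 911.42 295.49 0.32 1090.06 377.97    0.59      1657.02
groups: 30 | RIV 72.43% | %CV<0.8 100% | savings 44031
```

The seven MCC-tier codes are exactly the seven highest-effect codes planted
by the generator (one per diagnosis slot): stage 1 recovered the planted
severity ordering. Every final group has CV < 0.8 (the homogeneity
criterion for an acceptable DRG), each group's `upper_limit` is its
P75 + 1.5·IQR payment ceiling, and `savings` is the projected cohort-wide
reduction if every overuse case were reimbursed at its ceiling.

The same pipeline is available from the shell:

```sh
drgmix simulate --n 10000 --seed 1 --out claims.csv
drgmix compare  --claims claims.csv --seed 1 --out results/
drgmix tables-check
```

`compare` runs both the two-stage grouping and the rule-table benchmark on
one cohort and writes a side-by-side report.

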