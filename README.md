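# historiskscore

Histogram-based risk scoring of histopathology patch confidence scores,
with a survival-analysis and molecular-association evaluation layer.

## The problem

Weakly supervised classifiers for whole-slide images emit one
confidence score per tissue patch, so every case (patient) carries a
whole *distribution* of scores rather than a single prediction.  In
bladder-cancer prognosis, the shape of that distribution is
informative: cases whose scores pile up in a low decile of their score
range behave differently from cases dominated by a middle decile.
`historiskscore` implements a scoring system that turns the per-case
score distribution into a scalar risk score and a binary risk group,
corrects the score for distribution shift when applied to an external
cohort, and evaluates the resulting groups the way a clinical study
would: Kaplan–Meier curves, log-rank tests, Cox proportional-hazards
models, time-dependent AUROC, and contingency-table associations with
molecular signatures.

It is aimed at computational-pathology researchers who have patch-level
scores (from any model) plus case-level follow-up, and want a
reproducible, interpretable case-level risk stratification without
retraining anything.

## The scoring system

For each case with patch scores spanning `[s_min, s_max]`:

1. histogram the scores into 10 equal-width bins,
   `w = (s_max − s_min) / 10`;
2. max-normalize the bin counts so each bin frequency `D_k ∈ [0, 1]`;
3. the unadjusted score is `S_u = D_m − D_r`, the difference between a
   middle bin *m* and a reference bin *r* dominated by negative
   patches (defaults r = 2, m = 5);
4. adjust for the cohort's own distribution: with `µ = mean(S_u)` and
   `µ_1/2 = median(S_u − µ)`, the final score is
   `S_CSD = −µ + µ_1/2 + S_u`;
5. threshold at `T = µ₀ + 1.05·σ₀ + α`, where µ₀ and σ₀ are the mean
   and SD of `S_u` on a development cohort and `α = µ₀ − µ_c` corrects
   for the mean shift of the target cohort. `S_CSD ≥ T` is high risk.

A midrange quality check verifies that per-case equal-width bins line
up across cohorts (cohort medians of the bin-r and bin-m score
midpoints near 0.17 and 0.41).

The package also includes the upstream slide preprocessing (tissue
bounding box from a thumbnail, 2048 px tiling, >50 %-white tile
exclusion, area-averaged 512 px patches) and a synthetic cohort
generator — patch-score mixtures per latent risk group, exponential
survival with group-specific hazards and censoring, binary signatures
with configurable odds ratios — so the full pipeline runs and is
testable entirely offline.

## Worked example

```python
from historiskscore import SyntheticCohortConfig, generate_cohort, score_cohort
from historiskscore.survival import km_estimate, logrank, cox_fit

cfg = SyntheticCohortConfig(n_cases=412, seed=7)
cohort = generate_cohort(cfg)
cases, meta = score_cohort(cohort.patch_scores)

tm = meta["threshold_model"]
print(cases["risk_group"].value_counts().to_dict())
print(f"threshold T = {tm.threshold:.3f}")

m = cohort.survival.merge(cases[["case_id", "s_csd", "risk_group"]], on="case_id")
km = km_estimate(m.time_months, m.event, m.risk_group)
print({g: round(e.median, 1) for g, e in km.items()})
chi2, p = logrank(m.time_months, m.event, m.risk_group)
fit = cox_fit(m, covariates=["risk_group"])
r = fit.summary.loc["risk_group_high"]
print(f"log-rank p = {p:.2e};  HR {r.hr:.2f} (95% CI {r.ci_low:.2f}-{r.ci_high:.2f})")
```

prints

```
{'low': 297, 'high': 115}
threshold T = 0.357
{'low': 54.3, 'high': 27.5}
log-rank p = 2.37e-05;  HR 1.91 (95% CI 1.41-2.60)
```

The 412-case synthetic cohort splits into 297 low- and 115 high-risk
cases at the cohort threshold 0.357; the high-risk group reaches median
overall survival at ~28 months versus ~54 months for the low-risk
group, with a Cox hazard ratio of 1.91 — i.e. the scoring recovers the
prognostic separation built into the generator (true hazard ratio 2).

The package also ships the published 2×2 tables of TSC1 / ERBB3 /
FGFR3 mutation status versus risk group in the TCGA bladder-carcinoma
cohort:

```python
from historiskscore.association import fisher_or
from historiskscore.datasets import load_mutation_tables

res = fisher_or(load_mutation_tables()["TSC1"])
print(f"TSC1 OR {res.odds_ratio:.2f} (95% CI {res.ci_low:.2f}-{res.ci_high:.2f}), p={res.p_value:.4f}")
# TSC1 OR 0.36 (95% CI 0.15-0.76), p=0.0041
```

A `historiskscore` command-line tool exposes the stages
(`simulate`, `tile`, `score`, `survival`, `associate`, `run`); see
`historiskscore --help`.

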