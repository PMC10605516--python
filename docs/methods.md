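# Methods

## The scoring model

The package scores a case by the shape of its patch-score
distribution.  Scores are binned into 10 equal-width bins over the
case's own range `[s_min, s_max]` (bin width `(s_max − s_min)/10`);
bins are right-open with the last bin closed so `s_max` is counted and
counts sum exactly to the number of patches.  Bin counts are divided by
the case's maximum bin count, putting every bin frequency in [0, 1]
with at least one bin equal to 1.  The unadjusted score is the
difference between the middle bin and a negative-dominated reference
bin, `S_u = D_m − D_r ∈ [−1, 1]`.

Because bins are computed over each case's own range, the histogram —
and hence `S_u` — is invariant under any strictly increasing affine
transform of that case's scores.  This is the property that lets the
same scoring rule transfer across models whose score scales differ, and
it is asserted by the test suite.

**Degenerate cases.** A case whose scores are all identical has zero
bin width; all mass is assigned to the first bin and `S_u = 0` — a case
with no score spread carries no dominance signal.

**Bin selection.** When binary patch labels are available, the
reference bin *r* is chosen as the lowest pooled-score decile whose
fraction of negative patches exceeds 0.5, and *m* defaults to 5, the
median decile of the remainder; without labels the defaults (2, 5) are
used.  Pooled-score deciles are used for selection (a single global
partition), while scoring uses per-case equal-width bins; the midrange
QC below guards this identification.  If no decile is
negative-dominated the selection errors out and asks for manual
indices; both indices are configurable everywhere.

## Out-of-distribution adjustment and threshold

An external cohort may have a shifted `S_u` distribution.  With
`µ = mean(S_u)` over the cohort and `µ_1/2 = median(S_u − µ)`, each
score becomes `S_CSD = −µ + µ_1/2 + S_u`; the adjustment is one
cohort-wide constant, `median(S_u) − 2µ`.  Note this constant vanishes
after a single application (the adjusted scores have
`median − 2·mean = 0`), so the adjustment is idempotent.

The risk threshold is `T = µ₀ + 1.05·σ₀ + α`, with µ₀ and σ₀ the mean
and sample standard deviation (n−1 denominator) of the development
cohort's `S_u`, and `α = µ₀ − µ_c` the correction for the target
cohort's mean shift.  The 1.05 multiplier is a fixed model constant,
kept configurable (`sigma_factor`).  Cases with `S_CSD ≥ T` are high
risk; the boundary case goes to high risk (ties are measure-zero for
continuous scores).  Shifting every cohort score by +c shifts both α
and T by −c, so classification is shift-stable by construction.

**Midrange QC.** Since bin ranges differ per case, the cohort median
and IQR of each case's bin-r and bin-m score midpoints
(`s_min + (k − 0.5)·w`) are compared to reference medians 0.17 and 0.41
(IQRs 0.16–0.18 and 0.37–0.42).  The default pass tolerance is ±0.05 on
the medians — wide enough to accept the synthetic generator's
defaults (≈0.155 / 0.45), tight enough to flag a cohort whose bins have
drifted a full bin width.

## Slide preprocessing

Tissue is located on a low-magnification thumbnail by gray
thresholding; "white background" means intensity at or above the
threshold (default: Otsu's threshold on the thumbnail, shifted by half
an intensity level on integer images so boundary pixels stay tissue).
The minimal bounding box of tissue pixels — half-open, 0-based, so grid
arithmetic is exact — is scaled to the working magnification (origin
floored, far corner ceiled: the scaled box always covers the original),
divided into 2048-px tiles including padded partial edge tiles, and
each tile is excluded iff white pixels form a strict majority
(white_fraction > 0.5; a tile at exactly 50 % is kept).  Padding counts
as background, which biases mostly-empty edge tiles toward exclusion.
Kept tiles are downsized 2048 → 512 px by exact block averaging
(factor 4), the standard anti-aliased magnification change.  Pyramidal
slide formats are not decoded; any raster standing in for a pyramid
level works.

## Synthetic cohorts

The generator emulates the joint structure the analysis needs, not
histology itself:

* **Latent group**: Bernoulli(high_risk_fraction), default 0.3 —
  roughly the lethal fraction of a mixed-stage development cohort.
* **Patch scores**: Beta mixtures on [0, 1].  Both groups share a 10 %
  Uniform(0,1) background component (keeping each case's score range
  close to [0, 1], so per-case equal-width bins land near the fixed
  deciles) plus two concentrated components, Beta(12, 68) (mean 0.15,
  inside bin 2) and Beta(36, 44) (mean 0.45, inside bin 5), weighted
  75/15 in the low-risk group and 15/75 in the high-risk group.  This
  makes bin-2 vs bin-5 dominance the generative signal, tunable through
  two weights.  Patch counts per case are uniform on [200, 2000]
  (configurable; real per-case tile counts are cohort-specific).
* **Patch labels**: Bernoulli(score), so low scores are predominantly
  negative — sufficient structure for decile selection.
* **Survival**: exponential death times with hazard
  `baseline · HR^group` (defaults: baseline ln 2/60 ≈ 0.0116 events per
  month, i.e. ~60-month median survival in the low-risk group, and
  HR = 2, halving it), censored by an independent exponential
  (0.015/month).  Independent exponential censoring is the simplest
  mechanism satisfying the random-censoring assumption of KM/Cox.
* **Signatures**: binary markers with configured marginal prevalence
  and group odds ratio; the per-group rates are solved from the pair
  (prevalence, OR) by root finding, so empirical prevalence converges
  to the configured value regardless of group mix.  Defaults mirror
  three published bladder-cancer mutation markers (prevalences 39/412,
  45/412, 65/412 with ORs 0.36, 0.46, 0.49).

Each output table draws from its own child stream of the master seed
(SeedSequence spawning), so adding a signature never perturbs the
survival draws; patch scores are drawn vectorized per latent group.
Identical config and seed give identical tables.

What the generator does **not** emulate: pixel-level histology texture,
classifier miscalibration, per-case score-range pathologies (e.g.
outlier single patches compressing all bins), correlated censoring, or
covariate-dependent hazards.  Passing tests therefore demonstrate the
*algorithmic* correctness and statistical calibration of the pipeline
under its stated assumptions, not clinical performance on real slides.

## Evaluation layer

Kaplan–Meier, log-rank and Cox fits are delegated to lifelines; the
time-dependent AUROC is scikit-survival's cumulative/dynamic estimator
with inverse-probability-of-censoring weights (the incident/dynamic
variant is a reasonable alternative; cumulative/dynamic is the common
choice for fixed-horizon discrimination and is what is implemented).
Its standard error, when requested, is a case bootstrap.  Cox models
use the Efron approximation for tied event times; AIC is the
partial-likelihood AIC and BIC uses `k·ln(number of events)` as the
effective sample size, the usual convention for partial likelihoods.
Variance inflation factors are computed directly as `1/(1 − R²)` from
least-squares regressions of each design column on the others.
Columns whose values are exactly {low, high} are dummy-coded with
"low" as the reference, so reported hazard ratios are high-vs-low.

For 2×2 association tables the odds ratio is the conditional
maximum-likelihood estimate under Fisher's noncentral hypergeometric
model with the exact-test-inversion CI (scipy), not the sample
cross-product ratio; tests verify it against an independent log-OR grid
search of the conditional likelihood.  Chi-square tests on n×m tables
use no continuity correction (2×2 tables go through Fisher's test
instead); an optional Monte-Carlo p-value resamples tables with fixed
margins for sparse cases.  Post-hoc comparisons of multi-category
signatures use one-vs-rest Fisher tests ranked by p-value with
Benjamini–Hochberg critical values `rank/n_comparisons × FDR` at
FDR = 0.20 and the classic step-up rule with strict inequality.
Signatures are screened at chi-square p ≤ 0.10 before any post-hoc
testing; missing signature values are excluded (complete-case
analysis) unless explicitly retained.

## Numerical and design choices

* Median of an even-length list is the mean of the two central values.
* Histogram affine invariance is exact up to floating-point edge
  placement; scores exactly on a bin edge after transformation are a
  measure-zero concern for continuous scores.
* The development statistics (µ₀, σ₀) used by the pipeline default to a
  packaged synthetic development split (150 cases, fixed seed); supply
  your own development `S_u` values for real use.  Both "frozen
  development statistics" and "self-as-development" (α = 0) modes are
  exposed.
* Problem sizes in the test suite and acceptance script (n = 1000 × 100
  replicates for Cox coverage, 2000 permutation replicates for log-rank
  calibration, 412-case cohorts elsewhere) were chosen to keep
  Monte-Carlo error comfortably inside the asserted bounds while the
  whole suite runs in about a minute.

## Known limitations

* The threshold places high-risk cases in the upper tail of the
  development `S_u` distribution; if the development cohort is
  majority-high-risk, `µ₀ + 1.05σ₀` can exceed the high-risk mode and
  the split degenerates.  The development cohort is assumed to be
  majority low-risk.
* Decile selection assumes pooled-score deciles are meaningful across
  cases, i.e. scores are roughly on a common scale before per-case
  binning.
* No frailty, time-varying covariates or competing risks; no stain
  normalization or pyramidal-format decoding.
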