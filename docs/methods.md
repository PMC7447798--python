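# Methods

This note documents the statistical model, the synthetic world the generator
emulates, the numerical choices, and the limits of what a green test
establishes.

## The design

A cohort of monozygotic (MZ) twin pairs is classified by lifetime
major-depression (MD) status into discordant (one affected twin),
concordant-unaffected and concordant-affected pairs. The default cohort
composition is 27 / 42 / 6 pairs (150 twins, 39 affected). Within-pair
contrasts in discordant pairs carry the design's causal leverage; concordant
pairs act as negative controls and contribute between-pair information.

## Per-probe mean model

For probe *i*, twin *s* in pair *j*:

    M_is = beta0 + beta_MD * MD_s + beta_NK * NK_s + u_j + e_is,
    u_j ~ N(0, sigma_p^2),  e_is ~ N(0, sigma_e^2)

Because every pair has exactly two members, the orthonormal pair transform
s_j = (y_j1 + y_j2)/sqrt(2), d_j = (y_j1 − y_j2)/sqrt(2) splits the model
into two independent strata with variances sigma_e^2 + 2 sigma_p^2 and
sigma_e^2. We estimate each stratum's residual variance from its own OLS
residuals (the balanced-design ANOVA estimator) and combine the strata by
GLS. This is exact rather than iterative, and vectorizes across all probes
— the property that makes a 1000-permutation study affordable. Consequences
pinned down by tests:

- on a discordant-only design with a constant covariate the MD statistic
  equals the classical paired *t* statistic to machine precision;
- on mixed designs the fit agrees with iterative REML (`statsmodels`
  MixedLM) to ~1e-2 in the effect and ~0.1 in the t-value, the difference
  being the variance-estimation method, which is second-order at 150
  samples.

The Wald statistic uses a normal reference by default (`df_mode="bw"`
switches to a between-within t reference). Zero-variance probes are flagged
degenerate (stat 0, p 1). The per-probe effect size is reported as
R² = beta_MD² · var(MD) / var(M), clipped to [0, 1].

## Negative-control contrasts

Five contrasts are computed per probe. Contrast 1 (interest) is the MD fixed
effect above. Contrasts 4 and 5 are twin-order differences within
concordant-unaffected and concordant-affected pairs (one-sample t on pair
differences): under any status-driven model these are pure noise. Contrasts
2 and 3 are *status-matched* cross-pair-type comparisons:

- C2: concordant-affected pair means vs the affected twin of each
  discordant pair (all individuals affected);
- C3: concordant-unaffected pair means vs the unaffected twin of each
  discordant pair (all individuals unaffected);

both as Welch tests on pair-level values (a pair mean and a single twin have
different variances). The defining property, verified by test, is that a
genuine MD effect — which the twin design premise places in every affected
individual, including both twins of concordant-affected pairs — moves *none*
of the four control contrasts, while pair-type artifacts move them. An
alternative reconstruction (concordant-affected vs concordant-unaffected
pairs) was rejected because it responds to true signal and therefore filters
real probes out; the contrast set is isolated behind `ContrastSpec` so other
definitions remain pluggable.

## Variance model

The variably-methylated-probe statistic is F = var(cases)/var(controls)
(39 vs 111 samples by default), two-sided parametric p from
F(n₁−1, n₀−1). The F test ignores pair correlation deliberately; the
permutation null, which preserves the pair structure, is authoritative for
calling. Regional work uses log F, so "more variable" and "less variable"
are symmetric around zero.

## Regions and the trapezoidal area of influence

Probes enter region building if their statistic of interest lies in the
outer 5/95 (mean path) or 10/90 (variance path) genome-wide quantiles and no
control-contrast statistic lies in the outer 1/99 quantiles. A candidate
region is a maximal run of retained probes on one chromosome with
consecutive gaps ≤ 1 kb and a single statistic sign ("within 1 kb" binds
each gap, not the total span — published regions span more than 1 kb while
holding 4 probes). The score is the trapezoid sum h·(|a|+|b|)/2 over
consecutive probe pairs; the sign is kept as region direction so the score
is nonnegative. Construction is tested against a brute-force enumerator of
maximal valid runs, and the score against numeric quadrature.

The background universe — all maximal ≤ 1 kb runs of ≥ 2 probes with no
statistic filtering — defines where a region could in principle have been
found; enrichment null draws sample from it.

## Permutation scheme and FDR

Each of k permutations reassigns the pair concordance classes across pairs
without replacement (class counts are invariant) and picks the affected twin
uniformly within new discordant pairs; covariates and slides travel with
their samples. Everything downstream of relabeling is recomputed inside the
permutation, including the selection quantiles — an anti-conservative null
would result if thresholds were frozen at their observed values.

Probe-level: empirical p = (1 + #exceedances)/(N + 1) with the null pooled
across probes (t-like and log-F statistics share one scale across probes).
Pooling is what gives p-value resolution 1/(n·k) rather than 1/(k+1); at
k = 1000 and FDR < 1% the per-probe formula could never produce a single
call, so pooling is treated as the operative reading of the procedure.
Benjamini–Hochberg is then applied (via `statsmodels`), calls at q < 0.01.

Region-level: observed AUCs, sorted descending, are compared rank-by-rank
with the mean permuted order statistic (permuted lists are sorted and padded
with zeros or truncated to the observed length). For each threshold delta,
regions with observed − expected ≥ delta are called; the falsely-called
count is the median across permutations of permuted AUCs strictly above the
smallest called AUC; FDR = falsely called / called, capped at 1. Permuted
AUCs above the pooled (1 − trim_quantile) quantile (default 0.001) are
winsorized first, so one wild permutation cannot dominate the rank means.
The reported call set is the largest one with estimated FDR at or below the
target (10% mean path, 17% variance path). The estimator is noisy for call
sets of size ~1 (the median false count is then 0 or a small integer);
tests therefore pin its behavior at the scale the pipeline actually runs.

## Preprocessing

- beta → M uses base-2 logit with offset c = 0.001 (the offset value is a
  declared choice; tests are offset-robust).
- Detection filtering removes probes with detection p > 0.01 in ≥ 10% of
  samples (inclusive boundary) or on a cross-hybridization blacklist; a
  missing detection matrix skips the rule with a log entry.
- Quantile normalization maps every sample onto the cross-sample mean
  order-statistic distribution (plain, not probe-type-stratified: probe
  chemistry is not modeled here).
- Batch (slide) adjustment removes per-probe batch means exactly and
  rescales per-probe batch variances toward the pooled value after shrinking
  the batch variance estimate with 30 pseudo-observations. Full
  location/scale standardization (shrinkage 0) was rejected: with 12 samples
  per slide it erases genuine group-specific variability that happens to
  concentrate in a batch — exactly the signal the variance path looks for —
  while the shrunk version still removes systematic scale differences.
  Twin pairs share slides, so the primary within-pair contrast is
  batch-immune regardless.
- A PCA report (top PCs vs design factors) is a diagnostic, not a gate.

## The synthetic world

`simulate` emulates: clustered 450K-like probe placement with a controlled
isolated-probe fraction (default 0.25: a quarter of probes have no neighbor
within 1 kb, matching the array's reported geometry); bimodal baseline
methylation (mixture of low / intermediate / high beta components); a shared
pair component with pair_icc = 0.5 (sigma_p² / (sigma_p² + sigma_e²));
residual SD 0.25 M-units; slide shifts (SD 0.1) with six pairs per slide,
pairs assigned to slides in randomized order as a real plating protocol
would; NK proportions uniform on [0.02, 0.12] with optional case shift and
per-probe NK slopes (both off by default so covariate tests can toggle
them). Injected DMRs add a case-only M shift over a probe run constrained to
span 0.5–2.5 kb (the span range of published array DMRs); injected VMRs add
independent case-only noise sized so total case variance is var_ratio times
control variance. Affected twins in concordant-affected pairs carry the case
effect too. A shift of ~0.22 M-units reproduces the middle of the published
per-probe R² band (0.024–0.139); the recovery tests use 0.3 (R² ≈ 0.12).

Not emulated: probe type I/II chemistry, detection failures, SNP-affected
probes, cell-composition mixtures beyond the NK covariate, and genuine
genomic annotation (ChromHMM/island/LD-block tracks are random with
realistic shapes only). A green recovery test therefore establishes that the
*procedure* finds planted structure of realistic effect size and geometry at
its stated FDR — not that the biological findings of any particular cohort
would replicate.

## Determinism and numerics

One master seed drives every stochastic choice; per-permutation and
per-stage seeds derive from it deterministically (`default_rng((seed,
stream))`). Identical config + seed reproduces every output byte for byte.
Variance estimates are floored at 1e-12 before weighting; F with zero
control variance reports inf with p 0 and a flag; FDR ranking ties break by
(p, probe_id) for determinism. Internal coordinates are 1-based inclusive;
BED I/O converts at the boundary; chromosomes order naturally
(chr2 < chr10).

## Known limitations

- The two-stratum variance estimator can differ slightly from iterative
  REML when the between-pair variance estimate would be negative
  (truncation); probes where this matters are deep-null probes.
- The SAM-style FDR is unstable for single-region call sets; targets of
  10%/17% are meaningful for call sets of a handful of regions or more.
- Enrichment null matching (same element count, type, probe count ± 1)
  controls length confounding only to first order.
- The variance path has intrinsically lower regional power than the mean
  path at equal "effect" (log F of a 4× ratio competes with a wide retention
  band); sensitivity ~0.75 at 4-probe regions is expected, not a defect.
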