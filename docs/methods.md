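# Methods notes

## Scope and model

The package analyzes organ-level static PET uptake (`SUV_90–120`, the
duration-weighted mean SUV over frames whose midpoints fall in the closed
90–120 min window) with two network frameworks: single-scan perturbation of
an interorgan covariance network, and interscan connectivity with Markov
clustering and enrichment. SUV uses the preclinical g/mL convention,
`SUV = concentration(kBq/mL) × weight(g) / dose(kBq)`; since every
downstream statistic is a Pearson correlation, only the relative structure
of the table matters and the unit convention is immaterial. Injected dose
is taken from scan metadata; recomputing it from a whole-body TAC is
supported only as an alternative metadata source, not as an image
operation. Frame inclusion by midpoint (rather than exact overlap) is
robust to frame grids not aligned with the window edges; an unweighted mean
is available as an option because acquisition protocols differ in whether
late frames have equal length.

## Perturbation z-scores

The reference network REF is the plain Pearson correlation across the
pooled vehicle scans (no shrinkage, no Fisher transform). The perturbed
network PER adds the target scan to the pool (n+1 scans); vehicle scans
are instead removed from the pool (leave-one-out, n−1 scans), so for them
the z-scores measure the effect of removing the scan. The differential
network is always PER − REF. The default normalization is the
individual-differential-covariance convention for a one-scan perturbation,

    z = Δr / s ,   s = (1 − r_REF²) / (n_REF − 1).

`s` matches the leading-order scale of a single scan's effect on a pooled
Pearson correlation: adding one scan changes r by w/(n+1) + O(1/n²), where
w = x̃ỹ − r(x̃² + ỹ²)/2 has standard deviation (1 − r²) for a null scan.
An alternative *empirical* mode standardizes each edge against the standard
deviation of the reference pool's own leave-one-out Δr distribution
(config switch `z_mode`), useful when the reference pool is large enough to
estimate per-edge scales. Degenerate edges (|r_REF| = 1, s = 0) get z = 0
when Δr = 0 and sign(Δr) × 50 otherwise (cap configurable); this avoids
NaN poisoning of group summaries while still flagging genuine departures
from collinearity.

An important property, verified by the null-calibration experiment and
stated here so users do not over-interpret the z's: **the null z is not
standard normal**. w is a quadratic form in one scan's standardized values
and is leptokurtic at any reference size, and at n_REF = 15 the estimated
r_REF adds further spread. The per-edge rate of |z| > 3.12 on null vehicle
data is ≈ 2.5–3%, not the 0.18% a calibrated normal would give — still
comfortably below the 5% bound the analysis requires of null data, and the
appropriate mental model for the extreme-deviation threshold is "a
conservative screen for gross single-scan deviations", not a p-value.
A consequence quantified during development: planting a correlation delta
of 0.5 on designated edges of a 6-scan group (against a 15-scan reference)
moves those edges' expected z to only ≈ −0.7, so per-scan extreme rates on
planted edges are ≈ 9% vs ≈ 2.5% on null edges; ranking planted edges into
the top 5 of 28 by extreme percentage succeeds in roughly 70% of cohorts,
not more. Detecting single-edge rewiring of this size reliably needs
either larger effect sizes or a larger reference pool; organ-level mean
shifts, by contrast, are detected essentially always (they act as leverage
points on every edge of the affected organ).

## Extreme-deviation statistics

The threshold is the two-sided Bonferroni-corrected normal critical value
over the unique edges: `z_crit(0.05, 28) = 3.12` for 8 organs (two-sided
is fixed as default because the one-sided value, 2.92, does not match the
threshold this analysis family reports). Per-organ percentages are the
mean over the organ's 7 edges of per-edge percentages, exactly. The group
comparison is a one-way ANOVA over per-scan extreme counts with pairwise
pooled-variance t-tests against the designated control group and no
further correction by default; Welch and Bonferroni-adjusted modes are
available behind flags since the underlying variance assumption is a
judgment call. Density fits over pooled z use a Gaussian kernel with
Silverman bandwidth, with moments (mean, SD, excess kurtosis) reported
alongside so shape statements ("flatter", "heavier-tailed") are testable
numbers rather than visual impressions.

## Interscan network, MCL, enrichment

Interscan similarity is the Pearson correlation between two scans' organ
profiles. The graph keeps pairs with r ≥ 0.85 by default; the threshold is
deliberately surfaced in config and logs because cluster structure depends
on it and typical graph tools default to high-correlation edges. MCL is
implemented directly (expansion = matrix squaring; inflation = entry-wise
power `granularity`, column renormalization) with: self-loop weight equal
to the node's maximum incident weight (unit for isolated nodes), per-column
pruning of entries < 1e-5 with the column maximum always retained,
convergence when the largest entry change is < 1e-6, and a 200-iteration
cap that raises with the residual on non-convergence. Clusters are read
from attractor rows; attractor systems sharing support are merged; a node
reachable from several systems goes to the largest cluster, ties to the
lowest index; clusters are numbered 1..k by decreasing size. All constants
are keyword-configurable. Determinism: identical graph + granularity gives
identical assignments (no randomness anywhere in the algorithm).

Enrichment uses the one-sided Fisher exact test, i.e. the hypergeometric
upper tail P(X ≥ observed | N, group_size, cluster_size), equivalent to
the 2×2 overlap table test. The Bonferroni family defaults to the number
of scan groups, applied per cluster (×12 in the emulated design) —
recomputing the published values of this analysis family identifies that
multiplier uniquely — with a `clusters_x_groups` alternative. The expected
count uses the closed form cluster_size × group_size / N; its SD is
estimated by seeded label permutation (default 10,000 draws) rather than
the hypergeometric closed form, matching how interactive graph tools
report it; the permutation mean converges to the closed form (tested at 3
Monte Carlo SEs).

## Synthetic cohorts

The generator emulates two cohorts totalling 50 scans in 12 groups over 8
organs (brain, heart, lungs, kidneys, adrenal glands, spleen, liver, vena
cava): an endotoxin time course (vehicles 2 h/24 h/7 d = 3/5/4 scans; LPS
2 h/24 h/7 d = 6/6/7) and a blocking dose escalation (vehicles B 3,
baseline 3, doses 1–4 = 6/1/3/3). The 15 vehicle scans across both
cohorts form the reference pool.

Defaults and why:

- **Normative structure**: interorgan correlation 0.6 between all organ
  pairs except vena cava links at 0.2 (the blood pool couples only weakly
  to parenchymal organs); SDs are 15% of organ means. Strong enough that
  planted perturbations are detectable, weak enough to be realistic for
  between-animal uptake covariance.
- **Healthy mean profile** (SUV): brain 0.4, heart 2.5, lungs 1.2, kidneys
  2.8, adrenals 2.0, spleen 1.5, liver 2.2, vena cava 0.5 — the
  heart/kidney/liver-dominant pattern typical of TSPO tracers in mice.
- **Endotoxin groups**: 2 h elevates brain ×1.8, heart ×1.5, kidneys ×1.5
  and decorrelates the brain–heart–kidneys triangle by −0.5; 24 h shifts
  the response to liver ×2.8, spleen ×3.2, heart ×1.5 with the
  liver–spleen–heart triangle decorrelated by −0.5; 7 d is back to
  normal. Effect sizes are calibrated for detectability by the pipeline,
  not fitted to any real data.
- **Blocking groups**: means blend toward a blocked profile (brain 0.35,
  heart 0.7, lungs 0.55, kidneys 1.3, adrenals 0.6, spleen 0.45, liver
  1.5, vena cava 1.1 — excretory organs and blood pool retain relatively
  more signal when specific binding is occupied) with occupancies
  0.05/0.15/0.25/0.88/0.96 for baseline and doses 1–4, interorgan
  correlations weakening toward 0.3, and global scales 1/0.9/0.8/0.45/0.3.
  Global scaling multiplies means and SDs together (coefficient of
  variation preserved), so correlations — and hence all network statistics
  — are unaffected by the scale itself; the *profile shape* change is what
  separates blocked scans in the interscan analysis, and the mean offset
  is what drives their large add-one deviations.
- **Edge perturbations** are applied on the correlation scale and repaired
  to a PSD matrix by alternating projections between the PSD cone
  (eigenvalue clipping at 1e-8) and the requested-edge constraints, so
  requested values are honoured exactly whenever geometrically feasible
  (one-shot clipping systematically attenuates them); an error naming the
  offending edges is raised if the achievable correlation differs from the
  request by more than 0.05.
- **TACs**, when requested, are mono-exponential washouts to a plateau
  (rate 0.03/min, plateau fraction 0.6, 12 × 10-min frames), rescaled per
  organ so the windowed average reproduces the drawn SUV exactly — the
  pipeline needs TACs only to exercise the SUV stage, not to model
  kinetics.
- One RNG stream per cohort, advanced per group in declaration order, so
  records are reproducible and independent of downstream consumption.

What the generator does **not** emulate: image-domain effects (no voxels,
no reconstruction noise), tracer kinetics beyond the washout shape,
radiometabolism, non-Gaussian biological variability, or longitudinal
within-animal correlation (groups are independent animals). Passing tests
therefore demonstrate the statistical machinery is correct and calibrated
under multivariate-normal conditions — not that the biological effect
sizes are realistic.

## Numerical conventions

Pearson matrices are computed with means over the actual scan set used and
clipped to [−1, 1]; zero-variance organs (or constant scan profiles) raise
errors naming the offender rather than propagating NaN. Missing values are
never imputed. Interchange files are tab-separated text with floats at 12
significant digits, making runs diff-able; rerunning a pipeline config
reproduces artifacts byte-for-byte. Experiment sizes used by the test
suite and calibration script — 1,000 null cohorts, 100 recovery
replicates, 50 study-cohort replicates — were chosen to bound Monte Carlo
error on the reported rates at a few percent while keeping a full run in
the minutes range on one CPU.

## Known limitations

- The z normalization is one member of a family; the empirical switch is
  provided, but no attempt is made to calibrate the null to exact
  normality (see above — it cannot be, for a single-scan quadratic form).
- The enrichment expected-SD is a Monte Carlo estimate; its value varies
  by ±1/√n_permutations between seeds.
- The interscan edge threshold (0.85) is a sensitivity parameter; the
  granularity sweep plus ARI stability summary is the provided tool for
  judging robustness of cluster claims.
- ANOVA/t-tests on extreme counts treat counts as approximately normal
  within groups; with very small groups (n < 3) the post hoc p-values are
  fragile, and groups with fewer than 2 scans are excluded outright.
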