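# Methods

## Statistical model

Each probe's β-values (methylation proportions across subjects) are clipped
to [ε, 1−ε] with ε = 10⁻⁶ and logit-transformed to M-values,
M = log₂(β/(1−β)). Base 2 is used throughout: the back-transform is the
base-2 logistic, and the two are exact inverses to below 10⁻¹² over the
clipped range. The per-probe model is ordinary least squares of M on age
(years), BMI (kg/m², continuous) and patient status (0/1); the age
coefficient is the effect of interest, in M units per year. Rank-deficient
designs abort with the collinear columns named.

Residual variances s² with d degrees of freedom are moderated by an
empirical-Bayes scaled-inverse-chi-square prior (d₀, s₀²) estimated by
method of moments on log variances: with e = log s² − ψ(d/2) + log(d/2),
the prior follows from matching mean(e) and the excess of var(e) over the
sampling term ψ′(d/2), inverting the trigamma function by Newton iteration.
If the observed spread does not exceed sampling noise, d₀ = ∞ and every
posterior variance equals s₀². Otherwise the posterior variance is the
convex combination (d₀s₀² + ds²)/(d₀ + d), the moderated t is the slope
over its posterior standard error on d + d₀ df, and exact-zero variances
are floored at 10⁻¹² before taking logs. The implementation is
cross-checked in the test suite against the R limma reference on a shared
fixture (agreement to 10⁻⁶ relative).

P-values are adjusted once, jointly across all probes surviving filters,
by Benjamini–Hochberg; the significance call is adjusted p < 0.05.
Probe-level filters (detection p > 0.01 in at least one subject — strict
inequality; SNP-flagged; cross-reactive) remove each probe at most once
with precedence detection > SNP > cross-reactive, so the filter report's
counts partition the removals. Normalization is a pass-through: inputs are
expected pre-normalized (e.g. BMIQ), and a hook exists for plugging a
method in; the synthetic generator emits data that need none.

## Subgroups, back-transformation, ranking

Probes are classed by mean β across subjects: UM < 0.2, 0.2 ≤ HM ≤ 0.8
(both boundaries hemi-methylated), FM > 0.8. The intercept-method
back-transform Δβ = logistic₂(M₀+ΔM) − logistic₂(M₀) uses the probe's
observed mean M as M₀; the fitted model intercept is deliberately not the
default, because with uncentered covariates it extrapolates to age zero.
Δβ therefore always carries the sign of ΔM (the logistic is increasing).

Top lists take the k = 30 smallest adjusted p per subgroup (ties broken by
raw p, then probe id, stably); their union is the "top 90". The
high-magnitude flag requires |ΔM| strictly greater than 0.1 per year.
Percentages in report tables are rounded to two decimals only at write
time; a full-precision twin file is always written.

## Imprintome mapping

ICR intervals are read from 6-column BED (0-based, half-open; name field
`gene|origin`). A probe hits an interval iff start ≤ pos < end — the
position is compared directly against the half-open interval, so the end
coordinate is never a hit; this boundary convention is pinned by tests and
checked against a brute-force all-pairs scan. "Adjacent to an ICR" has a
configurable flank, default 0. Gene matching is by uppercased,
whitespace-stripped symbol with probes annotated to several genes exploded
and matched to each; no alias resolution is attempted (curate aliases into
the input lists instead). A probe inside two overlapping ICRs counts once
as a DMC but contributes a pairing per ICR; genes whose DMCs touch ICRs of
more than one parent-of-origin class carry a `multi_origin` flag.

## Scoring and selection

The score of interest is the sum of all eight binary indicators — ICR,
co-listed, multi-CpG, top-90, magnitude, opposite direction, island,
promoter. "Co-listed" means membership in at least three of the supplied
external study lists (the pipeline's own results never count toward it);
"multi-CpG" counts significant DMCs only; "opposite direction" means an
increase at a UM site or a decrease at an FM site, where change against
the subgroup's characteristic state is biologically most interesting.
Selection keeps ICR-linked ASD genes unconditionally and non-ICR ASD genes
scoring ≥ 3, then removes pseudogenes and genes whose only significant
DMCs sit on cross-reactive probes; output order is score descending, then
symbol, making the operation idempotent and input-order independent.

## Synthetic data generator

The generator emulates a 63-man cohort aged 18–35 measured on a 450K-style
array. What it reproduces:

- **Covariate structure.** Ages are discrete uniform on 18–35, resampled
  (best of 200) until the mean is within 0.5 years of 25.5. Overweight
  (BMI ≥ 25) and patient status follow logistic links in centred age
  (coefficients +0.25 and −0.35 per year); the intercepts are solved by
  root-finding on the realized ages so the marginal rates hit 31.8% and
  23.8% exactly in expectation, with patients skewing about six years
  younger. An abnormal-sperm-quality flag is drawn at 25.4%.
- **Methylation landscape.** Probe baselines come from a three-component
  beta mixture with weights 0.4695/0.1003/0.4302 and archetypes
  UM(mean 0.08, concentration 50), HM(0.50, 8), FM(0.92, 50). The
  archetype parameters were chosen by forward simulation so that, with the
  default subject noise, the UM/HM/FM fractions classified from mean β
  land within ~0.2 points of the target percentages; the implied
  array-wide mean methylation is ≈48.5%.
- **Age effects.** A configurable fraction of probes (default 3%) gets a
  slope ΔM/yr planted additively on the M scale — magnitudes gamma(shape 2,
  mean 0.06) or fixed, sign negative with per-subgroup probabilities
  0.92/0.75/0.53 (hypomethylation dominating, most strongly at UM sites).
  Subject values add Gaussian M-noise (sd 0.3) and map back through the
  logistic, so β is strictly inside (0, 1). A truth table records every
  planted effect for recovery testing.
- **Annotation.** Chromosomes 1–22 and X with uniform positions (per-probe
  densities are not calibrated), island relation at 30.9/23.3/9.5/36.3%
  (island/shore/shelf/open sea), functional regions at rough array-wide
  proportions, SNP and cross-reactive flags at 15% and 6%, 0–2 gene
  symbols per probe from a 2,000-gene pool. Sixty genes are tagged
  imprinted and given one ICR each spanning their probes' positions, so
  generated overlaps are recoverable by construction.

All draws flow from one master seed through named substreams; the same
configuration yields byte-identical fixture files.

What it does **not** emulate: probe type-I/type-II chemistry, batch or
chip effects, spatially correlated neighbouring CpGs, realistic
per-chromosome probe densities, or heteroscedastic residuals. Passing
tests therefore demonstrate correctness of the statistical machinery under
a clean generative model — unbiased slopes, controlled FDR, calibrated
subgroup fractions — not robustness to the technical artefacts of real
arrays.

## Problem sizes and numerical choices

The error-control study uses 200 null replicates of 63 × 20,000 arrays
(annotation and covariates held fixed, methylation redrawn per replicate);
the recovery study plants a fixed −0.05 M/yr on 10% of 4,000 probes; the
calibration check classifies a single default 63 × 50,000 array. Variance
floor 10⁻¹²; trigamma inversion to 10⁻¹⁰ relative; BH applied once
genome-wide; Pearson correlations on constant inputs are flagged undefined
rather than propagated as NaN; Mann–Whitney tests are two-sided,
tie-corrected, asymptotic.

## Known limitations

Cohort-specific probe-level results cannot be reproduced without the
original restricted data; the package validates the machinery on synthetic
fixtures instead. The moderated-t implementation is the plain variant
(no mean-variance trend, no robust downweighting). Back-transformed Δβ
values depend on the M₀ convention; the model-intercept alternative is
available via argument. The outlier rule for sensitivity reruns (global
mean β beyond 3 MADs from the median) is one reasonable choice among
several.
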