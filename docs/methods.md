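# Methods

## The discovery model

The workflow assumes a single-cohort, two-group design induced by an
anchor gene: samples strictly below the lower quartile (linear-interpolation
quantile, ties assigned to the high group) of anchor expression form the
"loss" group, the remainder the reference group. A `below_median` rule is
available for coarser splits. Grouping on a constant anchor, or a split
that empties either group, is an error rather than a silent degenerate fit.

Differential expression between the groups is tested with three statistics
per gene, chosen to capture complementary evidence:

* **Welch t** (unequal variances) on log2(x+1) expression — mean shift;
* **rank-sum z**, standardized with the exact finite-population variance of
  the rank sum, which is automatically tie-corrected — distributional shift
  robust to outliers;
* **log2-median-ratio (LMR)** on the linear scale — an interpretable effect
  size, also used as the ranking metric for enrichment.

Working on log2(x+1) for t and the rank statistic while keeping LMR on the
linear scale is a configuration default (`log_transform`), since location
tests behave better on logged expression while a fold-change effect size is
conventionally linear.

### Permutation null and p-values

Sample labels are permuted B times (default 10,000), preserving group
sizes; each permutation round feeds all three statistics, so their joint
null dependence is preserved. Two-tailed empirical p-values use the
positive-biased estimator p = 2·(min(#{null ≥ obs}, #{null ≤ obs}) + 1) /
(B + 1), which can never return 0 — required because p-values are next
converted to normal quantiles. An exhaustive mode enumerates all
C(n, n_low) assignments when feasible and is tested against brute-force
enumeration.

Null values are pooled across genes per statistic (default) to sharpen
tail resolution: t and rank-sum values are standardized by their per-gene
null moments first, LMR is pooled raw (its scale is comparable across
genes under the homoskedastic-on-log noise this pipeline targets). A
`per_gene` mode keeps each gene's own B-value null for data where that
assumption is doubtful.

### Combination and calibration

The three p-values are combined by Stouffer's method with equal weights:
z_i = sign_i · Φ⁻¹(1 − p_i/2), Z = Σz_i/√3, and the closed-form combined
p is 2(1 − Φ(|Z|)). That closed form assumes independent statistics. The
three statistics here are computed on the same samples and are strongly
positively correlated, which makes the closed form sharply
anti-conservative (measured in `tests/test_acceptance.py`: ~0.22 of null
genes at nominal α = 0.05). The pipeline therefore computes Z for every
permutation round as well — the rounds already carry all three statistics —
and reports `p_overall` as the empirical two-tailed p of the observed Z
against that permutation null. This keeps the Stouffer Z as the evidence
summary while restoring exchangeability-based calibration; the type-I
fraction then sits inside the binomial 99% envelope of α (acceptance
suite). `p_normal` preserves the closed form for comparison, and
`calibrate_overall=False` switches the pipeline to it.

### Multiple testing and DEG calling

Storey q-values use the fixed-λ estimator π̂₀ = #{p > λ}/(m(1 − λ)) with
λ = 0.5, capped at 1 (the λ-grid smoother variant is not implemented; at
the gene counts this pipeline targets the fixed-λ estimate is stable).
With π̂₀ = 1 the q-values equal Benjamini-Hochberg, which is the oracle
identity used in tests. DEGs require q < 0.05 and |LMR| > 0.58 (1.5-fold);
positive LMR means higher in the anchor-low group, so `up_genes` is the
loss-activated program.

## Signature scoring

Activation is the z-score method: per-gene standardization across the
application cohort (mean 0, sd 1), then score_j = mean z over present
up-genes − mean z over present down-genes. The mean (rather than sum/√k)
keeps scores comparable across cohorts with different signature coverage;
`aggregate="sum_sqrt"` provides the alternative. Standardization is always
per-application-cohort, matching per-cohort dichotomization; no
cross-cohort harmonization is attempted. Zero-variance genes are dropped
with a warning (detected with a relative tolerance, since rounding leaves
~1e−16 "variance" on constant rows), and coverage is reported.
Dichotomization: scores strictly above the median → "high" (activated);
quartile and two-gene co-loss rules mirror the anchor-group arithmetic.

## Survival analysis

Kaplan-Meier curves, the k-group log-rank test and Cox
proportional-hazards fits are delegated to lifelines (Efron tie handling;
Breslow switchable) and repackaged with Wald 95% CIs computed at
z = 1.959964 exactly, so CI round-trips match the meta-analysis
back-calculation convention. Categorical covariates are dummy-coded
against their first sorted level; group contrasts enter as indicators
against an explicit reference level. Tests pin the estimators to
hand-computed product-limit and O−E/V arithmetic and to a grid-search
maximization of the explicit partial likelihood.

## Hazard-ratio meta-analysis

Pooling is on log HR. SEs absent from input tables are back-calculated
from printed CIs as (ln hi − ln lo)/(2·1.959964), which assumes
log-symmetric (Wald) intervals. Fixed effects weight by 1/se²;
random effects add the DerSimonian-Laird τ̂² = max(0, (Q − df)/c),
c = Σw − Σw²/Σw, so τ̂² = 0 (and random = fixed exactly) whenever Q ≤ df.
I² = max(0, (Q − df)/Q). REML is intentionally not implemented; DL is the
classic default of the tooling this mirrors, and results are cross-checked
against statsmodels in the test suite.

## Enrichment

Genes are ranked by LMR descending, ties broken lexicographically by gene
id for determinism. The running sum increments at set members by
|metric|^w normalized over the set (w = 1 by default; w = 0 gives the
unweighted KS form, and both are exposed because the running-sum
literature uses both) and decrements at non-members by 1/(N − |S|). ES is
the signed maximum absolute deviation, ties broken toward the earlier
position with a 1e−12 tolerance so floating noise cannot flip the
convention; the vectorized hit-position evaluation used for permutation
nulls is tested to agree with the literal walk. NES divides ES by the mean
|null ES| of matching sign; p is the sign-matched tail fraction with a
pseudocount; FDR q is the GSEA-convention ratio of normalized-null to
observed tail fractions, capped at 1. Gene-set permutation draws random
sets of matched size from the ranked universe (cached per size);
phenotype permutation re-ranks by LMR under sample-label permutations
using the same label-permutation machinery as the DE module. Default set
size bounds after intersection with the universe: 15–500.

## Synthetic cohorts

The generator emulates the statistical structure the workflow assumes,
not any particular sequencing protocol:

* a latent loss state in `frac_anchor_low` (default 0.25) of samples;
* the anchor gene shifted down by `effect_log2` in latent-low samples, so
  quartile grouping recovers the latent state up to noise-induced boundary
  misclassification (this is deliberate, not hidden: at effect 2 and noise
  sd 0.5 a few samples swap sides);
* a **fixed block** of planted up/down gene ids shifted by ±`effect_log2`
  — fixed rather than redrawn per seed, so cohorts simulated at the same
  dimensions share one conserved loss program and signatures transfer
  across cohorts, as the multi-cohort validation design requires;
* lognormal noise (log2-scale sd `lognormal_sigma`, default 0.5) for
  "normalized" matrices, or gamma-Poisson counts with dispersion
  `nb_dispersion` (default 0.3) and log-uniform library sizes spanning
  `libsize_spread` (default 4-fold) for the raw-count path that exercises
  the TMM stage;
* exponential survival with hazard `baseline_hazard` (default 0.05 events
  per time unit) multiplied by `true_hr` (default 2.5) in latent-low
  samples; independent exponential censoring with per-subject rate chosen
  so the expected censored fraction is exactly `censor_rate` (default
  0.3); covariates drawn independently of outcome from a small
  distribution vocabulary.

Defaults were chosen once as a realistic localized-cancer regime: ~100-200
patients per cohort, a quarter of samples in the loss state, 2-fold to
4-fold planted expression shifts, HRs in the 2-3 range, ~30% censoring.

Randomness: one seed is split via `SeedSequence.spawn` into four fixed
child streams (latent/planted/expression; library sizes; survival;
covariates), so identical configs are byte-identical and changes confined
to a later stream do not perturb earlier ones.

What the generator does **not** emulate: batch effects, cohort-specific
platform differences, gene-gene correlation beyond the planted program,
single-cell structure, informative censoring, or covariates that confound
the signature-survival association. Passing recovery tests therefore shows
the estimators are correct under the stated model, not that the workflow
is robust to those real-data complications.

## Count preprocessing

Low-count filtering keeps genes whose summed raw count across libraries
reaches `min_total` (default 2); a per-library reading of the same rule is
available as `mode="each"`. TMM normalization follows the published
trimmed-mean-of-M-values procedure: reference = sample whose
upper-quartile count fraction is closest to the mean; per-sample M/A
values over genes positive in both; double trim (30% on M, 5% on A,
rank-based with floor(n·trim)+1 bounds); precision-weighted mean of the
surviving M-values with asymptotic-variance weights; factors renormalized
to unit geometric mean; output counts-per-million on effective library
sizes. Factors match Bioconductor edgeR to 1e−8 on the test fixture.
Exact invariance to scaling a single library holds for the unweighted
variant; the precision-weighted default is invariant only up to the weight
perturbation (~1%), matching the reference implementation's behavior.

## Numerical choices and degenerate inputs

* Empirical p-values never return 0 (pseudocount), and combined closed-form
  p is floored at the smallest positive double.
* Welch variance terms are clamped to exact zero below a relative
  tolerance (1e−12 of the mean square) so constant genes yield t = 0
  rather than cancellation noise; such genes propagate p = 1.
* Median ratios replace a zero median by half the smallest positive matrix
  value — only when the median is zero.
* Storey π̂₀ ≤ 0 (no p above λ) is floored at 1/m with a warning.
* Quantile thresholds use linear interpolation; ties at a grouping
  threshold always go to the non-extreme group.
* Cox non-convergence and constant covariates raise informative errors.

## Known limitations

* Phenotype-permutation enrichment re-ranks with a Python-level loop per
  permutation; it is meant for moderate n_perm (hundreds), while gene-set
  permutation is vectorized and comfortable at 10,000.
* Covariate-adjusted differential expression, paired designs, shrinkage
  effect estimates, time-varying covariates and competing risks are out of
  scope.
* The pooled-null default assumes roughly exchangeable LMR null scales
  across genes; use `null_mode="per_gene"` for strongly heteroskedastic
  data at the cost of tail resolution.
* Median dichotomization of the activation score intentionally reproduces
  the field's convention even though it dilutes a 25%-prevalence latent
  state into a 50% group; the README's worked example shows the resulting
  attenuation of per-cohort hazard ratios.
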