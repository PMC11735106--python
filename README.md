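# sigloss

Transcriptomic signatures of tumor-suppressor **loss** and their prognostic
value, as a tested, reusable pipeline.

Loss of the RNA-binding protein tristetraprolin (TTP, gene *ZFP36*)
destabilizes AU-rich-element transcripts and marks aggressive prostate
cancer. The analysis pattern behind that observation generalizes: pick an
*anchor* gene, split a discovery cohort into anchor-low (lower quartile)
versus anchor-high samples, derive the genes that move with the loss state,
score any other cohort for activation of that program, and ask whether
activated patients relapse faster. `sigloss` implements that whole chain —
plus the seeded synthetic cohorts with planted ground truth needed to test
every stage without access to controlled patient data.

## What it computes

**Integrated permutation DE test.** For each gene, three statistics compare
anchor-low vs anchor-high samples: Welch *t*, a tie-corrected rank-sum *z*,
and the log2-median-ratio LMR = log2(med_low/med_high). Their nulls are
estimated empirically by permuting sample labels *B* times (default
10,000); each observed statistic gets a two-tailed empirical p with the
+1/(B+1) pseudocount, converted to a signed normal quantile
z_i = sign_i · Φ⁻¹(1 − p_i/2), and combined as Stouffer's
Z = (z_t + z_w + z_lmr)/√3. Because the three statistics are computed on
the same samples and are strongly correlated, the normal tail of Z is
anti-conservative; the pipeline therefore also evaluates Z on every
permutation round and reports the overall p as the empirical two-tailed p
of Z against its own permutation null (the closed form is reported
alongside as `p_normal`). Storey's q-value (fixed-λ π₀ estimate) corrects
for multiple testing, and DEGs are genes with q < 0.05 and |LMR| > 0.58
(1.5-fold).

**Signature scoring and survival.** Activation of the signature in a new
cohort is the z-score method: per-gene standardization across the cohort,
then mean z over up-genes minus mean z over down-genes per sample. Groups
come from median dichotomization (or quartile rules, including two-gene
co-loss grouping); groups are compared by Kaplan-Meier curves, the
log-rank test, and Cox proportional-hazards fits (Efron ties, Wald 95% CIs
at z = 1.959964), with optional clinical covariate adjustment.

**Hazard-ratio meta-analysis.** Per-cohort HRs with 95% CIs (SE
back-calculated from printed bounds as (ln hi − ln lo)/(2·1.959964)) are
pooled on the log scale: inverse-variance fixed effects and
DerSimonian-Laird random effects, with Q, τ² and I².

**Gene-set enrichment.** Genes ranked by LMR feed a weighted
Kolmogorov-Smirnov running sum; significance comes from gene-set or
phenotype permutations, with NES and the permutation FDR q (q < 0.25
flagged, following common practice for this statistic).

**Synthetic cohorts.** `simulate_cohort` plants a latent loss state in a
fraction of samples (default 25%), shifts the anchor and a fixed block of
planted genes by a stated log2 effect, draws lognormal (normalized) or
negative-binomial (count) noise, and generates exponential survival times
whose hazard is multiplied by a stated true HR in the latent-low group,
with independent censoring at an exact expected rate.

## Worked example

```bash
sigloss run --write-example demo.yaml
sigloss run --config demo.yaml
```

or in Python:

```python
from sigloss import example_config, run_pipeline
report = run_pipeline(example_config(outdir="demo", seed=7))
```

This simulates one discovery cohort (120 samples, 1,000 genes, 50 + 50
planted genes at ±2 log2 units, true HR 2.5) and three validation cohorts
sharing the same planted program, then derives and applies the signature.
With `seed: 7` and `B: 1000` it prints per stage:

```
de:        n_low=30 n_high=90, signature 50 up / 51 down
survival:  discovery HR 1.16 [0.77, 1.77]   log-rank p 0.476
           cohort_A  HR 1.83 [1.15, 2.91]   log-rank p 0.010
           cohort_B  HR 1.23 [0.82, 1.84]   log-rank p 0.320
           cohort_C  HR 1.75 [1.01, 3.01]   log-rank p 0.042
meta:      pooled HR (random effects) 1.41,  Q 3.03, I2 0.01
gsea:      2 planted sets evaluated, 2 significant at q < 0.25
```

Reading this: the discovery split recovers essentially all planted genes
(50 up, 51 called down including the anchor's co-regulated block); scoring
each cohort and splitting at the median z-score dilutes the 25%-prevalence
loss state into a 50% group, so per-cohort HRs sit well below the true
latent-state HR of 2.5 and individual cohorts fluctuate around
significance — exactly the regime where pooling across cohorts is needed,
and the random-effects pooled HR of 1.41 is consistent with the expected
marginal (diluted) hazard ratio of ≈1.45.

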