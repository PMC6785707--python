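# Methods

`omniprs` implements a leave-one-out (LOO) cross-cohort validation of
gene-set-restricted polygenic risk scores (PRS), together with the two
validation studies that give the result its meaning: an experiment-wise
phenotype-permutation null, and an "omnigenic floor" built from random genic
and non-genic SNP sets. Because the multi-cohort case-control data such an
analysis needs cannot be redistributed, the package ships a synthetic
generator whose outputs have the statistical structure the pipeline assumes;
every experiment in `analysis/` and `scripts/acceptance.py` runs end-to-end
on generated data.

## The pipeline

For each study *s* among *K* case-control cohorts sharing a SNP panel:

1. **Training GWAS.** Pool the other *K−1* studies and fit, per SNP, a
   logistic regression of case status on additive dosage plus covariates
   (principal-component surrogates and study indicator dummies). The output
   per SNP is ln(OR), its Wald standard error and a two-sided Wald p.
   Samples missing a SNP's genotype are dropped for that SNP only.
2. **Risk orientation.** Every SNP is re-coded so its effect allele is the
   risk allele (ln OR ≥ 0); exact zeros keep their original allele.
3. **LD pruning.** The pooled training genotypes are pruned with the
   standard sliding-window procedure (window 50 SNPs, step 5, r² ≤ 0.25):
   within each window, whenever a retained pair exceeds the threshold the
   later-positioned SNP is removed. r² is the squared Pearson correlation of
   dosages over pairwise-complete samples.
4. **Set restriction and scoring.** The score is restricted to the SNPs of
   the gene set under test (a SNP belongs to a gene if it lies in the gene
   body, ≤ 5 kb upstream or ≤ 1 kb downstream, strand-aware, boundaries
   inclusive). For a p-value cutoff *t*, each sample's score is
   Σ ln(OR)·(risk-allele dosage) over set SNPs with training p < *t*;
   missing genotypes contribute 0 and decrement a per-sample valid-genotype
   count that is carried as a covariate (informative because scores are sums,
   not means).
5. **In-training threshold selection.** Nine cutoffs
   (0.0001, 0.001, 0.01, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50) are evaluated on
   the training samples by a likelihood-ratio test (LRT) of
   covariates+valid-count+score against covariates+valid-count; the cutoff
   with the largest LRT statistic wins, ties going to the smallest cutoff.
   Only this single score is ever evaluated on the held-out study, so the
   held-out p needs no multiple-testing correction.
6. **Held-out evaluation.** The same nested LRT on the held-out study gives
   the per-study p; effect size is the nested Nagelkerke R²:
   R²(covariates+valid+score) − R²(covariates+valid), both referenced to the
   intercept-only model, clipped at 0 for reporting. The direction is the
   sign of the score coefficient.
7. **Meta-analysis.** The *K* held-out results are combined with Stouffer's
   Z: z_i = sign_i · Φ⁻¹(1 − p_i/2), z_meta = Σ√n_i z_i / √Σn_i with
   n_i = cases+controls (effective-sample-size weights
   4/(1/n_case + 1/n_ctrl) available by option); p_meta is two-sided.
   Flagged (degenerate) records are excluded with a logged count. Nested R²
   across studies is summarised by median, IQR (linear-interpolation
   quantiles) and range.

A genome-wide mode scores all SNPs with no set restriction and, by default,
no pruning. `meta.expected_share(r2_gw, m_gw, m_set) = r2_gw · m_set / m_gw`
gives the equal-contribution yardstick a set would attain under a purely
uniform (omnigenic) architecture.

## Synthetic cohorts

The generator produces an annotated panel and *K* ascertained cohorts under a
liability-threshold model:

- **Annotation.** Non-overlapping stranded genes (lengths uniform on
  2–10 kb) packed on one chromosome with Dirichlet-distributed gaps; SNP
  positions uniform; every panel has both genic and non-genic SNPs.
- **Effects.** Per-SNP liability effects are zero-mean Gaussian — an
  omnigenic background in which every SNP is causal. SNPs mapped to a
  designated core gene set receive `core_enrichment` times the background
  variance. When `prop_causal_genic` is set, the genic/non-genic partition of
  heritability is rescaled to that exact split (1.0 puts all variance at
  genic SNPs). After drawing, effects are rescaled so Σ 2p(1−p)β² equals
  `h2_liability` exactly. The Gaussian background is a modelling choice; no
  particular effect-size law is implied by the analysis itself.
- **Cohorts.** Study-specific allele frequencies follow a Balding–Nichols
  beta distribution around the ancestral frequency with drift `F` (default
  0.02, the magnitude typical of intra-European cohort differences).
  Genotypes are Hardy–Weinberg at study frequencies; liability is the
  centred genetic score plus Gaussian noise to unit total variance; an
  individual is a case when liability exceeds Φ⁻¹(1−prevalence). Batches are
  rejection-sampled until the exact case/control counts are reached
  (ascertainment), with a capped batch count raising a named error for
  unreachable configurations. Uniform missingness is applied afterwards.
  Covariates are study-shifted Gaussian columns — surrogates for ancestry
  PCs that exercise the covariate-adjustment contract without a PCA step.
- **Prevalence 0.10.** The disease the design emulates has ~1% lifetime
  prevalence, but the generator's default is 0.10: rejection sampling costs
  ∝ 1/prevalence, and 0.10 preserves what matters to the pipeline — strong
  case oversampling relative to the population (5×) and the
  liability-threshold geometry — at a tractable cost. Prevalence remains a
  config field for anyone wanting the rarer regime.
- **Determinism.** All randomness derives from one root seed through
  `core.stage_rng(seed, *stage_tokens)` (a CRC-tokenised
  `numpy.random.SeedSequence`), so identical configs reproduce cohorts
  bit-for-bit, per stage and per study.

Desk-scale defaults (6 studies of 200–500 samples, 2,000 SNPs, 300 genes)
keep a full LOO run in seconds; consortium scale is a configuration, not a
code path.

## What the generator does *not* emulate

No linkage disequilibrium beyond drift-induced structure (so pruning removes
little on synthetic panels), hard-call genotypes only, no sex chromosomes, no
genotyping batch effects, and covariates are genuine PC surrogates rather
than eigenvectors of the realised genotype matrix. Passing tests therefore
demonstrate the pipeline's statistical correctness (calibration, leak
freedom, recovery of simulated enrichment), not robustness to the LD and
stratification pathologies of real panels.

## The permutation null, and a caveat discovered en route

The experiment-wise null shuffles case/control labels within each study
(preserving per-study margins, hence not confounding the study-indicator
covariates) and recomputes the full meta statistic per permutation.

Two variants exist, and the difference matters:

- **Fixed training weights (default).** Training GWAS, pruning and threshold
  selection are computed once from the observed phenotypes; each permutation
  re-evaluates the held-out models on permuted labels. The held-out z-scores
  are then independent across studies and the meta test is calibrated — the
  package measures ≈5% rejections at α=0.05 (e.g. 15/300 pooled across
  seeds at the standard conditions).
- **Full refit (`refit_training=True`).** Re-running the training GWAS and
  selection on permuted labels looks more thorough but is provably
  anti-conservative: study *i*'s labels enter the training sets of all other
  iterations, so for any pair of held-out studies the z-scores share a
  noise-product term with expectation ≈ 1/(K−1). With √n weights this
  doubles Var(z_meta) at *any* K (an idealized linear model, a Monte-Carlo
  of that model, and the pipeline itself all give ≈16% rejections at
  α=0.05). The inflation is a property of leave-one-out weight reuse, not of
  any implementation detail.

The default is the fixed-weights variant — the calibrated reading of an
experiment-wise randomisation test for this design, and the only regime in
which a "≈5% of permutations significant" validation claim is attainable.
The full-refit variant is retained (`analysis/03_permutation_null.py
--refit-training`) precisely because the inflation is worth demonstrating.

## Floor analyses

Random genic and non-genic SNP sets are drawn from pools pruned to
near-independence (r² < 0.01) over the pooled cohorts, then run through the
identical LOO pipeline. Exact set sizes are used rather than Poisson sizes
around a mean, for determinism (a size-jitter knob is not provided). Because
the training GWAS and the 0.25-prune do not depend on the gene set, they are
computed once per held-out study and shared across sets; results are
bit-identical to independent runs.

## Numerical choices

- **Per-SNP GWAS fits** run as a batched Newton–Raphson across SNPs (packed
  symmetric cross-products, per-SNP missingness masks, warm start at the
  covariate-only fit, convergence at max |Δθ| < 1e-6, ridge 1e-10·tr(H) for
  quasi-separated systems, coefficients capped at ±30 and flagged). The
  batch path agrees with per-SNP statsmodels fits to ~1e-10 on both
  coefficients and standard errors; the cross-check is part of the test
  suite. Monomorphic SNPs are reported as ln(OR)=0, p=1, flagged.
- **Single fits** (threshold selection, held-out evaluation) use statsmodels
  `Logit`, with constant/collinear columns dropped by a Gram-matrix rank
  screen (so, e.g., a constant valid-count column under zero missingness
  collapses cleanly into the intercept) and separation handled by
  flag-and-cap, never a crash. Flagged held-out fits are excluded from the
  meta-analysis.
- **Pruning** computes an r² band matrix (all pairs within the window span)
  with five BLAS products per column block, then applies the greedy
  remove-the-later-SNP rule per window. The greedy left-to-right rule equals
  the literal "remove the later SNP of the first violating pair, repeat"
  procedure; the test suite checks equality against a brute-force
  implementation of the latter. Note that "lower r² threshold ⇒ fewer SNPs
  kept" is *not* a theorem for this family of rules (adversarial correlation
  matrices violate it); it holds on the LD structure the tests generate and
  is asserted there empirically.
- **HWE QC** uses the 1-df Pearson chi-square (p ≤ 1e-6 in controls,
  ≤ 1e-10 in cases, following the usual consortium thresholds); sample
  heterozygosity deviation is Fhet = 1 − observed/expected heterozygote
  count over retained SNPs, |Fhet| < 0.2 retained. Filters apply in the
  conventional order (pre-sample SNP missingness, sample filters,
  post-sample SNP missingness, differential missingness, HWE); the filter is
  idempotent.
- **p = 0** entering Stouffer's Z is clamped to 1e-300 (the smallest value
  keeping the normal quantile finite), with a warning.

## Known limitations

- The score test grid and the evaluation statistic assume a binary
  phenotype; no quantitative-trait branch.
- The pooled "mega-analysis" training GWAS with study indicators stands in
  for a per-study meta-analysis of training cohorts; at the simulated drift
  levels the two are practically indistinguishable, but they are not the
  same estimator.
- Stouffer weights use total sample size by default; effective-sample-size
  weighting changes little at the simulated case/control balance but is
  available where cohorts are very unbalanced.
- The permutation-null caveat above applies to any leave-one-out pipeline
  that meta-analyses its held-out folds; the package documents it rather
  than solves it.
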