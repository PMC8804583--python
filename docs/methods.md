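# Methods

## The pooled-GWAS model

A pooled case-control experiment measures, for each SNP, the coded-allele
frequency of a DNA pool rather than individual genotypes. The chain of
randomness the package models is:

1. **Pool composition.** A pool of N subjects realises a frequency
   `f_pool = Binomial(2N, f_group) / 2N`, where `f_group` is the case or
   control population frequency. Case frequencies follow from the control
   frequency and the allelic odds ratio, `f_case = OR·f/(1−f+OR·f)`.
2. **Replicate measurement.** Each replicate array observes
   `f_rep = clip(f_pool + N(0, σ_array), 0, 1)`.
3. **Two-channel readout.** Intensities are `x = I·g·f_rep`,
   `y = I·(1−f_rep)` with lognormal total intensity I and channel gain g.
   Because I cancels in `x/(x+y)`, the estimated frequency is exactly
   `g·f/(g·f+1−f)`: any g > 1 overestimates the frequency — the documented
   bias of pooling platforms — and per-array median-matching normalisation
   removes it when the panel's coded-frequency distribution is roughly
   symmetric about 0.5.
4. **Bad arrays.** With probability `bad_array_rate` a replicate's per-SNP
   frequencies are randomly permuted. A permutation is a draw from the
   replicate's own empirical marginal, so summary statistics per array look
   normal while the inter-replicate correlation — the quantity the QC
   correlation filter tests — collapses to ~0. This mimics a failed
   hybridisation without inventing a second noise distribution.
5. **Stratification.** A fraction of SNPs receives a constant frequency
   shift in the case group only, the minimal confounding structure that
   inflates the association χ² median (λ > 1).

### Generator defaults

| parameter | default | rationale |
|---|---|---|
| pools | 331/176 cases vs 145/149 controls, two batches | the emulated study design |
| replicates per pool | 3 | study design |
| σ_array | 0.01 | typical replicate SD of pooling arrays (~1% on the frequency scale); the source study does not report its value |
| gain ratio g | 1.05 | reproduces the observed few-percent overestimation of pooled frequencies at intermediate MAF |
| intensity | lognormal, median 2000, log-SD 0.25 | arbitrary scale; cancels in frequency estimates, matters only for the intensity filter |
| bad-array rate | 1/6 | the emulated experiment discarded 2 of its 12 replicate arrays |
| coded-allele frequency | Uniform(0.05, 0.95) | allele labelling is arbitrary on a real array, so coded frequencies are symmetric about 0.5; MAF ≥ 5% keeps the MAF filter a boundary case rather than a bulk one |

Calibration experiments (type-I error measurement) set the bad-array rate
and stratification to zero: they measure the statistic, not QC robustness.

## QC cascade

Filter order is fixed: (1) replicate correlation, (2) low intensity,
(3) replicate divergence, (4) control-pool MAF. Decisions taken where the
procedure is underdetermined:

* **Correlation filter.** "Correlation between pooled replicates" is read as
  the Pearson correlation of per-SNP frequency estimates across the SNP
  panel; the unit of removal is the replicate array. Removal is greedy:
  while any replicate's mean pairwise R within its pool is below the cutoff,
  the worst replicate is dropped and correlations recomputed. A single
  one-shot rule would condemn every replicate of a pool containing one bad
  array (the bad array drags all means below 0.99); greedy removal discards
  exactly the bad array.
* **Intensity filter.** floor(fraction·n) lowest-total SNPs removed, ties
  broken lexicographically by SNP id for reproducibility; applied after
  dropping bad arrays, so a discarded array cannot doom low-intensity SNPs.
* **Divergence.** max−min of replicate frequencies within each pool
  separately; "greater than 5%" is strict, so a span of exactly 0.05 is
  kept.
* **MAF filter.** Control frequency is the unweighted mean over control
  pools of each pool's mean replicate frequency; MAF = min(f̄, 1−f̄);
  strictly-below-1% removed.

Each filter only removes; surviving values are untouched, so re-running the
cascade on its own output changes nothing except the percentile cut (which
by construction removes another 5% of whatever it is given).

## Association statistic and calibration

Per batch, `z = (f̂_c − f̂_k)/sqrt(f̄(1−f̄)(1/2n_c + 1/2n_k) + V_c + V_k)`
with f̄ the count-weighted pooled frequency (the statistic reduces to the
textbook two-proportion z when V = 0). V is the squared standard error of a
pool's replicate mean. The replicate-scatter estimate of V is pooled across
SNPs within each pool: measurement noise is a platform property, and per-SNP
2-df variance estimates would hand the z statistic t-like tails.

The variance model is treated as approximate and the null is calibrated
empirically, per batch, by the QQ line through the first and third
quartiles: slope `IQR/(2·0.6745)` (the empirical null SD) and intercept the
quartile midpoint. Quartiles are insensitive to true signals, which live in
the tails. The location term matters on small panels: per-array
normalisation factors carry sampling noise that shifts all of an array's
frequencies coherently, giving every z of a batch a small common offset.

Batches are combined by Stouffer weighting with sqrt of the effective sample
size `n_c·n_k/(n_c+n_k)` (reduces to the unweighted mean for equal batches),
then χ² = z², genomic control λ = median χ² of a seeded random SNP subset
divided by 0.4549 and floored at 1, adjusted χ² = χ²/λ, and p from the
1-df upper tail.

## Replication statistics

* Odds ratios use Woolf CIs with the Haldane–Anscombe +0.5 applied to all
  cells when any cell is empty. Published tables sometimes orient ORs to the
  case-enriched allele (reporting OR ≥ 1 even when the designated risk
  allele is depleted in cases); `allelic_or(..., orient_case_enriched=True)`
  reproduces that convention explicitly.
* The Cochran–Armitage trend test uses scores (0, 1, 2); under
  Hardy–Weinberg it agrees asymptotically with the allelic χ², which the
  tests verify by simulation.
* Covariate adjustment is an additive-genotype logistic model fit by IRLS
  (statsmodels); separation or non-convergence yields a flagged result, not
  an exception.
* IVW meta-analysis recovers per-study SEs from 95% CIs as
  `(ln hi − ln lo)/3.92`; the pooled log-odds is the inverse-variance
  weighted mean. Note that the published CIs are printed to 2 decimals, so a
  meta p-value recomputed from them is only approximate even when the meta
  OR reproduces exactly.
* Analytic power of the 1-df allelic test uses the noncentral χ² with
  NCP `(f₁−f₀)²/(p̄(1−p̄)(1/m₁+1/m₂))` (allele counts m = 2n, pooled p̄) —
  the convention of the standard genetic power calculators. The tests
  cross-check it against Monte-Carlo rejection rates.

## Two-locus EM and LD

Only double heterozygotes are phase-ambiguous; EM splits them by the current
cis/trans posterior, starting from linkage equilibrium, tolerance 1e-8, at
most 1,000 iterations, returning a flagged last iterate on non-convergence.
The test oracle exploits the fact that the MLE preserves observed allele
frequencies, reducing the search to a 1-D grid over the cis-haplotype
frequency. D′ uses the standard sign-dependent Dmax; a monomorphic locus
leaves D′/r² undefined and flagged rather than raising.

## ESE scanning

Additive PWM scores over windows of the motif width; windows containing N
are skipped; forward strand only (ESE context is the pre-mRNA sense
strand). The shipped SC35-like matrix is synthetic — the published
ESEfinder matrix is not redistributable, so the published per-site scores
cannot be reproduced; the module accepts any matrix in its TSV format.

## What the synthetic data does and does not show

The generator reproduces the statistical skeleton the pipeline relies on:
binomial pool composition, homoscedastic replicate noise, multiplicative
channel gain, uncorrelated bad arrays, and mean-shift stratification.
It does not model probe-sequence effects, cross-hybridisation, spatial
artefacts, batch chemistry, or unequal DNA contribution of pool members.
Passing tests therefore demonstrate internal statistical correctness and
calibration under the stated error model — not robustness to every failure
mode of physical arrays.

Problem sizes used by the test suite and the acceptance script (20,000-SNP
null panels, 10,000-SNP analysis runs, 10⁴ Monte-Carlo replicates, 10⁶
draws for scale recovery) were chosen so each check's Monte-Carlo error is
comfortably below the tolerance it asserts.

## Known limitations

* The empirical-null calibration assumes most SNPs are null; a panel
  dominated by true signal would deflate the statistic.
* Genomic control corrects a constant inflation only; confounding that
  varies across the genome needs mixed models, which are out of scope.
* The replication module targets candidate-SNP panels (≤ ~10³ SNPs); it is
  not a genome-wide individual-level GWAS engine.
* Pool-frequency variance omits unequal pool contribution (pipetting
  error); with it, σ_array would absorb part of that term in practice.
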