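# Methods

This note documents the statistical model behind `replifst`, the defaults
and the numerical conventions, in enough detail to audit or extend the
package.

## The question and the quantities

The package asks whether the *replicability* of published gene–disease
associations — the fraction of studies of an association that reported a
positive result — is related to how genetically differentiated the gene is
between the populations in which the studies were run.

Two association sets are built from per-study records:

- **Global Set**: gene–disease pairs studied ≥ 4 times anywhere
  (`min_studies`, default 4). Replicability is computed over all studies
  regardless of continent; records with Mixed or Unassigned ancestry count
  here.
- **Continental Set**: pairs with ≥ 4 studies in Europe AND ≥ 4 in East
  Asia (`min_per_continent`, default 4). Studies from any other continent
  are excluded from these counts. A configurable disease drop list removes
  continent-endemic phenotypes before counting.
- **Conservative subsets**: associations replicated ≥ 50% of the time
  (inclusive; in at least one continent for the Continental Set). Genes
  with < 10 SNPs are additionally flagged as ineligible for *mean-FST*
  analyses (they keep contributing to per-SNP analyses): a gene-average over
  a handful of SNPs is too noisy to serve as the gene's differentiation
  value.

Continent assignment is an explicit label → continent lookup
(`DEFAULT_ANCESTRY_MAP`, replaceable by a two-column TSV). Unknown labels
map to `Unassigned` and are logged, never dropped silently. Disease-name
synonyms are likewise an explicit table; the package deliberately does no
fuzzy matching, because name clustering is a judgement call that should be
visible in the input, not buried in an algorithm.

### Discordance: Cramér's φ

Per Continental-Set association the 2×2 table crosses continent (Europe,
East Asia) with study outcome (positive, negative). Cramér's
φ = |ad − bc| / √((a+b)(c+d)(a+c)(b+d)), identically √(χ²/N) with the
uncorrected Pearson χ². Equal positive proportions give φ = 0; 0% vs 100%
replicability gives φ = 1. Two conventions:

- **Zero margin** (e.g. all studies positive in both continents): φ = 0.
  No variation in outcome means no demonstrable discordance. The choice is
  recorded in output metadata.
- No continuity correction inside φ — a Yates correction would destroy the
  φ = 1 boundary identity. The Yates correction is used only in the
  derived-allele test below, where it reproduces the worked examples'
  printed p-values.

### Differentiation: Weir–Cockerham θ

Per SNP, from allele counts of r populations (n_i sampled alleles at
derived-allele frequency p_i):

```
nbar = Σn_i / r
nc   = (Σn_i − Σn_i²/Σn_i) / (r − 1)
pbar = Σ n_i p_i / Σ n_i
s²   = Σ n_i (p_i − pbar)² / ((r − 1) nbar)
a = (nbar/nc) [ s² − (pbar(1−pbar) − s²(r−1)/r) / (nbar − 1) ]
b = (nbar/(nbar−1)) [ pbar(1−pbar) − s²(r−1)/r ]
θ = a / (a + b)
```

This is the allele-based (haploid-count) form — the estimator operates on
allele frequencies, not on genotypic heterozygosity — which keeps the
fixed-difference identity exact: p₁ = 1, p₂ = 0 at equal n gives θ = 1.
Conventions and edge cases:

- **Negative θ retained.** Identical sample frequencies give θ ≤ 0 (the
  bias-correction term); clamping at zero before averaging would bias gene
  means upward. A `clamp_negative` switch exists for sensitivity analysis.
- SNPs monomorphic in the pooled sample have θ undefined (NaN) and are
  excluded from aggregates, with a log record.
- Populations with no calls at a SNP are dropped from that SNP's estimate;
  fewer than two populations with data → undefined.
- Pairwise θ is computed for EUR–EAS, EUR–AFR, EAS–AFR and a global θ with
  all populations in the same r-population formula.
- Before continental analyses, SNPs monomorphic in the **pooled** Europe +
  East Asia sample are removed. Under this (pooled) reading the filter
  provably cannot change pairwise EUR–EAS aggregates computed on the
  remainder, because exactly these SNPs have undefined EUR–EAS θ. (The
  per-population reading would also remove SNPs fixed for different alleles
  in the two continents, i.e. θ = 1 — a filter that would alter results;
  the pooled reading is therefore the one implemented.)
- When two East Asian panels are simulated or supplied separately they can
  be pooled into one analysis population via `pool_map` for FST while
  remaining separate for the derived-allele test.

Per gene, θ is aggregated three ways: mean over SNPs with defined θ,
maximum, and mean over tagSNPs. The maximum is strongly length-biased
(more SNPs, higher expected maximum), which the test suite demonstrates:
the Spearman correlation of SNP count with max θ exceeds that with mean θ
on simulated genes. Mean θ is the headline gene-level quantity.

### tagSNPs

Per population, SNPs with call rate ≥ 0.75 and MAF ≥ 0.1 are eligible. A
greedy set cover repeatedly picks the eligible SNP whose r² ≥ 0.8
neighbourhood covers the most still-uncovered eligible SNPs (ties broken by
lower genomic position), until all eligible SNPs are covered. r² is the
squared Pearson correlation of diploid dosages (composite LD; no phasing),
pairwise-complete over non-missing calls. The final tag set is the
intersection of the per-population tag sets. The contract is coverage, not
minimality: within each population every eligible SNP is within r² ≥ 0.8 of
one of that population's tags; this is brute-force verified in tests.
Intersecting across populations can of course leave genes with no common
tag — such genes simply have no tag-mean θ.

### Extreme-frequency percentage

Per gene and population pair: the percentage of SNPs (among those with a
defined MAF in both populations) with MAF < 0.1 in exactly one population
and MAF > 0.2 in the other (both strict). This quantifies how often a
variant common enough to detect in one continent is too rare to detect in
the other — the "pure statistical power" alternative explanation that the
stepwise regression can then discard.

### Ancestral/derived status

The ancestral allele is inferred by parsimony from two outgroup species: a
call is made only when both outgroup alleles agree and match one of the two
human alleles; otherwise the SNP is excluded. A population's major allele
(frequency ≥ 0.5) is then classified ANC or DER. A frequency of exactly
0.5 is classified DER by default — "the derived allele has reached ≥ 50%" —
with the tie direction configurable, since either reading of "major" is
defensible at the boundary.

## Statistical analyses

- **Spearman correlations** (scipy, average ranks, t-approximation p) relate
  φ to gene θ under each pooling mode. In per-SNP and per-tagSNP pooling,
  every SNP inherits the φ of its gene; these correlations are flagged
  `pseudo_replicated` in the output because SNPs of one gene are not
  independent observations.
- **Gene-resampling test**: the observed disease-gene-set mean θ is compared
  with `n_resamples` (default 10,000) random gene sets of the same size
  drawn without replacement from the genome-wide pool; the empirical p is
  k/N in the stated tail (default lower, since the hypothesis is *reduced*
  differentiation of disease genes); k = 0 is reported as the bound
  "< 1/N" rather than 0. Draws are vectorised (random-key argpartition) and
  chunked to bound memory.
- **Median split**: Global-Set associations are split at the median
  replicability with ties included in BOTH strata (low: ≤ median, high:
  ≥ median), and both stratum sizes are always reported — with many ties at
  the median the strata overlap, so reporting only one n would be
  ambiguous.
- **Derived-allele test**: per population, the 2×2 stratum × (ANC, DER)
  count table — each association contributes its gene's SNP classifications
  once per association — is tested with the Yates-corrected Pearson χ²
  (1 df, two-sided). The continuity correction is the convention that
  reproduces the printed p-values of the worked examples from their printed
  counts (the uncorrected statistic does not).
- **Forward stepwise regression** of φ on eight candidates (mean EUR–EAS θ,
  SNP count, % intronic SNPs, total/EUR/EAS study counts, mean sample size,
  mean publication year; the extreme-frequency % can be added as a ninth).
  Probability-of-F entry at p < 0.05, removal at p > 0.10 (the classical
  defaults of the era's statistics packages; both are flags). Variables are
  z-scored, so coefficients are standardized β; tolerance of each selected
  predictor is 1 − R² of that predictor on the other selected ones; the
  model F is the overall F against the intercept-only model with df
  (k, n − k − 1). (Step-wise software of that era sometimes printed the
  step-1 F-change instead; the overall F is what this package reports.)
  The selector is validated against an independent RSS-based enumeration
  oracle on small candidate sets.
- The analysis is repeated without the two genes with the most SNPs, whose
  SNP counts dominate the per-SNP analyses, and the report carries both
  variants.

## The synthetic-data generator

The generator is first-class, tested code; its defaults define the study
conditions for all recovery experiments.

- **Allele frequencies.** Per SNP, the ancestral derived-allele frequency
  p₀ ~ Uniform(0.05, 0.95) (bounded away from 0/1 so monomorphic SNPs do
  not dominate; they still arise after sampling and are handled downstream).
  Population k draws p_k ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) — the
  Balding–Nichols model, chosen because its parametric F_ST equals F,
  giving a closed-form recovery target; F = 0 returns p₀ exactly.
  Defaults: EUR n=60, F=0.10; EAS n=90, F=0.10; AFR n=60, F=0.15
  (HapMap-like sample sizes; F of 0.1 puts pairwise EUR–EAS θ near the
  genome-wide values reported for those populations). Genes vary in
  divergence through a per-gene multiplier d_g ~ Uniform(0.25, 1.75)
  applied to every population's F — the analysis needs between-gene
  variance in differentiation to have anything to correlate.
- **Genotypes.** Diploid dosages ~ Binomial(2, p_k); missing calls at rate
  0.02; two outgroup species carry the ancestral allele independently with
  probability 0.99 each (so the parsimony rule has a realistic failure
  mode: species can disagree → exclusion, or both can carry the derived
  allele → a flipped call).
- **Associations and studies.** 120 genes, 40 associations on distinct
  random genes (the remaining genes form the background pool for the
  resampling test); 8–16 studies per continent per association
  (shifted-Poisson, mean 10); half the associations causal in exactly one
  continent (fair coin which), the rest causal in both. With coupling
  strength s, heterogeneous status is assigned by ranking genes on
  divergence and taking the top priorities of
  s·rank + (1−s)·Uniform — s = 1 pins heterogeneity to the most divergent
  genes, s = 0 decouples them. A study is positive with probability 0.8
  (power) when the association is causal in its continent, 0.05 (false
  positive rate) otherwise. Sample sizes are log-normal (median ≈ 400),
  years Uniform 1990–2010; ~10% of records carry the tested marker's SNP
  ID, mirroring how rarely real records do. Occasional extra records with
  minor-ancestry or mixed labels exercise the normalisation path.
- Everything flows from one seeded numpy Generator: same config, same
  bytes.

What the generator does **not** emulate: linkage disequilibrium within
genes (SNPs are independent given the gene's divergence — correlated SNPs
for tagger tests are built by copying columns in fixtures), ascertainment
bias of genotyping panels, publication bias in study outcomes, disease-name
noise, and real site-frequency spectra (p₀ is uniform, so roughly half of
all derived alleles are major — real derived-allele fractions are far
lower). Passing recovery tests therefore show the *pipeline* is correct
and calibrated under the stated model, not that any particular biological
dataset would yield the same effect sizes.

## Problem sizes and determinism

The default conditions (40 associations, 120 genes, ~1,700 SNPs, 210
diploids) run the full analysis in a few seconds; the recovery experiments
in the test suite use 50 replicate seeds for the null-coupling check, 200
repetitions for resampling-null calibration, and 5,000 SNPs for estimator
recovery — sizes chosen so the whole battery stays comfortably within an
interactive development loop while keeping Monte-Carlo error well below the
asserted tolerances (e.g. the binomial standard error of the 50-replicate
rejection-rate check is ~1.4 percentage points against a 10-point margin).
Every stochastic routine takes a seed or Generator; report tables rerun
byte-identically under the same config.

## Known limitations

- The mean-of-ratios gene θ (averaging per-SNP θ) is mildly downward-biased
  relative to the parametric F at small sample sizes; at F = 0.1 with 60
  diploids per population the bias is ≈ 0.01 on the estimator-recovery
  fixture. Ratio-of-sums combination was not adopted because the analysis
  needs per-SNP values for the per-SNP and tagSNP pooling modes.
- The greedy tagger guarantees coverage, not minimal tag sets; tag counts
  are therefore upper bounds on what an optimal tagger would report.
- Stepwise selection inherits the usual caveats (selection inference,
  order dependence near ties); the enumeration oracle checks the selector's
  mechanics, not the inferential validity of stepwise regression itself.
- With an even number of associations and no ties, the median split's two
  strata are equal halves; with heavy ties both strata can exceed half the
  set — downstream counts always report both stratum sizes for this reason.
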