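# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the design decisions taken where several
reasonable implementations exist.

## Association tests

**Cochran-Armitage trend test.** For a 2×3 genotype table with case counts
(r₀, r₁, r₂) and control counts (s₀, s₁, s₂), scores w = (0, 1, 2) give the
1-df chi-square

χ² = N·(N·T − R·Σwₙ)² / [R(N − R)(N·Σw²ₙ − (Σwₙ)²)],  T = Σwᵢrᵢ,

the score-test form without a continuity correction, matching standard
trend-test defaults. It equals N times the squared Pearson correlation
between the dosage score and the case indicator, which is how the test
suite cross-checks it. Monomorphic or degenerate tables are reported as
undefined and the SNP is skipped.

**TDT.** Transmissions are counted on minor-allele dosages. For a family
with one heterozygous parent, the homozygous parent's contribution to the
child is known, so the het parent's transmission is determined. With both
parents heterozygous, the child's dosage fixes only the *total* number of
minor alleles transmitted; a heterozygous child is ambiguous and the
standard allele-counting rule applies (one transmission, one
non-transmission). This matches the behaviour of common TDT tools on
unphased data; it is a documented convention, not an inference about any
particular study's choice. Families with a missing genotype at a SNP
contribute nothing there.

**Effect estimates for the meta layer.** The case-control allelic lnOR and
its SE come from the 2×2 allele-count table; the TDT lnOR is ln(b/c) with
SE √(1/b + 1/c). A 0.5 Haldane-Anscombe correction is applied to all cells
only when a zero cell occurs, and its use is flagged in the output.

## Quality control

Filter order is: per-sample call rate (≥ 0.95), then per-SNP call rate,
MAF, and exact HWE — each SNP is counted once under the first filter it
fails. The order matters because sample exclusion changes the MAF and HWE
denominators; samples are filtered first. MAF minima are design-specific
(0.01 whole-sample for case-control, 0.05 on parents for trios), and the
HWE stratum is controls (case-control), parents (trios) or the whole sample
(population design). A per-SNP call-rate threshold is not part of the
classical filter set this mirrors; 0.95 is adopted symmetrically to the
per-sample threshold and is configurable. MAF is computed on non-missing
calls only.

The HWE test is the exact conditional test: given the minor-allele count,
the probability of each attainable heterozygote count h (same parity) is
proportional to 2ʰ·n!/(n_AA!·n_Ab!·n_bb!), and the two-sided p-value sums
all h whose probability does not exceed the observed one (relative tie
tolerance 10⁻¹²; computed with log-gamma for stability). The suite verifies
it against exact rational-arithmetic enumeration for every table with
n ≤ 50.

Mendelian checking flags dosage triples (F, M, C) with
C < (F=2) + (M=2) or C > (F≥1) + (M≥1); all three members are set missing
at a flagged SNP and families with a flagged fraction above 5% are dropped.
Trios additionally require at least one transmission *and* one
non-transmission of the minor allele genome-wide per SNP
(informativeness).

## Gene-wise corrected p-values

P_g is the fraction of permutation replicates whose per-gene minimal
single-SNP p-value is **equal to or smaller than** the observed minimum —
exactly r/n, not (r + 1)/(n + 1). A zero count is reported with a flag
(P_g < 1/n); the adaptive schedule exists precisely to refine such genes
(10⁴ replicates, then 10⁵ for genes with P_g ≤ 0.01, then 10⁶ for
P_g ≤ 0.001; the schedule is configurable and tests use reduced stages).
Internally the comparison runs on the chi-square scale (min-p ⇔ max-χ²,
which are monotone images of each other under a common 1-df distribution),
avoiding per-replicate tail evaluations.

One label vector per replicate is shared across all SNPs (case-control),
and one flip decision per family per replicate (trios). This preserves
cross-SNP LD in the null, makes gene scores live on a common null GWAS —
required for the clustering-pruning step to be meaningful — and mirrors
max(T)-style permutation in standard GWAS tools. The alternative reading
(independent permutations per SNP) would destroy the correlation structure
and is not implemented.

A consequence worth knowing: because every gene's P_g is referenced to the
same observed label vector and the same replicate stream, gene scores
within one dataset are positively correlated genome-wide. Each P_g is
marginally uniform under the null, but the empirical distribution across
genes in a *single* realisation fluctuates more than an iid-uniform sample
would. The uniformity check in the acceptance suite therefore pools gene
scores over several independent null replicates.

**Regression correction (summary-statistic path).** Where permutation is
impossible (meta-analysis of mixed designs), the gene score
−log₁₀(best-SNP p) is regressed (OLS with intercept) on gene size in kb,
SNP count, greedy-pruned independent-SNP count (r² < 0.8 on dosages,
complete pairs, scan in map order) and any user-supplied columns
(recombination hotspots, genetic distance). The corrected p-value is the
residual's empirical upper-tail rank, (#{residuals ≥ residual_g})/(N + 1),
so the most extreme gene attains 1/(N + 1) and output lies in (0, 1].
Collinear confounder columns are dropped (later column loses) with a
warning — on LD-free synthetic data the independent-SNP count duplicates
the SNP count and is dropped automatically. The regression recipe is this
package's documented construction; external tools implementing analogous
corrections differ in detail. On the same fitted sample the permutation
and regression corrections agree in rank (Spearman ≈ 0.97–0.99 in the
acceptance run), the behaviour reported for such method pairs.

## Enrichment testing

Pruning is genome-wide: genes are grouped by their selected (best) SNP and
only the lowest-P_g gene of each group is retained, *then* sets are
intersected with the pruned universe.

The percentile cut-off at level P is the (100 − P)% quantile of the gene
p-values (linear interpolation between order statistics): the
"95th percentile" cut-off isolates the top 5% most significant genes.

The leading-edge-fraction test draws `n_samplings` sets of the observed set
size from the full gene-p list without replacement and reports the fraction
of samplings with an equal or larger leading-edge fraction, floored at
1/n_samplings. Because the only statistic of a sampling is its
below-cut-off count, drawing the counts directly from the hypergeometric
distribution is an exact realisation of this null (not an approximation),
and is how the implementation samples; a with-replacement flag switches to
binomial draws for sensitivity analysis. The test is exact up to Monte
Carlo error whenever the cut-off is fixed, which the suite verifies against
the closed-form hypergeometric tail. Note the attainable significance
levels are discrete: for a 16-gene set at the median cut-off the level
closest to 0.05 from below is ≈ 0.038, so calibration checks against a
nominal 0.05 should expect rejection rates slightly under 0.05.

The alternative rank tests are one-sided with the alternative "set
p-values are smaller": Wilcoxon-Mann-Whitney (exact when the smaller group
has ≤ 20 members and no ties, otherwise normal approximation with tie
correction), the one-sided two-sample Kolmogorov-Smirnov statistic
sensitive to the set ECDF lying above the complement's, and Welch's t on
−log₁₀(p) — a t-test on raw bounded p-values is ill-behaved, so the
transform is the default and the choice is flagged here. Bonferroni
adjustment multiplies by the number of sets, capped at 1.

## Meta-analysis

Fixed-effect inverse-variance pooling: weights 1/se², combined
lnOR = Σw·lnOR/Σw, SE = 1/√Σw, two-sided normal p. The case-control + trio
combination pools the allelic lnOR with ln(b/c) — the core of the classical
CC/TDT combination method; stratified variants are out of scope. SNPs
missing from some studies are pooled over the available ones and flagged
with the contributing-study count. Study effects are harmonised to a
common effect allele by allele-label comparison before pooling (combining
k identical studies multiplies z by exactly √k, which the suite asserts to
machine precision).

## Synthetic data

The generator emulates the designs this pipeline targets, with defaults
chosen once as the study conditions:

- **Genome**: genes tiled per chromosome, lengths 20–120 kb, intergenic
  gaps 20–200 kb. The gap range reproduces human gene density (~one gene
  per 150 kb), which matters because the ±110/40 kb extension margins make
  the physical-clustering pruning fraction density-dependent; at this
  density roughly 10–30% of genes are pruned, the same regime as real
  annotation. SNPs are placed with 5–20 kb spacing, MAF ~ U(0.05, 0.5).
- **LD**: first-order haplotype copying — adjacent alleles identical with
  probability `ld_rho`, else a fresh Bernoulli(MAF) draw, never across a
  chromosome boundary. This is the simplest model that exercises LD-aware
  steps (pruning, independent-SNP counting); it does not reproduce human
  block structure, recombination hotspots or long-range LD, so passing
  tests demonstrate correctness of the machinery, not realism of human LD.
- **Phenotype**: logit P(case) = logit(prevalence) + Σ dosage·ln(OR) over
  causal SNPs (additive on the log-odds scale, matching the additive tests
  downstream); baseline prevalence 0.1. Cases and controls are ascertained
  by rejection sampling until their quotas are met.
- **Trios**: parental genotypes from the population model, child haplotypes
  by Mendelian transmission, family retained only if the child is affected
  under the same logistic model. Rejection sampling is capped (default 10⁶
  draws) and raises an infeasibility error beyond the cap, so a zero
  prevalence fails loudly rather than looping. Clean output contains no
  Mendelian inconsistencies; an error-injection rate exists solely to
  exercise the QC path, and the injected-cell mask is returned for
  cross-checking.
- **Gene sets**: one named planted set plus decoy sets sampled without
  replacement from non-planted genes (decoys are disjoint from the planted
  set, not from each other).
- **Determinism**: every generator draws from its own child stream of the
  config seed, so identical seed + config gives byte-identical output
  regardless of which generators are invoked and in which order.

Not emulated: population stratification, imputation, genotyping batch
effects, sex chromosomes and mitochondrial variants, realistic human LD
maps. Minor alleles are defined by population frequency with label-order
tie-breaking at 0.5.

## Numerical and engineering choices

- Coordinates: annotation input is 0-based half-open (UCSC convention);
  all reports are 1-based inclusive. Interval containment for SNP
  assignment is inclusive at both ends on 1-based positions.
- Boundary extension is strand-aware by default (upstream against the
  transcription direction); a flag applies 110 kb left / 40 kb right
  uniformly. Both behaviours are available because "upstream/downstream"
  is ambiguous without a strand convention; neither is presented as any
  particular study's choice.
- The >1 Mb transcript rule is evaluated as the inter-transcript gap by
  default, with the total-span reading behind a flag.
- Minor-allele orientation: whole-sample frequencies for case-control
  input, parents-only for trios; frequency ties at 0.5 break by allele
  label order.
- Permutation engines are batched (512 replicates per block) as three
  BLAS matmuls per block over genotype-class indicator matrices; per-gene
  minima use `maximum.reduceat` over a flattened gene→SNP index.
- The pipeline writes a manifest (seed, config hash excluding the output
  directory, per-stage counts) and re-runs are byte-identical under a
  fixed seed; per-stage RNG streams are spawned from the run seed.
- Test problem sizes: calibration and power checks use genomes of 200
  genes (~2,000–3,000 SNPs) with reduced permutation schedules (500–2,000
  replicates) and 100–1,000 subjects, which keeps each acceptance check in
  the seconds-to-a-minute range; production defaults are the full
  10⁴/10⁵/10⁶ schedule and 10,000 samplings.

## Known limitations

- The power of the 50th-percentile leading-edge test is combinatorially
  capped when only a minority of set genes carry signal: a 16-gene set
  needs ≈ 12 genes below the median to reject at 0.05, so with 5 causal
  genes power cannot exceed ≈ 0.27 regardless of effect size. Sparse-signal
  sets are the 95th percentile's regime (power ≈ 0.9–1.0 in the acceptance
  run); the 50th percentile detects *distributed* weak signal.
- Covariate-adjusted association (logistic regression), genomic control,
  imputation, X/Y/mtDNA, random-effects meta-analysis and heterogeneity
  statistics are out of scope.
- The regression correction assumes ≥ 10× more genes than confounder
  columns and is refused otherwise.
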