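# Methods

## Background mutation model

The null hypothesis is that somatic mutations accumulate independently and
uniformly *within* three sequence categories, each with its own per-base,
per-patient background mutation rate (BMR):

| category | definition | default rate |
|---|---|---|
| A/T | adenine or thymine | 8.54 × 10⁻⁷ |
| C/G | cytosine or guanine outside a CpG dinucleotide | 1.2 × 10⁻⁶ |
| CpG | either base of a CpG dinucleotide | 4.31 × 10⁻⁶ |
| indel | insertion/deletion, no sequence specificity | 2.2 × 10⁻⁷ |

The defaults are exome-wide rates estimated in ovarian-cancer cohort
sequencing. The CpG category captures the elevated C→T rate from
deamination of 5-methylcytosine; since the dinucleotide is its own reverse
complement, both members receive the CpG rate. Because no sequence
specificity is available for indels, the indel rate is *added to each*
substitution category by default (`fold_indel_rate(mode="add")`;
`mode="split"` apportions it equally instead — the choice is exposed
because either reading of "fold the indel rate in" is defensible, and at
the default rates the difference is below 2% of any effective rate).
Ambiguity codes (N) form a fourth category with rate 0. The model is
deliberately minimal: no trinucleotide signatures, no per-patient rate
heterogeneity, no coverage or expression covariates.

## Library construction

Only probe-covered exonic bases can produce calls in exome data, so the
simulation substrate is the intersection of merged per-gene exons with the
merged capture-probe intervals. Conventions that matter:

* All coordinates are 0-based half-open internally; GTF (1-based closed)
  and MAF positions are converted on read, BED is native.
* Exons of multiple transcripts of one gene are unioned first, so no base
  is double-counted within a gene. Bases shared *between* genes count for
  each gene independently, matching symbol-level aggregation of mutation
  counts downstream.
* CpG context is looked up in the genome one base beyond each interval
  end — context is a property of the genome, not of probe boundaries. At a
  chromosome edge the absent neighbour is treated as non-C/non-G.

## Simulation and the expected count

Per patient, each base of category *c* mutates independently with
probability eff_c, at most once. The sampler draws one binomial count per
(gene, category) block: the sum of n independent Bernoulli(p) trials *is*
Binomial(n, p), so the shortcut is exactly distributionally equivalent to
flipping every base; a literal per-base mode is retained and the test
suite checks the two are statistically indistinguishable. A replicate is a
cohort of `n_patients` independent patients; the per-gene expected count
S_g is the mean cohort total over `n_replicates` replicates (the analytic
expectation `n_patients × Σ_bases eff` is reported alongside as a
cross-check). The reference design is 316 patients × 100 replicates =
31,600 patient-level runs.

RNG streams are derived as `SeedSequence(seed, spawn_key=(replicate,
patient))`, so any subset of the design can be reproduced independently of
execution order, and repeated runs are bit-identical.

## Ranking

Genes qualify if observed at least once (O_g ≥ 1) and simulated with
S_g > 0 (zero-expectation genes can arise in tiny toy libraries and are
excluded rather than pseudocounted; a `pseudocount` option exists but
defaults off). The statistic is the plain ratio r_g = O_g / S_g; selection
of the candidate sets is purely rank-based (k smallest, k largest; k = 50
by default), with ties broken by larger O_g then gene symbol so re-runs
are identical. The log-ratio histogram uses log₁₀. An optional per-gene
Poisson tail probability is computed only as a diagnostic and plays no
role in selection. No multiple-testing machinery is involved because no
p-value is thresholded.

## Omics comparison

The pooled comparison flattens every individual (gene, sample) value —
and for methylation every (site, sample) value of every site mapped to the
gene — into one vector per gene set, then applies the two-sample
Kolmogorov–Smirnov test (scipy; asymptotic p for the large pooled sizes,
exact for small n). Pooling raw site values (rather than averaging sites
per gene first) is the default; `average_sites=True` gives the other
convention. The reported direction is the set with the greater median,
falling back to the mean when medians tie exactly — which is the norm for
discrete copy-number values centred at 2.

**Statistical caveat:** pooled values from one gene across samples are
treated as independent observations. They are not (within-gene
correlation), so the KS p-values overstate certainty; they are used here
as a descriptive effect-size summary with direction, mirroring how such
pooled comparisons are commonly reported.

Per-gene stratification (`expression_by_mutation_status`) splits one
gene's per-sample expression by whether that sample carries a mutation in
the gene; strata with fewer than 2 samples are flagged underpowered and
not tested.

## Synthetic data: what it emulates and what it does not

The generator exists so every stage has a ground truth. Selection is a
per-gene rate multiplier s_g (s < 1 depletion, s > 1 excess) — the
minimal mechanism consistent with "selected against mutation"; no
functional consequence is modelled.

* **Genome.** A first-order Markov chain over {A,C,G,T} whose stationary
  distribution equals the requested marginal (GC split equally between C
  and G) and whose C→G transition is inflated so the expected CpG
  dinucleotide frequency is exactly `cpg_enrichment × (gc/2)²`. Genes are
  laid out non-overlapping; probes tile a configurable fraction of each
  exon. Defaults: 1000 genes × 2 exons of 300–700 bp, GC 0.4, CpG
  enrichment 2 — roughly exome-like composition at toy scale.
* **Cohort.** Each base of gene g mutates per patient with probability
  s_g × eff_cat, implemented as explicit per-base uniform draws —
  deliberately sharing no sampling code with the simulator, so the
  cross-module calibration test is meaningful. Records are written as a
  MAF-dialect TSV with genuine coordinates, reference alleles and sample
  barcodes, plus a truth ledger of every emitted count.
* **Omics.** Expression ~ Normal(8 + δ, 1) (log2-RMA-like scale);
  methylation ~ Beta with mean 0.5 + δ and concentration 10 over 1–3
  sites per gene; copy number = round(Normal(2 + δ, 0.6)) clipped to
  [0, 8]. Default deltas for the planted non-mutated set: expression +1,
  methylation −0.2, copy number +0.5 — the direction pattern reported for
  real cohorts (higher expression, lower methylation, higher copy number
  for non-mutated genes).

Passing the planted-recovery and direction benchmarks therefore shows the
*machinery* is correct and powered under idealized conditions — i.i.d.
rates within categories, no mutation-calling noise, no purity or coverage
variation, no correlated omics structure. It does not validate the
biological model on real data.

## Benchmark design and problem sizes

The standard studies (in `exomesim.benchmark`, driven by `analysis/` and
`scripts/acceptance.py`) use sizes chosen to be well-powered yet quick on
a single CPU:

* run-count check: 20 genes × 25 bases, full 316 × 100 design (~3 s);
* calibration: 200 identical genes of 25 bases (15 A/T, 7 C/G, 3 CpG),
  published rates ×1000 so expected cohort counts ≈ 11; per-gene
  z = (mean − analytic)/SE with SE from the binomial variance over 100
  replicates. Note that z is standard normal per gene, so out of 200
  genes ~0.5 are expected beyond 3 SE by chance in any single realization;
  the per-gene z table is written so the family-wise picture is visible.
* recovery: 1000 genes, rates ×100, 300 patients → neutral S_g ≈ 40
  (≥ 20 everywhere), 20 genes planted at s = 0.1 and 20 at s = 10,
  k = 50; the chance-level null uses the same simulation with an
  all-neutral cohort and a hypergeometric 95% interval.
* KS studies: two 50-gene sets × 300 samples; 100 generations for power
  (+1 sd shift), 200 for null uniformity.

## Known limitations

* The background model ignores trinucleotide context, regional mutation
  rate covariates (replication timing, expression) and patient-level
  hypermutators; ratios on real cohorts inherit those biases.
* Observed counts are taken from the MAF's gene-symbol column as given —
  no re-intersection with the library, no consequence filtering, no
  per-patient deduplication beyond what the caller produced.
* KS p-values on pooled omics treat correlated values as independent (see
  caveat above).
* Tail size k is a choice, not an inference; quantile boundaries are
  reported (k/N and (N−k)/N), not estimated.
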