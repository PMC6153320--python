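# Methods

## The gene-level model

Counts of de novo mutations (DNMs) in a gene are modelled per mutation
class c ∈ {LoF, D-Mis}. With N trios and a per-gene, per-class background
rate μ_c (per haploid genome per generation), the null expectation is
λ_c = 2 N μ_c. Under the risk-gene alternative the count is
Poisson(λ_c γ) with relative risk γ ~ Gamma(shape = γ̄ β, rate = β), so
the marginal alternative is negative binomial with size r = γ̄ β and
success probability p = β/(β + λ_c). The class Bayes factor is the
likelihood ratio of those two marginals, computed in log space
(`scipy.stats.nbinom.logpmf − poisson.logpmf`), and per-gene evidence is
the product over the two classes. Degenerate inputs: λ = 0 with x = 0
returns BF = 1 by convention (logged); λ = 0 with x > 0 is an error,
since the observation is impossible under the null.

The model assumes counts are independent across genes and classes given
the rates, that the background rate tables are correct in expectation,
and that a single Gamma prior per class describes risk-gene effects.

### Hyperparameters

| parameter | default | meaning |
|---|---|---|
| π | 0.05 | prior fraction of risk genes |
| γ̄_LoF, β_LoF | 20, 1 | prior mean / dispersion of LoF relative risk |
| γ̄_DMis, β_DMis | 4.7, 1 | same for damaging missense |
| M | 1000 | Monte Carlo null draws per gene |

These are conventional settings for severe neurodevelopmental trio
cohorts; none is estimated from data (moment matching is out of scope).
All are exposed in `TadaParams` and the pipeline config.

### q-values

Two constructions are computed and written side by side:

- **Bayesian FDR** (`q_bayes`): rank genes by decreasing total BF; the
  q-value at rank k is the mean posterior null probability
  (1−π)/((1−π)+π·BF) over the top k. Ties in BF share the q of the worst
  tied rank. This quantity needs no simulation and has no resolution
  floor.
- **BH on simulation p** (`q_bh`): per gene, M null count pairs are drawn
  from Poisson(λ_c), the null BF recomputed, and
  p = (#{BF\* ≥ BF_obs}+1)/(M+1); Benjamini–Hochberg (hand-rolled
  step-up, cross-checked against statsmodels) converts p to q. Per-gene
  RNG streams are seeded from (master seed, CRC-32 of the gene symbol),
  so results are independent of gene order.

The consensus stage uses `q_bh` by default (`q_method` switches to
`bayes`). Note the interaction between M and the gene count m: the
smallest attainable p is 1/(M+1), so the smallest attainable BH q is
roughly m/(M·k) where k genes sit at the floor. With M = 1000 and
thousands of genes, `q_bh` cannot reach 0.1 unless many genes hit the
floor; either raise `n_null_samples` to ~10·m or use `q_method: bayes`.
The observed log-BF entering the comparison is computed from the same
per-count lookup tables as the null draws, so ties are exact in floating
point — comparing against an independently assembled log(BF) loses the
ties and makes the p-value anti-conservative.

For calibration checks a tie-randomized variant is available
(`randomized=True`): p = (#{BF\* > BF_obs} + U·(#{BF\* = BF_obs}+1))/(M+1),
which is exactly uniform under the null. It is the right oracle for
uniformity tests but is never reported, since it can fall below 1/(M+1).

### Consensus across rate models

Four background-rate models (GC-content, sequence-context, methylation
and divergence based) are scored independently. A gene is
high-confidence iff its q-value is < 0.1 under ≥ 3 models **and** it
carries ≥ 2 DNMs (all coding DNMs, including synonymous, are counted for
this gate); the relaxed tier repeats the rule at q < 0.3. A gene absent
from one model's rate table counts as not significant there. Rate tables
supplying only a total gene rate are split 0.1/0.3 into LoF/D-Mis by
default (configurable, logged).

## Variant filtering and classification

Rows with a non-exonic class or maximum population minor-allele
frequency ≥ 0.001 are removed (the boundary value is removed);
synonymous variants are coding and survive this filter. LoF covers
frameshift and non-frameshift indels, stop-gain, stop-loss and splicing
SNVs — non-frameshift indels are included by default and the switch
`lof_includes_nonframeshift_indels` records the ambiguity. Missense is
D-Mis at ≥ 8 of 14 damaging predictor votes; a missense row with missing
votes is treated as 0 votes and logged. Gene symbols are matched
case-sensitively after trimming; no alias resolution. An optional
exact-duplicate drop on (sample, chrom, pos, ref, alt) is available for
overlapping source cohorts but is off by default.

## Network connectivity

Co-expression edges join gene pairs with |Pearson r| above 0.6 across
all expression samples; anti-correlation counts (absolute value). PPI
edges load from a STRING-style scored list with a default combined-score
cutoff of 400 (the cutoff is configurable since no canonical value
exists). The permutation test resamples the query set uniformly without
replacement from the gene universe (network nodes by default; partners
can be excluded), recomputes the connected-query-node count and the
query–partner edge count, and reports p = (#{null ≥ obs}+1)/(n_iter+1)
per statistic, with the uncorrected r/n convention written alongside.
Edges with both endpoints inside both sets count once. The two-sample
Kolmogorov–Smirnov comparison of per-gene interaction counts uses
log10(count+1) and the asymptotic p.

## Co-expression modules

Unsigned soft adjacency a_ij = |cor(x_i, x_j)|^6 (power configurable);
topological overlap TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij)
with unit diagonal; average-linkage clustering on 1 − TOM. Dynamic tree
cut is deliberately not re-implemented: with a target module count n the
tree is cut into progressively more clusters until n of them reach the
minimum size (5 by default), because loosely attached genes peel off as
singletons first and a fixed n-way cut would isolate noise instead of
separating modules. Genes in undersized clusters are unassigned
(label 0); modules are numbered by decreasing size. A fixed cut height
is the alternative cut specification.

The module eigengene is the first principal component of the
gene-standardized module expression (samples as observations), scaled to
unit variance and sign-anchored so its correlation with the module's
mean standardized profile is non-negative. Per developmental period the
trajectory reports mean ± 1.96·SEM; no loess smoothing. All samples
(regions × periods) enter the correlations jointly; region averaging was
considered and rejected to keep sample-level variance visible.

## Burden tests

All burden tests are two-sided Fisher's exact tests on 2×2 tables with
the cross-product odds ratio ad/bc; when any cell is zero the Haldane
correction (0.5 to every cell) is applied to the OR (and flagged), never
to the p-value. Gene-set enrichment intersects every set with the stated
background universe and corrects across the collection with BH by
default (Bonferroni available). Intolerance flags: intolerant = RVIS
percentile ≤ 25, extremely intolerant = pLI > 0.9 (strict), hot zone =
both. Module mutation burden contrasts LoF vs D-Mis composition of two
modules at three levels — DNM count, genes with ≥ 1 qualifying DNM, and
distinct carrier samples (a child with three LoF DNMs in a module counts
once) — with odds ratios oriented module-1/module-2.

## Synthetic data

The generators produce every input the pipeline reads, with planted
ground truth returned in `SimTruth`:

- **Trio DNMs**: per-gene, per-class rates lognormal (median 1e-5,
  σ = 1); counts Poisson(2Nμγ) with γ = 20 (LoF) / 4.7 (D-Mis) for
  planted risk genes, 1 otherwise; distinct carriers per gene; decoy rows
  (synonymous, sub-threshold missense, non-coding, MAF ≥ 0.001) exercise
  the filters and are exactly the rows the filter removes. Four rate
  tables are lognormal-noised copies of the truth (σ = 0.2), chosen so
  the ≥3-of-4 consensus rule actually disagrees on marginal genes.
  Default scale: 5,000 genes, 1,027 case / 951 control trios, 63 risk
  genes.
- **Expression**: 15 ordered developmental periods × 6 brain regions;
  module 1 (39 genes) follows a trajectory rising to a peak at 16–19
  post-conception weeks then declining to a childhood minimum; module 2
  (18 genes) falls to an infancy minimum then recovers and plateaus in
  adulthood; 6 background genes are pure noise. Gene-level Gaussian noise
  σ = 0.5 against template amplitude ~1.4, enough that recovery is
  non-trivial but reliable.
- **Network**: Erdős–Rényi background plus planted query–partner edges;
  with no planting the graph is label-exchangeable — the null for
  permutation-test calibration.
- **Gene sets / intolerance**: sets drawing a stated fraction of members
  from the query set; annotations with hot-zone rates elevated in the
  query.

What the generators do **not** emulate: trinucleotide-context mutation
processes, region-specific covariance in expression, scale-free PPI
degree distributions, and symbol aliasing. Passing tests therefore
demonstrate correctness and calibration of the statistics under their
assumed models, not robustness to those real-data features.

## Calibration conditions and problem sizes

The test suite and `scripts/acceptance.py` use these desk-scale designs:

- Bayes factors vs quadrature: grid x ∈ 0..6, λ ∈ {1e-4, 1e-2, 1},
  γ̄ ∈ {2, 20}, β ∈ {0.2, 1, 5}; agreement < 1e-6 relative.
- FDR calibration: 20 cohorts at the default generator scale. The
  Bayesian FDR's guarantee presupposes a correctly specified prior, so
  the calibration run sets π to the planted fraction (63/5000 ≈ 0.0126);
  under the deliberately mismatched default π = 0.05 the realized FDP is
  ~0.27 and is reported un-asserted as a robustness number. Null cohorts
  (no planted risk genes) are checked for ≈ 0 discoveries.
- Monte Carlo p: 2,000 null genes; uniformity via the tie-randomized
  variant (KS), validity of the conservative variant via
  P(p ≤ α) ≤ α.
- Permutation test: exhaustive enumeration on a 4-gene universe (6
  possible query sets) within 3 standard errors at 60,000 iterations;
  null calibration over 200 exchangeable networks (universe 360, edge
  probability 0.05, query 25) at 600 iterations each.
- Module recovery: 10 seeds at generator defaults; adjusted Rand index
  on the planted module genes and the module-1 eigengene peak period.

BF monotonicity in the count holds exactly when λ ≤ β(γ̄−1) — satisfied
by many orders of magnitude at per-gene DNM scales — and is asserted
only there; for λ beyond that bound the BF can dip at x = 1
(BF(x)/BF(x−1) = (γ̄β+x−1)/(β+λ)).

## Known limitations

- Fixed priors; no empirical-Bayes estimation of γ̄/β or π.
- Case-control and transmitted-variant extensions are out of scope.
- The simplified tree cut targets a stated module count; it does not
  discover the number of modules.
- TOM dissimilarity is not a metric; only [0,1] bounds are guaranteed.
- The BH q-value inherits the Monte Carlo p resolution floor (see above).
- Multi-allelic/duplicate DNM reports are only handled by the optional
  exact-duplicate drop; no fuzzy matching across cohorts.
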