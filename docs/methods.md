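# Methods

This note documents the statistical models the package implements, the
choices made where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Marker-set enrichment (MSEA)

**Model.** Let the background be the LD-pruned set of all SNPs mapped to
any gene, with values x = −log10 p. For a quantile ladder
q = (0.50, 0.25, 0.10, 0.05, 0.01), cutoffs cⱼ are the (1−qⱼ) empirical
quantiles of the background. For a gene set with m distinct mapped
markers, Oⱼ = #{set markers with x ≥ cⱼ} and Eⱼ = m·fⱼ with fⱼ the
background fraction ≥ cⱼ. The statistic is

    Q = Σⱼ (Oⱼ − Eⱼ) / √(Eⱼ + κ),   κ = 1.

κ stabilises the variance of the sparse upper-tail terms; the ladder and
κ are configuration-exposed (`quantiles`, `kappa`) because no canonical
values exist — results in this family of methods are not sensitive to
the exact ladder, and the default spans the bulk (median) through the
extreme tail (99th percentile).

**Null and p-value.** The null draws gene sets of the same *gene* count
uniformly from the mapped-gene universe; each sampled gene keeps its
real marker list. Genes with many markers therefore inflate null
statistics exactly as they inflate observed ones — this is the
gene-size-bias control, and it is why the null is at the gene level and
not the marker level. The p-value is the upper Gaussian tail at the
standardised observed Q (one-sided: enrichment only). The Gaussian
approximation trades a little accuracy in the extreme tail (the true
permutation distribution is mildly right-skewed, ~+1% absolute at the
5% level in our calibration runs) for tail resolution far beyond
1/n_perm. BH FDR is applied across all sets tested; with several
SNP→gene mappings a set counts as significant at FDR < 5% in at least
one mapping.

**Permutation sharing.** For a fixed marker assignment the null
distribution of Q depends on the drawn set only through its gene count,
so permutations are computed once per distinct mapped-gene count and
shared by all sets of that size; each size uses an independent,
deterministic substream of the master seed. This is statistically
identical to per-set permutation and an order of magnitude faster.

**Degenerate inputs.** Sets with fewer than two mapped genes are
skipped and logged (not an error of the batch); a permutation count
below 100 is rejected; a degenerate null (sd = 0) raises.

## SNP→gene mapping and LD pruning

Distance mapping links a SNP to every gene whose body ±window (default
50,000 bp, inclusive at exactly the window) contains it; eQTL mapping
links eSNPs to their target genes at FDR < 5% ("significant") or
P < 1e-5 ("suggestive"), cis and trans alike; mappings combine by union
with per-link source tags. All cutoff comparisons are strict (<) and
the MAF input filter removes maf < 1%; the boundary conventions are
documented here because they are conventions, not derivable facts.

Pruning is genome-wide greedy: SNPs are visited in ascending p (ties
broken lexicographically by SNP id, which makes the output a pure
function of the inputs with no seed); a SNP is kept iff r² < 0.7 against
every SNP already kept. Because LD data restrict nonzero r² to listed
pairs or within-block entries, no sliding window is needed; candidate
checks only touch a SNP's block mates and listed partners.

## Superset merging

Two significant sets merge when (a) their overlap coefficient
|A∩B|/min(|A|,|B|), computed on genes intersected with the mapped-gene
universe, is ≥ 0.33 and (b) the shared genes are enriched versus the
universe by one-sided Fisher exact test at Bonferroni-corrected
p < 0.05 (corrected by the number of pairs examined). Components close
transitively (union–find). A single pass is not idempotent — the union
of two sets can newly exceed the overlap threshold against a third — so
rounds repeat until a fixed point, which makes merging idempotent by
construction. Supersets are annotated against reference pathways
(one-sided Fisher, Bonferroni by the number of reference sets per
superset) and confirmed by a second enrichment round at Bonferroni
p < 0.05 across supersets.

## Key-driver analysis (KDA)

For candidate gene v in network N with disease gene set D, the
neighborhood H(v) is the set of nodes within `depth` edges (default 1;
directions ignored — mixed directed/undirected source networks are
treated uniformly). With O = |H∩D∩N| and E = |H|·|D∩N|/|N|, the
statistic is (O−E)/√(E+κ), κ = 1. Candidates default to nodes with at
least 5 neighbors: leaves give degenerate nulls.

The null permutes disease labels over nodes. For this statistic a label
permutation induces exactly a hypergeometric draw of O for each
neighborhood size, so the default null samples O directly from the
hypergeometric distribution (per distinct size, shared across
candidates); a literal label-permutation mode (`null_mode="permute"`)
is kept for validation and agrees with the resampling mode. P-values
are Gaussian upper tails as in MSEA, BH FDR across candidates at the
stringent 1% level, and the top 5 candidates by p per (gene set ×
network) are reported as key drivers with their subnetworks
(KD + neighborhood).

*Limitation:* for neighborhoods of only a handful of nodes the
hypergeometric O takes few values and the Gaussian p inherits that
discreteness; calibration checks should use networks whose candidate
neighborhoods are at least tens of nodes.

Reported key drivers can be tested for over-representation of essential
genes (loss-of-function-intolerant, pLI ≥ 0.9) by one-sided Fisher
exact test against the network node universe.

## SNP-set heritability

Within an LD block with z-scores z, correlation matrix V, and GWAS
sample size n, the variance explained is estimated as

    h²_block = (zᵀV⁺z − q) / (n − q),

with V⁺ the eigendecomposition pseudo-inverse truncating eigenvalues
below 1e-8 and q the retained rank. This is the standard
summary-statistics local-heritability estimator; it is the one
externally sourced formula in the package. Only z² enters, so z derived
from two-sided p-values (sign unknown) is valid. Set-level h² sums
block estimates over the blocks a SNP set touches (SNPs outside any
block are singleton blocks with V = [1], where the estimator reduces to
(z²−1)/(n−1)); negative block estimates are retained so the sum stays
unbiased; the SE is a delete-one-block jackknife.

A gene subnetwork's h² is judged against random gene sets of matched
*gene* count (the matching unit is genes, not SNPs — a SNP-count-matched
mode is available via the mapping options) drawn from a pool excluding
the subnetwork, each processed identically (map → prune → h²):
P = #(h²_random > h²_target)/n_perm, with resolution exactly 1/n_perm;
a zero count is reported as "< 1/n_perm".

## Synthetic data

The generators emulate the statistical structure the analysis assumes,
not human genetics:

- **LD**: AR(1) blocks V_ij = ρ^|i−j| (positive-definite for ρ < 1,
  closed-form structure); a compound-symmetry alternative is available.
  Real LD maps, MAF-dependent LD, and population structure are *not*
  emulated.
- **GWAS**: z ~ MVN(√n·V·β, V) per block — the standard asymptotic
  summary-statistics model — rather than simulating genotypes. This is
  exact under the additive model at large n and fast at desk scale, but
  it does not produce case/control ascertainment effects, liability
  thresholds, or confounding.
- **Genome layout**: genes in disjoint regions, one LD block per gene,
  so distance mapping is unambiguous. Overlapping genes and shared
  markers across genes do occur in real data and are supported by the
  analysis code (markers deduplicate within a set), just not produced
  by this layout.
- **Gene sets**: uniform random sets, optionally with pairs of
  controlled overlap coefficient for merge testing.
- **Networks**: preferential-attachment graphs (heavy-tailed degrees);
  the planted key drivers are the top-degree hubs, whose neighbors
  enter the disease set with probability π against a background base
  rate b, so π/b is the planted fold-enrichment. Either the disease-set
  size or b may be fixed; requesting π·|pool| beyond the disease-set
  size is an error rather than a silent truncation.
- **Truth files** record causal sets, per-SNP β (with Σβ² equal to the
  planted h² to 1e-12), and planted key drivers, so every planted
  quantity can be recomputed independently of the pipeline.

Passing tests on these generators demonstrate internal correctness and
statistical calibration of the methods under their own assumptions;
they do not demonstrate robustness to the violations listed above.

## Problem sizes and numerical choices

Calibration and recovery checks run at desk scale, chosen as the
smallest sizes at which the asymptotic approximations are exercised
meaningfully: null calibration on 20,000 markers / 2,000 genes / 500
sets with 2,000 permutations; power and key-driver recovery over 20
replicates; heritability recovery over 50 replicates of 2,000
independent SNPs at n = 50,000; permutation-heritability null over 100
replicates at 400 permutations. Production defaults are 10,000
permutations throughout. Every permutation stage derives an independent
substream from one master seed (NumPy `SeedSequence` with a
stage-specific spawn key), which is what makes full pipeline reruns
byte-identical. Floating-point p-values of exactly 0 in inputs are
floored to the smallest positive normal double to preserve extreme
signals in rank-based statistics; p-values entering BH are clipped at
1e-300 to avoid spurious zeros from the Gaussian tail.
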