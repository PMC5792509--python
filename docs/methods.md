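# Methods

`antcolonykin` reconstructs the genetic structure of social-insect colonies
— how many queens, how many male mates, and how related nestmates are —
from biallelic SNP genotypes of sampled workers. It was built around the
study design of acacia-ant systems (several species, ~13–18 trees per
species, ~6 workers sampled per tree, panels of ~300–750 SNPs with
56–84% matrix completeness), but every component is generic. This note
records the models, the defaults and why they were chosen, and the limits
of what the validation suite demonstrates.

## Genotype model and filtering

Genotypes are unphased biallelic calls (hom-ref / het / hom-alt / missing).
Filtering follows the standard RADseq post-calling cascade, in this fixed
order:

1. **Individual cull.** Loci are screened at a preliminary presence cutoff
   (`r_prelim`, default 0.5, per species); individuals whose call rate over
   the screened loci is below `min_coverage` (default 0.2) are removed.
2. **Locus filters.** A locus is kept only if, within every species, its
   call rate is at least the species' presence cutoff `r` (defaults are
   configurable per species; typical values 0.5–0.75 chosen to land near a
   target panel size), its observed heterozygosity is ≤ `max_het`
   (default 0.5; an excess of heterozygotes in haplodiploid workers flags
   collapsed paralogs), and its minor allele frequency is ≥ `min_maf`
   (default 0.02).

Whether the locus filters run before or after the individual cull is not
dictated by any external constraint; the cull-first order above is a fixed
design choice, asserted by the test suite. MAF and heterozygosity are
computed from retained individuals, pooled within species, because locus
catalogs are built per species. Strict `>` removes on the heterozygosity
rule; NaN statistics (all-missing loci within one species) do not remove a
locus by themselves — presence rules handle those.

## Pairwise relatedness

Two moment estimators of relatedness r are implemented, Lynch–Ritland
(primary) and Queller–Goodnight (comparator). Both are computed per
"reference direction": with reference alleles a, b, proband alleles c, d,
allele frequencies p_x, and identity indicators S_xy,

* Lynch–Ritland: per-locus numerator
  `p_a(S_bc + S_bd) + p_b(S_ac + S_ad) − 4 p_a p_b`, denominator
  `(1 + S_ab)(p_a + p_b) − 4 p_a p_b`;
* Queller–Goodnight: numerator
  `0.5(S_ac + S_ad + S_bc + S_bd) − p_a − p_b`, denominator
  `1 + S_ab − p_a − p_b`.

The multilocus estimate is the ratio of locus sums (each locus is thereby
weighted by its information content; loci missing in either individual are
skipped), and the final estimate averages the two directions so it is
exactly symmetric in the pair. Pairs with no usable locus, or with a zero
denominator sum in both directions, yield an undefined (NaN) estimate that
aggregation excludes — never silently zero. Reference allele frequencies
default to the pooled sample frequencies of all retained same-species
individuals including the focal pair; in small, family-structured samples
this biases between-colony estimates slightly negative (visible in the
synthetic runs as between-tree means around −0.05 to −0.2), which is a
property of the estimator-plus-frequency choice, not an error.

Within-tree and between-tree summaries average tree-first: raw pairwise
values are averaged within each tree (or unordered tree pair), and species
means ± SE are taken over those unit means, so unbalanced sampling does not
weight trees unequally. Queens recovered as mothers of the sampled workers
are excluded from these averages (flagged `excluded`); a queen recovered as
a sister of the workers is retained like any nestmate.

## Estimator evaluation on simulated dyads

`simeval` simulates dyads of four relationship classes — parent–offspring,
full-sib, half-sib, unrelated; expected r = 0.5, 0.5, 0.25, 0 for
diploid-by-diploid pairs — from explicit pedigrees at a given frequency
panel, scores each estimator by the Pearson correlation between true and
estimated r pooled over all four classes, and selects the argmax (ties
break to name order with a warning). Dyads are diplodiploid by default,
matching how such benchmark simulations are conventionally run even for
haplodiploid study species; a haplodiploid mode (full-sister r = 0.75) is
available for sensitivity analysis. Simulation frequencies double as the
estimation reference frequencies. At 300+ loci with MAF uniform on
[0.1, 0.5], both estimators reach pooled correlations near 0.96.

## Sibship reconstruction

The core inference partitions a tree's workers into maternal families, each
subdivided into paternal families — a nested partition. Under haplodiploidy
the father is haploid, so all his daughters carry his identical allele at
every locus; this constraint is what makes paternity recoverable from
workers alone. Per maternal family and locus,

```
L = Σ_{G_m} P(G_m) Π_f [ Σ_{a_f} P(a_f) Π_{w∈f} P(obs_w | G_m, a_f) ]
```

with Hardy–Weinberg priors for the mother genotype G_m and the father
allele a_f. Loci are independent, and parental genotypes are integrated out
locus by locus (parents treated as independent across loci given the
partition). This per-locus marginalization is exact for the stated model
and makes exhaustive enumeration cheap; its cost is that it ignores linkage
of a parent's genotype across loci, a standard trade-off in this class of
likelihood.

**Error model.** Observations pass through a two-class channel: a true
heterozygote drops to either homozygote with probability ε_d/2 each
(allelic dropout, default ε_d = 0.0001), then each allele is independently
miscalled with probability ε_o (default 0.0025). Missing calls contribute
likelihood 1. The synthetic-data generator applies exactly this channel, so
the likelihood is correctly specified on simulated data. Impossible data
under a zero-error model yield −∞ log-likelihood and a warning.

**Candidate queens.** A sampled queen enters each maternal family as a
mixture: with prior π her genotype is the mother's (point mass; her missing
calls are marginalized under HWE), with 1 − π the mother is an unknown HWE
draw. The conventional prior is π = 0.5 / (number of trees). She is
reported as assigned where her posterior mixture weight exceeds one half.
Because the mixture is applied independently per family, nothing prevents
her being assigned to two families; at the small π values used this has
never arisen in testing and is accepted as a simplification.

**Search.** Exhaustive enumeration of all nested partitions is the oracle
(1, 3, 12, 60, 358, 2471 configurations for 1–6 workers; refused above a
cap of 8). The production search is simulated annealing over
split/merge/move proposals on the nested partition (geometric cooling from
T₀ = 2.0 to 0.02 over 250 + 120 n iterations), followed by a greedy
single-worker polish that repeatedly applies the best reassignment until no
move improves. The total log-likelihood decomposes over maternal families,
so both searches cache per-family terms and proposals cost only the
families they touch. Ties in likelihood resolve toward fewer mothers, then
fewer fathers (parsimony). Against the oracle the annealer attained the
global optimum in 250/250 seeded runs on mixed noisy fixtures of up to six
workers, and by construction can never exceed it.

**Maternal genotype recovery.** Each mother's maximum-posterior diploid
genotype is emitted per locus. Each allele slot carries its own posterior
support — carriage probability for the first copy of an allele, the
homozygote posterior for a second copy of the same allele — and a slot
below the masking threshold (default 0.90) is recorded as missing. Because
the genotype encoding is biallelic-unphased, a genotype with one masked
allele becomes a missing call; half-calls carry no information downstream.

**Queen kinship.** Inferred mothers from all trees of a species are pooled
and reconstructed again in diplodiploid mode (queens are diploid daughters
of diploid parents). Pairs in the same maternal and paternal family are
full siblings, same maternal family only are half siblings, and "related"
pools both. Counts are tabulated within-tree versus between-tree and
compared by a two-sided Fisher's exact test. Note a structural limit: with
fathers nested under mothers, paternal half-siblings with different mothers
cannot be expressed, so the classification is slightly conservative.

## Colony metrics

Polygyny Index = number of maternal families among sampled workers;
Polyandry Index = number of paternal families; queen (male) dominance =
largest maternal (paternal) family size over workers sampled. Males per
queen counts paternal sub-families only for mothers with ≥ `min_offspring`
(default 4) sampled workers, since a mother seen through one or two
offspring cannot reveal polyandry. All indices are relative to the sample:
unsampled families are invisible, so they bound the colony's true diversity
from below, and tests compare them against the *sampled* pedigree truth
(distinct mothers/fathers among sampled workers), not the designed queen
and mate numbers.

## Statistics

Species comparisons use ANOVA + Tukey HSD or Kruskal–Wallis + Nemenyi; the
family is a caller decision recorded in the report, not an automated
normality gate. The Nemenyi variant is all-pairs comparison of pooled mean
ranks with a chi-square (k − 1 df) reference and tie correction. Between-
tree relatedness is tested against zero with a one-tailed (greater) t test
using tree-pair means as the sampling unit (the alternative — trees as
units — is available from the aggregation layer). Tree-size screens use
Pearson (optionally square-root transforming counts such as males per
queen) or Spearman correlation, plus an ANCOVA `metric ~ species + size`
with type-II sums of squares and no interaction term. Fisher's exact test
is two-sided by the sum-of-small-probabilities convention and is checked in
the tests against a brute-force hypergeometric enumeration.

## Synthetic data: what it emulates and what it does not

The generator produces, per tree, Q diploid queens (optionally a natal
sister cohort: each queen joins with probability `p_sister_queens`, cohort
members being daughters of one auxiliary mother–father pair), M haploid
mates per queen, and n_w workers allocated to queens by a symmetric
Dirichlet skew (concentration 0.35 by default, giving a dominant-queen
share near 0.55–0.7 at Q = 3, the range seen in polygynous field colonies;
an explicit dominant share may be set instead) and to mates uniformly.
Inheritance is recorded allele-by-allele, so realized identity-by-descent
between any two workers is computable exactly — the oracle used to check
the estimators (full sisters share 0.75 of their genome under
haplodiploidy). Observation noise is the dropout/miscall channel above plus
i.i.d. per-genotype missingness (default 0.3, matching ~56–84% completeness
in expectation only — real missingness is structured by locus and by
library quality, which is deliberately not modelled). No read-level
processes (coverage, alleles dropping out as a function of depth, paralog
collapse) are simulated, so passing tests validate the estimators and the
sibship likelihood under the stated error model, not robustness to
upstream assembly artifacts.

Default problem sizes in the test and validation suites (100 dyads per
relationship class at 309–500 loci; 50 simulated trees of ≤ 6 workers at
300 loci; pipeline runs of 5–18 trees per species at 150–764 loci) mirror
the field-study scale the package targets while keeping each suite run in
minutes on one core.

## Numerical choices and degenerate inputs

* Fixed loci (p = 0 or 1) make both estimators' denominators 0; sample
  frequencies are clamped to (1e−9, 1 − 1e−9) and such loci are expected to
  be removed by the MAF filter. Monomorphic loci passed to the sibship
  likelihood simply contribute ≈ 0 information and are retained.
* A direction whose denominator sum is exactly 0 (e.g. an all-heterozygous
  reference under Queller–Goodnight) is dropped; if both directions are
  degenerate the estimate is undefined.
* Log-likelihood arithmetic is done in log space throughout
  (`scipy.special.logsumexp`); −∞ propagates correctly for impossible
  configurations.
* ANOVA F statistics that cancel to tiny negative values are clamped to
  exactly 0 with p = 1.
* All randomness flows from one `numpy.random.Generator` per entry point;
  identical seed and configuration reproduce results byte-for-byte, and
  the pipeline manifest records content hashes to prove it.

## Known limitations

* Inbreeding, diploid males, and multi-generation pedigrees are out of
  scope of the sibship likelihood.
* Per-locus parental integration ignores cross-locus linkage of parental
  genotypes (see above); with hundreds of informative loci the partition
  itself is still recovered essentially always in testing.
* The candidate-queen mixture is per-family independent.
* Between-tree relatedness inherits the negative bias of sample allele
  frequencies estimated from family-structured data; comparisons between
  species are unaffected because all species share the convention.
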