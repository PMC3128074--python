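# Methods

## Design and substrate

The pipeline analyses a gene × stage × replicate matrix of
log₂(male/female) expression ratios from a two-colour competitive
hybridization design: three biological replicates at each of five
developmental stages (L1, L2-3, L4 larvae, pupae, adults).  Missing
cells are first-class throughout — they are never imputed or replaced
by zero, because 0 is a meaningful log-ratio (equal expression).

## Normalization

`lowess_normalize` removes intensity-dependent dye bias on the MA
plane: M = log₂(male/female) is regressed on A = mean log intensity by
locally weighted linear regression (statsmodels lowess, span 0.3, 2
robustness iterations — common two-colour practice, both configurable)
and the fit is subtracted.  Spots with a nonpositive intensity in
either channel are set missing rather than clipped.

## Gene screening

Three rules, in cascade:

1. **Replicate rule** — a gene must be observed in ≥ 66% (inclusive)
   of all stage × replicate slots.  The fraction is computed jointly
   over all slots by default (a per-stage mode is available).
2. **ANOVA rule** — among those genes, a one-way ANOVA of the null that
   all stage means are zero, at α = 0.05.  With only 3 replicates a
   per-gene variance is unstable, so the error term is a *cross-gene*
   pooled within-stage replicate variance: squared deviations from each
   gene's per-stage replicate mean are pooled over every gene and
   stage, giving F = (Σₛ nₛ ȳₛ²/S) / s²_pool on (S, df_pool) degrees of
   freedom.  This is a defined, testable stand-in for proprietary
   "cross-gene error model" implementations in microarray suites; its
   type-I error is verified by simulation (null rejection rate 0.05 ±
   0.01 at 5000 genes).
3. **Recovery rule** — genes failing 1 or 2 are recovered if at some
   stage |mean of replicates| > 0.6 log₂ (strict) and ≥ 66% of that
   stage's replicates share the mean's sign.

All printed thresholds are read strictly ("higher than 0.8", "superior
to 0.6") except the 66% replicate fractions, which are inclusive ("at
least").  No multiple-testing correction is applied to the ANOVA
p-values by design.  Only admitted genes flow downstream.

## Bias calls and summaries

Per admitted gene and stage, the mean of non-missing replicates is
classified male (> +0.8), female (< −0.8), unbiased (otherwise) or
undetermined (no data).  The two reporting tiers (|log₂| > 0.8 and
> 1.6) stratify counts by effect size.  Percentages are printed to one
decimal, rounding half away from zero (integer mode for the
cross-species summaries).  Note that 2^0.8 ≈ 1.741: the package
computes the fold change exactly rather than using the rounded
1.73-fold shorthand sometimes printed for this cutoff.  The ontogeny
Venn partition pools the three larval stages; a gene is larvae-biased
if biased at any larval stage.

## Clustering

Profiles eligible for clustering are sex-biased at ≥ 1 stage with
≥ 3 of 5 stage means observed.  The distance between profiles is the
mean of squared differences over jointly observed stages — the simplest
metric consistent with ratio profiles already centred at 0 (no
re-centring or scaling); on complete profiles it is squared Euclidean
distance / 5.  QT clustering (greedy diameter-bounded cluster growth,
largest-first extraction, minimum size 5) suggests a cluster count;
K-means (k-means++-style seeding, 50 restarts, empty clusters re-seeded
from the farthest point) produces the final partition.  The default
k = 11 reflects the cluster count this class of data typically
resolves into; both k and the QT diameter are configuration knobs since
no canonical values exist.  Groups: M if the adult centroid exceeds
+0.8, F below −0.8, otherwise E (early-biased); a cluster matching no
definition is labelled E with a warning.

## Enrichment

Per cluster and namespace, each term present in the cluster is tested
by the upper-tail hypergeometric distribution against the analysed
background (admitted genes, not the genome).  Genes without any
annotation are excluded from both cluster and background sizes
(annotated-universe convention; switchable).  Bonferroni correction is
over the terms tested within one cluster and namespace; default
α = 0.001.  GO ancestor propagation is deliberately out of scope.

## Codon usage

QC for codon analysis: strict ACGT alphabet, ATG start, length ≡ 0
(mod 3), no internal stop, longest transcript per gene (ties broken by
lexicographically smallest transcript id, for determinism).  ENC uses
the homozygosity estimator F̂ = (nΣp² − 1)/(n − 1) per amino-acid
family, class means over families with F̂ > 0, and weights 9/1/5/3 for
the 2-/3-/4-/6-fold classes of the standard nuclear code, with the
three 6-fold families (Leu, Ser, Arg) kept whole.  A missing 3-fold
class mean is imputed as the average of the 2- and 4-fold means (the
classical fallback); a missing 6-fold mean is imputed the same way; if
the 2- or 4-fold class is missing the gene's ENC is missing.  ENC is
capped at 61.  Genes under 50 codons are reported missing (estimator
instability; configurable).

Optimal codons are inferred from the data: genes are ranked by ENC, the
codon counts of the lowest-ENC decile (high bias) and highest-ENC
decile (low bias) are pooled, and a codon is a candidate when its
within-family relative usage is higher in the high-bias pool with a
significant two-proportion chi-square after Bonferroni correction over
the 59 codons of multi-synonym families.  The candidate with the
largest usage increase wins; without any candidate the high-bias pool's
most frequent codon is used and flagged weak.  Fop is the fraction of
optimal codons among codons of amino acids with ≥ 2 synonyms (Met, Trp
and stops excluded).  Class contrasts use the two-sample
Kolmogorov–Smirnov test with the asymptotic p-value.

## Phylogenomics

"Unique" means no identifiable orthologue in the named comparator
genome(s); any orthology type counts as identifiable.  Over/under-
representation of unique genes in a gene set is tested two-tailed
against the hypergeometric distribution using the mid-P convention
(each tail carries half the observed point's probability mass).  Plain
doubled tails are available (`mid_p=False`) but are conservative on a
discrete statistic and their null p-values are measurably non-uniform;
mid-P restores uniform null calibration, which the test suite verifies
by simulation.  Bonferroni is over all (set × comparison) tests emitted
in one invocation.  Conservation calls use one-to-one orthologue pairs
only, crossing the focal adult-stage call with the comparator class:
male×male and female×female are conserved, male×female (either
direction) reversed, biased×unbiased and unbiased×biased form the two
asymmetric categories; unbiased×unbiased pairs carry no category.

## Synthetic data

The generators emulate the statistical structure of the study design,
not its biology.  Defaults (fixed once, before any acceptance run):
per-stage sex-biased fractions {L1 1%, L2-3 1.5%, L4 2%, P 3%, A
28.5%} with male shares {85, 85, 85, 60, 36}% — few, mostly male-biased
genes early; many, mostly female-biased genes in adults; effect sizes
uniform on [0.9, 3.0] log₂ with sign by sex; replicate noise Normal
with σ = 0.3 log₂; 2% missing cells.  Bias is planted independently
per stage, so temporal autocorrelation of real sex-biased programmes is
*not* emulated — passing recovery tests demonstrates the screening and
calling machinery, not robustness to correlated developmental
trajectories.  CDS simulation draws amino acids uniformly and tilts
synonymous codon choice toward one designated codon per amino acid with
weight e^β (β = 0 uniform); sequences are QC-clean by construction.
Orthologue presence is Bernoulli per comparator with optional planted
enrichment; comparator bias classes are drawn with concordance
probabilities {conserved male 15%, conserved female 38%, reversal 3%,
biased partner of an unbiased focal gene 20%}, echoing the magnitude of
cross-species conservation such comparisons report.  Real-data features
not modelled: dye/spatial artefacts, probe-level intensity structure,
heavy-tailed replicate noise (a t-distributed option exists),
correlated annotation structure.

## Numerical and reproducibility choices

All randomness flows from a single integer seed through
`numpy.random.SeedSequence` spawning (derived seeds kept below 2³¹).
K-means is deterministic given the seed; report tables are written with
fixed column order, fixed float formatting and NA as "NA", so identical
(inputs, config, seed) produce byte-identical bundles — verified by
test.  Degenerate inputs: percentage of n = 0 is reported missing; an
all-missing stage yields an undetermined call; constant vectors make
rank correlations missing rather than raising.

## Problem sizes

The test suite and acceptance script run the full pipeline at 5000
genes (the default bundle), the screening recovery suite at 2000 genes,
null calibrations at 5000 genes / 200 replicates, and the
optimal-codon recovery at 100 runs × 200 genes — sizes at which the
measured rates are stable to well within the asserted bounds.

## Known limitations

- The pooled cross-gene error variance assumes homoscedastic replicate
  noise across genes; an intensity-binned pool is the natural extension
  and is not implemented.
- QT clustering is O(n³) and intended for cluster-count exploration at
  hundreds of profiles, not for clustering thousands (K-means does
  that).
- Optimal-codon inference by decile contrast presumes ENC variation is
  driven by selection-like bias, which the generator guarantees; on
  real data mutational processes (GC pressure) would confound it.
- Term enrichment ignores the GO graph; parent terms are only tested if
  annotated explicitly.
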