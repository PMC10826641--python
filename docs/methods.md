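# Methods

This note documents the models and estimators implemented in
`introscape`, the choices made where the design was genuinely open, and
what the synthetic-data checks do and do not demonstrate about real
data.

## Genotype matrix and soft filters

All statistics run on a site × sample table of diploid alternate-allele
counts (0/1/2/missing) built from a VCF, retaining both variant and
invariant sites so that the diversity denominators of an "all sites"
callset are correct.  Filters apply in the order quality → depth →
missingness and are idempotent:

1. **Site quality** (QUAL, default ≥ 20).  A failing *variant* site is
   converted to an invariant reference site rather than dropped: a
   low-confidence variant call still represents sequenced reference-like
   positions, and dropping it would bias the π/d<sub>xy</sub>
   denominators downward.  The quality rule acts at site level because
   its consequence (conversion to invariant) is a site-level action; an
   optional per-genotype GQ threshold is available separately.
2. **Depth**.  Site total depth outside [3, 60] masks all genotypes at
   the site (and the site is then usually removed by the missingness
   cap); per-genotype depth < 2 masks that genotype only.  Bounds are
   tuned to ~10–13× resequencing coverage.
3. **Missingness**.  Sites with > 50% missing genotypes are dropped.

Multi-allelic records are dropped, not decomposed: every downstream
statistic is a biallelic frequency formula.  Consensus sequences render
heterozygotes as IUPAC ambiguity codes so the LOF scanner can see both
alleles, and missing genotypes as N.

## Windows

Two window systems: fixed-bp tiles (default 10 kb and 50 kb,
nonoverlapping) for diversity and window trees, and SNP-count sliding
windows (10 000/2 500 down to 500/125 SNPs) for f<sub>dM</sub>.
Terminal partial windows are kept and flagged rather than discarded, so
coverage stays accountable; callers can exclude them by flag.  The bp
span of a SNP window is [first SNP, last SNP + 1), which is also the
span used when pairing SNP windows with genic fraction (the fraction of
window bp covered by merged CDS intervals).  Alignment-based window
filtering drops a window when any sample exceeds 75% N; the CDS profile
instead removes individuals above 50% N and keeps the alignment.

## Diversity

π and d<sub>xy</sub> count allele-pair differences and comparisons per
site — within a population, diffs = c(n−c) and comparisons = n(n−1)/2
for c alternate among n non-missing alleles; between populations,
diffs = c_A(n_B−c_B) + (n_A−c_A)c_B over n_A·n_B pairs — and aggregate
windows as Σdiffs / Σcomparisons (ratio of sums).  This estimator is
unbiased under missing data, unlike averaging per-site ratios, and the
missing-comparison count it tracks feeds the outlier pre-filter: windows
with more missing counts than actual comparisons are removed before the
genome-wide mean/SD (sample SD, n−1) used for the Z > 3
d<sub>xy</sub>-outlier call.  F<sub>ST</sub> is the two-population
Weir–Cockerham (1984) estimator with observed heterozygosity from
genotypes, aggregated as Σa / Σ(a+b+c); per-site ratios are never
averaged.  Sites where either population has no genotyped individual,
or the mean sample size is ≤ 1 individual, contribute nothing.

## Introgression statistics

Population allele frequencies p₁…p₄ for an oriented trio (P1, P2, P3)
plus outgroup give per-site ABBA = (1−p₁)p₂p₃(1−p₄) and
BABA = p₁(1−p₂)p₃(1−p₄); a site is skipped for a trio when any of its
four populations is entirely missing there.  D sums these over sites.
Significance is a delete-one block jackknife over 20 contiguous
equal-SNP blocks (configurable), SE² = (B−1)/B·Σ(D₋ⱼ−mean)², two-tailed
normal p; blocks follow matrix order and therefore scaffold order,
which matters because SNPs within one genealogy are fully correlated.
Trios are enumerated from the guide tree with (P1, P2) the cherry pair,
lexicographic tie-break under polytomies, and Bonferroni correction at
α = 0.05 across trios.

The f₄-ratio is S(P1,P2;P3,O)/S(P1,P3;P3,O) with
S = Σ p₃(1−p₄)(p₂−p₁) and the denominator substituting P3 for P2.  It
estimates the migrant fraction f of an instantaneous pulse; simulation
shows mild downward bias (≈ 0.075–0.09 recovered at f = 0.1) from
post-admixture drift, a known property of the estimator rather than an
implementation artifact.

**f<sub>dM</sub>.**  The window numerator is Σ(ABBA−BABA).  The
per-site denominator uses a donor-frequency proxy: when p₂ ≥ p₁,
p_D = max(p₂, p₃) replaces both p₂ and p₃; otherwise
p_D = max(p₁, p₃) replaces both p₁ and p₃ and the term is negated.
Conditioning on the sign of (p₂ − p₁) rather than on the sign of the
per-site numerator is deliberate: the two agree at every site where
p₃(1−p₄) > 0, but only the frequency-difference form keeps f<sub>dM</sub>
*exactly* antisymmetric under a P1/P2 swap at degenerate sites (p₃ = 0
or p₄ = 1), and antisymmetry plus |f<sub>dM</sub>| ≤ 1 are the
properties that pin the construction down.  The candidate-region test
is a one-sample, upper-tailed t-test of region windows against the
scaffold-wide window mean (mean over windows, not sites); a
zero-variance region returns t = 0, p = 0.5 when it sits at the mean.

**f-branch.**  For a branch b with sister s and a candidate tip C
descending from neither, f_b(C) = median over B ∈ tips(s) of
[min over A ∈ tips(b) of f₄-ratio(B, A, C, O)], negatives truncated at
0.  Cells where C descends from b or s are invalid (NaN): such tests
are inconsistent with the guide-tree topology.  Significance jackknifes
the whole median-min statistic over the same blocks (Z > 3).  The
median/min nesting follows the published f-branch construction; the
orientation places the sister's tip as P1 and the focal branch's tip as
P2 so that C-sharing with b's descendants drives the ratio positive.

## Discordance

Robinson–Foulds distances are computed on canonical nontrivial
bipartitions restricted to the trees' shared tips and normalized by the
total internal-split count of both trees — 2(n−3) for binary trees —
so polytomous trees normalize by what they can maximally disagree on.

Topology weighting enumerates one-tip-per-taxon combinations exactly up
to 10 000 combinations, then switches to seeded uniform sampling with a
reported Monte-Carlo SE.  Exact enumeration is preferred over
always-sampling for testability: weights then sum to 1 to machine
precision and equal a brute-force pruning oracle.  Unrooted topologies
are identified by canonical split sets; rendering roots the display at
the lexicographically smallest taxon.  An internal-branch weight is the
summed weight of topologies in which the branch's taxa form a clade
against everything else including the outgroup.

When sample-level window trees are compared against a taxon-level guide
tree (the pipeline's RF and gCF stages on simulated data), each window
tree is first pruned to one representative sample per population — the
lexicographically smallest sample name — and relabelled to the
population.  Topology weighting needs no such choice, which is exactly
its advantage; RF after subsampling should be read alongside the
weights.

Gene concordance factors require a binary species tree: a gene tree is
decisive for a branch iff it holds ≥ 1 tip in each of the four subtrees
around the branch, and gCF is the percentage of decisive trees
containing the branch's induced split.  Site concordance draws
n_quartets = 100 seeded quartets (one tip per surrounding block); a
site is decisive when it shows exactly two states, each in two quartet
members, and sCF is the mean over quartets of the concordant
percentage, skipping quartets without decisive sites.

## Synthetic data

Gene trees are drawn under the multispecies coalescent on an ultrametric
species tree with branch lengths in coalescent units (2N generations):
within a branch, each lineage pair coalesces at rate 1, branches merge
at species-tree nodes, and the process continues above the root until
one lineage remains.  Migration is an instantaneous pulse: at the event
time every lineage in the recipient branch independently jumps to the
donor branch with probability f.  This is the simplest model whose
admixture fraction the f₄-ratio targets; continuous gene flow is out of
scope.  Mutations are infinite-sites: each SNP falls on one branch with
probability proportional to branch length, the derived allele marks
exactly the subtended tips, and two haploid tips per sample pair into a
diploid genotype (no selfing).  Each gene tree owns a fixed-width
scaffold block (default 5–10 kb), emulating recombination-driven
landscape variation at block resolution; there is no recombination
*within* a block, no selection, no demographic size change and no
sequencing error.  Consequently the generator reproduces the
ILS/introgression structure the statistics assume but none of the
selective or error processes real data add — passing calibrations show
the estimators are correct under their own model, not that real-data
filtering artifacts are handled.

CDS fixtures inject controlled mutations into a random clean CDS (ATG
start, no internal stops): frameshift indels (length ≢ 0 mod 3), large
deletions (≥ 100 bp by default; the biological motivation is ~500-bp
exon-removing deletions), premature-stop substitutions (nearest stop
codon by Hamming distance) and nonsynonymous domain substitutions,
heterozygous variants encoded as IUPAC codes.

## LOF scanner

Indels are maximal gap runs against the reference row; a deletion ≥ the
size threshold is a large deletion (annotated with overlapped exons)
and any indel with length ≢ 0 mod 3 is a frameshift (a ≥ 100-bp
deletion can be both).  Premature stops translate the gap-stripped copy
in the reference frame and report the first stop strictly upstream of
the terminal codon; IUPAC sites are resolved into two pseudo-haplotypes
(first/second allele at every ambiguous site), and a stop on one
haplotype only is heterozygous.  No terminal-tolerance rule is applied:
any upstream in-frame stop counts.  Domain substitutions are
nonsynonymous differences whose amino-acid position falls in a named
domain interval; domains downstream of a frameshift are flagged and not
scanned because their frame is ambiguous.  Verdicts: any large
deletion, frameshift or premature stop → `LOF`; only domain
substitutions → `putative_reduced_function`; otherwise `intact`.
In-frame indels and substitutions outside domains are reported
informationally.  Samples sharing an identical event (kind, position,
length) are clustered as shared mutations.  Alignment construction is
out of scope: the scanner consumes alignments.  Heterozygous *indels*
cannot be represented in a single alignment row and are reported as
homozygous — a known limitation.

## Problem sizes for the simulation checks

The simulation experiments use 4 taxa × 4 diploid samples on the
species tree (((P1,P2),P3),O) with unit internal branches, λ = 12
expected SNPs per 5-kb gene-tree block: null calibration runs 200
datasets of 500 genealogies (~6 000 SNPs each), pulse recovery 50
datasets of 800 genealogies (~9 600 SNPs).  The genealogy counts were
set by a power consideration: the block jackknife's effective sample
size is the number of independent genealogies, not SNPs, and these
counts give the Z > 3 detection power at f = 0.1 that a genome-scale
study design (tens of thousands of genealogies) would have, at desk
scale.  The MSC closed-form check uses 10 000 gene trees at internal
branch t = 1.0, where the concordant-topology fraction, gCF/100 and
mean internal-branch topology weight all equal 1 − (2/3)e⁻¹ ≈ 0.755;
the outgroup is attached by a long (8-unit) branch so the three-taxon
closed form applies to the quartet to far below the 0.02 tolerance.

## Numerical choices and degenerate inputs

* Jackknife SE = 0 → flagged degenerate rather than Z = ∞.
* f₄-ratio and f<sub>dM</sub> return NaN on zero denominators, with a
  warning; NaN windows are excluded (and counted) by the landscape
  regression.
* Outlier detection with SD = 0 returns the empty set; < 2 retained
  windows is an error.
* Interval merging is idempotent and order-independent; abutting
  intervals merge.
* All generators and samplers take explicit integer seeds; identical
  config + seed reproduces byte-identical pipeline outputs
  (checksummed in the run manifest).

## Known limitations

No recombination within gene-tree blocks; pulse (not continuous)
migration; no selection or demographic change in the generator; gCF/sCF
require binary species trees; heterozygous indels in the LOF scanner;
plots use rolling-mean smoothing for display only — no statistic is
computed from smoothed values.
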