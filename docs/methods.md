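# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `syndense`, in the spirit of the methods documentation of
packages like msprime or statsmodels.

## Block detection

Genes are ordered per chromosome by (start, end, gene id); ordinals
0..n−1 index this order. An *intervening gene* between two block members
is any gene with an ordinal strictly between theirs, regardless of its
orthogroup status (or lack of one). Detection parameters default to the
field-standard window: at least `min_genes = 3` orthologous members with
at most `max_interveners = 5` genes between consecutive members on both
genomes of a pair. Collinearity and strand are deliberately ignored:
across phylum-scale divergences local order is scrambled while
neighborhood composition persists, so requiring order would discard most
true signal. Strand is parsed and carried but never used.

The pairwise algorithm is a fixed-point refinement:

1. Candidate segments: per chromosome, the genes whose orthogroup occurs
   in both genomes, split wherever more than `max_interveners` genes
   separate neighbors.
2. For each segment pair, restrict both sides to their common
   orthogroups, re-split at gaps, and recurse over all resulting subpair
   combinations until nothing changes. Member sets shrink monotonically,
   so this terminates; at a fixed point both sides have identical
   orthogroup sets.
3. Stable pairs with ≥ `min_genes` members on both sides are emitted;
   emitted pairs sharing a gene on either side are merged (union–find).

All copies of a shared orthogroup inside a segment are members, so tandem
arrays stay intact (paralogous blocks are a downstream category, not a
detection-time exclusion). Chromosomes and genes are processed in
lexicographic/ordinal order, so output and block ids are stable across
runs. On micro-genomes the output provably matches an exhaustive search
over all orthogroup subsets satisfying the window rule in both species
(the test suite checks this equivalence on 50 random instances).

Two monotonicity caveats discovered during development: the *number* of
blocks is not monotone in either parameter, because removing a small
"bridge" block can split a merged block into two; the total number of
member genes is monotone (non-increasing in `min_genes`, non-decreasing
in `max_interveners`) and that is the property the tests assert. The
share-a-gene merge can in principle place one side's members on two
chromosomes; instances are re-split per chromosome at fusion, so
downstream types are always chromosome-contiguous.

## Fusion and multi-species blocks

Pairwise blocks are nodes of a graph with an edge when they share ≥ 3
orthogroups, or — both blocks having **more than three** orthogroups — at
least 50% of the smaller block's orthogroup set (the 50% rule is read
against the smaller set; orthogroup identities, not gene copies, are
counted). Connected components become multi-species blocks. Per species,
member genes from all contributing pairwise blocks are merged and
re-split by the same ≤ 5-intervener rule into instances; fragments with
fewer than three members are dropped. Block ids are assigned by
decreasing species count, then lexicographically smallest orthogroup.

## Emergence nodes

The species tree is rooted, may be multifurcating, and must have named
internal nodes; recency values are user-supplied relative age ranks
(higher = younger), no dating is performed. Novelty at a node requires
≥ 2 present ingroup species spread over ≥ 2 children clades with an empty
outgroup; the stricter reading (≥ 2 species in each of ≥ 2 children) is
available via `strict_novelty=True`. The default matches the two-species
floor used for inherited blocks. The root is handled with an empty
outgroup, so root novelty reduces to the two-children condition. When
several nodes satisfy novelty (possible under gene loss), the node
closest to the root wins — the single-gain parsimony choice; ties at
equal depth break lexicographically for determinism. A block novel at X
is necessarily absent at every ancestor of X (its species all lie in one
child of the ancestor), which the suite checks as an invariant.

Retention of a node's novel blocks in a clade counts blocks with at least
one carrier species in the clade; nodes without novel blocks yield NaN
rather than 0/0. The recency correlation is the plain Pearson
product-moment r with a two-sided t-test on n − 2 degrees of freedom.

## Gene density

Block boundaries are the outermost coding bases of the member genes
(coding spans are used throughout because UTR annotation is inconsistent
across genome releases). `genes_in_span` counts every gene whose start
*and* end lie inside the span — members and interveners alike, including
genes with no orthogroup label; partially overlapping genes are excluded.
Intergenic distances are taken between consecutive members as
`max(0, next.start − prev.end − 1)` (overlapping neighbors clamp to 0;
real annotations do overlap and the distance is not meaningfully
negative). The whole-genome density denominator uses the assembly size
supplied in a sidecar file, never the maximum gene end: unannotated
sequence is part of the genome.

Random blocks reproduce the observed instance's structural parameters
exactly: the member count and the per-gap intervener counts. A chromosome
is chosen with probability proportional to its gene count (every gene
equally likely to start a window), a start ordinal uniformly among
placements that fit, and density statistics are computed on the slot
genes exactly as for observed members. Because the ordinal window of an
instance can never exceed its own chromosome, the "block larger than any
chromosome" error is a defensive guard against malformed input only.

One numerical property worth knowing: span-based density over small
windows is biased upward relative to the genome average (the span
excludes the flanking intergenic stretches), so random-block normalized
densities center near ~1.1 rather than 1.0 on exponential-gap genomes.
Observed and random blocks share the bias, so comparisons and CNGD are
unaffected in direction; only on genomes of perfectly abutting genes is
the window density exactly 1, which the analytic identity checks exploit.

Observed-vs-random comparisons pool all observed instance values of a
grouping cell against all their random samples in a two-sided Wilcoxon
rank-sum test (α = 0.05), matching distribution-level comparisons; a
paired per-block alternative would weight blocks equally but is not the
default. CNGD per block and taxon takes the median over the taxon's
observed instances of the block against the median over all their random
samples. The regime thresholds (below 1 low, above 2 high, boundaries
inclusive to average) are tentative, sampling-free calls; species-specific
quartile thresholds can be passed explicitly. Cross-taxon regime
conservation is the Spearman correlation of per-block CNGD between taxa,
reported only for pairs sharing at least 10 blocks.

A note on the CNGD scale: the relative-change formula
`(median_obs − median_rand)/median_rand` is asymmetric — doubling gives
+1 but halving gives −0.5, with −1 approached only as the observed
density goes to zero. A log2-ratio would be symmetric (±1 for 2× and ½×)
but is not the definition used here; the linear form is kept because it
is the form the downstream identities and the swap relation
`CNGD(rand, obs) = 1/(1 + CNGD(obs, rand)) − 1` are stated for, and any
monotone transform leaves the cross-taxon Spearman correlations
unchanged.

Paralogy is computed over syntenic members only (interveners excluded —
they are not part of the conserved unit): the fraction of members in the
largest same-orthogroup subset, paralogous iff strictly greater than
0.40.

## Rank-sum testing

The Wilcoxon rank-sum / Mann–Whitney test is implemented in-package
because the small-sample path must enumerate the exact permutation
distribution with the U = #(x>y) + ½#(x=y) tie convention: when both
samples have ≤ 8 observations, all C(n₁+n₂, n₁) relabelings are
enumerated via pooled average ranks and the two-sided p is
min(1, 2·min(P(U≤u), P(U≥u))). Larger samples use the tie-corrected
normal approximation with a 0.5 continuity correction. The suite
cross-checks the exact path against scipy's exact test on tie-free inputs
and against an independently coded enumeration on tied inputs.

## Coexpression

Expression panels are genes × samples TPM matrices; developmental series
and tissue panels are treated identically (columns are exchangeable). A
gene is "expressed" with TPM > 0 in ≥ 1 sample by default — the weakest
defensible criterion; both thresholds are configurable. Spearman
correlations use average ranks for ties (Pearson on ranked data). Pairs
involving a gene constant across all samples are undefined and dropped
with a warning rather than scored 0; a block needs at least one defined
pair. Random-block coexpression is computed on the slot genes of each
random sample — the analog of the syntenic members — under the same
eligibility rule. The output is strictly inside (−1, 1) by the nextafter
guard.

## The synthetic generator

The generator emulates the input corpus of a phylum-scale comparative
study so every pipeline stage has a no-download test surface. Defaults
define the reference study conditions: 4 clades × 3 species on a balanced
tree, 4 chromosomes × 500 genes per species (2,000 genes), mean gene
length 1,500 bp (lognormal, σ = 0.5) with exponential intergenic gaps of
mean 3,000 bp — a gene every ~4.5 kb, the packing of a compact
invertebrate genome — and 40 planted blocks of 5 members spread over
three nodes (root, one clade pair, one clade) with full retention.

Background order is independent across species, so cross-species
clustering outside planted blocks is chance-level — the same floor the
shuffled-genome null measures. Background sharing is 500 orthogroups
present in each species with probability 0.65 (≈ 210 shared labels per
species pair). This value is set to preserve the *chance-synteny floor*
of real data rather than the raw labeled fraction: the expected number
of chance triple-clusters per species pair scales as S³/N⁴ (S shared
orthogroups, N genes), so naively scaling a 20,000-gene genome down to
2,000 genes while keeping ~40% sharing would inflate the false-positive
floor about tenfold. With ≈ 210 shared per pair the expected chance
blocks per pair (~0.015) match the per-pair floor implied by
shuffled-genome analyses at real scale. Consequently the labeled
fraction per species (~16% background plus planted members) is lower
than in real annotations — the cost of keeping the null realistic at
desk scale.

Planted runs are inserted as contiguous member runs with a configured
per-gap intervener pattern (interveners are ordinary background genes),
member order permuted per species since collinearity is not required.
Gaps inside a run with density multiplier m are exponential with scale
F/m − L̄ (F the mean per-gene footprint, L̄ the mean gene length):
multiplier-1 runs are distributionally identical to background — which
is what makes the type-I calibration of the density comparison honest —
and multiplier-m runs have ≈ m-fold local density (within ~20%, edge
effects from unscaled gene lengths included). Paralogous plants repeat
one member orthogroup; retention is a per-leaf Bernoulli deletion of the
whole run (gene-by-gene decay is out of scope). Expression gives each
planted gene log-expression λ·latent(block, sample) + (1−λ)·noise with
independent noise for background genes, exponentiated to a TPM-like
scale.

What the generator does *not* emulate: sequence evolution, explicit
rearrangement events, duplication–loss–transfer processes, assembly
fragmentation, or annotation error. Passing the planted-truth recovery
suite therefore demonstrates correctness of the inference machinery
under its stated model, not robustness to noisy annotation.

## Problem sizes and determinism

The test suite runs the reference conditions (12 species × 2,000 genes,
40 planted blocks, observed plus two shuffled replicates) in a few
seconds; density and coexpression calibrations use single-genome
configurations of 2,000 and 500 genes with 100 and 25 random samples per
block, and 20 seeded replicates for the null-calibration checks. All
randomness flows from explicit seeds: the pipeline derives per-instance
sampling seeds deterministically from (master seed, block id, species,
instance index) and records them in its outputs, and reruns are
byte-identical.

## Known limitations

- Orthogroups are taken as given; errors in orthology inference propagate
  directly into detection.
- The ≤ 5-intervener, ≥ 3-member window is a sensitivity/false-positive
  trade-off, not a biological constant; on highly fragmented assemblies
  blocks are undercounted because a pairwise block cannot span two
  scaffolds of one species.
- Emergence assignment is presence/absence parsimony with a two-species
  floor, not probabilistic ancestral-state reconstruction; patchy
  retention plus small clades can misplace emergence by one node.
- Density comparisons inherit the small-window span bias described above;
  absolute normalized densities near 1 should not be over-interpreted.
- TAD/Hi-C structure, recombination-rate variation and the
  density-vs-assembly-size regression diagnostic are out of scope.
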