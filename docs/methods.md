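# Methods

This note documents the models and procedures implemented in `coalpoly`,
the defaults they ship with, and what the synthetic-data validation does
and does not demonstrate.

## Deep-coalescence scoring

The central statistic is Maddison's extra-lineage (deep-coalescence)
count. For a rooted species tree *S*, a rooted gene tree *G* and a map
from gene-tree leaves (alleles) to species-tree leaves, every non-root
edge of *S* defines a cluster *C*; the number of gene lineages exiting
*C* is the number of maximal clades of *G* whose leaf set maps entirely
into *C*, and the edge contributes that number minus one. Pendant edges
are included: with several alleles per taxon, failure to coalesce on a
terminal branch is real discordance and must be counted. The total over
edges (and, for a posterior sample, over trees) is the MDC score; it is
zero exactly when a concordant embedding exists.

Implementation: gene trees are encoded as arrays of leaf-set bitmasks
(at most 62 distinct alleles per locus), so scoring a whole tree sample
against a species tree is a handful of vectorised bit operations. All
rooted topologies on *n* ≤ 7 labels — at most 10,395 — are enumerated
once and share their clusters (a cluster's extra-lineage count is
computed once and summed into every topology containing it), which makes
the "best species tree under this labelling" step exact rather than
heuristic at study scale. Above 7 labels the package falls back to NNI
hill climbing with random restarts; exhaustive agreement is property-
tested at 5 labels.

## Sub-genome assignment search

A polyploid sample with ploidy *p* has *p*/2 labelled sub-genome bins,
each holding at most two alleles per locus. An assignment is a choice of
bin for every polyploid allele at every locus; its score is the MDC
total under the best species tree for the induced labelling. The search
is hill climbing with reinitialization: starting from a random valid
assignment, moves are accepted on strict improvement until a local
optimum, at which point the state is re-randomised; the best state over
all climbs and restarts is returned, deterministically for a given seed.
Defaults are 1,000 iterations (an iteration is one accepted move or one
reinitialization) and 10 restarts.

Two move types are used: (i) swapping one allele between two bins of one
sample at one locus (moving an allele into a bin with free capacity
counts as a swap with an empty slot); and (ii) permuting one locus's bin
labels wholesale. The second move exists because bin labels are only
meaningful jointly across loci: two loci whose bins are anti-aligned
differ by *two* swaps, and both single-swap intermediates score worse, so
a swap-only neighbourhood has label-switching local optima that random
restarts escape only slowly. With the permutation move, the climb reaches
the exhaustive optimum on every planted instance we test.

Per locus, the score contribution depends only on that locus's joint bin
state, of which there are few (6 for one tetraploid, 90 for one
hexaploid); contributions are therefore cached, and the whole topology
vector is updated incrementally when one locus changes. The validation
suite uses
100–200 iterations and 3 restarts, which saturates at these problem
sizes; search effort only trades time for optimality, never correctness
of the score.

Tied optima are first deduplicated up to a per-lineage global permutation
of bin labels (such pairs are the same partition). Genuinely distinct
tied partitions — the expected signature of autopolyploidy, where bins
are exchangeable — are broken by the summed log multispecies-coalescent
probability of the gene-tree topologies under each assignment's species
tree.

## Gene-tree probabilities for the tie-break

P(gene-tree topology | species tree with branch lengths in coalescent
units) is computed by enumerating coalescent histories: each gene-tree
internal node is placed on a species-tree branch at or above the MRCA of
its descendants' species and at or above its children's placements. A
history contributes ∏_b g_{u_b v_b}(T_b) · w_b / d_{u_b v_b}, with
g_{uv}(T) the standard (Tavaré) probability that u lineages coalesce to
v within T, d_{uv} the number of distinct u→v coalescence sequences, and
w_b the number of orderings of branch b's events compatible with the
gene-tree ancestry (hook-length formula on the induced forest). The
implementation reproduces the 3-taxon closed form 1 − (2/3)e^(−T) to
machine precision and is property-tested to sum to one over topologies.

MDC provides no branch lengths, so the tie-break estimates them from the
gene trees themselves: internal edges by inverting the expected triplet
concordance (T = −ln(1.5(1−p̂)), clamped to [0.05, 8] coalescent units),
pendant edges of multi-allele taxa from the observed allele-monophyly
rate (T = −ln(1−p̂_mono)). These are coarse point estimates; they only
rank two equally parsimonious assignments. Enumeration is refused above
a cheap upper bound of 10^5 candidate histories or 12 gene-tree leaves,
in which case the tie falls back to a deterministic lexicographic choice
with a warning.

## The synthetic-data generator

The simulator plants a known history and emits every downstream input
with truth labels. Its defaults describe a small montane plant clade:
crown age 4.39 Ma (σ = 0.91 Ma retained as metadata; the root is pinned
at the mean), five nuclear loci of 300 bp plus one plastid locus, a
nuclear substitution rate of 5 × 10⁻⁹ /site/year, a 3-year generation
time, and a per-branch effective population size of N = 5 × 10⁴ diploids,
making one coalescent unit (2N generations) 0.3 Ma — deep enough for
clear species boundaries but shallow enough to leave visible incomplete
lineage sorting. Effective sizes underlying the real system are unknown;
N is a free parameter.

Polyploids form instantaneously, with no gene flow or homoeologous
exchange afterwards. Allopolyploid sub-genomes are *disomic*: each is its
own population from the present back to the origin time, then merges into
its diploid parent, so alleles coalesce within but never across
sub-genomes below the origin. Autopolyploids are *polysomic*: all *p*
allele copies share one population until the origin, then merge into the
single parent. This is why an autopolyploid's truth bins are exchangeable
(assigned by allele index, any permutation is equally true) and why its
sub-genome leaves are sisters in the MUL-tree. The plastid locus carries
one lineage per sample, routed through the maternal sub-genome only, with
half the nuclear effective size (maternal haploid transmission).

Per locus the generator can emit many independent coalescent genealogies
sharing one allele label set. These emulate a Bayesian posterior tree
sample in the cheapest faithful way: they carry genuine gene-tree-level
uncertainty (ILS) around the planted history, but *not* the estimation
noise, among-tree correlation, or rooting error of a real MCMC sample.
Passing recovery tests on them shows the assignment machinery extracts
the signal that coalescent theory says is present; it does not bound the
additional error contributed by real gene-tree inference.

True allele sequences evolve by HKY (κ = 3 by default) on a simulated
genealogy. For *read-level* benchmarking a separate generator plants
alleles at a controlled pairwise divergence (default 8%, ≈ 24 SNPs over
300 bp — the high end of what deeply diverged homeologs in one individual
can show, chosen so that chimera detectability is not the limiting
factor; see below). Reads are drawn uniformly from allele copies; a
configurable fraction are PCR chimeras (prefix of one allele + suffix of
another, uniform breakpoint, truth recorded in the read id). Phred
strings are *calibrated*: per-base qualities are drawn from a high
(31–41) / low (3–15) band mixture whose implied error probability
averages `error_rate`, and each base is then miscalled with its own
implied probability — so quality-derived error estimates downstream are
consistent by construction, and `error_rate = 0` yields error-free reads.

## Allele calling

Reads failing the quality rule (more than 10% of positions below Phred
20; the boundary is kept) are discarded. Survivors are clustered by
average-linkage agglomeration on pairwise mismatch counts, cut at 1.5
times the Phred-implied within-allele error distance (twice the mean
per-read expected error count, floored at one mismatch); the contract
downstream stages rely on is simply a partition of the reads. Clusters
smaller than ceil(0.5 × total/ploidy) are not allele candidates; the 0.5
factor encodes "at least half the reads an even allele share would
predict" and is exposed as a parameter.

A read is flagged as chimeric when some breakpoint k and ordered allele
pair (a, b) make its mismatches to a[1..k]+b[k+1..L] strictly smaller
than its mismatches to every single candidate allele (computed in O(A·L)
per read via prefix/suffix mismatch sums). Note the intrinsic limit: a
chimera whose breakpoint falls outside the span of sites distinguishing
its two parents is *identical* to data generated from a single allele and
cannot be flagged by any method; expected detectability is roughly the
parents' differing-site span divided by the read length, which is why the
benchmark divergence matters. After removing flagged reads the survivors
are re-clustered and each retained cluster is collapsed column-wise:
bases at relative frequency ≥ 20% are kept as IUPAC wobble codes,
otherwise the majority base wins (ties → wobble over the tied bases).

Two design calculators round out the module: the coupon-collector
inclusion–exclusion probability Σ_i (−1)^i C(k,i)((k−i)/k)^n that n
picked clones cover all k equally frequent alleles (27 clones give
0.9566 ≥ 0.95 for k = 6; 26 give 0.9480), and ploidy classification from
flow-cytometric fluorescence ratios against non-overlapping reference
intervals (defaults bracket observed taxon means: 2x 2.9–4.3, 4x
5.3–6.7, 6x 7.0–8.3; out-of-range ratios go to the nearest interval with
a warning).

## Alignment post-processing

Simple indel coding: one binary character per distinct (start, end) gap;
a sequence whose longer gap strictly contains a coded indel is scored
missing for that character, since its state there is unobservable.
Region masking uses 1-based inclusive coordinates (e.g. a microsatellite
motif at positions 249–294). The paralog screen runs on gene trees with
support values: a clade is excluded when support ≥ 0.95, its stem is ≥ 3
times the median internal branch length (no universal constant defines
"long", so the factor is a parameter), its members span ≥ 2
a-priori taxa, and removal leaves every affected sample at least one
sequence at the locus (checked cumulatively, longest stems first). No
minimum clade size is imposed.

## Networks and scenario ranking

Branches with support strictly below 0.7 are contracted into polytomies
(0.70 exactly is kept); node heights are untouched. Folding merges each
polyploid's sub-genome leaves into one node with one incoming edge per
former leaf position; edges sharing a single parent (an autopolyploid
cherry) collapse into one edge flagged `auto`. Collapsing weak branches
and folding commute as long as no collapsed branch is adjacent to a
reticulation; both orders are available, and the ambiguous adjacent case
is left to the caller. A polyploid's age interval is the covering
interval (min lower, max upper) of its sub-genomes' divergence-time 95%
HPDs — deliberately broad, since the sub-genome splits bracket, rather
than date, the formation event.

Species-delimitation scenarios — partitions of the polyploid samples
into putative lineages, samples within a lineage sharing sub-genome
bins — are ranked by the best assignment's total MDC score, ascending.
This is a surrogate for the marginal-likelihood comparison used with
full Bayesian machinery, and is labelled as such in the output header;
it compares the same models by parsimony of lineage sorting instead of
integrated likelihood, so only the ranking, not any Bayes-factor-like
magnitude, is meaningful.

## Plastid haplotype networks

Aligned plastid sequences collapse to distinct haplotypes (gaps either
excluded column-wise or kept, a contiguous gap run counting one
mutational step; samples with deletions longer than a threshold are
flagged as ambiguous). The maximum connection length is the largest j
whose parsimony probability is ≥ 0.95 under a per-site Poisson
substitution model with Jukes–Cantor correction moment-matched to the
observed divergence: λ(j) = −(3/4)ln(1 − 4j/(3L)) and
P_j = [λe^(−λ)/((3/4)(1 − e^(−4λ/3)))]^j, the probability that every
observed difference reflects exactly one substitution. Published
statistical-parsimony programs differ subtly in this calculation; the
series above *is* this package's definition, stated so results are
reproducible, and gives e.g. a limit of 9 steps for 600 bp. Construction:
haplotype pairs are processed in increasing step distance; a pair is
connected (inserting d−1 hypothetical intermediates) unless the current
network already joins it within d steps, all pairs at one distance being
judged against the same snapshot so equal-length alternative connections
are all retained — a conservative simplification of the classical
cladogram-estimation refinements, which instead choose among alternatives
by frequency and topology criteria.

## Numerical and degenerate-input choices

* Topology enumeration is exact to 7 labels; (2n−3)!! grows too fast
  beyond that and NNI search takes over.
* Encoded trees cap at 62 leaf labels per locus (64-bit masks).
* Clusters with no alleles at a locus contribute zero lineages.
* Cluster-size ordering, tied consensus bases, tied scenario ranks and
  tied search optima all break deterministically (size, then id; IUPAC
  over ties; shared rank; lexicographic after canonicalisation).
* All randomness flows from explicit integer seeds; repeated runs are
  bit-identical.

## Validation scale and limitations

The test suite runs planted histories at 5–10 loci × 40–100 gene trees
with 20 (tetraploid) and 10 (hexaploid, autopolyploid, two-origin) seeds
— sizes at which the full suite completes in about a minute on one CPU
while leaving wide statistical margins. Known limitations: no
homoeologous exchange, gene flow, allele dosage uncertainty, or
post-formation sub-genome loss in the simulator; no indel realism in
reads (and no pyrosequencing homopolymer error model); assignment
assumes the called alleles are correct and single-copy (the paralog
screen is a filter, not a model); the tie-break branch-length estimates
are method-of-moments approximations; and the scenario surrogate ranks
but does not weigh evidence.
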