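# Methods

This note documents the model behind `protoclust`, its tunable parameters,
the numerical and design choices made where the procedure was genuinely
open, what the synthetic data generator does and does not emulate, and the
known limitations.

## Relatedness, distance, and aggregation

Two sequences are *related* when their aggregated pairwise hit satisfies
`identity ≥ I` and `coverage ≥ C` (closed bounds).  Coverage is required of
**both** sequences (the minimum of the two per-sequence coverages); this
makes relatedness symmetric, which undirected clustering needs.  A
shorter-sequence-only mode (`coverage_mode="shorter"`) is available for
users who want domain-containing matches to pass.

A pair may align in several local blocks (HSPs).  Aggregation takes HSPs in
decreasing score order and drops any block more than 50 % of whose query
*or* subject span is already covered (the fraction is configurable);
coverage is then the union of retained spans over each sequence length and
identity is pooled over retained blocks.  Single-block pairs reduce to that
block's own percentages.

The clustering distance is `d = 1 − identity/100` for related pairs and
+∞ otherwise.  Coverage is deliberately a pass/fail gate only: merge
decisions are threshold-driven and identity is the only graded quantity
used.  Where a *finite* surrogate is needed for members of a cluster formed
by transitivity — average linkage, clustroid scoring — unrelated pairs
contribute the cap 1.0 instead of ∞.

The built-in aligner is a BLOSUM62 local alignment with affine gaps
(open −11, extend −1) producing one best block per pair.  In place of an
E-value (meaningless without a database size) a raw-score floor (default
40) discards spurious hits; at the default ~120-residue protein length
random pairs score well below it.  "Similarity" is percent identity;
counting positive substitutions instead is a configuration switch.  A
12-column tabular hit file from an external aligner can be substituted at
any stage, aggregated by the same rules.

## Stage thresholds (the published parameterization)

| stage                      | identity | coverage |
|----------------------------|----------|----------|
| genome dereplication       | 95 %     | (whole-genome) |
| near-identical collapse    | 98 %     | 100 %    |
| in-clade clustering        | 80 %     | 85 %     |
| tight grouping             | 80 %     | 85 %     |
| seed clustering, extension | 50 %     | 70 %     |
| liberal seed-neighbor filter | 10 %   | 70 %     |

Greedy k-mer stages use `maxaccepts 8` / `maxrejects 64`.  The published
greedy runs used word length 16; on amino-acid sequences 16-mers share
almost nothing below ~95 % identity at this package's scale, so the default
word length is 5 with 16 available in the configuration.  The published
hash-table sizing (`slots 400000009`) is an implementation hint, not a
contract; native hash maps are used.  The verifier clamps a requested
identity below 10 % up to 10 %, so the liberal filter cannot accept
arbitrarily weak hits.  Greedy input order is decreasing length (ties by
id), the standard choice for greedy incremental clustering.

## Hierarchical engine

Graph-restricted agglomeration: starting from singletons, repeatedly merge
the closest pair of clusters that (a) shares at least one related edge and
(b) has linkage distance ≤ `1 − I/100`.  Linkage is size-weighted average
of pairwise capped distances by default; complete and single linkage are
selectable behind the same interface.  Ties are broken by the smallest
member id, making every run deterministic.  The merge loop uses a lazy
heap; pair statistics never change while both clusters are alive, so heap
entries are exact and stale entries are simply discarded.

**Seed-protecting modification.**  When a seed-containing cluster merges
with a seed-free one, the merged cluster's distances (and connectivity and
effective size) to everything else are those of the seed-containing part
alone.  Seed–seed and nonseed–nonseed merges use standard linkage.  With no
seeds present the modified algorithm is exactly the base algorithm, which
the test suite asserts on hundreds of random instances.

**Genome dereplication** reuses the same engine with complete linkage on
`(100 − ANI)/100`, so the guarantee "every within-group pair ≥ 95 %
identical" is structural.  Whole-genome identities are an input table; for
self-contained runs a proteome proxy is provided (coding-region-weighted
mean of each protein's best identity in the other genome, averaged over
both directions).  The proxy is a stand-in for nucleotide-level genome
comparison, not a re-implementation of it, and is labeled as such.

## Genomic-context refinement

Each coding region carries a window of 5 sequence-cluster ids at gene-order
offsets −2…+2 on its contig.  Windows of minus-strand focal genes are
reversed so conserved neighborhoods match regardless of contig orientation
(the source procedure is silent on orientation; this is a documented
choice).  Two regions are context-consistent when ≥ 3 of the 5 positions
carry equal, present ids; the rule is evaluated pairwise between region
windows (not against a cluster consensus) over all 5 slots — absent slots
(contig ends, unclustered neighbors) never match, so an end gene with three
present, matching slots still passes.  Sub-clusters are the connected
components of this relation over the cluster's regions; a protein follows
the plurality of its regions (ties: the component containing the smallest
region id).  The center slot always matches within a sequence cluster, so
consistency effectively requires ≥ 2 of the 4 flanking genes to agree.

**Clustroids and conservative clusters.**  The clustroid minimizes the
weighted average distance to the other members, weights being the number of
coding regions in non-clonal genomes encoding each member; ties go to the
larger own weight, then the smallest id.  Intra-cluster unrelated pairs are
capped at 1.0 so transitively-formed clusters remain scoreable.  A cluster
is *conservative* when its members span ≥ 90 % of the clade's
representative genomes.  The exact published criterion for "conservative"
is not stated; the 90 %-of-genomes fraction is this package's declared,
configurable choice (`conservative_fraction`).  Abundant clades are those
with ≥ 10 non-clonal genomes.

## Global cascade

Seed clusters are built from the conservative clustroids of abundant clades
at 50 %/70 %.  Extension candidates are compared **only to clustroids**,
never to each other; "compatible" means related to at least one clustroid
of the target cluster (an all-clustroids mode exists), and "nearest" is
measured by identity with ties broken by coverage then cluster id, so the
result is independent of candidate processing order.  Leftovers keep their
best sub-threshold hit as a neighbor link.  The full cascade is: direct
assignment of tight matches to clustroids → greedy tight-grouping of the
remainder → liberal filtering of group representatives against clustroids →
extension of survivors → propagation of representative assignments back to
group members.  The optional loss audit re-examines dropped representatives
by exhaustive alignment and reports the fraction of extension-assignable
representatives the filter missed.

## Partitioned execution

Merges only follow related edges, so connected components of the
relatedness graph can be clustered independently: per-partition output
provably equals whole-set output for every offered linkage, and the test
suite asserts this on random instances.  Components come from a
union-by-rank disjoint-set forest; path compression is added as a pure
optimization.  Concurrency is a *contract* — the per-partition cluster
function must be deterministic and share no mutable state — satisfied by
the serial loop and the thread-pool backend alike; outputs are
concatenated in deterministic partition order, so worker count never
changes the result.

## Synthetic pan-genomes

The generator emulates the structure the pipeline assumes, with planted
ground truth (protein → family, region → locus, genome → clonal group):

* **Clades and clonal groups.**  Default: 3 abundant clades of 12 genomes,
  each with two clonal pairs (copies mutated at 99.5 % per protein), giving
  10 non-clonal representatives — exactly at the abundance threshold — plus
  one 3-genome clade whose proteins exercise the extension path the way
  rare genomes do in real collections.
* **Families.**  20 core families per clade descend from shared global
  ancestors at 80 % clade identity, so cross-clade variants sit near 60 %
  identity — inside the 50 %/70 % seed band, outside the 80 %/85 % in-clade
  band.  Within-clade variants are drawn at 95–99 % identity to the clade
  founder (mutual ≥ 90 %).  An optional fast-diverging core fraction
  (default 0) lowers some families' clade identity to 68 % (cross-clade
  ≈ 43 %), used by the threshold-sweep study configuration so the
  50 %→30 % sweep exhibits the qualitative seed-count drop; it is off by
  default because fast families legitimately form one seed cluster per
  clade, which would break the one-cluster-per-family bookkeeping of the
  default conditions.
* **Paralog pairs.**  A pair is two families whose clade founders differ by
  exactly the partner divergence (94 %): the clade-level mutation patch is
  applied at identical positions to both partners, so within-clade
  cross-paralog identity is 84–92 % — always mergeable by sequence — while
  the two loci are planted with disjoint flanking families, sharing only
  the focal window position (1 of 5), so context refinement must separate
  them.  Globally the partner families often stay mutually related
  (≈ 55 %) and form one seed cluster per pair; each family still lands in
  exactly one extended seed cluster.
* **Accessory gradient.**  Accessory genes form a block after the core
  region; each genome carries a *prefix* of the block with
  binomially-distributed length (marginal presence ≈ 0.5).  The nested
  design yields a realistic core-to-rare gene frequency spectrum and — the
  reason it was chosen — keeps every carried accessory gene's upstream
  neighborhood deterministic, so presence/absence variation cannot
  spuriously fragment context clusters.  Core windows are likewise immune
  because the accessory block only borders the last core genes, which
  always retain three stable window positions.
* **Unique proteins** are fresh random sequences per genome (2 by
  default); **mutation** is substitution-only with an exact identity
  floor(`target·len`)/len, so planted identities are exact (an indel knob
  exists but voids the exactness guarantee and is excluded from exact
  assertions).

What the generator does **not** emulate: phylogeny-aware substitution
processes, indel/length variation within families, horizontal transfer,
operon rearrangement, fragmented or mis-annotated gene calls, and corpus
scale.  Passing tests therefore demonstrate the algorithms' contracts —
separation, conservation, determinism, safety — under clean, separable
conditions, not performance on real annotation noise; the thresholds
themselves are the published operating point for real collections.

## Problem sizes and numerics

Default runs cluster ~1 200 distinct proteins across 39 genomes; oracle
comparisons use 200 random instances of ≤ 15 items per algorithm and 50
instances of 30 for partition safety — sizes chosen so brute-force
references stay exact and the whole suite runs in about a minute.  Merge
cutoff comparisons use a 1e-12 tolerance; random continuous identities make
exact linkage ties vanishingly rare, and all remaining ties (equal
linkage, equal weight, equal score) resolve by lexicographic id.  The
`partition_id` of a component is its smallest member id, and cluster ids
embed the smallest member, so all outputs are stable across runs and
machines.

## Known limitations

* The built-in aligner reports one best local block per pair; genuinely
  multi-domain HSP structure only arises via external hit files.
* The proteome-based genome-identity proxy tracks, but does not equal,
  nucleotide ANI; with real genomes, supply a genome-similarity table.
* Average linkage uses the 1.0 cap for unrelated pairs; very sparse
  clusters are therefore conservative about further merging (by design).
* Extension compares candidates to clustroids only; a member-level
  comparison mode would be more sensitive but quadratic.
* Super-clustering of seed clusters and neighbor-graph construction
  between clusters are out of scope.
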