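# protoclust

Three-level protein clustering for collections of microbial genomes.

Large pan-genome collections are dominated by redundancy: the same protein
family recurs in every genome of a species-level clade, and clades are
sampled with wildly uneven density (a handful of clinical species contribute
thousands of near-clonal genomes).  Clustering all proteins against all
proteins at that scale is both wasteful and fragile — greedy all-vs-all
clustering drowns in the long tail of unique, fast-evolving and poorly
annotated sequences.  `protoclust` implements a multilevel alternative for
microbiologists and comparative genomicists building protein family
resources from genome collections:

1. **Genome dereplication.**  Within each clade, near-clonal genomes are
   grouped by complete-linkage clustering at a 95 % whole-genome identity
   cutoff; one representative per group is kept, preferring the clade
   reference, then membership in a curated pathway database, then any
   annotated genome.
2. **In-clade clustering.**  Tight protein clusters (identity ≥ 80 %,
   coverage ≥ 85 % of both sequences) are built from the complete proteins
   of a clade's representative genomes — but sequence similarity alone
   cannot tell recent paralogs apart.  Each coding region therefore carries
   a 5-gene context window (cluster ids at gene-order offsets −2…+2,
   orientation-normalized); two regions are context-consistent when ≥ 3 of
   the 5 positions agree, and the connected components of that relation
   split each sequence cluster into locus-specific sub-clusters.
   Every cluster gets a **clustroid**: the member p minimizing the weighted
   average distance

       argmin_p  Σ_{q≠p} w_q·d(p,q) / Σ_{q≠p} w_q,

   where w_q counts the coding regions in non-clonal genomes encoding q and
   d = 1 − identity/100 (capped at 1 for unrelated members).
3. **Seed clustering and extension.**  Clustroids of *conservative*
   clusters (present in ≥ 90 % of a clade's representative genomes, in
   clades with ≥ 10 non-clonal genomes) are agglomerated at the global
   thresholds (identity ≥ 50 %, coverage ≥ 70 %) into **seed clusters**.
   The rest of the data is attached to the seeds without ever being
   compared to itself: near-identical and tight groups are collapsed by
   greedy k-mer clustering (98 %/100 %, then 80 %/85 %), group
   representatives are filtered against the clustroids with a liberal
   k-mer search (identity ≥ 10 %, coverage ≥ 70 %), and survivors join the
   seed cluster of their highest-identity compatible clustroid.

A modified hierarchical algorithm is also provided: when a seed-containing
cluster absorbs a seed-free one, the absorbed part is excluded from all
subsequent distance computations, so drifting homolog chains cannot distort
a seed's profile.  Because merges only ever follow related edges, the
relatedness graph is split into connected components with a union-by-rank
disjoint-set forest and each component is clustered independently — results
are identical for any worker count.

A deterministic synthetic pan-genome generator (clades, clonal groups, core
/ accessory / unique families, planted paralog pairs with disjoint gene
neighborhoods) provides ground truth for every stage.

## Worked example

```bash
protoclust simulate --seed 1 --out data/
protoclust run-all --data-dir data/ --out-dir out/
```

The second command logs the stage cascade and writes
`out/report.json`; on the default simulation (3 abundant clades × 12
genomes with two clonal pairs each, one 3-genome clade, 20 core families,
2 paralog pairs, 8 accessory families, 2 unique proteins per genome) it
prints:

```
run-all complete: 24 seed clusters, conservation=True
```

and the report contains (abridged):

```json
{
  "n_abundant_clades": 3,
  "n_nonclonal_by_clade": {"cladeA": 10, "cladeB": 10, "cladeC": 10, "smallA": 3},
  "inclade": {"cladeA": {"n_coding_regions": 300, "n_clusters": 50,
                          "n_conservative": 26, "compression_ratio": 6.0}},
  "n_conservative_clustroids": 78,
  "n_seed_clusters": 24,
  "global": {"n_input_proteins": 1175, "n_direct_assigned": 856,
              "n_tight_group_representatives": 105, "n_filter_retained": 24,
              "n_extension_members": 933, "n_leftovers": 164,
              "conserved": true},
  "seed_region_compression": 42.125
}
```

Reading: each clade's 300 coding regions compress ~6× into 50 in-clade
clusters (20 core + 4 paralog + 8 accessory + 20 unique families — the two
planted paralog pairs are merged by sequence identity and split by genomic
context).  The 78 conservative clustroids form 24 seed clusters: one per
core family (cross-clade identity ≈ 60 % falls inside the 50 %/70 % band),
one per paralog pair (the partners stay mutually related globally), and two
for the near-universal accessory families.  Of the 1 175 input proteins,
856 match a clustroid tightly and are assigned directly; the remaining 241
collapse into 105 tight-group representatives, of which the liberal filter
keeps the 24 genuine seed neighbors (the small clade's core proteins).
Leftovers are the accessory and unique proteins with no seed family — the
poorly-clustering periphery.  Every protein is accounted for exactly once
(`conservation=True`).

The same pipeline is available as a library:

```python
from protoclust import SimConfig, generate, run_all
from protoclust.io import PipelineConfig

sim = generate(SimConfig(seed=1))
result = run_all(sim.dataset, PipelineConfig())
print(len(result.seeds), result.report["global"]["conserved"])   # 24 True
```

Stage-level commands (`protoclust collapse / filter / seed / extend /
partition / derep / inclade`) expose the individual operations on FASTA and
TSV files; see `docs/FORMATS.md` for the file formats and `docs/methods.md`
for the model, parameters and design decisions.

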