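# File formats

All tables are tab-separated with a header row.  Ids are opaque strings.
Booleans are written `true`/`false` (readers also accept `1`/`0`).

## Dataset inputs (a *data directory*)

| file | columns / format |
|------|------------------|
| `proteins.faa` | amino-acid FASTA; record id = `protein_id`; identical sequences must share one record |
| `genes.tsv` | `genome_id  contig_id  ordinal  strand  protein_id  is_complete` — `ordinal` is the 0-based gene-order index along the contig (not nucleotides), consecutive from 0; `strand` ∈ `+`/`-`; region ids are derived as `contig_id:ordinal` |
| `clades.tsv` | `genome_id  clade_id  is_annotated  is_rep_pref  in_pathway_db` — the three booleans are representative-preference ranks 3, 1 and 2 |
| `genome_similarity.tsv` (optional) | `genome_a  genome_b  identity_pct` — whole-genome identity; computed by the proteome proxy when absent |

## Pairwise hits

12-column tabular format, one row per HSP, no header:

    qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore

Coordinates are 1-based inclusive.  Rows sharing an ordered (query,
subject) pair are aggregated into one hit (overlap-pruned union coverage,
pooled identity).

## Outputs

| file | columns |
|------|---------|
| clusters TSV | `cluster_id  level  clade_id  protein_id  role  is_conservative` — `role` ∈ `clustroid`/`plain`; `clade_id` is `-` for global clusters |
| seed clusters TSV | `cluster_id  protein_id  role` — `role` ∈ `clustroid`/`extension` |
| assignment TSV | `member_id  representative_id  identity  coverage` (self rows 100/100) |
| leftovers TSV | `protein_id  neighbor_clustroid  neighbor_cluster  neighbor_identity  neighbor_coverage` (`-` when no sub-threshold neighbor exists) |
| partition map TSV | `protein_id  partition_id` (partition id = smallest member) |
| neighborhood map TSV | `cluster_id  genome_id  offset  neighbor_cluster_id` — the −2…+2 context window per member region |
| derep groups TSV | `genome_id  group_id  is_representative` |
| report | `report.json` (nested) plus `report.txt` (flat `key<TAB>value` twin) |

## Configuration

`PipelineConfig` round-trips through YAML (`config_used.yaml` is written by
`run-all`); keys are the dataclass field names, e.g. `inclade_identity: 80.0`,
`min_nonclonal: 10`, `linkage: average`, `seed: 0`.  Unknown keys are
rejected.  The simulator accepts a YAML of `SimConfig` fields the same way.
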