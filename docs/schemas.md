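# File schemas

All tables are UTF-8, tab-separated, with a header line; lines starting
with `#` are comments and ignored on read.  All coordinates are 0-based,
half-open (`[start, end)`, the BED convention).  GC values are fractions
in [0, 1].

## Hit table (`hits.tsv`)

Long format: one row per gene, grouped by `hit_id`.  `genome_id`,
`replicon_id`, `category` and `system_type` must be constant within a
`hit_id`.

| column | type | meaning |
|---|---|---|
| hit_id | str | system/BGC identifier, groups gene rows |
| genome_id | str | owning genome |
| replicon_id | str | replicon carrying the gene |
| category | `defence` \| `bgc` | hit class |
| system_type | str | e.g. `RM`, `Wadjet`, `T1PKS` |
| subtype | str, optional | finer classification, may be empty |
| gene_start | int | 0-based inclusive start |
| gene_end | int | exclusive end, > gene_start |
| strand | `+` \| `-` | carried but unused by statistics |
| gene_gc | float | GC fraction of the gene |
| gene_index | int, optional | ordinal of the gene among the replicon's CDS; required only for island detection |

## Genome metadata (`metadata.tsv`)

One row per replicon; genome-level fields repeat on each of the genome's
rows.

| column | type |
|---|---|
| genome_id, phylum, genus, species | str |
| replicon_id | str (cohort-unique) |
| replicon_type | `chromosome` \| `plasmid` |
| topology | `linear` \| `circular` |
| length | int bp, > 0 |
| gc | float in [0, 1] |

## Prophage intervals (`prophages.bed`)

Plain BED: `replicon_id <tab> start <tab> end`, extra columns ignored.
Overlapping or touching intervals are merged on read.

## Trees

Newick with branch lengths; leaf labels must be unique and match
`genome_id`s when used with a presence/absence matrix.

## Result tables

Written with 12 significant digits for floats so a read-back round-trips.
Stage outputs: `per_genome_counts.tsv`, `group_summary.tsv`,
`islands.tsv`, `differential_abundance.tsv`, `locations.tsv`,
`mge_contribution.tsv`, `gc_scores.tsv`, `positions.tsv`,
`spatial_profiles.tsv` / `profiles.tsv`, `phylo_signal.tsv` — column
names are fixed by the writer functions in each module.
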