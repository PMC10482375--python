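"""Readers and writers for the tabular, interval, and tree formats.

Formats
-------
* **Hit tables** — long-format TSV, one row per gene, grouped by ``hit_id``;
  columns are fixed (see ``HIT_COLUMNS`` and ``docs/schemas.md``).
* **Genome metadata** — TSV, one row per replicon.
* **Prophage intervals** — BED (0-based half-open, first three columns used);
  overlapping intervals are merged on read.
* **Trees** — Newick with branch lengths, via dendropy.
* **Result tables** — TSV with ``#``-prefixed comment header lines; floats
  are written with 12 significant digits so that read-back round-trips.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence, Union

import dendropy
import pandas as pd

from .model import (
    GeneLocus,
    GenomeMetadata,
    IntervalSet,
    RepliconMetadata,
    SchemaError,
    SystemHit,
    ValidationError,
)

PathLike = Union[str, Path]

HIT_COLUMNS = [
    "hit_id",
    "genome_id",
    "replicon_id",
    "category",
    "system_type",
    "subtype",
    "gene_start",
    "gene_end",
    "strand",
    "gene_gc",
    "gene_index",
]
_HIT_REQUIRED = [
    "hit_id",
    "genome_id",
    "replicon_id",
    "system_type",
    "gene_start",
    "gene_end",
]

METADATA_COLUMNS = [
    "genome_id",
    "phylum",
    "genus",
    "species",
    "replicon_id",
    "replicon_type",
    "topology",
    "length",
    "gc",
]


def _read_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_hit_table(
    path: PathLike,
    category: Optional[str] = None,
    replicons: Optional[dict[str, RepliconMetadata]] = None,
) -> list[SystemHit]:
    """Parse a long-format hit table into :class:`SystemHit` records.

    ``category`` overrides (or supplies, when the column is absent) the
    defence/bgc category.  When ``replicons`` is given, gene coordinates are
    additionally checked against replicon lengths.
    """
    df = _read_tsv(path)
    for col in _HIT_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"hit table {path}: missing required column {col!r}")
    if category is None and "category" not in df.columns:
        raise SchemaError(
            f"hit table {path}: no 'category' column and no category argument"
        )
    hits: list[SystemHit] = []
    if df.empty:
        return hits
    for hit_id, rows in df.groupby("hit_id", sort=False):
        for col in ("genome_id", "replicon_id", "system_type"):
            if rows[col].nunique() != 1:
                raise ValidationError(
                    f"hit {hit_id}: column {col!r} is not constant across its rows"
                )
        first = rows.iloc[0]
        genes = []
        for _, row in rows.iterrows():
            start, end = int(row["gene_start"]), int(row["gene_end"])
            gidx = row.get("gene_index")
            gene_index = None
            if gidx is not None and not (isinstance(gidx, float) and math.isnan(gidx)):
                if str(gidx) not in ("", "nan"):
                    gene_index = int(float(gidx))
            try:
                genes.append(
                    GeneLocus(
                        start=start,
                        end=end,
                        strand=str(row.get("strand", "+") or "+"),
                        gc=float(row.get("gene_gc", 0.5) or 0.5),
                        gene_index=gene_index,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"hit {hit_id}: {exc}") from exc
        subtype = first.get("subtype")
        if isinstance(subtype, float) and math.isnan(subtype):
            subtype = None
        hit = SystemHit(
            hit_id=str(hit_id),
            genome_id=str(first["genome_id"]),
            replicon_id=str(first["replicon_id"]),
            category=category or str(first["category"]),
            system_type=str(first["system_type"]),
            subtype=subtype,
            genes=genes,
        )
        if replicons is not None:
            rep = replicons.get(hit.replicon_id)
            if rep is None:
                raise ValidationError(
                    f"hit {hit.hit_id}: unknown replicon {hit.replicon_id}"
                )
            for gene in hit.genes:
                if gene.end > rep.length:
                    raise ValidationError(
                        f"hit {hit.hit_id}: gene [{gene.start},{gene.end}) outside "
                        f"replicon {rep.replicon_id} of length {rep.length}"
                    )
        hits.append(hit)
    return hits


def hits_to_frame(hits: Sequence[SystemHit]) -> pd.DataFrame:
    rows = []
    for hit in hits:
        for gene in hit.genes:
            rows.append(
                {
                    "hit_id": hit.hit_id,
                    "genome_id": hit.genome_id,
                    "replicon_id": hit.replicon_id,
                    "category": hit.category,
                    "system_type": hit.system_type,
                    "subtype": hit.subtype if hit.subtype is not None else "",
                    "gene_start": gene.start,
                    "gene_end": gene.end,
                    "strand": gene.strand,
                    "gene_gc": gene.gc,
                    "gene_index": gene.gene_index
                    if gene.gene_index is not None
                    else "",
                }
            )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def write_hit_table(hits: Sequence[SystemHit], path: PathLike) -> None:
    write_results(hits_to_frame(hits), path)


def read_metadata(path: PathLike) -> list[GenomeMetadata]:
    """Parse the one-row-per-replicon metadata TSV into genome records."""
    df = _read_tsv(path)
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"metadata {path}: missing required column {col!r}")
    genomes: list[GenomeMetadata] = []
    for genome_id, rows in df.groupby("genome_id", sort=False):
        first = rows.iloc[0]
        replicons = [
            RepliconMetadata(
                replicon_id=str(row["replicon_id"]),
                genome_id=str(genome_id),
                replicon_type=str(row["replicon_type"]),
                topology=str(row["topology"]),
                length=int(row["length"]),
                gc=float(row["gc"]),
            )
            for _, row in rows.iterrows()
        ]
        genomes.append(
            GenomeMetadata(
                genome_id=str(genome_id),
                phylum=str(first["phylum"]),
                genus=str(first["genus"]),
                species=str(first["species"]),
                replicons=replicons,
            )
        )
    return genomes


def metadata_to_frame(genomes: Sequence[GenomeMetadata]) -> pd.DataFrame:
    rows = []
    for genome in genomes:
        for rep in genome.replicons:
            rows.append(
                {
                    "genome_id": genome.genome_id,
                    "phylum": genome.phylum,
                    "genus": genome.genus,
                    "species": genome.species,
                    "replicon_id": rep.replicon_id,
                    "replicon_type": rep.replicon_type,
                    "topology": rep.topology,
                    "length": rep.length,
                    "gc": rep.gc,
                }
            )
    return pd.DataFrame(rows, columns=METADATA_COLUMNS)


def write_metadata(genomes: Sequence[GenomeMetadata], path: PathLike) -> None:
    write_results(metadata_to_frame(genomes), path)


def read_intervals(path: PathLike) -> dict[str, IntervalSet]:
    """Read a BED-style interval file into per-replicon merged interval sets."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(
                    f"{path}:{lineno}: BED line needs >= 3 tab-separated fields"
                )
            replicon_id, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: interval [{start},{end}) is empty or reversed"
                )
            out.setdefault(replicon_id, []).append((start, end))
    return {rid: IntervalSet(rid, ivs) for rid, ivs in out.items()}


def write_intervals(intervals: dict[str, IntervalSet], path: PathLike) -> None:
    with open(path, "w") as fh:
        for rid in sorted(intervals):
            for start, end in intervals[rid].intervals:
                fh.write(f"{rid}\t{start}\t{end}\n")


def read_tree(path: PathLike) -> dendropy.Tree:
    """Read and validate a Newick tree (unique leaf labels, lengths >= 0)."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parser error types
        if "uplicate" in str(type(exc).__name__) or "same taxa" in str(exc):
            raise ValidationError(f"duplicate leaf labels in {path}: {exc}") from exc
        raise SchemaError(f"cannot parse Newick tree {path}: {exc}") from exc
    return validate_tree(tree)


def parse_tree(newick: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        if "uplicate" in str(type(exc).__name__) or "same taxa" in str(exc):
            raise ValidationError(f"duplicate leaf labels: {exc}") from exc
        raise SchemaError(f"cannot parse Newick string: {exc}") from exc
    return validate_tree(tree)


def validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValidationError(f"duplicate leaf labels in tree: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValidationError(f"negative branch length {edge.length}")
    return tree


def write_tree(tree: dendropy.Tree, path: PathLike) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def write_results(
    table: pd.DataFrame, path: PathLike, header: Optional[str] = None
) -> None:
    """Write a result table as TSV; floats keep 12 significant digits."""
    if table is None:
        raise ValidationError("cannot write a null table")
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_results(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
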