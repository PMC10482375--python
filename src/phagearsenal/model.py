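"""Core domain types for defence-arsenal comparative genomics.

Conventions used throughout the package:

* All genomic coordinates are **0-based, half-open** ``[start, end)`` (the
  BED convention), so interval arithmetic needs no off-by-one bookkeeping.
* GC content is a fraction in ``[0, 1]``, never a percentage.
* Strand is carried for provenance but ignored by every statistic.

The atoms are :class:`SystemHit` (one detected defence system or
biosynthetic gene cluster, with its genes' coordinates) and the replicon /
genome metadata that provide denominators and strata for every analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence


class SchemaError(ValueError):
    """A table is missing a required column or has an inconsistent schema."""


class ValidationError(ValueError):
    """A record violates a domain invariant (coordinates, GC range, ...)."""


REPLICON_TYPES = frozenset({"chromosome", "plasmid"})
TOPOLOGIES = frozenset({"linear", "circular"})
CATEGORIES = frozenset({"defence", "bgc"})
STRANDS = frozenset({"+", "-"})


@dataclass(frozen=True)
class RepliconMetadata:
    """One replicon (chromosome or plasmid) of a genome."""

    replicon_id: str
    genome_id: str
    replicon_type: str
    topology: str
    length: int
    gc: float

    def __post_init__(self) -> None:
        if self.replicon_type not in REPLICON_TYPES:
            raise ValidationError(
                f"replicon {self.replicon_id}: replicon_type must be one of "
                f"{sorted(REPLICON_TYPES)}, got {self.replicon_type!r}"
            )
        if self.topology not in TOPOLOGIES:
            raise ValidationError(
                f"replicon {self.replicon_id}: topology must be one of "
                f"{sorted(TOPOLOGIES)}, got {self.topology!r}"
            )
        if self.length <= 0:
            raise ValidationError(
                f"replicon {self.replicon_id}: length must be > 0, got {self.length}"
            )
        if not 0.0 <= self.gc <= 1.0:
            raise ValidationError(
                f"replicon {self.replicon_id}: gc must be in [0,1], got {self.gc}"
            )


@dataclass
class GenomeMetadata:
    """Taxonomic labels and the replicons of one genome."""

    genome_id: str
    phylum: str
    genus: str
    species: str
    replicons: list[RepliconMetadata] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.replicons:
            raise ValidationError(f"genome {self.genome_id}: needs >= 1 replicon")
        for rep in self.replicons:
            if rep.genome_id != self.genome_id:
                raise ValidationError(
                    f"genome {self.genome_id}: replicon {rep.replicon_id} "
                    f"belongs to {rep.genome_id}"
                )

    @property
    def total_length(self) -> int:
        return sum(rep.length for rep in self.replicons)


@dataclass(frozen=True)
class GeneLocus:
    """One gene of a system, on its replicon.

    ``gene_index`` is the ordinal position of the gene among the replicon's
    CDS (0-based); it is required only by defence-island detection, which
    counts intervening *proteins* rather than base pairs.
    """

    start: int
    end: int
    strand: str = "+"
    gc: float = 0.5
    gene_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"gene [{self.start},{self.end}): need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0.0 <= self.gc <= 1.0:
            raise ValidationError(f"gene gc must be in [0,1], got {self.gc}")
        if self.gene_index is not None and self.gene_index < 0:
            raise ValidationError(f"gene_index must be >= 0, got {self.gene_index}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SystemHit:
    """One detected defence system or BGC: the atom of every statistic."""

    hit_id: str
    genome_id: str
    replicon_id: str
    category: str
    system_type: str
    genes: list[GeneLocus]
    subtype: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"hit {self.hit_id}: category must be one of {sorted(CATEGORIES)}, "
                f"got {self.category!r}"
            )
        if not self.genes:
            raise ValidationError(f"hit {self.hit_id}: needs >= 1 gene")
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))

    @property
    def span(self) -> tuple[int, int]:
        """[min gene start, max gene end) of the hit."""
        return self.genes[0].start, max(g.end for g in self.genes)

    @property
    def start(self) -> int:
        return self.genes[0].start


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals: sorted, non-overlapping, non-touching."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for start, end in ivs:
        if start >= end:
            raise ValidationError(f"interval [{start},{end}): need start < end")
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class IntervalSet:
    """A merged union of intervals (e.g. prophage regions) on one replicon.

    Intervals are normalized on construction: sorted, non-overlapping,
    half-open. ``total_length`` is therefore the exact measure of the union.
    """

    replicon_id: str
    intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals)

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def overlap(self, start: int, end: int) -> int:
        """Base pairs of [start, end) covered by the union."""
        if start >= end:
            raise ValidationError(f"query [{start},{end}): need start < end")
        return sum(
            max(0, min(end, e) - max(start, s)) for s, e in self.intervals
        )


def index_replicons(
    genomes: Sequence[GenomeMetadata],
) -> dict[str, RepliconMetadata]:
    """Map replicon_id -> metadata; replicon ids must be cohort-unique."""
    out: dict[str, RepliconMetadata] = {}
    for genome in genomes:
        for rep in genome.replicons:
            if rep.replicon_id in out:
                raise ValidationError(f"duplicate replicon_id {rep.replicon_id}")
            out[rep.replicon_id] = rep
    return out


def index_genomes(genomes: Sequence[GenomeMetadata]) -> dict[str, GenomeMetadata]:
    out: dict[str, GenomeMetadata] = {}
    for genome in genomes:
        if genome.genome_id in out:
            raise ValidationError(f"duplicate genome_id {genome.genome_id}")
        out[genome.genome_id] = genome
    return out


def validate_hits(
    hits: Sequence[SystemHit], genomes: Sequence[GenomeMetadata]
) -> None:
    """Check every hit against the cohort: known genome/replicon, in-bounds genes."""
    reps = index_replicons(genomes)
    gens = index_genomes(genomes)
    for hit in hits:
        if hit.genome_id not in gens:
            raise ValidationError(f"hit {hit.hit_id}: unknown genome {hit.genome_id}")
        rep = reps.get(hit.replicon_id)
        if rep is None:
            raise ValidationError(
                f"hit {hit.hit_id}: unknown replicon {hit.replicon_id}"
            )
        if rep.genome_id != hit.genome_id:
            raise ValidationError(
                f"hit {hit.hit_id}: replicon {hit.replicon_id} is not part of "
                f"genome {hit.genome_id}"
            )
        for gene in hit.genes:
            if gene.end > rep.length:
                raise ValidationError(
                    f"hit {hit.hit_id}: gene [{gene.start},{gene.end}) outside "
                    f"replicon {rep.replicon_id} of length {rep.length}"
                )
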