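"""Descriptive arsenal statistics: counts, frequency, abundance, defence islands.

Two distinct per-type summaries are used throughout:

* **frequency** — fraction of genomes carrying at least one copy;
* **abundance** — mean copies per genome (multi-copy genomes count fully).

Abundance >= frequency always, since a copy count dominates its indicator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import pandas as pd

from .model import (
    GenomeMetadata,
    SystemHit,
    ValidationError,
    index_genomes,
    merge_intervals,
)

logger = logging.getLogger(__name__)


@dataclass
class ArsenalSummary:
    """Per-group arsenal description."""

    group_label: str
    n_genomes: int
    mean_systems_per_genome: float
    per_type: dict[str, tuple[float, float]]  # type -> (frequency, abundance)


@dataclass
class DefenseIsland:
    """>= 2 defence systems chained by the intervening-protein criterion."""

    replicon_id: str
    member_hit_ids: list[str]
    span: tuple[int, int]


def systems_per_genome(
    hits: Sequence[SystemHit], genomes: Sequence[GenomeMetadata]
) -> dict[str, int]:
    """Number of systems per genome; genomes without hits map to 0."""
    counts = {g.genome_id: 0 for g in genomes}
    for hit in hits:
        if hit.genome_id not in counts:
            raise ValidationError(
                f"hit {hit.hit_id} references unknown genome {hit.genome_id}"
            )
        counts[hit.genome_id] += 1
    return counts


def group_summary(
    hits: Sequence[SystemHit],
    genomes: Sequence[GenomeMetadata],
    group_fn: Callable[[GenomeMetadata], str],
) -> list[ArsenalSummary]:
    """Frequency and abundance of every system type, per genome group."""
    index_genomes(genomes)  # uniqueness check
    by_group: dict[str, list[GenomeMetadata]] = {}
    for genome in genomes:
        by_group.setdefault(group_fn(genome), []).append(genome)

    copies: dict[str, dict[str, int]] = {g.genome_id: {} for g in genomes}
    for hit in hits:
        if hit.genome_id not in copies:
            raise ValidationError(
                f"hit {hit.hit_id} references unknown genome {hit.genome_id}"
            )
        bucket = copies[hit.genome_id]
        bucket[hit.system_type] = bucket.get(hit.system_type, 0) + 1
    all_types = sorted({hit.system_type for hit in hits})

    summaries: list[ArsenalSummary] = []
    for label in sorted(by_group):
        members = by_group[label]
        n = len(members)
        if n == 0:
            logger.warning("group %r is empty; excluded from summary", label)
            continue
        per_type: dict[str, tuple[float, float]] = {}
        for system_type in all_types:
            counts = [copies[g.genome_id].get(system_type, 0) for g in members]
            frequency = sum(1 for c in counts if c > 0) / n
            abundance = sum(counts) / n
            per_type[system_type] = (frequency, abundance)
        mean_total = sum(ab for _, ab in per_type.values())
        summaries.append(
            ArsenalSummary(
                group_label=label,
                n_genomes=n,
                mean_systems_per_genome=mean_total,
                per_type=per_type,
            )
        )
    return summaries


def summaries_to_frame(summaries: Sequence[ArsenalSummary]) -> pd.DataFrame:
    rows = []
    for summary in summaries:
        for system_type, (freq, ab) in sorted(summary.per_type.items()):
            rows.append(
                {
                    "group": summary.group_label,
                    "n_genomes": summary.n_genomes,
                    "system_type": system_type,
                    "frequency": freq,
                    "abundance": ab,
                }
            )
    return pd.DataFrame(
        rows, columns=["group", "n_genomes", "system_type", "frequency", "abundance"]
    )


def defense_genome_fraction(
    hits: Sequence[SystemHit], genomes: Sequence[GenomeMetadata]
) -> dict[str, float]:
    """Fraction of each genome (bp) occupied by defence genes.

    Overlapping defence genes are merged per replicon before summing, so
    tandem or nested annotations are never double counted.  Only hits with
    ``category == 'defence'`` contribute; the denominator is the summed
    length of all the genome's replicons.
    """
    per_genome_intervals: dict[str, dict[str, list[tuple[int, int]]]] = {
        g.genome_id: {} for g in genomes
    }
    for hit in hits:
        if hit.category != "defence":
            continue
        if hit.genome_id not in per_genome_intervals:
            raise ValidationError(
                f"hit {hit.hit_id} references unknown genome {hit.genome_id}"
            )
        bucket = per_genome_intervals[hit.genome_id].setdefault(hit.replicon_id, [])
        bucket.extend((gene.start, gene.end) for gene in hit.genes)

    fractions: dict[str, float] = {}
    for genome in genomes:
        total_bp = genome.total_length
        defence_bp = 0
        for ivs in per_genome_intervals[genome.genome_id].values():
            defence_bp += sum(e - s for s, e in merge_intervals(ivs))
        fractions[genome.genome_id] = defence_bp / total_bp
    return fractions


def detect_islands(
    hits: Sequence[SystemHit], max_intervening: int = 20
) -> list[DefenseIsland]:
    """Chain co-located systems on one replicon into defence islands.

    Two systems belong to the same island when the number of CDS strictly
    between them (between the max gene ordinal of the upstream system and
    the min gene ordinal of the downstream one) is < ``max_intervening``;
    islands are the maximal chains under this criterion.  Singletons are
    not reported.  Requires every gene to carry ``gene_index``.
    """
    if not hits:
        return []
    replicons = {hit.replicon_id for hit in hits}
    if len(replicons) != 1:
        raise ValidationError(
            f"detect_islands expects hits from a single replicon, got {sorted(replicons)}"
        )
    for hit in hits:
        if any(gene.gene_index is None for gene in hit.genes):
            raise ValidationError(
                f"hit {hit.hit_id}: every gene needs a gene_index (CDS ordinal); "
                "supply gene ordinals to use island detection"
            )
    ranges = sorted(
        (
            (
                min(g.gene_index for g in hit.genes),
                max(g.gene_index for g in hit.genes),
                hit,
            )
            for hit in hits
        ),
        key=lambda entry: (entry[0], entry[1]),
    )
    islands: list[DefenseIsland] = []
    chain = [ranges[0]]
    for entry in ranges[1:]:
        prev_max = max(r[1] for r in chain)
        intervening = entry[0] - prev_max - 1
        if intervening < max_intervening:
            chain.append(entry)
        else:
            if len(chain) >= 2:
                islands.append(_island_from_chain(chain))
            chain = [entry]
    if len(chain) >= 2:
        islands.append(_island_from_chain(chain))
    return islands


def _island_from_chain(chain: list[tuple[int, int, SystemHit]]) -> DefenseIsland:
    members = [entry[2] for entry in chain]
    start = min(hit.span[0] for hit in members)
    end = max(hit.span[1] for hit in members)
    return DefenseIsland(
        replicon_id=members[0].replicon_id,
        member_hit_ids=[hit.hit_id for hit in members],
        span=(start, end),
    )


def islands_to_frame(islands: Sequence[DefenseIsland]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "replicon_id": isl.replicon_id,
                "n_systems": len(isl.member_hit_ids),
                "span_start": isl.span[0],
                "span_end": isl.span[1],
                "member_hit_ids": ",".join(isl.member_hit_ids),
            }
            for isl in islands
        ],
        columns=["replicon_id", "n_systems", "span_start", "span_end", "member_hit_ids"],
    )
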