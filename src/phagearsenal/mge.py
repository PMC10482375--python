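"""Mobile-genetic-element attribution and GC-based HGT scoring.

Each hit is attributed to exactly one of three mutually exclusive
locations, with prophage taking precedence over plasmid (a prophage
integrated on a plasmid counts as prophage):

* **prophage** — a defence system if at least one of its genes overlaps a
  prophage interval by >= 1 bp; a BGC if at least 50 % of its span
  [min gene start, max gene end) lies within the merged prophage union
  (ties at exactly 50 % count as prophage);
* **plasmid** — otherwise, when the replicon is annotated as a plasmid;
* **chromosome** — otherwise.

The GC score of a gene is its GC fraction divided by the GC fraction of
its replicon; values well below 1 mark candidate horizontal transfers.  A
hit is flagged ``low_gc`` when the mean gene score falls below a
configurable threshold (default 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd

from .model import (
    GenomeMetadata,
    IntervalSet,
    RepliconMetadata,
    SystemHit,
    ValidationError,
    index_replicons,
)
from .profile import group_summary

LOCATIONS = ("chromosome", "plasmid", "prophage")


@dataclass
class LocationCall:
    hit_id: str
    system_type: str
    category: str
    location: str
    prophage_overlap_bp: int
    overlap_fraction: float


@dataclass
class GcScore:
    hit_id: str
    system_type: str
    gene_scores: list[float]
    mean_score: float
    low_gc_flag: bool


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention used for report percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def attribute_location(
    hit: SystemHit,
    replicon: RepliconMetadata,
    prophages: Optional[IntervalSet] = None,
) -> LocationCall:
    """Attribute one hit to chromosome, plasmid, or prophage."""
    if hit.replicon_id != replicon.replicon_id:
        raise ValidationError(
            f"hit {hit.hit_id} is on {hit.replicon_id}, not {replicon.replicon_id}"
        )
    if prophages is not None and prophages.replicon_id != replicon.replicon_id:
        raise ValidationError(
            f"prophage intervals are for {prophages.replicon_id}, "
            f"not {replicon.replicon_id}"
        )
    span_start, span_end = hit.span
    span_len = span_end - span_start
    gene_overlap_bp = 0
    span_overlap_bp = 0
    if prophages is not None and prophages.intervals:
        gene_overlap_bp = sum(
            prophages.overlap(gene.start, gene.end) for gene in hit.genes
        )
        span_overlap_bp = prophages.overlap(span_start, span_end)
    overlap_fraction = span_overlap_bp / span_len

    if hit.category == "defence":
        is_prophage = gene_overlap_bp > 0
    else:  # bgc: at least half of the region inside the prophage union
        is_prophage = overlap_fraction >= 0.5
    if is_prophage:
        location = "prophage"
    elif replicon.replicon_type == "plasmid":
        location = "plasmid"
    else:
        location = "chromosome"
    return LocationCall(
        hit_id=hit.hit_id,
        system_type=hit.system_type,
        category=hit.category,
        location=location,
        prophage_overlap_bp=gene_overlap_bp,
        overlap_fraction=overlap_fraction,
    )


def attribute_all(
    hits: Sequence[SystemHit],
    genomes: Sequence[GenomeMetadata],
    prophages: dict[str, IntervalSet],
) -> list[LocationCall]:
    replicons = index_replicons(genomes)
    calls = []
    for hit in hits:
        rep = replicons.get(hit.replicon_id)
        if rep is None:
            raise ValidationError(
                f"hit {hit.hit_id}: unknown replicon {hit.replicon_id}"
            )
        calls.append(attribute_location(hit, rep, prophages.get(hit.replicon_id)))
    return calls


def calls_to_frame(calls: Sequence[LocationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "hit_id": c.hit_id,
                "system_type": c.system_type,
                "category": c.category,
                "location": c.location,
                "prophage_overlap_bp": c.prophage_overlap_bp,
                "overlap_fraction": c.overlap_fraction,
            }
            for c in calls
        ],
        columns=[
            "hit_id",
            "system_type",
            "category",
            "location",
            "prophage_overlap_bp",
            "overlap_fraction",
        ],
    )


def mge_contribution(calls: Sequence[LocationCall]) -> pd.DataFrame:
    """Per-type relative contribution of chromosome / plasmid / prophage.

    Fractions sum to 1 exactly for every type; ``n_total`` is reported
    alongside so bar-style summaries can show the number of occurrences.
    """
    df = calls_to_frame(list(calls))
    if df.empty:
        return pd.DataFrame(
            columns=[
                "system_type",
                "n_total",
                "fraction_chromosome",
                "fraction_plasmid",
                "fraction_prophage",
            ]
        )
    rows = []
    for system_type, sub in df.groupby("system_type", sort=True):
        n = len(sub)
        counts = sub["location"].value_counts()
        rows.append(
            {
                "system_type": system_type,
                "n_total": n,
                "fraction_chromosome": counts.get("chromosome", 0) / n,
                "fraction_plasmid": counts.get("plasmid", 0) / n,
                "fraction_prophage": counts.get("prophage", 0) / n,
            }
        )
    return pd.DataFrame(rows)


def gc_score(
    hit: SystemHit, replicon: RepliconMetadata, threshold: float = 0.8
) -> GcScore:
    """Per-gene GC / replicon GC; the hit-level score is the mean over genes."""
    if hit.replicon_id != replicon.replicon_id:
        raise ValidationError(
            f"hit {hit.hit_id} is on {hit.replicon_id}, not {replicon.replicon_id}"
        )
    if replicon.gc <= 0:
        raise ValidationError(
            f"replicon {replicon.replicon_id}: GC must be > 0 to compute a GC score"
        )
    scores = [gene.gc / replicon.gc for gene in hit.genes]
    mean_score = sum(scores) / len(scores)
    return GcScore(
        hit_id=hit.hit_id,
        system_type=hit.system_type,
        gene_scores=scores,
        mean_score=mean_score,
        low_gc_flag=mean_score < threshold,
    )


def gc_scores_to_frame(scores: Sequence[GcScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "hit_id": s.hit_id,
                "system_type": s.system_type,
                "mean_score": s.mean_score,
                "low_gc_flag": s.low_gc_flag,
            }
            for s in scores
        ],
        columns=["hit_id", "system_type", "mean_score", "low_gc_flag"],
    )


def frequency_vs_mge(
    hits: Sequence[SystemHit],
    genomes: Sequence[GenomeMetadata],
    prophages: dict[str, IntervalSet],
    gc_threshold: float = 0.8,
) -> pd.DataFrame:
    """Join per-genus frequency with MGE fraction and mean GC score per type.

    One row per (genus, system_type) with the type present in the genus:
    the substrate for the frequency-vs-mobility and frequency-vs-GC
    relationships (rare systems tend to be MGE-borne and AT-enriched).
    """
    replicons = index_replicons(genomes)
    genome_genus = {g.genome_id: g.genus for g in genomes}
    summaries = group_summary(hits, genomes, lambda g: g.genus)
    calls = attribute_all(hits, genomes, prophages)
    call_by_hit = {c.hit_id: c for c in calls}
    scores = {
        h.hit_id: gc_score(h, replicons[h.replicon_id], threshold=gc_threshold)
        for h in hits
    }
    hits_by_genus_type: dict[tuple[str, str], list[SystemHit]] = {}
    for hit in hits:
        key = (genome_genus[hit.genome_id], hit.system_type)
        hits_by_genus_type.setdefault(key, []).append(hit)

    rows = []
    for summary in summaries:
        for system_type, (freq, _ab) in sorted(summary.per_type.items()):
            members = hits_by_genus_type.get((summary.group_label, system_type), [])
            if not members:
                continue
            mge = sum(
                1
                for h in members
                if call_by_hit[h.hit_id].location in ("plasmid", "prophage")
            )
            mean_gc = sum(scores[h.hit_id].mean_score for h in members) / len(members)
            rows.append(
                {
                    "genus": summary.group_label,
                    "system_type": system_type,
                    "frequency_in_genus": freq,
                    "mge_fraction": mge / len(members),
                    "mean_gc_score": mean_gc,
                    "n_occurrences": len(members),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "genus",
            "system_type",
            "frequency_in_genus",
            "mge_fraction",
            "mean_gc_score",
            "n_occurrences",
        ],
    )
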