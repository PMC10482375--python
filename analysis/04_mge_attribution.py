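#!/usr/bin/env python
"""Attribute every hit to chromosome, plasmid, or prophage; score GC shifts.

Defence systems count as prophage-borne when any gene overlaps a prophage
interval; BGCs when at least half of their span does.  The GC score
(gene GC / replicon GC, averaged per hit) flags candidate horizontal
transfers below 0.8.  Also writes the per-genus frequency-vs-mobility
join table.
"""

import argparse
from pathlib import Path

from phagearsenal import io as paio
from phagearsenal.mge import (
    attribute_all,
    calls_to_frame,
    frequency_vs_mge,
    gc_score,
    gc_scores_to_frame,
    mge_contribution,
    round_half_up,
)
from phagearsenal.model import index_replicons


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--outdir", type=Path, default=Path("results/mge"))
    parser.add_argument("--gc-threshold", type=float, default=0.8)
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    genomes = paio.read_metadata(args.cohort / "metadata.tsv")
    replicons = index_replicons(genomes)
    hits = paio.read_hit_table(args.cohort / "hits.tsv", replicons=replicons)
    prophages = paio.read_intervals(args.cohort / "prophages.bed")

    calls = attribute_all(hits, genomes, prophages)
    paio.write_results(calls_to_frame(calls), args.outdir / "locations.tsv")
    contrib = mge_contribution(calls)
    paio.write_results(contrib, args.outdir / "mge_contribution.tsv")
    scores = [
        gc_score(h, replicons[h.replicon_id], threshold=args.gc_threshold)
        for h in hits
    ]
    paio.write_results(gc_scores_to_frame(scores), args.outdir / "gc_scores.tsv")
    join = frequency_vs_mge(hits, genomes, prophages, gc_threshold=args.gc_threshold)
    paio.write_results(join, args.outdir / "frequency_vs_mge.tsv")

    n = len(calls)
    n_plasmid = sum(c.location == "plasmid" for c in calls)
    n_prophage = sum(c.location == "prophage" for c in calls)
    print(f"{n} hits: {round_half_up(100 * n_plasmid / n, 1)} % plasmid-borne "
          f"({n_plasmid}), {round_half_up(100 * n_prophage / n, 1)} % "
          f"prophage-borne ({n_prophage})")
    low = sum(s.low_gc_flag for s in scores)
    print(f"{low} hits flagged low-GC (< {args.gc_threshold})")


if __name__ == "__main__":
    main()
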