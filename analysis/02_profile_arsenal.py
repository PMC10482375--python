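#!/usr/bin/env python
"""Profile the defence arsenal of the simulated cohort.

Reports systems per genome, per-phylum frequency/abundance of each system
type, the genome fraction devoted to defence genes, and defence islands
(systems separated by fewer than 20 intervening CDS).
"""

import argparse
from pathlib import Path

import pandas as pd

from phagearsenal import io as paio
from phagearsenal.model import index_replicons
from phagearsenal.profile import (
    defense_genome_fraction,
    detect_islands,
    group_summary,
    islands_to_frame,
    summaries_to_frame,
    systems_per_genome,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--outdir", type=Path, default=Path("results/profile"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    genomes = paio.read_metadata(args.cohort / "metadata.tsv")
    hits = paio.read_hit_table(
        args.cohort / "hits.tsv", replicons=index_replicons(genomes)
    )
    defence = [h for h in hits if h.category == "defence"]

    counts = systems_per_genome(defence, genomes)
    fractions = defense_genome_fraction(defence, genomes)
    per_genome = pd.DataFrame(
        sorted(counts.items()), columns=["genome_id", "n_systems"]
    )
    per_genome["defense_genome_fraction"] = [
        fractions[g] for g in per_genome["genome_id"]
    ]
    paio.write_results(per_genome, args.outdir / "per_genome_counts.tsv")

    summaries = group_summary(defence, genomes, lambda g: g.phylum)
    paio.write_results(summaries_to_frame(summaries), args.outdir / "group_summary.tsv")

    by_replicon: dict[str, list] = {}
    for hit in defence:
        by_replicon.setdefault(hit.replicon_id, []).append(hit)
    islands = []
    for replicon_hits in by_replicon.values():
        if len(replicon_hits) >= 2:
            islands.extend(detect_islands(replicon_hits))
    paio.write_results(islands_to_frame(islands), args.outdir / "islands.tsv")

    for s in summaries:
        print(f"{s.group_label}: {s.n_genomes} genomes, "
              f"{s.mean_systems_per_genome:.2f} systems/genome")
    print(f"mean defence genome fraction: "
          f"{100 * per_genome['defense_genome_fraction'].mean():.3f} %")
    print(f"defence islands (>=2 systems, <20 intervening CDS): {len(islands)}")


if __name__ == "__main__":
    main()
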