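#!/usr/bin/env python
"""Spatial distribution of systems along the linear chromosomes.

Normalizes each hit's start to [0, 1), profiles each sufficiently common
system type, and reports the fraction of occurrences in the chromosomal
extremities (first/last 10 % and 1 %) with an exact binomial test against
the uniform 20 % baseline.
"""

import argparse
from pathlib import Path

from phagearsenal import io as paio
from phagearsenal.model import index_replicons
from phagearsenal.spatial import (
    positions_to_frame,
    profiles_to_frame,
    spatial_profiles,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--outdir", type=Path, default=Path("results/spatial"))
    parser.add_argument("--min-occurrences", type=int, default=45)
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    genomes = paio.read_metadata(args.cohort / "metadata.tsv")
    replicons = index_replicons(genomes)
    hits = [
        h
        for h in paio.read_hit_table(args.cohort / "hits.tsv", replicons=replicons)
        if replicons[h.replicon_id].topology == "linear"
    ]
    paio.write_results(positions_to_frame(hits, genomes), args.outdir / "positions.tsv")
    profiles = spatial_profiles(hits, genomes, min_occurrences=args.min_occurrences)
    paio.write_results(
        profiles_to_frame(profiles, with_p=True), args.outdir / "profiles.tsv"
    )

    for p in sorted(profiles, key=lambda q: -q.extremity_fraction_10):
        print(f"{p.system_type:>12}: n={p.n:4d}  "
              f"extremity10={100 * p.extremity_fraction_10:5.1f} %  "
              f"extremity1={100 * p.extremity_fraction_1:5.1f} %")


if __name__ == "__main__":
    main()
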