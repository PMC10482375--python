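#!/usr/bin/env python
"""Screen system types for differential abundance between the two phyla.

For each type: abundance in focal and background genomes, the normalized
difference estimator, two-group ANOVA on per-genome copy counts, and a
Bonferroni-corrected enrichment class (absent / enriched / depleted /
not significant).
"""

import argparse
from pathlib import Path

from phagearsenal import io as paio
from phagearsenal.diffabund import screen
from phagearsenal.model import index_replicons


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--outdir", type=Path, default=Path("results/diffabund"))
    parser.add_argument("--focal", default="Actinobacteria")
    parser.add_argument("--alpha", type=float, default=0.05)
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    genomes = paio.read_metadata(args.cohort / "metadata.tsv")
    hits = paio.read_hit_table(
        args.cohort / "hits.tsv", replicons=index_replicons(genomes)
    )
    defence = [h for h in hits if h.category == "defence"]
    df = screen(defence, genomes, args.focal, alpha=args.alpha)
    paio.write_results(df, args.outdir / "differential_abundance.tsv")

    for _, row in df.iterrows():
        print(f"{row['system_type']:>12}: estimator {row['estimator']:+.2f} "
              f"p_adj {row['p_adj']:.2e} -> {row['class_label']}"
              if row['class_label'] != 'absent' else
              f"{row['system_type']:>12}: absent from focal group")


if __name__ == "__main__":
    main()
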