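#!/usr/bin/env python
"""Run the whole pipeline in one step and write the markdown report.

Equivalent to running scripts 01-06 with the same seed, but through the
file-based orchestrator, which also assembles results/run/report.md.
"""

import argparse
import sys
from pathlib import Path

from phagearsenal.pipeline import PipelineStageError, RunConfig, run_pipeline

sys.path.insert(0, str(Path(__file__).parent))
template = __import__("01_simulate_cohort")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results/run"))
    args = parser.parse_args()

    from dataclasses import asdict

    config = RunConfig(
        outdir=str(args.outdir),
        seed=args.seed,
        cohort={
            "n_genomes_in": 200,
            "n_genomes_out": 200,
            "system_specs": [asdict(s) for s in template.SYSTEM_SPECS],
        },
    )
    try:
        outputs = run_pipeline(config)
    except PipelineStageError as exc:
        print(exc, file=sys.stderr)
        raise SystemExit(1)
    for stage, path in outputs.items():
        print(f"{stage}: {path}")


if __name__ == "__main__":
    main()
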