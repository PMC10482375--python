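"""End-to-end orchestration: simulate -> profile -> diffabund -> mge -> spatial -> physig.

Stages communicate only through files in the output directory, so every
intermediate is inspectable and any stage can be re-run in isolation.
Each output TSV starts with a comment header recording the package
version, the configuration hash and the seed; reruns with the same
configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from . import io as paio
from .cohort import CohortSpec, SystemSpec, simulate_cohort, simulate_tree
from .diffabund import screen
from .mge import (
    attribute_all,
    calls_to_frame,
    gc_score,
    gc_scores_to_frame,
    mge_contribution,
)
from .model import ValidationError, index_replicons
from .phylosig import signal_screen
from .profile import (
    defense_genome_fraction,
    detect_islands,
    group_summary,
    islands_to_frame,
    summaries_to_frame,
    systems_per_genome,
)
from .spatial import positions_to_frame, profiles_to_frame, spatial_profiles

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run (load with :func:`load_config`)."""

    outdir: str
    seed: int = 0
    cohort: Optional[dict] = None  # CohortSpec fields; None -> use input paths
    metadata_path: Optional[str] = None
    hits_path: Optional[str] = None
    prophages_path: Optional[str] = None
    tree_path: Optional[str] = None
    focal_phylum: str = "Actinobacteria"
    alpha: float = 0.05
    gc_threshold: float = 0.8
    extremity_thresholds: tuple[float, float] = (0.10, 0.01)
    min_occurrences: int = 45
    island_max_intervening: int = 20

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = json.load(fh)
    if "extremity_thresholds" in data:
        data["extremity_thresholds"] = tuple(data["extremity_thresholds"])
    return RunConfig(**data)


def _cohort_spec_from_config(config: RunConfig) -> CohortSpec:
    data = dict(config.cohort or {})
    system_specs = [SystemSpec(**s) for s in data.pop("system_specs", [])]
    data.setdefault("seed", config.seed)
    if "chromosome_length_range" in data:
        data["chromosome_length_range"] = tuple(data["chromosome_length_range"])
    return CohortSpec(system_specs=system_specs, **data)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage; returns a map stage -> primary output path."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = (
        f"phagearsenal v{__version__} config={config.config_hash()} "
        f"seed={config.seed}"
    )
    outputs: dict[str, Path] = {}

    def _write(df: pd.DataFrame, name: str) -> Path:
        path = outdir / name
        paio.write_results(df, path, header=header)
        return path

    # ---- stage: simulate (or load) -------------------------------------
    stage = "simulate"
    try:
        if config.cohort is not None:
            cohort = simulate_cohort(_cohort_spec_from_config(config))
            genomes, hits, prophages = cohort.genomes, cohort.hits, cohort.prophages
            paio.write_metadata(genomes, outdir / "metadata.tsv")
            paio.write_hit_table(hits, outdir / "hits.tsv")
            paio.write_intervals(prophages, outdir / "prophages.bed")
            outputs[stage] = outdir / "hits.tsv"
        else:
            if not (config.metadata_path and config.hits_path):
                raise ValidationError(
                    "need either a cohort spec or metadata_path + hits_path"
                )
            genomes = paio.read_metadata(config.metadata_path)
            hits = paio.read_hit_table(
                config.hits_path, replicons=index_replicons(genomes)
            )
            prophages = (
                paio.read_intervals(config.prophages_path)
                if config.prophages_path
                else {}
            )
    except Exception as exc:
        raise PipelineStageError(f"stage '{stage}' failed: {exc}") from exc

    defence_hits = [h for h in hits if h.category == "defence"]

    # ---- stage: profile -------------------------------------------------
    stage = "profile"
    try:
        counts = systems_per_genome(defence_hits, genomes)
        counts_df = pd.DataFrame(
            sorted(counts.items()), columns=["genome_id", "n_systems"]
        )
        fractions = defense_genome_fraction(hits, genomes)
        counts_df["defense_genome_fraction"] = [
            fractions[g] for g in counts_df["genome_id"]
        ]
        outputs[stage] = _write(counts_df, "per_genome_counts.tsv")
        summaries = group_summary(defence_hits, genomes, lambda g: g.phylum)
        _write(summaries_to_frame(summaries), "group_summary.tsv")
        islands = []
        by_replicon: dict[str, list] = {}
        for hit in defence_hits:
            by_replicon.setdefault(hit.replicon_id, []).append(hit)
        for replicon_hits in by_replicon.values():
            if len(replicon_hits) >= 2 and all(
                g.gene_index is not None for h in replicon_hits for g in h.genes
            ):
                islands.extend(
                    detect_islands(
                        replicon_hits, max_intervening=config.island_max_intervening
                    )
                )
        _write(islands_to_frame(islands), "islands.tsv")
    except Exception as exc:
        raise PipelineStageError(f"stage '{stage}' failed: {exc}") from exc

    # ---- stage: diffabund ----------------------------------------------
    stage = "diffabund"
    try:
        diff = screen(
            defence_hits, genomes, config.focal_phylum, alpha=config.alpha
        )
        outputs[stage] = _write(diff, "differential_abundance.tsv")
    except Exception as exc:
        raise PipelineStageError(f"stage '{stage}' failed: {exc}") from exc

    # ---- stage: mge ------------------------------------------------------
    stage = "mge"
    try:
        calls = attribute_all(hits, genomes, prophages)
        outputs[stage] = _write(calls_to_frame(calls), "locations.tsv")
        _write(mge_contribution(calls), "mge_contribution.tsv")
        replicons = index_replicons(genomes)
        scores = [
            gc_score(h, replicons[h.replicon_id], threshold=config.gc_threshold)
            for h in hits
        ]
        _write(gc_scores_to_frame(scores), "gc_scores.tsv")
    except Exception as exc:
        raise PipelineStageError(f"stage '{stage}' failed: {exc}") from exc

    # ---- stage: spatial --------------------------------------------------
    stage = "spatial"
    try:
        linear = [
            h
            for h in hits
            if replicons[h.replicon_id].topology == "linear"
        ]
        if linear:
            _write(positions_to_frame(linear, genomes), "positions.tsv")
            profiles = spatial_profiles(
                linear,
                genomes,
                min_occurrences=config.min_occurrences,
                thresholds=config.extremity_thresholds,
            )
            outputs[stage] = _write(
                profiles_to_frame(profiles, with_p=True), "spatial_profiles.tsv"
            )
        else:
            logger.warning("no hits on linear replicons; spatial stage skipped")
    except Exception as exc:
        raise PipelineStageError(f"stage '{stage}' failed: {exc}") from exc

    # ---- stage: physig ---------------------------------------------------
    stage = "physig"
    try:
        focal_ids = sorted(
            g.genome_id for g in genomes if g.phylum == config.focal_phylum
        )
        tree = None
        if config.tree_path:
            tree = paio.read_tree(config.tree_path)
        elif config.cohort is not None and len(focal_ids) >= 4:
            tree = simulate_tree(len(focal_ids), seed=config.seed + 1)
            for leaf, genome_id in zip(tree.leaf_node_iter(), focal_ids):
                leaf.taxon.label = genome_id
            paio.write_tree(tree, outdir / "tree.nwk")
        if tree is None:
            logger.warning("no tree available; physig stage skipped")
        else:
            presence = _presence_matrix(defence_hits, focal_ids)
            if presence.shape[1] == 0:
                logger.warning("no defence types in focal group; physig skipped")
            else:
                signal = signal_screen(presence, tree)
                outputs[stage] = _write(signal, "phylo_signal.tsv")
    except Exception as exc:
        raise PipelineStageError(f"stage '{stage}' failed: {exc}") from exc

    # ---- stage: report ---------------------------------------------------
    stage = "report"
    try:
        outputs[stage] = _write_report(outdir, header)
    except Exception as exc:
        raise PipelineStageError(f"stage '{stage}' failed: {exc}") from exc
    return outputs


def _presence_matrix(hits, genome_ids: list[str]) -> pd.DataFrame:
    types = sorted({h.system_type for h in hits})
    mat = pd.DataFrame(0, index=genome_ids, columns=types, dtype=int)
    wanted = set(genome_ids)
    for hit in hits:
        if hit.genome_id in wanted:
            mat.loc[hit.genome_id, hit.system_type] = 1
    return mat


def _write_report(outdir: Path, header: str) -> Path:
    """Assemble the human-readable summary strictly from the stage TSVs."""
    lines = [f"# Pipeline report", "", f"_{header}_", ""]

    counts = paio.read_results(outdir / "per_genome_counts.tsv")
    lines += [
        "## Arsenal profile",
        "",
        f"- genomes: {len(counts)}",
        f"- mean defence systems per genome: {counts['n_systems'].mean():.3f}",
        f"- mean genome fraction in defence genes: "
        f"{100 * counts['defense_genome_fraction'].mean():.3f} %",
        "",
    ]
    summary = paio.read_results(outdir / "group_summary.tsv")
    for group, sub in summary.groupby("group"):
        lines.append(
            f"- {group}: {sub['abundance'].sum():.3f} systems/genome "
            f"over {sub['system_type'].nunique()} types"
        )
    lines.append("")

    diff = paio.read_results(outdir / "differential_abundance.tsv")
    by_class = diff["class_label"].value_counts()
    lines += [
        "## Differential abundance",
        "",
        "| class | n |",
        "|---|---|",
    ]
    for label in ("enriched", "depleted", "absent", "not_significant"):
        lines.append(f"| {label} | {int(by_class.get(label, 0))} |")
    lines.append("")

    contrib = paio.read_results(outdir / "mge_contribution.tsv")
    lines += ["## MGE contribution", "", "```\n" + contrib.to_string(index=False) + "\n```", ""]

    spatial_path = outdir / "spatial_profiles.tsv"
    if spatial_path.exists():
        prof = paio.read_results(spatial_path)
        lines += ["## Spatial profiles", "", "```\n" + prof.to_string(index=False) + "\n```", ""]

    signal_path = outdir / "phylo_signal.tsv"
    if signal_path.exists():
        signal = paio.read_results(signal_path)
        tested = signal[signal["status"] == "tested"]
        lines += [
            "## Phylogenetic signal",
            "",
            f"- types tested: {len(tested)}",
            f"- patchy (no significant signal): {int(tested['patchy'].sum())}"
            if len(tested)
            else "- no types tested",
            "",
        ]

    path = outdir / "report.md"
    path.write_text("\n".join(lines))
    return path
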