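"""Synthetic cohorts of genomes, defence-system hits, prophages, trees and traits.

The generator emulates the *statistical structure* of detector output
tables for a two-group comparison (a focal phylum against a background):
per-group system abundances, mobile-genetic-element carriage, GC shifts of
horizontally transferred genes, placement biases along linear replicons,
and traits evolving on ultrametric trees with a controlled phylogenetic
signal.  No nucleotide sequence is ever generated — only the coordinates,
GC values and taxonomy that the downstream statistics consume.

Placement families (position fraction along the replicon):

* ``uniform`` — U(0, 1)
* ``core_biased`` — Beta(5, 5), peaked at the replicon centre
* ``arm_biased`` — ½ Beta(1, 9) + ½ Beta(9, 1), pushed into both arms
* ``end_biased`` — ½ Beta(0.2, 20) + ½ Beta(20, 0.2), pinned to the ends

The default cohort scale (200 genomes per group, mean 1.3 prophages per
genome, 39 % plasmid carriage, GC-rich focal genomes on multi-megabase
linear chromosomes) mirrors, at desk scale, a GC-rich actinobacterial
cohort compared against a background phylum.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .model import (
    GeneLocus,
    GenomeMetadata,
    IntervalSet,
    RepliconMetadata,
    SystemHit,
    ValidationError,
)

PLACEMENTS = frozenset({"uniform", "core_biased", "arm_biased", "end_biased"})
COPIES_MODELS = frozenset({"poisson", "bernoulli"})

#: approximate CDS footprint (gene + spacer) used to derive gene ordinals
GENE_SPACING = 1000


@dataclass(frozen=True)
class SystemSpec:
    """Planted effect structure for one system type."""

    system_type: str
    abundance_in: float
    abundance_out: float
    copies_model: str = "poisson"
    mge_prob: float = 0.0
    gc_shift: float = 1.0
    placement: str = "uniform"
    n_genes: int = 3
    category: str = "defence"

    def __post_init__(self) -> None:
        if self.abundance_in < 0 or self.abundance_out < 0:
            raise ValidationError(f"{self.system_type}: abundances must be >= 0")
        if self.copies_model not in COPIES_MODELS:
            raise ValidationError(f"{self.system_type}: unknown copies_model")
        if not 0.0 <= self.mge_prob <= 1.0:
            raise ValidationError(f"{self.system_type}: mge_prob must be in [0,1]")
        if self.gc_shift <= 0:
            raise ValidationError(f"{self.system_type}: gc_shift must be > 0")
        if self.placement not in PLACEMENTS:
            raise ValidationError(f"{self.system_type}: unknown placement")
        if self.n_genes < 1:
            raise ValidationError(f"{self.system_type}: n_genes must be >= 1")


@dataclass
class CohortSpec:
    """Scale and effect structure of a synthetic two-group cohort."""

    seed: int
    n_genomes_in: int = 200
    n_genomes_out: int = 200
    system_specs: list[SystemSpec] = field(default_factory=list)
    genera: Optional[list[tuple[str, int]]] = None
    prophage_rate: float = 1.3
    plasmid_prob: float = 0.39
    chromosome_length_range: tuple[int, int] = (2_000_000, 10_000_000)
    topology: str = "linear"
    focal_phylum: str = "Actinobacteria"
    background_phylum: str = "Proteobacteria"

    def __post_init__(self) -> None:
        if self.n_genomes_in < 0 or self.n_genomes_out < 0:
            raise ValidationError("genome counts must be >= 0")
        if self.prophage_rate < 0:
            raise ValidationError("prophage_rate must be >= 0")
        if not 0.0 <= self.plasmid_prob <= 1.0:
            raise ValidationError("plasmid_prob must be in [0,1]")
        lo, hi = self.chromosome_length_range
        if lo <= 0 or hi < lo:
            raise ValidationError("invalid chromosome_length_range")
        if self.topology not in ("linear", "circular"):
            raise ValidationError("topology must be 'linear' or 'circular'")
        if self.topology == "circular":
            biased = [s.system_type for s in self.system_specs
                      if s.placement != "uniform"]
            if biased:
                raise ValidationError(
                    "placement-biased systems require linear topology "
                    f"(spatial analysis is undefined on circular replicons): {biased}"
                )


@dataclass
class SyntheticCohort:
    """Output bundle of :func:`simulate_cohort`.

    ``truth`` records, per hit, whether the copy was designated to sit on a
    mobile element and the placement fraction drawn for it — ground truth
    for recovery tests, never consumed by the analysis modules.
    """

    genomes: list[GenomeMetadata]
    hits: list[SystemHit]
    prophages: dict[str, IntervalSet]
    truth: pd.DataFrame


def sample_position_fractions(
    placement: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` position fractions in [0, 1) from a placement family."""
    if placement not in PLACEMENTS:
        raise ValidationError(f"unknown placement {placement!r}")
    if placement == "uniform":
        x = rng.uniform(0.0, 1.0, size=n)
    elif placement == "core_biased":
        x = rng.beta(5.0, 5.0, size=n)
    elif placement == "arm_biased":
        left = rng.random(n) < 0.5
        x = np.where(left, rng.beta(1.0, 9.0, size=n), rng.beta(9.0, 1.0, size=n))
    else:  # end_biased
        left = rng.random(n) < 0.5
        x = np.where(
            left, rng.beta(0.2, 20.0, size=n), rng.beta(20.0, 0.2, size=n)
        )
    return np.clip(x, 0.0, np.nextafter(1.0, 0.0))


def _genus_labels(spec: CohortSpec) -> list[str]:
    """Genus label per focal genome, honouring explicit (name, count) pairs."""
    if spec.genera:
        labels = []
        for name, count in spec.genera:
            labels.extend([name] * count)
        if len(labels) < spec.n_genomes_in:
            labels.extend(
                labels[i % max(len(labels), 1)] if labels else "GenusA"
                for i in range(spec.n_genomes_in - len(labels))
            )
        return labels[: spec.n_genomes_in]
    names = ["GenusA", "GenusB", "GenusC", "GenusD"]
    return [names[i % len(names)] for i in range(spec.n_genomes_in)]


def _draw_copies(spec: SystemSpec, mean: float, rng: np.random.Generator) -> int:
    if spec.copies_model == "poisson":
        return int(rng.poisson(mean))
    return int(rng.random() < min(mean, 1.0))


def _make_genes(
    start: int,
    n_genes: int,
    gc: float,
    rng: np.random.Generator,
) -> list[GeneLocus]:
    genes = []
    pos = start
    for _ in range(n_genes):
        length = int(rng.integers(600, 1500))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneLocus(
                start=pos,
                end=pos + length,
                strand=strand,
                gc=gc,
                gene_index=pos // GENE_SPACING,
            )
        )
        pos += length + 50
    return genes


def _hit_span(n_genes: int) -> int:
    # worst-case footprint of _make_genes: n genes of <1500 bp + 50 bp gaps
    return n_genes * 1550


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Simulate a two-group cohort of genomes with planted system structure.

    Deterministic given ``spec.seed``; per-genome substreams are spawned
    from one :class:`numpy.random.SeedSequence` so genome ``i`` is
    reproducible independently of how many genomes precede it.
    """
    root_ss = np.random.SeedSequence(spec.seed)
    n_total = spec.n_genomes_in + spec.n_genomes_out
    children = root_ss.spawn(n_total)
    genus_in = _genus_labels(spec)

    genomes: list[GenomeMetadata] = []
    hits: list[SystemHit] = []
    prophages: dict[str, IntervalSet] = {}
    truth_rows: list[dict] = []
    hit_counter = 0

    for i in range(n_total):
        rng = np.random.default_rng(children[i])
        focal = i < spec.n_genomes_in
        genome_id = f"G{i:05d}"
        if focal:
            phylum, genus = spec.focal_phylum, genus_in[i]
            chrom_gc = float(rng.uniform(0.60, 0.74))
        else:
            phylum, genus = spec.background_phylum, f"BG{i % 4}"
            chrom_gc = float(rng.uniform(0.45, 0.60))
        lo, hi = spec.chromosome_length_range
        chrom_len = int(rng.integers(lo, hi + 1))
        chrom = RepliconMetadata(
            replicon_id=f"{genome_id}_chr",
            genome_id=genome_id,
            replicon_type="chromosome",
            topology=spec.topology,
            length=chrom_len,
            gc=chrom_gc,
        )
        replicons = [chrom]
        plasmid: Optional[RepliconMetadata] = None
        if rng.random() < spec.plasmid_prob:
            plasmid = RepliconMetadata(
                replicon_id=f"{genome_id}_pls",
                genome_id=genome_id,
                replicon_type="plasmid",
                topology=spec.topology,
                length=int(rng.integers(50_000, 300_000)),
                gc=float(np.clip(chrom_gc + rng.normal(0.0, 0.02), 0.05, 0.95)),
            )
            replicons.append(plasmid)
        genomes.append(
            GenomeMetadata(
                genome_id=genome_id,
                phylum=phylum,
                genus=genus,
                species=f"{genus} sp{i:05d}",
                replicons=replicons,
            )
        )

        # prophage intervals on the chromosome, 10-60 kb, placed uniformly
        n_pro = int(rng.poisson(spec.prophage_rate))
        pro_ivs: list[tuple[int, int]] = []
        for _ in range(n_pro):
            plen = int(rng.integers(10_000, 60_000))
            if plen >= chrom_len:
                continue
            pstart = int(rng.integers(0, chrom_len - plen))
            pro_ivs.append((pstart, pstart + plen))
        if pro_ivs:
            prophages[chrom.replicon_id] = IntervalSet(chrom.replicon_id, pro_ivs)
        pro_merged = prophages.get(chrom.replicon_id)

        for sysspec in spec.system_specs:
            mean = sysspec.abundance_in if focal else sysspec.abundance_out
            n_copies = _draw_copies(sysspec, mean, rng)
            for _ in range(n_copies):
                hit_counter += 1
                hit_id = f"H{hit_counter:06d}"
                span = _hit_span(sysspec.n_genes)
                designated = rng.random() < sysspec.mge_prob
                target_rep = chrom
                target = "chromosome"
                frac = float(
                    sample_position_fractions(sysspec.placement, 1, rng)[0]
                )
                start = int(frac * max(1, chrom_len - span))
                if designated:
                    options = []
                    if pro_merged is not None and any(
                        e - s > span for s, e in pro_merged.intervals
                    ):
                        options.append("prophage")
                    if plasmid is not None and plasmid.length > span:
                        options.append("plasmid")
                    if options:
                        target = options[int(rng.integers(0, len(options)))]
                        if target == "prophage":
                            fitting = [
                                (s, e)
                                for s, e in pro_merged.intervals
                                if e - s > span
                            ]
                            s, e = fitting[int(rng.integers(0, len(fitting)))]
                            start = int(rng.integers(s, e - span))
                        else:
                            target_rep = plasmid
                            start = int(rng.integers(0, plasmid.length - span))
                    else:
                        designated = False
                gene_gc = float(np.clip(target_rep.gc * sysspec.gc_shift, 0.05, 0.95))
                hits.append(
                    SystemHit(
                        hit_id=hit_id,
                        genome_id=genome_id,
                        replicon_id=target_rep.replicon_id,
                        category=sysspec.category,
                        system_type=sysspec.system_type,
                        genes=_make_genes(start, sysspec.n_genes, gene_gc, rng),
                    )
                )
                truth_rows.append(
                    {
                        "hit_id": hit_id,
                        "system_type": sysspec.system_type,
                        "genome_id": genome_id,
                        "focal": focal,
                        "designated_mge": designated,
                        "target": target,
                        "position_fraction": frac,
                    }
                )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "hit_id",
            "system_type",
            "genome_id",
            "focal",
            "designated_mge",
            "target",
            "position_fraction",
        ],
    )
    return SyntheticCohort(genomes, hits, prophages, truth)


def simulate_tree(n_leaves: int, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric tree scaled to unit root-to-leaf depth."""
    if n_leaves < 2:
        raise ValidationError("simulate_tree needs n_leaves >= 2")
    import dendropy as _dendropy

    if n_leaves == 2:
        # the pure-birth process stops at the first split: a unit cherry
        return _dendropy.Tree.get(data="(T0000:1,T0001:1);", schema="newick")
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_leaves,
        rng=random.Random(seed),
    )
    for idx, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"T{idx:04d}"
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    depth = max(leaf.root_distance for leaf in tree.leaf_node_iter())
    if depth <= 0:
        raise ValidationError("degenerate zero-depth tree")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    # absorb floating-point drift so every leaf sits at depth exactly 1
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += 1.0 - leaf.root_distance
    return tree


def simulate_trait(
    tree: dendropy.Tree,
    lam: float,
    sigma2: float,
    seed: int,
    binarize_at: Optional[float] = None,
    cov: Optional[pd.DataFrame] = None,
) -> pd.Series:
    """Draw one trait under lambda-transformed Brownian motion on the tree.

    Returns a Series indexed by leaf label.  With ``binarize_at`` (an
    empirical quantile in (0, 1)), the continuous draw is thresholded to a
    0/1 presence/absence vector with roughly that fraction of absences.
    ``cov`` may carry a precomputed covariance of the same tree.
    """
    from .phylosig import lambda_transform, tree_covariance

    if not 0.0 <= lam <= 1.0:
        raise ValidationError(f"lambda must be in [0,1], got {lam}")
    if sigma2 < 0:
        raise ValidationError(f"sigma2 must be >= 0, got {sigma2}")
    if cov is None:
        cov = tree_covariance(tree)
    labels = list(cov.index)
    v = sigma2 * lambda_transform(cov.to_numpy(), lam)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(len(labels))
    if sigma2 == 0.0:
        y = np.zeros(len(labels))
    else:
        chol = np.linalg.cholesky(v + 1e-12 * np.eye(len(labels)))
        y = chol @ z
    if binarize_at is not None:
        if not 0.0 < binarize_at < 1.0:
            raise ValidationError("binarize_at must be a quantile in (0,1)")
        threshold = np.quantile(y, binarize_at)
        y = (y > threshold).astype(float)
    return pd.Series(y, index=labels)
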