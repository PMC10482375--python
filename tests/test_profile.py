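"""Arsenal profiling: counts, group summaries, genome fraction, defence islands."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phagearsenal.model import (
    GeneLocus,
    GenomeMetadata,
    RepliconMetadata,
    SystemHit,
    ValidationError,
)
from phagearsenal.profile import (
    defense_genome_fraction,
    detect_islands,
    group_summary,
    systems_per_genome,
)


def _genome(genome_id, length=1_000_000, genus="GenusA", phylum="P"):
    rep = RepliconMetadata(
        f"{genome_id}_chr", genome_id, "chromosome", "linear", length, 0.6
    )
    return GenomeMetadata(genome_id, phylum, genus, f"{genus} sp", [rep])


def _hit(hit_id, genome_id, system_type="RM", genes=None, indices=None):
    if genes is None:
        genes = [(100, 1000)]
    loci = [
        GeneLocus(s, e, gene_index=(indices[i] if indices else None))
        for i, (s, e) in enumerate(genes)
    ]
    return SystemHit(hit_id, genome_id, f"{genome_id}_chr", "defence", system_type, loci)


class TestSystemsPerGenome:
    def test_counts_with_zeros(self):
        genomes = [_genome("g1"), _genome("g2"), _genome("g3")]
        hits = [_hit("h1", "g1"), _hit("h2", "g1"), _hit("h3", "g3")]
        assert systems_per_genome(hits, genomes) == {"g1": 2, "g2": 0, "g3": 1}

    def test_no_hits_all_zeros(self):
        genomes = [_genome("g1"), _genome("g2")]
        assert systems_per_genome([], genomes) == {"g1": 0, "g2": 0}

    def test_orphan_hit_names_genome(self):
        with pytest.raises(ValidationError, match="gX"):
            systems_per_genome([_hit("h1", "gX")], [_genome("g1")])

    def test_total_equals_hit_count(self):
        genomes = [_genome(f"g{i}") for i in range(7)]
        hits = [_hit(f"h{i}", f"g{i % 7}") for i in range(23)]
        assert sum(systems_per_genome(hits, genomes).values()) == 23


class TestGroupSummary:
    def test_hand_arithmetic_frequency_and_abundance(self):
        """Copies [0, 2, 1, 1] of RM over four genomes: frequency 3/4,
        abundance 4/4."""
        genomes = [_genome(f"g{i}") for i in range(4)]
        hits = [
            _hit("h1", "g1"),
            _hit("h2", "g1"),
            _hit("h3", "g2"),
            _hit("h4", "g3"),
        ]
        (summary,) = group_summary(hits, genomes, lambda g: "all")
        freq, ab = summary.per_type["RM"]
        assert freq == pytest.approx(0.75)
        assert ab == pytest.approx(1.0)
        assert summary.mean_systems_per_genome == pytest.approx(1.0)

    def test_every_genome_one_copy_frequency_equals_abundance(self):
        genomes = [_genome(f"g{i}") for i in range(5)]
        hits = [_hit(f"h{i}", f"g{i}") for i in range(5)]
        (summary,) = group_summary(hits, genomes, lambda g: "all")
        assert summary.per_type["RM"] == (1.0, 1.0)

    def test_abundance_never_below_frequency(self):
        rng = np.random.default_rng(0)
        genomes = [_genome(f"g{i}") for i in range(20)]
        hits = []
        k = 0
        for g in genomes:
            for _ in range(rng.poisson(1.5)):
                hits.append(_hit(f"h{k}", g.genome_id))
                k += 1
        (summary,) = group_summary(hits, genomes, lambda g: "all")
        for freq, ab in summary.per_type.values():
            assert ab >= freq

    def test_whole_cohort_as_one_group_conserves_totals(self):
        genomes = [_genome(f"g{i}", genus=f"G{i % 3}") for i in range(9)]
        hits = [_hit(f"h{i}", f"g{i % 9}", system_type=f"S{i % 2}") for i in range(30)]
        per_genus = group_summary(hits, genomes, lambda g: g.genus)
        (pooled,) = group_summary(hits, genomes, lambda g: "all")
        for system_type in ("S0", "S1"):
            total = sum(
                s.per_type[system_type][1] * s.n_genomes for s in per_genus
            )
            assert total == pytest.approx(
                pooled.per_type[system_type][1] * pooled.n_genomes
            )


class TestDefenseGenomeFraction:
    def test_simple_arithmetic(self):
        genomes = [_genome("g1", length=1_000_000)]
        hits = [_hit("h1", "g1", genes=[(0, 5_900)])]
        frac = defense_genome_fraction(hits, genomes)
        assert frac["g1"] == pytest.approx(0.0059)

    def test_no_hits_zero(self):
        assert defense_genome_fraction([], [_genome("g1")]) == {"g1": 0.0}

    def test_overlapping_genes_merged_before_summing(self):
        genomes = [_genome("g1", length=1000)]
        hits = [
            _hit("h1", "g1", genes=[(0, 100)]),
            _hit("h2", "g1", genes=[(50, 150)]),
        ]
        frac = defense_genome_fraction(hits, genomes)
        assert frac["g1"] == pytest.approx(150 / 1000)

    def test_bgc_hits_do_not_count(self):
        genomes = [_genome("g1", length=1000)]
        bgc = SystemHit(
            "b1", "g1", "g1_chr", "bgc", "T1PKS", [GeneLocus(0, 500)]
        )
        assert defense_genome_fraction([bgc], genomes)["g1"] == 0.0


class TestDetectIslands:
    def test_twelve_intervening_chains_into_one_island(self):
        hits = [
            _hit("h1", "g1", genes=[(10_000, 12_500)], indices=[10]),
            _hit("h2", "g1", genes=[(25_000, 27_500)], indices=[25]),
        ]
        # gene ordinals 10-12 and 25-27 once each hit's genes are expanded
        hits[0].genes = [GeneLocus(i * 1000, i * 1000 + 900, gene_index=i) for i in (10, 11, 12)]
        hits[1].genes = [GeneLocus(i * 1000, i * 1000 + 900, gene_index=i) for i in (25, 26, 27)]
        islands = detect_islands(hits, max_intervening=20)
        assert len(islands) == 1
        assert islands[0].member_hit_ids == ["h1", "h2"]
        assert islands[0].span == (10_000, 27_900)

    def test_twenty_seven_intervening_stays_apart(self):
        hits = [_hit("h1", "g1"), _hit("h2", "g1")]
        hits[0].genes = [GeneLocus(i * 1000, i * 1000 + 900, gene_index=i) for i in (10, 11, 12)]
        hits[1].genes = [GeneLocus(i * 1000, i * 1000 + 900, gene_index=i) for i in (40, 41)]
        assert detect_islands(hits, max_intervening=20) == []

    def test_single_system_no_island(self):
        assert detect_islands([_hit("h1", "g1", indices=[5])]) == []

    def test_missing_gene_index_instructs_caller(self):
        with pytest.raises(ValidationError, match="gene_index"):
            detect_islands([_hit("h1", "g1"), _hit("h2", "g1")])

    def test_mixed_replicons_rejected(self):
        with pytest.raises(ValidationError, match="single replicon"):
            detect_islands([_hit("h1", "g1", indices=[1]), _hit("h2", "g2", indices=[2])])

    @given(st.data())
    def test_chaining_matches_pairwise_transitive_closure(self, data):
        """Island membership is the connected-component closure of the
        pairwise fewer-than-k-intervening criterion."""
        n = data.draw(st.integers(2, 8))
        spans = []
        for _ in range(n):
            lo = data.draw(st.integers(0, 120))
            hi = lo + data.draw(st.integers(0, 5))
            spans.append((lo, hi))
        k = data.draw(st.integers(1, 30))
        hits = []
        for idx, (lo, hi) in enumerate(spans):
            genes = [
                GeneLocus(j * 1000, j * 1000 + 900, gene_index=j)
                for j in range(lo, hi + 1)
            ]
            hits.append(SystemHit(f"h{idx}", "g1", "g1_chr", "defence", "RM", genes))

        # oracle: union-find over all pairs
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                (lo_i, hi_i), (lo_j, hi_j) = spans[i], spans[j]
                if lo_i <= lo_j:
                    gap = lo_j - hi_i - 1
                else:
                    gap = lo_i - hi_j - 1
                if gap < k:
                    parent[find(i)] = find(j)
        components = {}
        for i in range(n):
            components.setdefault(find(i), set()).add(f"h{i}")
        expected = {
            frozenset(m) for m in components.values() if len(m) >= 2
        }

        islands = detect_islands(hits, max_intervening=k)
        got = {frozenset(isl.member_hit_ids) for isl in islands}
        assert got == expected
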