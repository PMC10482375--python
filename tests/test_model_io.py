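"""Domain types, TSV/BED/Newick round trips, and interval normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phagearsenal import io as paio
from phagearsenal.model import (
    GeneLocus,
    GenomeMetadata,
    IntervalSet,
    RepliconMetadata,
    SchemaError,
    SystemHit,
    ValidationError,
    merge_intervals,
    validate_hits,
)


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


HIT_HEADER = "hit_id\tgenome_id\treplicon_id\tcategory\tsystem_type\tsubtype\tgene_start\tgene_end\tstrand\tgene_gc\tgene_index\n"


class TestHitTable:
    def test_two_row_hit_parses_to_one_system_with_two_genes(self, tmp_path):
        path = _write(
            tmp_path,
            "hits.tsv",
            HIT_HEADER
            + "h1\tg1\tr1\tdefence\tRM\t\t100\t400\t+\t0.5\t0\n"
            + "h1\tg1\tr1\tdefence\tRM\t\t500\t900\t-\t0.6\t1\n",
        )
        hits = paio.read_hit_table(path)
        assert len(hits) == 1
        assert len(hits[0].genes) == 2
        assert hits[0].span == (100, 900)
        assert hits[0].system_type == "RM"

    def test_header_only_file_gives_empty_list(self, tmp_path):
        path = _write(tmp_path, "hits.tsv", HIT_HEADER)
        assert paio.read_hit_table(path) == []

    def test_reversed_gene_coordinates_rejected(self, tmp_path):
        path = _write(
            tmp_path,
            "hits.tsv",
            HIT_HEADER + "h1\tg1\tr1\tdefence\tRM\t\t400\t100\t+\t0.5\t0\n",
        )
        with pytest.raises(ValidationError, match="h1"):
            paio.read_hit_table(path)

    def test_missing_column_names_the_column(self, tmp_path):
        path = _write(tmp_path, "hits.tsv", "hit_id\tgenome_id\nh1\tg1\n")
        with pytest.raises(SchemaError, match="replicon_id"):
            paio.read_hit_table(path)

    def test_inconsistent_system_type_within_hit_rejected(self, tmp_path):
        path = _write(
            tmp_path,
            "hits.tsv",
            HIT_HEADER
            + "h1\tg1\tr1\tdefence\tRM\t\t100\t400\t+\t0.5\t0\n"
            + "h1\tg1\tr1\tdefence\tWadjet\t\t500\t900\t+\t0.5\t1\n",
        )
        with pytest.raises(ValidationError, match="system_type"):
            paio.read_hit_table(path)

    def test_gene_outside_replicon_bounds_names_hit(self, tmp_path):
        path = _write(
            tmp_path,
            "hits.tsv",
            HIT_HEADER + "h9\tg1\tr1\tdefence\tRM\t\t100\t4000\t+\t0.5\t0\n",
        )
        rep = RepliconMetadata("r1", "g1", "chromosome", "linear", 2000, 0.5)
        with pytest.raises(ValidationError, match="h9"):
            paio.read_hit_table(path, replicons={"r1": rep})

    def test_round_trip(self, tmp_path):
        hits = [
            SystemHit(
                "h1",
                "g1",
                "r1",
                "defence",
                "RM",
                [GeneLocus(100, 400, "+", 0.51, 3), GeneLocus(500, 900, "-", 0.62, 4)],
            )
        ]
        path = tmp_path / "hits.tsv"
        paio.write_hit_table(hits, path)
        back = paio.read_hit_table(path)
        assert paio.hits_to_frame(back).equals(paio.hits_to_frame(hits))


class TestIntervals:
    def test_overlapping_lines_merge(self, tmp_path):
        path = _write(tmp_path, "p.bed", "r1\t0\t100\nr1\t50\t150\n")
        out = paio.read_intervals(path)
        assert out["r1"].intervals == [(0, 150)]

    def test_two_replicons_two_keys(self, tmp_path):
        path = _write(tmp_path, "p.bed", "r1\t0\t100\nr2\t10\t20\n")
        out = paio.read_intervals(path)
        assert set(out) == {"r1", "r2"}

    def test_empty_interval_rejected(self, tmp_path):
        path = _write(tmp_path, "p.bed", "r1\t100\t100\n")
        with pytest.raises(ValidationError):
            paio.read_intervals(path)

    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 200)).map(
                lambda t: (t[0], t[0] + t[1])
            ),
            min_size=0,
            max_size=30,
        )
    )
    def test_merge_is_sorted_disjoint_and_measure_preserving(self, raw):
        merged = merge_intervals(raw)
        for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
            assert e1 < s2  # sorted and strictly disjoint
        # the union measure equals a per-base oracle
        covered = set()
        for s, e in raw:
            covered.update(range(s, e))
        assert sum(e - s for s, e in merged) == len(covered)

    def test_interval_set_overlap_matches_per_base_count(self):
        ivs = IntervalSet("r1", [(0, 100), (200, 300)])
        assert ivs.overlap(50, 250) == 50 + 50
        assert ivs.overlap(100, 200) == 0  # half-open: touching is no overlap


class TestTrees:
    def test_two_leaf_tree(self, tmp_path):
        path = _write(tmp_path, "t.nwk", "(A:1,B:1);\n")
        tree = paio.read_tree(path)
        leaves = list(tree.leaf_node_iter())
        assert sorted(l.taxon.label for l in leaves) == ["A", "B"]
        assert all(l.edge.length == 1 for l in leaves)

    def test_root_to_leaf_depth_is_path_sum(self, tmp_path):
        path = _write(tmp_path, "t.nwk", "((A:1,B:1):1,C:2);\n")
        tree = paio.read_tree(path)
        tree.calc_node_root_distances(return_leaf_distances_only=False)
        depths = {l.taxon.label: l.root_distance for l in tree.leaf_node_iter()}
        assert depths == {"A": 2.0, "B": 2.0, "C": 2.0}

    def test_duplicate_labels_rejected(self, tmp_path):
        path = _write(tmp_path, "t.nwk", "(A:1,A:1);\n")
        with pytest.raises(ValidationError, match="duplicate"):
            paio.read_tree(path)

    def test_unparseable_tree_rejected(self, tmp_path):
        path = _write(tmp_path, "t.nwk", "(A:1,B:1\n")
        with pytest.raises(SchemaError):
            paio.read_tree(path)

    def test_negative_branch_length_rejected(self, tmp_path):
        path = _write(tmp_path, "t.nwk", "(A:1,B:-0.5);\n")
        with pytest.raises(ValidationError, match="negative"):
            paio.read_tree(path)


class TestResultsRoundTrip:
    def test_round_trip_integers_exact_reals_12_digits(self, tmp_path):
        df = pd.DataFrame(
            {
                "system_type": ["RM", "Wadjet"],
                "n": [12, 7],
                "estimator": [-1.234567890123456, 0.3333333333333333],
            }
        )
        path = tmp_path / "out.tsv"
        paio.write_results(df, path, header="unit test")
        back = paio.read_results(path)
        assert list(back["n"]) == [12, 7]
        np.testing.assert_allclose(back["estimator"], df["estimator"], rtol=1e-11)

    def test_empty_table_writes_header_only(self, tmp_path):
        df = pd.DataFrame(columns=["a", "b"])
        path = tmp_path / "out.tsv"
        paio.write_results(df, path)
        back = paio.read_results(path)
        assert list(back.columns) == ["a", "b"] and back.empty


class TestDomainInvariants:
    def test_genome_needs_replicons(self):
        with pytest.raises(ValidationError):
            GenomeMetadata("g1", "P", "G", "s", replicons=[])

    def test_gc_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            RepliconMetadata("r1", "g1", "chromosome", "linear", 100, 1.5)

    def test_validate_hits_cross_references_cohort(self):
        rep = RepliconMetadata("r1", "g1", "chromosome", "linear", 1000, 0.5)
        genome = GenomeMetadata("g1", "P", "G", "s", [rep])
        good = SystemHit("h1", "g1", "r1", "defence", "RM", [GeneLocus(0, 500)])
        validate_hits([good], [genome])
        orphan = SystemHit("h2", "gX", "r1", "defence", "RM", [GeneLocus(0, 500)])
        with pytest.raises(ValidationError, match="h2"):
            validate_hits([orphan], [genome])
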