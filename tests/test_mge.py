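"""MGE attribution rules, contribution fractions, GC scores."""

import numpy as np
import pytest
from scipy import stats

from phagearsenal.cohort import CohortSpec, SystemSpec, simulate_cohort
from phagearsenal.mge import (
    LocationCall,
    attribute_all,
    attribute_location,
    frequency_vs_mge,
    gc_score,
    mge_contribution,
    round_half_up,
)
from phagearsenal.model import (
    GeneLocus,
    IntervalSet,
    RepliconMetadata,
    SystemHit,
    ValidationError,
)


def _replicon(rid="r1", rtype="chromosome", length=100_000, gc=0.7):
    return RepliconMetadata(rid, "g1", rtype, "linear", length, gc)


def _defence(genes, rid="r1"):
    return SystemHit("h1", "g1", rid, "defence", "RM", [GeneLocus(s, e) for s, e in genes])


def _bgc(genes, rid="r1"):
    return SystemHit("b1", "g1", rid, "bgc", "T1PKS", [GeneLocus(s, e) for s, e in genes])


class TestAttributeLocation:
    def test_defence_partial_gene_overlap_is_prophage(self):
        hit = _defence([(100, 400), (500, 900)])
        call = attribute_location(hit, _replicon(), IntervalSet("r1", [(850, 2000)]))
        assert call.location == "prophage"
        assert call.prophage_overlap_bp == 50

    def test_bgc_under_half_coverage_is_not_prophage(self):
        call = attribute_location(
            _bgc([(0, 1000)]), _replicon(), IntervalSet("r1", [(0, 499)])
        )
        assert call.location == "chromosome"
        assert call.overlap_fraction == pytest.approx(0.499)

    def test_bgc_exactly_half_coverage_is_prophage(self):
        call = attribute_location(
            _bgc([(0, 1000)]), _replicon(), IntervalSet("r1", [(0, 500)])
        )
        assert call.location == "prophage"
        assert call.overlap_fraction == pytest.approx(0.5)

    def test_plasmid_without_prophage(self):
        call = attribute_location(
            _defence([(100, 400)]), _replicon(rtype="plasmid"), None
        )
        assert call.location == "plasmid"

    def test_prophage_takes_precedence_over_plasmid(self):
        call = attribute_location(
            _defence([(100, 400)]),
            _replicon(rtype="plasmid"),
            IntervalSet("r1", [(0, 500)]),
        )
        assert call.location == "prophage"

    def test_touching_gene_is_not_overlap(self):
        # half-open arithmetic: gene [100,400) and prophage [400,900) share 0 bp
        call = attribute_location(
            _defence([(100, 400)]), _replicon(), IntervalSet("r1", [(400, 900)])
        )
        assert call.location == "chromosome"

    def test_replicon_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            attribute_location(_defence([(0, 10)], rid="rX"), _replicon(), None)


class TestMgeContribution:
    def _calls(self, chromosome, plasmid, prophage, system_type="X"):
        calls = []
        for loc, n in (
            ("chromosome", chromosome),
            ("plasmid", plasmid),
            ("prophage", prophage),
        ):
            for i in range(n):
                calls.append(
                    LocationCall(f"{loc}{i}", system_type, "defence", loc, 0, 0.0)
                )
        return calls

    def test_simple_counting(self):
        df = mge_contribution(self._calls(7, 2, 1))
        row = df.iloc[0]
        assert (
            row["fraction_chromosome"],
            row["fraction_plasmid"],
            row["fraction_prophage"],
        ) == (0.7, 0.2, 0.1)
        assert row["n_total"] == 10

    def test_all_chromosome(self):
        row = mge_contribution(self._calls(5, 0, 0)).iloc[0]
        assert row["fraction_chromosome"] == 1.0
        assert row["fraction_plasmid"] == 0.0 and row["fraction_prophage"] == 0.0

    def test_fractions_sum_to_one_exactly(self):
        rng = np.random.default_rng(0)
        calls = []
        for t in range(5):
            c, p, v = rng.integers(1, 50, size=3)
            calls += self._calls(int(c), int(p), int(v), system_type=f"S{t}")
        df = mge_contribution(calls)
        totals = (
            df["fraction_chromosome"] + df["fraction_plasmid"] + df["fraction_prophage"]
        )
        assert np.all(np.abs(totals - 1.0) < 1e-12)

    def test_round_half_up_matches_reporting_convention(self):
        assert round_half_up(3.35, 1) == 3.4
        assert round_half_up(2.04, 1) == 2.0
        assert round_half_up(100 * 469 / 13833, 1) == 3.4


class TestGcScore:
    def test_low_gc_gene_flagged(self):
        hit = SystemHit(
            "h1", "g1", "r1", "defence", "RM", [GeneLocus(0, 100, gc=0.35)]
        )
        score = gc_score(hit, _replicon(gc=0.70))
        assert score.mean_score == pytest.approx(0.5)
        assert score.low_gc_flag

    def test_matching_gc_scores_one(self):
        hit = SystemHit(
            "h1", "g1", "r1", "defence", "RM", [GeneLocus(0, 100, gc=0.70)]
        )
        score = gc_score(hit, _replicon(gc=0.70))
        assert score.mean_score == pytest.approx(1.0)
        assert not score.low_gc_flag

    def test_mean_over_genes(self):
        hit = SystemHit(
            "h1",
            "g1",
            "r1",
            "defence",
            "RM",
            [GeneLocus(0, 100, gc=0.6), GeneLocus(200, 300, gc=0.8)],
        )
        score = gc_score(hit, _replicon(gc=0.7))
        assert score.gene_scores == pytest.approx([0.6 / 0.7, 0.8 / 0.7])
        assert score.mean_score == pytest.approx(1.0)

    def test_zero_gc_replicon_rejected(self):
        hit = SystemHit("h1", "g1", "r1", "defence", "RM", [GeneLocus(0, 100)])
        with pytest.raises(ValidationError):
            gc_score(hit, _replicon(gc=0.0))


class TestFrequencyVsMge:
    def test_fully_chromosomal_type_has_zero_mge_fraction(self):
        spec = CohortSpec(
            seed=0,
            n_genomes_in=20,
            n_genomes_out=0,
            system_specs=[SystemSpec("RM", 1.0, 0.0, copies_model="bernoulli")],
            prophage_rate=0.0,
            plasmid_prob=0.0,
        )
        cohort = simulate_cohort(spec)
        df = frequency_vs_mge(cohort.hits, cohort.genomes, cohort.prophages)
        assert (df["frequency_in_genus"] == 1.0).all()
        assert (df["mge_fraction"] == 0.0).all()

    def test_planted_rare_mobile_types_give_negative_correlation(self):
        """Rare types planted with high MGE carriage, common types fully
        chromosomal: frequency and MGE fraction correlate negatively."""
        rhos = []
        for seed in range(5):
            spec = CohortSpec(
                seed=seed,
                n_genomes_in=60,
                n_genomes_out=0,
                system_specs=[
                    SystemSpec("Common1", 0.9, 0.0, copies_model="bernoulli"),
                    SystemSpec("Common2", 0.8, 0.0, copies_model="bernoulli"),
                    SystemSpec("Rare1", 0.15, 0.0, mge_prob=0.8),
                    SystemSpec("Rare2", 0.15, 0.0, mge_prob=0.8),
                ],
                prophage_rate=3.0,
                plasmid_prob=0.6,
            )
            cohort = simulate_cohort(spec)
            df = frequency_vs_mge(cohort.hits, cohort.genomes, cohort.prophages)
            rho, _ = stats.spearmanr(df["frequency_in_genus"], df["mge_fraction"])
            rhos.append(rho)
        assert np.mean(rhos) < 0

    def test_empty_cohort_gives_no_rows(self):
        spec = CohortSpec(
            seed=0,
            n_genomes_in=5,
            n_genomes_out=0,
            system_specs=[SystemSpec("RM", 0.0, 0.0)],
        )
        cohort = simulate_cohort(spec)
        df = frequency_vs_mge(cohort.hits, cohort.genomes, cohort.prophages)
        assert df.empty


class TestPlantedMgeRecovery:
    def test_designated_copies_are_attributed_to_mges(self):
        spec = CohortSpec(
            seed=21,
            n_genomes_in=80,
            n_genomes_out=0,
            system_specs=[SystemSpec("Mob", 2.0, 0.0, mge_prob=0.5)],
            prophage_rate=3.0,
            plasmid_prob=0.5,
        )
        cohort = simulate_cohort(spec)
        calls = {c.hit_id: c for c in attribute_all(cohort.hits, cohort.genomes, cohort.prophages)}
        truth = cohort.truth
        designated = truth[truth["designated_mge"]]["hit_id"]
        attributed = sum(
            calls[h].location in ("plasmid", "prophage") for h in designated
        )
        assert attributed / len(designated) >= 0.95
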