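"""Scoring unit tests on hand-built hits plus end-to-end invariants."""

import pytest

from probemap.core import MODERATE, STRONG, WEAK, AlignmentHit, PlatformParams
from probemap.scoring import (
    coverage_score,
    detected_transcripts,
    overall_score,
    processivity_requirement,
    robustness_score,
    score_probeset,
    specific_genes_of_probe,
    specificity_score,
    survival_probability,
    targeted_gene,
)

from conftest import make_db, make_probeset


def hit(probe_id, tid, tier, t_start=1, probeset_id=None):
    raw = {STRONG: 25, MODERATE: 20, WEAK: 12}[tier]
    return AlignmentHit(
        probe_id=probe_id,
        probeset_id=probeset_id or probe_id.split(":", 1)[0],
        transcript_id=tid,
        raw_score=raw,
        bit_score=2 * raw,
        t_start=t_start,
        t_end=t_start + 24,
        strand="+",
        tier=tier,
    )


@pytest.fixture()
def db2():
    return make_db(
        {
            "tA1": (1000, "geneA"),
            "tA2": (900, "geneA"),
            "tB1": (1000, "geneB"),
        }
    )


class TestSpecificity:
    def test_strong_to_one_gene_is_specific(self, db2):
        hits = [hit("ps:1", "tA1", STRONG)]
        assert specific_genes_of_probe(hits, db2) == {"geneA"}

    def test_moderate_elsewhere_disqualifies(self, db2):
        hits = [hit("ps:1", "tA1", STRONG), hit("ps:1", "tB1", MODERATE)]
        assert specific_genes_of_probe(hits, db2) == set()

    def test_two_strong_genes_disqualify_each_other(self, db2):
        hits = [hit("ps:1", "tA1", STRONG), hit("ps:1", "tB1", STRONG)]
        assert specific_genes_of_probe(hits, db2) == set()

    def test_moderate_to_same_gene_is_harmless(self, db2):
        hits = [hit("ps:1", "tA1", STRONG), hit("ps:1", "tA2", MODERATE)]
        assert specific_genes_of_probe(hits, db2) == {"geneA"}

    def test_weak_hits_never_count(self, db2):
        hits = [hit("ps:1", "tA1", STRONG), hit("ps:1", "tB1", WEAK)]
        assert specific_genes_of_probe(hits, db2) == {"geneA"}

    @pytest.mark.parametrize("n_specific, expected", [(10, 10 / 11), (3, 3 / 11), (0, 0.0)])
    def test_specificity_fraction(self, db2, n_specific, expected):
        ps = make_probeset("ps", ["ACGTA" * 5] * 11)
        hits = [hit(f"ps:{i}", "tA1", STRONG) for i in range(1, n_specific + 1)]
        # remaining probes cross-hybridize and are specific for nothing
        hits += [hit(f"ps:{i}", "tA1", STRONG) for i in range(n_specific + 1, 12)]
        hits += [hit(f"ps:{i}", "tB1", MODERATE) for i in range(n_specific + 1, 12)]
        assert specificity_score(ps, hits, db2) == pytest.approx(expected)


class TestTargetedGene:
    def test_majority_wins(self, db2):
        ps = make_probeset("ps", ["ACGTA" * 5] * 11)
        hits = [hit(f"ps:{i}", "tA1", STRONG) for i in range(1, 11)]
        assert targeted_gene(ps, hits, db2) == ("geneA", False)

    def test_tie_breaks_lexicographically_and_flags(self, db2):
        ps = make_probeset("ps", ["ACGTA" * 5] * 10)
        hits = [hit(f"ps:{i}", "tA1", STRONG) for i in range(1, 6)]
        hits += [hit(f"ps:{i}", "tB1", STRONG) for i in range(6, 11)]
        assert targeted_gene(ps, hits, db2) == ("geneA", True)

    def test_no_specific_probe_gives_none(self, db2):
        ps = make_probeset("ps", ["ACGTA" * 5] * 11)
        hits = [hit(f"ps:{i}", "tA1", STRONG) for i in range(1, 12)]
        hits += [hit(f"ps:{i}", "tB1", MODERATE) for i in range(1, 12)]
        assert targeted_gene(ps, hits, db2) == (None, False)


class TestCoverage:
    @pytest.mark.parametrize("n_strong, detected", [(11, True), (6, True), (5, False)])
    def test_strict_majority_rule(self, db2, n_strong, detected):
        ps = make_probeset("ps", ["ACGTA" * 5] * 11)
        hits = [hit(f"ps:{i}", "tA1", STRONG) for i in range(1, n_strong + 1)]
        got = detected_transcripts(ps, "geneA", hits, db2)
        assert ("tA1" in got) is detected

    def test_fraction_of_isoforms(self, db2):
        ps = make_probeset("ps", ["ACGTA" * 5] * 11)
        hits = [hit(f"ps:{i}", "tA1", STRONG) for i in range(1, 12)]
        assert coverage_score(ps, "geneA", hits, db2) == pytest.approx(0.5)
        assert coverage_score(ps, None, hits, db2) == 0.0


class TestRobustness:
    @pytest.mark.parametrize(
        "length, t_start, expected", [(1000, 976, 25), (1000, 101, 900), (25, 1, 25)]
    )
    def test_processivity_requirement(self, length, t_start, expected):
        db = make_db({"t": (length, "g")})
        h = hit("ps:1", "t", STRONG, t_start=t_start)
        assert processivity_requirement(h, db) == expected

    def test_survival_matches_printed_value(self):
        """(1 - 1/600)^268 is the 0.64 robustness printed for the best
        estrogen-receptor probe set."""
        assert survival_probability(268, 1 / 600) == pytest.approx(0.64, abs=0.005)

    def test_survival_limits_and_monotonicity(self):
        assert survival_probability(0, 1 / 600) == 1.0
        for n in (1, 10, 500):
            assert survival_probability(n + 1, 1 / 600) < survival_probability(n, 1 / 600)
            assert survival_probability(n, 1 / 300) < survival_probability(n, 1 / 600)

    def test_even_count_median(self):
        db = make_db({"t": (1000, "g")})
        ps = make_probeset("ps", ["ACGTA" * 5] * 4)
        starts = [1000 - r + 1 for r in (100, 200, 300, 400)]
        hits = [hit(f"ps:{i + 1}", "t", STRONG, t_start=s) for i, s in enumerate(starts)]
        n, s_r = robustness_score(ps, "g", hits, db, PlatformParams())
        assert n == 250
        assert s_r == pytest.approx(survival_probability(250, 1 / 600))

    def test_no_strong_hits(self, db2):
        ps = make_probeset("ps", ["ACGTA" * 5] * 11)
        assert robustness_score(ps, "geneA", [], db2) == (None, 0.0)


class TestOverall:
    def test_product(self):
        assert overall_score(10 / 11, 1.0, 0.64) == pytest.approx(0.5818, abs=1e-4)

    def test_annihilator_and_identity(self):
        assert overall_score(0.91, 0.0, 0.64) == 0.0
        assert overall_score(1.0, 1.0, 1.0) == 1.0


class TestScoreProbeset:
    def test_no_hits_anywhere(self, db2):
        ps = make_probeset("ps", ["ACGTA" * 5] * 11)
        s = score_probeset(ps, [], db2)
        assert s.targeted_gene is None
        assert (s.specificity, s.coverage, s.robustness, s.overall) == (0, 0, 0, 0)
        assert s.proc_requirement is None

    def test_product_invariant_and_bound(self, bundle7):
        from probemap.align import search_all
        from probemap.scoring import score_all

        hits = search_all(list(bundle7.probesets), bundle7.db)
        for s in score_all(list(bundle7.probesets), hits, bundle7.db):
            assert s.overall == s.specificity * s.coverage * s.robustness
            assert s.overall <= min(s.specificity, s.coverage, s.robustness)

    def test_invariant_under_hit_permutation(self, bundle7):
        from probemap.align import search_all

        ps = next(p for p in bundle7.probesets if "cross" in p.probeset_id)
        hits = search_all([ps], bundle7.db)
        assert score_probeset(ps, hits, bundle7.db) == score_probeset(
            ps, hits[::-1], bundle7.db
        )
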