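"""Aligner unit and property tests: calibration, planted cases, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from probemap.align import best_local_alignment, bits, classify_bits, search_all
from probemap.core import MODERATE, STRONG, WEAK, ScoringParams, TranscriptDB, revcomp

from oracle import enumerate_best, oracle_best, random_instance

PARAMS = ScoringParams()


class TestBits:
    @pytest.mark.parametrize(
        "raw, expected",
        [(24, 48.067), (16, 32.209), (15, 30.226), (0, 0.492)],
    )
    def test_closed_form(self, raw, expected):
        assert bits(raw, PARAMS) == pytest.approx(expected, abs=1e-3)

    @given(st.integers(min_value=0, max_value=100))
    @settings(derandomize=True, max_examples=50)
    def test_strictly_increasing(self, raw):
        assert bits(raw + 1, PARAMS) > bits(raw, PARAMS)


class TestClassify:
    @pytest.mark.parametrize(
        "raw, tier",
        [(25, STRONG), (24, STRONG), (23, MODERATE), (16, MODERATE), (15, WEAK)],
    )
    def test_length_tier_correspondence(self, raw, tier):
        """Perfect n-mer raw scores land in the tiers their lengths imply."""
        assert classify_bits(bits(raw, PARAMS), PARAMS) == tier

    def test_boundaries_are_inclusive(self):
        assert classify_bits(48.0, PARAMS) == STRONG
        assert classify_bits(47.999, PARAMS) == MODERATE
        assert classify_bits(32.0, PARAMS) == MODERATE
        assert classify_bits(31.999, PARAMS) == WEAK

    def test_miscalibrated_lambda_rejected(self):
        """Truncating lambda to 1.37 drops a perfect 24-mer below 48 bits."""
        with pytest.raises(ValueError):
            ScoringParams(lambda_u=1.37)


def _plant(rng, probe, n, at):
    t = list("".join(rng.choice(list("ACGT"), size=n)))
    t[at : at + len(probe)] = probe
    return "".join(t)


class TestBestLocalAlignment:
    def test_planted_exact_match(self, rng):
        probe = "".join(rng.choice(list("ACGT"), size=25))
        transcript = _plant(rng, probe, 400, 100)  # 1-based 101..125
        hit = best_local_alignment(probe, transcript, PARAMS)
        oracle = oracle_best(probe, transcript)
        assert (hit.raw_score, hit.t_start, hit.t_end, hit.strand) == oracle
        assert hit.raw_score == 25
        assert (hit.t_start, hit.t_end) == (101, 125)
        assert hit.strand == "+"
        assert hit.tier == STRONG

    def test_central_mismatch_keeps_whole_block(self, rng):
        """One mismatch costs 3: the full 25-base block (raw 21) still beats
        either flank alone, landing in the moderate tier."""
        probe = "".join(rng.choice(list("ACGT"), size=25))
        transcript = _plant(rng, probe, 300, 50)
        mutated = list(probe)
        mutated[12] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[12]]
        hit = best_local_alignment("".join(mutated), transcript, PARAMS)
        oracle = oracle_best("".join(mutated), transcript)
        assert (hit.raw_score, hit.t_start, hit.t_end, hit.strand) == oracle
        assert hit.raw_score == 24 - 3
        assert hit.tier == MODERATE

    def test_reverse_complement_symmetry(self, rng):
        probe = "".join(rng.choice(list("ACGT"), size=25))
        transcript = _plant(rng, probe, 400, 150)
        fwd = best_local_alignment(probe, transcript, PARAMS)
        rev = best_local_alignment(revcomp(probe), transcript, PARAMS)
        assert rev.raw_score == fwd.raw_score == 25
        assert (rev.t_start, rev.t_end) == (fwd.t_start, fwd.t_end)
        assert fwd.strand == "+" and rev.strand == "-"

    def test_no_seed_returns_none(self):
        probe = "A" * 25
        transcript = ("A" * 7 + "C") * 12  # longest A-run is 7 < word_size
        assert best_local_alignment(probe, transcript, PARAMS) is None
        assert oracle_best(probe, transcript) is None

    def test_matches_exhaustive_enumeration(self, rng):
        """Aligner, offset-scan oracle and full (offset, start, end)
        enumeration agree on small randomized instances."""
        for _ in range(80):
            probe, transcript = random_instance(rng, max_len=150)
            hit = best_local_alignment(probe, transcript, PARAMS)
            got = None if hit is None else (hit.raw_score, hit.t_start, hit.t_end, hit.strand)
            assert got == oracle_best(probe, transcript)
            assert got == enumerate_best(probe, transcript)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_oracle_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        probe, transcript = random_instance(rng, max_len=300)
        hit = best_local_alignment(probe, transcript, PARAMS)
        got = None if hit is None else (hit.raw_score, hit.t_start, hit.t_end, hit.strand)
        assert got == oracle_best(probe, transcript)


class TestSearchAll:
    def test_planted_specific_probeset(self, bundle7):
        """The ideal archetype hits every isoform of its own gene strongly
        and nothing else above the weak tier."""
        ps = next(p for p in bundle7.probesets if "specific_3prime" in p.probeset_id)
        hits = search_all([ps], bundle7.db)
        strong = [h for h in hits if h.tier == STRONG]
        gene = {bundle7.db.gene_of[h.transcript_id] for h in strong}
        assert len(gene) == 1
        n_iso = len(bundle7.db.transcripts_of(gene.pop()))
        assert len(strong) == ps.n_probes * n_iso
        assert all(h.tier == WEAK for h in hits if h not in strong)

    def test_cross_hybridizer_moderate_hits(self, bundle7):
        """Probes covered by the shared block pick up off-target moderate hits."""
        ps = next(p for p in bundle7.probesets if "cross_hybridizer" in p.probeset_id)
        hits = search_all([ps], bundle7.db)
        own_gene = max(
            set(bundle7.db.gene_of[h.transcript_id] for h in hits if h.tier == STRONG)
        )
        moderate_other = [
            h
            for h in hits
            if h.tier == MODERATE and bundle7.db.gene_of[h.transcript_id] != own_gene
        ]
        assert len(moderate_other) == 5
        for h in moderate_other:
            assert 16 <= h.raw_score <= 23

    def test_invariant_to_transcript_order(self, bundle7):
        ps = list(bundle7.probesets)[:2]
        db = bundle7.db
        reordered = TranscriptDB(
            sequences=dict(reversed(list(db.sequences.items()))),
            gene_of=db.gene_of,
        )
        assert search_all(ps, db) == search_all(ps, reordered)
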