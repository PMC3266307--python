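"""Probe-set quality scores: specificity, coverage, robustness, overall.

Given tier-classified alignment hits, each probe set receives

* a *targeted gene*: the gene specifically detected by the largest number
  of its probes (a probe is specific for a gene when it aligns strongly to
  at least one of the gene's transcripts and has no strong or moderate
  alignment to any other gene);
* a specificity score ``S_s``: the fraction of probes specific for the
  targeted gene;
* a coverage score ``S_c``: the fraction of the targeted gene's transcripts
  detected by the probe set (a transcript is detected when a strict
  majority of probes align strongly to it);
* a robustness score ``S_r = (1 - p)**N``: the probability that in vitro
  transcription synthesizes labeled target far enough from the 3' end to
  reach the probes without interruption, where ``p`` is the per-base
  interruption probability and ``N`` the probe set's median processivity
  requirement over its strong hits to the targeted gene;
* an overall score ``S_o = S_s * S_c * S_r``.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from statistics import median

from .core import (
    MODERATE,
    STRONG,
    AlignmentHit,
    PlatformParams,
    ProbeSet,
    ProbeSetScores,
    TranscriptDB,
)

__all__ = [
    "specific_genes_of_probe",
    "targeted_gene",
    "specificity_score",
    "detected_transcripts",
    "coverage_score",
    "processivity_requirement",
    "survival_probability",
    "robustness_score",
    "overall_score",
    "score_probeset",
    "score_all",
]


def specific_genes_of_probe(
    probe_hits: list[AlignmentHit], db: TranscriptDB
) -> set[str]:
    """Genes a single probe specifically detects (a set of size 0 or 1).

    A gene qualifies when the probe has at least one strong hit to one of
    its transcripts and no strong-or-moderate hit to a transcript of any
    other gene; two genes with strong hits disqualify each other.
    """
    strong = {db.gene_of[h.transcript_id] for h in probe_hits if h.tier == STRONG}
    strong_or_mod = {
        db.gene_of[h.transcript_id]
        for h in probe_hits
        if h.tier in (STRONG, MODERATE)
    }
    return {g for g in strong if not (strong_or_mod - {g})}


def _hits_by_probe(
    probeset: ProbeSet, hits: list[AlignmentHit]
) -> dict[str, list[AlignmentHit]]:
    by_probe: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        if h.probeset_id == probeset.probeset_id:
            by_probe[h.probe_id].append(h)
    return by_probe


def targeted_gene(
    probeset: ProbeSet, hits: list[AlignmentHit], db: TranscriptDB
) -> tuple[str | None, bool]:
    """The gene specifically detected by the most probes, with a tie flag.

    Ties resolve to the lexicographically smallest gene id and are flagged
    ambiguous; when no probe is specific for any gene the result is
    (None, False).
    """
    by_probe = _hits_by_probe(probeset, hits)
    tally: Counter[str] = Counter()
    for probe in probeset.probes:
        for gene in specific_genes_of_probe(by_probe.get(probe.probe_id, []), db):
            tally[gene] += 1
    if not tally:
        return None, False
    top = max(tally.values())
    winners = sorted(g for g, n in tally.items() if n == top)
    return winners[0], len(winners) > 1


def specificity_score(
    probeset: ProbeSet, hits: list[AlignmentHit], db: TranscriptDB
) -> float:
    """Fraction of the probe set's probes specific for its targeted gene."""
    gene, _ = targeted_gene(probeset, hits, db)
    if gene is None:
        return 0.0
    by_probe = _hits_by_probe(probeset, hits)
    n_specific = sum(
        1
        for probe in probeset.probes
        if specific_genes_of_probe(by_probe.get(probe.probe_id, []), db) == {gene}
    )
    return n_specific / probeset.n_probes


def detected_transcripts(
    probeset: ProbeSet, gene: str, hits: list[AlignmentHit], db: TranscriptDB
) -> set[str]:
    """Transcripts of ``gene`` strongly hit by a strict majority of probes."""
    strong_probes: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        if h.probeset_id == probeset.probeset_id and h.tier == STRONG:
            if db.gene_of[h.transcript_id] == gene:
                strong_probes[h.transcript_id].add(h.probe_id)
    half = probeset.n_probes / 2
    return {t for t in db.transcripts_of(gene) if len(strong_probes.get(t, ())) > half}


def coverage_score(
    probeset: ProbeSet, gene: str | None, hits: list[AlignmentHit], db: TranscriptDB
) -> float:
    """Fraction of the targeted gene's transcripts the probe set detects."""
    if gene is None:
        return 0.0
    return len(detected_transcripts(probeset, gene, hits, db)) / len(
        db.transcripts_of(gene)
    )


def processivity_requirement(hit: AlignmentHit, db: TranscriptDB) -> int:
    """Bases of labeled target that IVT must synthesize to reach the probe.

    Synthesis starts at the transcript 3' end, so the requirement is the
    inclusive distance from the alignment's 5'-most transcript base to the
    3' terminus: ``L - t_start + 1``.
    """
    return db.length(hit.transcript_id) - hit.t_start + 1


def survival_probability(n_bases: float, p: float) -> float:
    """Probability that IVT synthesis of ``n_bases`` completes uninterrupted.

    Each base is interrupted independently with probability ``p``, so the
    survival probability is ``(1 - p)**n_bases``; half-integral exponents
    (from even-count medians) are used as-is.
    """
    return (1.0 - p) ** n_bases


def robustness_score(
    probeset: ProbeSet,
    gene: str | None,
    hits: list[AlignmentHit],
    db: TranscriptDB,
    params: PlatformParams = PlatformParams(),
) -> tuple[float | None, float]:
    """(N, S_r): median processivity requirement and survival probability.

    ``N`` is the median over all strong (probe, transcript-of-gene) hits;
    with no strong hits (or no targeted gene) the result is (None, 0.0).
    """
    if gene is None:
        return None, 0.0
    reqs = [
        processivity_requirement(h, db)
        for h in hits
        if h.probeset_id == probeset.probeset_id
        and h.tier == STRONG
        and db.gene_of[h.transcript_id] == gene
    ]
    if not reqs:
        return None, 0.0
    n = median(reqs)
    return n, survival_probability(n, params.p)


def overall_score(specificity: float, coverage: float, robustness: float) -> float:
    """Product of the three component scores."""
    return specificity * coverage * robustness


def score_probeset(
    probeset: ProbeSet,
    hits: list[AlignmentHit],
    db: TranscriptDB,
    params: PlatformParams = PlatformParams(),
) -> ProbeSetScores:
    """All scores for one probe set from its classified hits."""
    gene, ambiguous = targeted_gene(probeset, hits, db)
    s_s = specificity_score(probeset, hits, db)
    s_c = coverage_score(probeset, gene, hits, db)
    n, s_r = robustness_score(probeset, gene, hits, db, params)
    return ProbeSetScores(
        probeset_id=probeset.probeset_id,
        targeted_gene=gene,
        n_probes=probeset.n_probes,
        specificity=s_s,
        coverage=s_c,
        proc_requirement=n,
        robustness=s_r,
        overall=overall_score(s_s, s_c, s_r),
        ambiguous_target=ambiguous,
    )


def score_all(
    probesets: list[ProbeSet],
    hits: list[AlignmentHit],
    db: TranscriptDB,
    params: PlatformParams = PlatformParams(),
) -> list[ProbeSetScores]:
    """Score every probe set; hits are partitioned by probe-set id once."""
    by_set: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        by_set[h.probeset_id].append(h)
    return [
        score_probeset(ps, by_set.get(ps.probeset_id, []), db, params)
        for ps in probesets
    ]
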