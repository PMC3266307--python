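"""Ungapped probe-vs-transcript alignment with bit-score tiers.

Probes are short (25-base) oligos, so the search is a seeded, ungapped
local alignment: a hit exists only where probe and transcript (on either
strand) share a ``word_size`` exact word, and the reported alignment is the
maximum-scoring ungapped block over all offsets with match = +1 and
mismatch = -3.  Raw scores are converted to bits with the Karlin-Altschul
normalization and classified into three affinity tiers:

* strong   (>= 48 bits, >= 24 identical bases): the probe almost certainly
  detects the target;
* moderate ([32, 48) bits, 16-23 identical bases): the probe may or may not
  respond;
* weak     (< 32 bits): unlikely to respond.

Gapped alignment is deliberately out of scope: within a 25-mer a gap costs
more than it can recover at the tier-relevant thresholds.
"""

from __future__ import annotations

import math

import numpy as np

from .core import (
    MODERATE,
    STRONG,
    WEAK,
    AlignmentHit,
    ProbeSet,
    ScoringParams,
    TranscriptDB,
    revcomp,
)

__all__ = [
    "bits",
    "classify_bits",
    "best_local_alignment",
    "search_all",
]


def bits(raw_score: float, params: ScoringParams = ScoringParams()) -> float:
    """Normalized (bit) score of an ungapped raw alignment score.

    ``bits = (lambda * raw - ln K) / ln 2``; strictly increasing in the raw
    score.  With the default calibration a perfect n-mer scores
    approximately 2n bits (24 -> 48.1, 16 -> 32.2).
    """
    return (params.lambda_u * raw_score - math.log(params.k)) / math.log(2)


def raw_from_bits(bit_score: float, params: ScoringParams = ScoringParams()) -> int:
    """Nearest raw score whose bit score equals ``bit_score`` (inverse of bits)."""
    return round((bit_score * math.log(2) + math.log(params.k)) / params.lambda_u)


def classify_bits(bit_score: float, params: ScoringParams = ScoringParams()) -> str:
    """Tier of a bit score: strong (>=48), moderate ([32, 48)) or weak (<32)."""
    if bit_score >= params.strong_min_bits:
        return STRONG
    if bit_score >= params.moderate_min_bits:
        return MODERATE
    return WEAK


def _has_seed(query: str, transcript: str, word_size: int) -> bool:
    """True if query and transcript share an exact word of ``word_size`` bases."""
    for i in range(len(query) - word_size + 1):
        if query[i : i + word_size] in transcript:
            return True
    return False


def _diagonal_scores(query: bytes, transcript: bytes, params: ScoringParams) -> np.ndarray:
    """Match/mismatch scores laid out per diagonal.

    Returns an (m, n_diag) matrix where column j is the diagonal with offset
    ``j - (m - 1)`` and row i is probe position i.  Positions falling outside
    the transcript score as mismatches, which can never improve a block.
    """
    m, n = len(query), len(transcript)
    n_diag = n + m - 1
    q = np.frombuffer(query, dtype=np.uint8)
    pad = np.zeros(m - 1, dtype=np.uint8)  # 0 matches no base
    t = np.concatenate([pad, np.frombuffer(transcript, dtype=np.uint8), pad])
    scores = np.empty((m, n_diag), dtype=np.int32)
    for i in range(m):
        scores[i] = np.where(t[i : i + n_diag] == q[i], params.match, params.mismatch)
    return scores


def _max_block_scores(diag_scores: np.ndarray) -> np.ndarray:
    """Maximum ungapped block score on each diagonal (vectorized Kadane)."""
    m, n_diag = diag_scores.shape
    cur = np.full(n_diag, -(10**9), dtype=np.int64)
    best = np.full(n_diag, -(10**9), dtype=np.int64)
    for i in range(m):
        cur = np.maximum(cur, 0) + diag_scores[i]
        best = np.maximum(best, cur)
    return best


def _earliest_block(vals: np.ndarray, target: int) -> tuple[int, int]:
    """Earliest (start, end) probe-index block on one diagonal summing to ``target``.

    Among blocks achieving the diagonal's maximum score, the one with the
    smallest start is returned, and among those the smallest end.
    """
    prefix = np.concatenate([[0], np.cumsum(vals)])
    # suffix max of prefix[b+1] over b >= a
    suffix_max = np.maximum.accumulate(prefix[1:][::-1])[::-1]
    for a in range(len(vals)):
        if suffix_max[a] - prefix[a] == target:
            for b in range(a, len(vals)):
                if prefix[b + 1] - prefix[a] == target:
                    return a, b
    raise AssertionError("target block score not found on diagonal")


def _best_on_strand(
    query: str, transcript: str, params: ScoringParams
) -> tuple[int, int, int] | None:
    """(raw, t_start, t_end) of the best ungapped block of query vs transcript.

    Ties on raw score resolve to the smallest t_start, then smallest t_end.
    Returns None for empty inputs only; seeding is enforced by the caller.
    """
    m = len(query)
    if m == 0 or not transcript:
        return None
    diag = _diagonal_scores(query.encode(), transcript.encode(), params)
    best = _max_block_scores(diag)
    raw = int(best.max())
    if raw <= 0:  # no positive-scoring block on this strand
        return None
    candidates = []
    for j in np.flatnonzero(best == raw):
        a, b = _earliest_block(diag[:, j], raw)
        offset = int(j) - (m - 1)
        candidates.append((a + offset + 1, b + offset + 1))
    t_start, t_end = min(candidates)
    return raw, t_start, t_end


def best_local_alignment(
    probe: str,
    transcript: str,
    params: ScoringParams = ScoringParams(),
    *,
    probe_id: str = "",
    probeset_id: str = "",
    transcript_id: str = "",
) -> AlignmentHit | None:
    """Best ungapped local alignment of a probe against a transcript.

    Both the probe as given and its reverse complement are searched; the
    strand of the winning block is recorded.  Returns None when neither
    strand shares an exact ``word_size`` word with the transcript (no seed).
    Among equal-scoring blocks the smallest t_start wins, then the smallest
    t_end, then the plus strand.
    """
    fwd = probe
    rev = revcomp(probe)
    if not (
        _has_seed(fwd, transcript, params.word_size)
        or _has_seed(rev, transcript, params.word_size)
    ):
        return None
    best: tuple[int, int, int, int, str] | None = None  # (-raw, t_start, t_end, order, strand)
    for order, (strand, query) in enumerate((("+", fwd), ("-", rev))):
        found = _best_on_strand(query, transcript, params)
        if found is None:
            continue
        raw, t_start, t_end = found
        key = (-raw, t_start, t_end, order, strand)
        if best is None or key < best:
            best = key
    assert best is not None
    raw, t_start, t_end, _, strand = -best[0], best[1], best[2], best[3], best[4]
    bit = bits(raw, params)
    return AlignmentHit(
        probe_id=probe_id,
        probeset_id=probeset_id,
        transcript_id=transcript_id,
        raw_score=raw,
        bit_score=bit,
        t_start=t_start,
        t_end=t_end,
        strand=strand,
        tier=classify_bits(bit, params),
    )


def search_all(
    probesets: list[ProbeSet],
    db: TranscriptDB,
    params: ScoringParams = ScoringParams(),
) -> list[AlignmentHit]:
    """Align every probe against every transcript; one best hit per pair.

    Pairs without a shared ``word_size`` word on either strand produce no
    hit.  Weak-tier hits are retained for diagnostics; downstream consumers
    filter by tier.  The result is sorted by (probeset, probe, transcript)
    and therefore independent of input order.
    """
    hits: list[AlignmentHit] = []
    transcripts = [(tid, db.sequences[tid]) for tid in sorted(db.sequences)]
    for ps in probesets:
        for probe in ps.probes:
            for tid, tseq in transcripts:
                hit = best_local_alignment(
                    probe.sequence,
                    tseq,
                    params,
                    probe_id=probe.probe_id,
                    probeset_id=ps.probeset_id,
                    transcript_id=tid,
                )
                if hit is not None:
                    hits.append(hit)
    hits.sort(key=lambda h: (h.probeset_id, h.probe_id, h.transcript_id))
    return hits
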