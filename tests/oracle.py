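"""Independent brute-force oracles for the ungapped aligner.

``oracle_best`` scans every ungapped offset of probe-vs-transcript (both
strands) with prefix sums, entirely separate from the package's seeded,
diagonal-matrix implementation.  ``enumerate_best`` is a third, even
blunter route — explicit enumeration of every (offset, block-start,
block-end) triple — used at tiny sizes to validate the oracle itself.

Both report (raw, t_start, t_end, strand) of the maximum-scoring block,
resolving ties toward the smallest t_start, then smallest t_end, then the
plus strand, and return None when no ``word_size`` consecutive matches
exist on any offset of either strand.
"""

from __future__ import annotations

MATCH = 1
MISMATCH = -3
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _offset_vals(query: str, transcript: str, offset: int) -> tuple[list[int], int]:
    """Per-position scores along one offset, plus the probe index of the
    first aligned position (block coordinates are probe indices)."""
    m, n = len(query), len(transcript)
    i_lo = max(0, -offset)
    i_hi = min(m, n - offset)
    vals = [
        MATCH if query[i] == transcript[i + offset] else MISMATCH
        for i in range(i_lo, i_hi)
    ]
    return vals, i_lo


def oracle_best(
    probe: str, transcript: str, word_size: int = 8
) -> tuple[int, int, int, str] | None:
    m, n = len(probe), len(transcript)
    best: tuple[int, int, int, int] | None = None  # (-raw, t_start, t_end, order)
    best_strand = "+"
    max_run = 0
    for order, (strand, query) in enumerate((("+", probe), ("-", _revcomp(probe)))):
        for offset in range(-(m - 1), n):
            vals, i_lo = _offset_vals(query, transcript, offset)
            if not vals:
                continue
            # longest run of matches on this offset (seed detection)
            run = 0
            for v in vals:
                run = run + 1 if v == MATCH else 0
                max_run = max(max_run, run)
            # max block via prefix sums, earliest start then earliest end
            prefix = 0
            min_prefix = 0
            min_at = 0
            blk_best = None
            for b, v in enumerate(vals):
                prefix += v
                s = prefix - min_prefix
                if blk_best is None or s > blk_best[0]:
                    blk_best = (s, min_at, b)
                if prefix < min_prefix:
                    min_prefix = prefix
                    min_at = b + 1
            raw, a, b = blk_best
            if raw <= 0:
                continue
            t_start = i_lo + a + offset + 1
            t_end = i_lo + b + offset + 1
            key = (-raw, t_start, t_end, order)
            if best is None or key < best:
                best = key
                best_strand = strand
    if max_run < word_size or best is None:
        return None
    return -best[0], best[1], best[2], best_strand


def enumerate_best(
    probe: str, transcript: str, word_size: int = 8
) -> tuple[int, int, int, str] | None:
    """Every (offset, a, b) triple, explicitly.  Small inputs only."""
    m, n = len(probe), len(transcript)
    best = None
    best_strand = "+"
    max_run = 0
    for order, (strand, query) in enumerate((("+", probe), ("-", _revcomp(probe)))):
        for offset in range(-(m - 1), n):
            vals, i_lo = _offset_vals(query, transcript, offset)
            run = 0
            for v in vals:
                run = run + 1 if v == MATCH else 0
                max_run = max(max_run, run)
            for a in range(len(vals)):
                total = 0
                for b in range(a, len(vals)):
                    total += vals[b]
                    if total <= 0:
                        continue
                    t_start = i_lo + a + offset + 1
                    t_end = i_lo + b + offset + 1
                    key = (-total, t_start, t_end, order)
                    if best is None or key < best:
                        best = key
                        best_strand = strand
    if max_run < word_size or best is None:
        return None
    return -best[0], best[1], best[2], best_strand


def random_instance(rng, max_len: int = 2000):
    """A randomized probe/transcript pair mixing planted and chance cases."""
    n = int(rng.integers(50, max_len + 1))
    transcript = "".join(rng.choice(list("ACGT"), size=n))
    mode = rng.integers(5)
    m = int(rng.integers(18, 26))
    if mode == 0 or n < m + 2:  # unrelated probe: usually no seed
        probe = "".join(rng.choice(list("ACGT"), size=m))
        return probe, transcript
    start = int(rng.integers(0, n - m))
    probe = transcript[start : start + m]
    if mode == 2:  # mutated copy
        probe = list(probe)
        for _ in range(int(rng.integers(1, 7))):
            i = int(rng.integers(m))
            probe[i] = "ACGT"[int(rng.integers(4))]
        probe = "".join(probe)
    elif mode == 3:  # reverse-complement planting
        probe = _revcomp(probe)
    elif mode == 4:  # second, mutated copy elsewhere
        other = int(rng.integers(0, n - m))
        t = list(transcript)
        copy = list(probe)
        for _ in range(int(rng.integers(0, 5))):
            i = int(rng.integers(m))
            copy[i] = "ACGT"[int(rng.integers(4))]
        t[other : other + m] = copy
        transcript = "".join(t)
    return probe, transcript
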