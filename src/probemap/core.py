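"""Core data structures shared across the pipeline.

The unit of analysis is the *probe set*: a manufacturer-defined group of
(nominally 25-base) DNA probes that is summarized into a single expression
value on 3'-biased Affymetrix expression arrays.  Probe sets are scored
against a reference transcriptome (cDNA sequences plus a transcript→gene
table) and the best-scoring probe set is selected to represent each gene.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

PROBE_LENGTH = 25

STRONG = "strong"
MODERATE = "moderate"
WEAK = "weak"

_DNA = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


class ProbeFormatError(ValueError):
    """Raised when a probe input file violates the expected format."""


class TranscriptomeError(ValueError):
    """Raised when the transcriptome FASTA and gene map are inconsistent."""


@dataclass(frozen=True)
class Probe:
    probe_id: str
    sequence: str


@dataclass(frozen=True)
class ProbeSet:
    """A named, ordered group of probe sequences.

    Sequences must be non-empty uppercase A/C/G/T (ambiguity codes are
    rejected); lengths other than 25 bases are tolerated with a warning
    because the scoring model is calibrated for 25-mers.
    """

    probeset_id: str
    probes: tuple[Probe, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for probe in self.probes:
            if not probe.sequence:
                raise ProbeFormatError(
                    f"probe {probe.probe_id!r} in set {self.probeset_id!r} has an "
                    "empty sequence"
                )
            bad = set(probe.sequence) - _DNA
            if bad:
                raise ProbeFormatError(
                    f"probe {probe.probe_id!r} in set {self.probeset_id!r} contains "
                    f"non-ACGT character(s) {sorted(bad)!r}"
                )
            if len(probe.sequence) != PROBE_LENGTH:
                warnings.warn(
                    f"probe {probe.probe_id!r} in set {self.probeset_id!r} is "
                    f"{len(probe.sequence)} bases, not {PROBE_LENGTH}",
                    stacklevel=2,
                )
            if probe.probe_id in seen:
                raise ProbeFormatError(
                    f"duplicate probe id {probe.probe_id!r} in set {self.probeset_id!r}"
                )
            seen.add(probe.probe_id)

    @property
    def n_probes(self) -> int:
        return len(self.probes)


class TranscriptDB:
    """cDNA sequences (5'→3') plus a transcript→gene assignment.

    Every transcript carries exactly one gene id and every gene has at least
    one transcript; transcripts without a gene assignment are excluded
    upstream, at read time.
    """

    def __init__(self, sequences: dict[str, str], gene_of: dict[str, str]) -> None:
        if set(sequences) != set(gene_of):
            missing = set(sequences) ^ set(gene_of)
            raise TranscriptomeError(
                f"sequence ids and gene-map ids disagree for {sorted(missing)[:5]!r}"
            )
        if not sequences:
            raise TranscriptomeError("empty transcript database")
        self.sequences = dict(sequences)
        self.gene_of = dict(gene_of)
        self._by_gene: dict[str, list[str]] = {}
        for tid in sorted(self.sequences):
            self._by_gene.setdefault(self.gene_of[tid], []).append(tid)

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.sequences

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TranscriptDB):
            return NotImplemented
        return self.sequences == other.sequences and self.gene_of == other.gene_of

    @property
    def genes(self) -> list[str]:
        return sorted(self._by_gene)

    def length(self, transcript_id: str) -> int:
        return len(self.sequences[transcript_id])

    def transcripts_of(self, gene_id: str) -> list[str]:
        return list(self._by_gene[gene_id])


@dataclass(frozen=True)
class AlignmentHit:
    """One probe-vs-transcript ungapped local alignment.

    Coordinates are 1-based inclusive on the transcript with
    ``t_start <= t_end``; ``strand`` is the transcript strand matched by the
    probe sequence as given ('+' as-is, '-' reverse complement).
    """

    probe_id: str
    probeset_id: str
    transcript_id: str
    raw_score: int
    bit_score: float
    t_start: int
    t_end: int
    strand: str
    tier: str


@dataclass(frozen=True)
class ScoringParams:
    """Ungapped alignment scoring and tier calibration.

    ``match``/``mismatch`` follow the BLASTN defaults (+1/-3); ``lambda_u``
    and ``k`` are the Karlin-Altschul parameters for that scheme on uniform
    base composition, so a perfect 24-mer scores just above the 48-bit
    strong threshold and a perfect 16-mer just above the 32-bit moderate
    threshold.  lambda_u must be kept to at least three decimals: 1.37 would
    put a 24-base exact match at 47.9 bits, below the strong tier.
    """

    match: int = 1
    mismatch: int = -3
    lambda_u: float = 1.374
    k: float = 0.711
    word_size: int = 8
    strong_min_bits: float = 48.0
    moderate_min_bits: float = 32.0

    def __post_init__(self) -> None:
        def _bits(raw: int) -> float:
            return (self.lambda_u * raw - math.log(self.k)) / math.log(2)

        ok = (
            _bits(24) >= self.strong_min_bits > _bits(23)
            and _bits(16) >= self.moderate_min_bits > _bits(15)
        )
        if not ok:
            raise ValueError(
                "scoring parameters are mis-calibrated: the 24-base/strong and "
                "16-base/moderate correspondences must hold"
            )


#: Per-base probability that in vitro transcription of the labeled target is
#: interrupted (degradation or polymerase drop-off).  1/600 matches the
#: design criterion of the U95/U133 families; 1/300 matches the X3P array.
PLATFORM_P = {
    "u95": 1 / 600,
    "u133": 1 / 600,
    "u133plus2": 1 / 600,
    "x3p": 1 / 300,
}


@dataclass(frozen=True)
class PlatformParams:
    p: float = 1 / 600

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"interruption probability p must be in (0, 1), got {self.p}")

    @classmethod
    def for_platform(cls, name: str) -> "PlatformParams":
        try:
            return cls(p=PLATFORM_P[name.lower()])
        except KeyError:
            raise ValueError(
                f"unknown platform {name!r}; known: {sorted(PLATFORM_P)}"
            ) from None


@dataclass(frozen=True)
class ProbeSetScores:
    """Specificity, coverage and robustness components for one probe set.

    ``overall`` is the product of the three component scores; when no gene is
    targeted every component is zero and ``proc_requirement`` is None.
    """

    probeset_id: str
    targeted_gene: str | None
    n_probes: int
    specificity: float
    coverage: float
    proc_requirement: float | None
    robustness: float
    overall: float
    ambiguous_target: bool = False

    def __post_init__(self) -> None:
        for name in ("specificity", "coverage", "robustness", "overall"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.targeted_gene is None and self.overall != 0.0:
            raise ValueError("untargeted probe sets must score zero")


@dataclass(frozen=True)
class MappingRow:
    gene_id: str
    probeset_id: str
    overall_score: float
    tie_broken: bool


@dataclass(frozen=True)
class GeneMapping:
    """One-to-one gene → probe-set assignment with tie diagnostics."""

    rows: tuple[MappingRow, ...]

    def __post_init__(self) -> None:
        genes = [r.gene_id for r in self.rows]
        if len(genes) != len(set(genes)):
            raise ValueError("a gene appears more than once in the mapping")
        probesets = [r.probeset_id for r in self.rows]
        if len(probesets) != len(set(probesets)):
            raise ValueError("a probe set represents more than one gene")

    def __len__(self) -> int:
        return len(self.rows)

    def lookup(self, gene_id: str) -> str | None:
        for row in self.rows:
            if row.gene_id == gene_id:
                return row.probeset_id
        return None
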