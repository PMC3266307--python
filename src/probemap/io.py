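"""Readers and writers for the external formats the pipeline touches.

Inputs: Affymetrix probe-tab files (TSV), probe FASTA, cDNA FASTA plus a
transcript→gene table, and 12-column BLAST tabular hits (``-outfmt 6``) for
users who aligned probes externally.  Outputs: a per-probe-set score CSV
and a gene→probe-set mapping TSV.  Every reader/writer pair round-trips.
"""

from __future__ import annotations

import csv
import logging
import re
from pathlib import Path

from Bio import SeqIO

from .core import (
    AlignmentHit,
    GeneMapping,
    MappingRow,
    Probe,
    ProbeFormatError,
    ProbeSet,
    ProbeSetScores,
    ScoringParams,
    TranscriptDB,
    TranscriptomeError,
)
from .align import classify_bits, raw_from_bits
from .select import best_probeset_per_gene

logger = logging.getLogger(__name__)

__all__ = [
    "read_probe_tab",
    "write_probe_tab",
    "read_probe_fasta",
    "write_probe_fasta",
    "read_transcriptome",
    "write_transcriptome",
    "read_blast_tabular",
    "write_scores",
    "read_scores",
    "write_mapping",
    "read_mapping",
]

PROBESET_COLUMN = "Probe Set Name"
SEQUENCE_COLUMN = "Probe Sequence"
X_COLUMN = "Probe X"
Y_COLUMN = "Probe Y"

SCORE_COLUMNS = [
    "probeset_id",
    "targeted_gene",
    "n_probes",
    "specificity",
    "coverage",
    "proc_requirement",
    "robustness",
    "overall",
    "best",
]


def _build_probesets(
    rows: list[tuple[str, str | None, str]], source: str
) -> list[ProbeSet]:
    """Group (probeset_id, probe_id-or-None, sequence) rows preserving order.

    Probe ids are synthesized as ``<probeset_id>:<ordinal>`` (1-based) when
    the source format does not provide them.
    """
    grouped: dict[str, list[tuple[str | None, str]]] = {}
    for ps_id, probe_id, seq in rows:
        grouped.setdefault(ps_id, []).append((probe_id, seq))
    probesets = []
    for ps_id, probes in grouped.items():
        built = tuple(
            Probe(probe_id=pid if pid is not None else f"{ps_id}:{i}", sequence=seq)
            for i, (pid, seq) in enumerate(probes, start=1)
        )
        try:
            probesets.append(ProbeSet(probeset_id=ps_id, probes=built))
        except ProbeFormatError as exc:
            raise ProbeFormatError(f"{source}: {exc}") from None
    return probesets


def read_probe_tab(
    path: str | Path,
    probeset_col: str = PROBESET_COLUMN,
    sequence_col: str = SEQUENCE_COLUMN,
    x_col: str = X_COLUMN,
    y_col: str = Y_COLUMN,
) -> list[ProbeSet]:
    """Read an Affymetrix probe-tab file (TSV with a header line).

    Probes are grouped by the probe-set column preserving file order; when
    X/Y coordinate columns are present the probe id is
    ``<probeset>:<x>:<y>``, otherwise a 1-based ordinal is used.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ProbeFormatError(f"{path}: empty file") from None
        for required in (probeset_col, sequence_col):
            if required not in header:
                raise ProbeFormatError(
                    f"{path}: missing required column {required!r}"
                )
        idx_ps = header.index(probeset_col)
        idx_seq = header.index(sequence_col)
        idx_x = header.index(x_col) if x_col in header else None
        idx_y = header.index(y_col) if y_col in header else None
        rows: list[tuple[str, str | None, str]] = []
        for lineno, record in enumerate(reader, start=2):
            if not record:
                continue
            ps_id = record[idx_ps]
            seq = record[idx_seq]
            if set(seq) - set("ACGT") or not seq:
                raise ProbeFormatError(
                    f"{path}: line {lineno}: sequence {seq!r} is not uppercase ACGT"
                )
            probe_id = None
            if idx_x is not None and idx_y is not None:
                probe_id = f"{ps_id}:{record[idx_x]}:{record[idx_y]}"
            rows.append((ps_id, probe_id, seq))
    return _build_probesets(rows, str(path))


def write_probe_tab(probesets: list[ProbeSet], path: str | Path) -> None:
    """Write probe sets in minimal probe-tab form (name + sequence columns)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([PROBESET_COLUMN, SEQUENCE_COLUMN])
        for ps in probesets:
            for probe in ps.probes:
                writer.writerow([ps.probeset_id, probe.sequence])


DEFAULT_ID_PATTERN = r"^([^:]+):(\S+)"


def read_probe_fasta(
    path: str | Path, id_pattern: str = DEFAULT_ID_PATTERN
) -> list[ProbeSet]:
    """Read probes from FASTA; headers encode probe-set and probe ids.

    ``id_pattern`` is a regex with two capture groups (probe-set id, probe
    index); the default splits on the first ':' as in ``PSa:1``.
    """
    pattern = re.compile(id_pattern)
    rows: list[tuple[str, str | None, str]] = []
    for record in SeqIO.parse(str(path), "fasta"):
        m = pattern.match(record.id)
        if m is None or len(m.groups()) < 2:
            raise ProbeFormatError(
                f"{path}: header {record.id!r} does not match pattern {id_pattern!r}"
            )
        ps_id, probe_idx = m.group(1), m.group(2)
        seq = str(record.seq)
        if set(seq) - set("ACGT") or not seq:
            raise ProbeFormatError(
                f"{path}: record {record.id!r}: sequence is not uppercase ACGT"
            )
        rows.append((ps_id, f"{ps_id}:{probe_idx}", seq))
    return _build_probesets(rows, str(path))


def write_probe_fasta(probesets: list[ProbeSet], path: str | Path) -> None:
    """Write probes as FASTA with ``probeset:ordinal`` headers."""
    with Path(path).open("w") as fh:
        for ps in probesets:
            for i, probe in enumerate(ps.probes, start=1):
                fh.write(f">{ps.probeset_id}:{i}\n{probe.sequence}\n")


def _read_gene_map(path: Path) -> dict[str, str]:
    """Two-column transcript→gene table; a ``transcript_id`` header is optional."""
    gene_of: dict[str, str] = {}
    with path.open(newline="") as fh:
        for lineno, record in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not record:
                continue
            if len(record) < 2:
                raise TranscriptomeError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(record)}"
                )
            if lineno == 1 and record[0] == "transcript_id":
                continue
            gene_of[record[0]] = record[1]
    return gene_of


def read_transcriptome(
    fasta_path: str | Path, gene_map_path: str | Path
) -> TranscriptDB:
    """Read cDNA FASTA and a transcript→gene table into a TranscriptDB.

    The transcript id is the first whitespace-delimited header token.
    Transcripts absent from the gene map can confer neither specificity nor
    coverage and are dropped with a logged count; an empty intersection of
    FASTA and map ids is fatal.
    """
    gene_of = _read_gene_map(Path(gene_map_path))
    sequences: dict[str, str] = {}
    n_total = 0
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        n_total += 1
        if record.id in gene_of:
            sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise TranscriptomeError(
            f"no transcript in {fasta_path} appears in the gene map {gene_map_path}"
        )
    dropped = n_total - len(sequences)
    if dropped:
        logger.warning(
            "dropped %d transcript(s) without a gene assignment", dropped
        )
    return TranscriptDB(
        sequences=sequences,
        gene_of={tid: gene_of[tid] for tid in sequences},
    )


def write_transcriptome(
    db: TranscriptDB, fasta_path: str | Path, gene_map_path: str | Path
) -> None:
    """Write the transcript FASTA and its transcript→gene table."""
    with Path(fasta_path).open("w") as fh:
        for tid in sorted(db.sequences):
            fh.write(f">{tid}\n{db.sequences[tid]}\n")
    with Path(gene_map_path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["transcript_id", "gene_id"])
        for tid in sorted(db.sequences):
            writer.writerow([tid, db.gene_of[tid]])


def read_blast_tabular(
    path: str | Path,
    db: TranscriptDB | None = None,
    params: ScoringParams = ScoringParams(),
) -> list[AlignmentHit]:
    """Ingest 12-column BLAST tabular hits produced by an external aligner.

    The query id must follow the ``probeset:probe`` convention and the
    subject id must be a transcript id; subject start > end marks a
    minus-strand hit (coordinates are normalized to ascending).  Per
    (probe, transcript) pair only the maximum-bit-score row is kept; rows
    whose subject is unknown to ``db`` are skipped with a warning.
    """
    best: dict[tuple[str, str], AlignmentHit] = {}
    n_skipped = 0
    with Path(path).open(newline="") as fh:
        for lineno, record in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not record or record[0].startswith("#"):
                continue
            if len(record) < 12:
                raise ProbeFormatError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(record)}"
                )
            qseqid, sseqid = record[0], record[1]
            try:
                bit_score = float(record[11])
            except ValueError:
                raise ProbeFormatError(
                    f"{path}: line {lineno}: non-numeric bit score {record[11]!r}"
                ) from None
            if db is not None and sseqid not in db:
                n_skipped += 1
                continue
            s_start, s_end = int(record[8]), int(record[9])
            strand = "+" if s_start <= s_end else "-"
            t_start, t_end = min(s_start, s_end), max(s_start, s_end)
            hit = AlignmentHit(
                probe_id=qseqid,
                probeset_id=qseqid.split(":", 1)[0],
                transcript_id=sseqid,
                raw_score=raw_from_bits(bit_score, params),
                bit_score=bit_score,
                t_start=t_start,
                t_end=t_end,
                strand=strand,
                tier=classify_bits(bit_score, params),
            )
            key = (qseqid, sseqid)
            if key not in best or hit.bit_score > best[key].bit_score:
                best[key] = hit
    if n_skipped:
        logger.warning("skipped %d hit row(s) with unknown transcript ids", n_skipped)
    return sorted(
        best.values(), key=lambda h: (h.probeset_id, h.probe_id, h.transcript_id)
    )


def write_scores(scores: list[ProbeSetScores], path: str | Path) -> None:
    """Write the per-probe-set score table as CSV.

    Scores are printed with 4 decimals; ``best`` flags the probe set
    selected for its targeted gene; rows are sorted by probe-set id.
    """
    mapping = best_probeset_per_gene(scores)
    chosen = {row.probeset_id for row in mapping.rows}
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(SCORE_COLUMNS)
        for s in sorted(scores, key=lambda s: s.probeset_id):
            writer.writerow(
                [
                    s.probeset_id,
                    s.targeted_gene if s.targeted_gene is not None else "",
                    s.n_probes,
                    f"{s.specificity:.4f}",
                    f"{s.coverage:.4f}",
                    "" if s.proc_requirement is None else f"{s.proc_requirement:.1f}",
                    f"{s.robustness:.4f}",
                    f"{s.overall:.4f}",
                    s.probeset_id in chosen,
                ]
            )


def read_scores(path: str | Path) -> list[ProbeSetScores]:
    """Read a score CSV back (values at the file's printed precision)."""
    scores = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != SCORE_COLUMNS:
            raise ProbeFormatError(
                f"{path}: unexpected score columns {reader.fieldnames!r}"
            )
        for row in reader:
            scores.append(
                ProbeSetScores(
                    probeset_id=row["probeset_id"],
                    targeted_gene=row["targeted_gene"] or None,
                    n_probes=int(row["n_probes"]),
                    specificity=float(row["specificity"]),
                    coverage=float(row["coverage"]),
                    proc_requirement=(
                        float(row["proc_requirement"])
                        if row["proc_requirement"]
                        else None
                    ),
                    robustness=float(row["robustness"]),
                    overall=float(row["overall"]),
                )
            )
    return scores


def write_mapping(mapping: GeneMapping, path: str | Path) -> None:
    """Write the gene→probe-set mapping as TSV sorted by gene id.

    The overall score is written at full (round-trip) precision.
    """
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", "probeset_id", "overall_score", "tie_broken"])
        for row in sorted(mapping.rows, key=lambda r: r.gene_id):
            writer.writerow(
                [
                    row.gene_id,
                    row.probeset_id,
                    repr(row.overall_score),
                    "true" if row.tie_broken else "false",
                ]
            )


def read_mapping(path: str | Path) -> GeneMapping:
    """Read a mapping TSV written by :func:`write_mapping`."""
    rows = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rows.append(
                MappingRow(
                    gene_id=row["gene_id"],
                    probeset_id=row["probeset_id"],
                    overall_score=float(row["overall_score"]),
                    tie_broken=row["tie_broken"] == "true",
                )
            )
    return GeneMapping(rows=tuple(rows))
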