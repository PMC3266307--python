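"""Synthetic transcriptomes and probe sets with analytically known scores.

The generator emulates the pipeline's input universe — a RefSeq-style cDNA
FASTA with a transcript→gene table, and Affymetrix-style probe sets — at a
scale where every score can be predicted from the construction alone.
Genes carry a few splice isoforms built by sharing a 3'-terminal block
(mimicking alternative 5' starts with a common 3' UTR), and each planted
probe set follows one archetype:

* ``specific_3prime``: probes tiled inside the shared 3' block, close to
  the 3' end — the ideal probe set (S_s = S_c = 1, high S_r);
* ``cross_hybridizer``: as above, but a sub-block of the probe region is
  copied into another gene, so the overlapping probes pick up moderate (or
  strong) off-target alignments and lose specificity;
* ``isoform_partial``: probes sit on a region private to one isoform, so
  only that isoform is detected (S_c = 1/isoforms);
* ``five_prime_shifted``: probes far from the 3' end — a large
  processivity requirement collapses the robustness score;
* ``orphan``: probes drawn from random sequence absent from the
  transcriptome — no targeted gene, all scores zero.

Expected scores are computed directly from the planted coordinates and the
tier rules (never by running the aligner or scorer), so pipeline-vs-expected
comparisons are a genuine end-to-end check.  Rejection sampling guarantees
exactness: any probe whose 16-mers (either strand) occur in the
transcriptome outside the planted loci triggers regeneration, and the bases
flanking a copied cross-hybridization block are forced to mismatch so the
off-target alignment score equals the planted overlap length exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from statistics import median

import numpy as np

from .core import (
    PROBE_LENGTH,
    Probe,
    ProbeSet,
    ProbeSetScores,
    TranscriptDB,
)
from . import io as pio

__all__ = ["ArchetypeSpec", "FixtureSpec", "FixtureBundle", "generate", "write_bundle"]

ARCHETYPES = (
    "specific_3prime",
    "cross_hybridizer",
    "isoform_partial",
    "five_prime_shifted",
    "orphan",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_CHECK_WORD = 16  # shortest exact match that can reach the moderate tier


@dataclass(frozen=True)
class ArchetypeSpec:
    """One planted probe set.

    ``distance_from_3prime`` is the number of transcript bases strictly 3'
    of the probe nearest the 3' end; successive probes shift 5' by
    ``tile_step`` bases.  ``shared_block_len`` (cross_hybridizer only) is
    the length of the block copied into ``cross_target_gene``: 16-23 bases
    produce moderate off-target alignments, >= 24 strong ones.
    """

    archetype: str
    n_probes: int = 11
    distance_from_3prime: int = 100
    tile_step: int = 3
    shared_block_len: int = 20
    cross_target_gene: str | None = None

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.n_probes < 1:
            raise ValueError("n_probes must be positive")
        if self.distance_from_3prime < 0:
            raise ValueError("distance_from_3prime must be >= 0")


def _default_archetypes() -> tuple[ArchetypeSpec, ...]:
    return (
        ArchetypeSpec("specific_3prime"),
        ArchetypeSpec("cross_hybridizer"),
        ArchetypeSpec("isoform_partial"),
        ArchetypeSpec("five_prime_shifted", distance_from_3prime=3000),
        ArchetypeSpec("orphan"),
    )


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for one synthetic platform + transcriptome.

    The defaults mirror U133-class conditions: 11 probes of 25 bases per
    set, p = 1/600, transcripts roughly 0.8-1.4 kb (stretched where an
    archetype needs more room), 2-3 isoforms per gene.  ``n_genes`` counts
    transcriptome genes; genes beyond the probe-bearing archetypes are
    untargeted decoys (the first decoy hosts cross-hybridization targets
    unless an explicit ``cross_target_gene`` is named).
    """

    seed: int
    n_genes: int = 7
    isoforms_per_gene: tuple[int, int] = (2, 3)
    transcript_length: tuple[int, int] = (800, 1400)
    archetypes: tuple[ArchetypeSpec, ...] = field(default_factory=_default_archetypes)
    p: float = 1 / 600

    def __post_init__(self) -> None:
        n_gene_archetypes = sum(1 for a in self.archetypes if a.archetype != "orphan")
        needs_decoy = any(
            a.archetype == "cross_hybridizer" and a.cross_target_gene is None
            for a in self.archetypes
        )
        if self.n_genes < n_gene_archetypes + (1 if needs_decoy else 0):
            raise ValueError(
                "n_genes too small for the requested archetypes (plus a decoy "
                "cross-hybridization target)"
            )
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must be in (0, 1)")
        lo, hi = self.transcript_length
        if not 100 <= lo <= hi:
            raise ValueError("transcript_length range must satisfy 100 <= lo <= hi")


@dataclass(frozen=True)
class FixtureBundle:
    probesets: tuple[ProbeSet, ...]
    db: TranscriptDB
    expected: tuple[ProbeSetScores, ...]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mismatching_base(rng: np.random.Generator, base: str) -> str:
    others = [b for b in "ACGT" if b != base]
    return others[int(rng.integers(len(others)))]


def _probe_block_starts(arch: ArchetypeSpec, block_len: int) -> list[int]:
    """0-based start of each probe inside the shared 3' block (i=0 is 3'-most)."""
    starts = []
    for i in range(arch.n_probes):
        proc = arch.distance_from_3prime + arch.tile_step * i + PROBE_LENGTH
        start = block_len - proc
        if start < 0:
            raise ValueError(
                f"archetype {arch.archetype}: block of {block_len} bases cannot "
                f"hold probe {i} (needs {proc})"
            )
        starts.append(start)
    return starts


def _block_len_for(arch: ArchetypeSpec) -> int:
    span = arch.distance_from_3prime + arch.tile_step * (arch.n_probes - 1) + PROBE_LENGTH
    return span + 10


_DECOY_BLOCK = 200
_MIN_PREFIX = 30


def _isoform_lengths(
    rng: np.random.Generator, n_iso: int, block_len: int, length_range: tuple[int, int]
) -> list[int]:
    lo = max(length_range[0], block_len + _MIN_PREFIX)
    hi = max(length_range[1], lo + 60)
    return [int(rng.integers(lo, hi + 1)) for _ in range(n_iso)]


def generate(spec: FixtureSpec) -> FixtureBundle:
    """Build probe sets, transcriptome and analytically expected scores.

    Deterministic in ``spec.seed``; rejection sampling (regeneration with a
    derived stream) removes any accidental 16-base sharing between a probe
    and a transcript outside the planted loci.
    """
    for attempt in range(50):
        rng = np.random.default_rng([spec.seed % (2**31), attempt])
        bundle = _generate_once(spec, rng)
        if bundle is not None:
            return bundle
    raise RuntimeError(
        "could not generate a collision-free fixture in 50 attempts; "
        "the requested transcriptome is too repetitive for exact expectations"
    )


def _generate_once(spec: FixtureSpec, rng: np.random.Generator) -> FixtureBundle | None:
    indexed = list(enumerate(spec.archetypes))
    gene_archetypes = [(i, a) for i, a in indexed if a.archetype != "orphan"]
    orphans = [(i, a) for i, a in indexed if a.archetype == "orphan"]

    gene_ids = [f"G{i + 1:02d}" for i in range(spec.n_genes)]
    arch_gene = {idx: gene_ids[k] for k, (idx, _) in enumerate(gene_archetypes)}
    decoy_genes = gene_ids[len(gene_archetypes):]

    iso_lo, iso_hi = spec.isoforms_per_gene
    sequences: dict[str, str] = {}
    gene_of: dict[str, str] = {}
    # per gene: 3' block string and per-isoform prefix lengths (None for
    # isoform_partial extras, which share nothing with the probe region)
    blocks: dict[str, str] = {}
    planted_tids: dict[str, list[str]] = {}

    def add_gene(gene: str, block_len: int, partial: bool) -> None:
        n_iso = int(rng.integers(iso_lo, iso_hi + 1))
        block = _random_seq(rng, block_len)
        blocks[gene] = block
        lengths = _isoform_lengths(rng, n_iso, block_len, spec.transcript_length)
        planted_tids[gene] = []
        for k, total in enumerate(lengths, start=1):
            tid = f"{gene}.{k}"
            gene_of[tid] = gene
            if partial and k > 1:
                lo, hi = spec.transcript_length
                sequences[tid] = _random_seq(rng, int(rng.integers(lo, hi + 1)))
            else:
                prefix = _random_seq(rng, total - block_len)
                sequences[tid] = prefix + block
                planted_tids[gene].append(tid)

    for idx, arch in gene_archetypes:
        add_gene(arch_gene[idx], _block_len_for(arch), arch.archetype == "isoform_partial")
    for gene in decoy_genes:
        add_gene(gene, _DECOY_BLOCK, False)

    # probes: exact substrings of each gene's 3' block
    probesets: list[ProbeSet] = []
    probe_meta: dict[str, dict] = {}  # probeset_id -> plumbing for validation/expected

    def ps_id(idx: int, arch: ArchetypeSpec) -> str:
        return f"ps{idx + 1:02d}_{arch.archetype}"

    # paste bookkeeping: (probeset_id, probe ordinal) -> allowed interval in
    # the cross transcript
    cross_allowed: dict[str, tuple[str, int, int]] = {}

    for idx, arch in gene_archetypes:
        gene = arch_gene[idx]
        block = blocks[gene]
        starts = _probe_block_starts(arch, len(block))
        psid = ps_id(idx, arch)
        probes = tuple(
            Probe(probe_id=f"{psid}:{j + 1}", sequence=block[s : s + PROBE_LENGTH])
            for j, s in enumerate(starts)
        )
        probesets.append(ProbeSet(probeset_id=psid, probes=probes))
        probe_meta[psid] = {
            "arch": arch,
            "gene": gene,
            "starts": starts,
            "overlaps": [0] * arch.n_probes,
        }

    # cross-hybridization pastes
    for idx, arch in gene_archetypes:
        if arch.archetype != "cross_hybridizer":
            continue
        gene = arch_gene[idx]
        block = blocks[gene]
        psid = ps_id(idx, arch)
        meta = probe_meta[psid]
        target_gene = arch.cross_target_gene
        if target_gene is None:
            if not decoy_genes:
                raise ValueError("cross_hybridizer needs a decoy target gene")
            target_gene = decoy_genes[0]
        target_tid = planted_tids[target_gene][0]
        blen = arch.shared_block_len
        anchor = min(arch.n_probes - 1, 7)
        ostart = meta["starts"][anchor]
        if ostart < 3 or ostart + blen + 3 > len(block):
            raise ValueError("shared block does not fit inside the probe region")
        origin = block[ostart : ostart + blen]
        seq = list(sequences[target_tid])
        pos = 5  # inside the 5' prefix, clear of the target's own 3' block
        if pos + blen + 3 >= len(seq) - len(blocks[target_gene]):
            return None  # prefix too short; regenerate
        seq[pos : pos + blen] = origin
        # force the three bases flanking the paste to mismatch what every
        # overlapping probe carries there, so no alignment can extend past
        # the copied block
        for f in range(1, 4):
            seq[pos - f] = _mismatching_base(rng, block[ostart - f])
            seq[pos + blen - 1 + f] = _mismatching_base(rng, block[ostart + blen - 1 + f])
        sequences[target_tid] = "".join(seq)
        meta["cross_tid"] = target_tid
        meta["paste"] = (pos, pos + blen - 1)
        for j, s in enumerate(meta["starts"]):
            lo = max(s, ostart)
            hi = min(s + PROBE_LENGTH - 1, ostart + blen - 1)
            meta["overlaps"][j] = max(0, hi - lo + 1)
        cross_allowed[psid] = (target_tid, pos, pos + blen - 1)

    # orphan probe sets: random probes, validated against the transcriptome
    for idx, arch in orphans:
        psid = ps_id(idx, arch)
        probes = tuple(
            Probe(probe_id=f"{psid}:{j + 1}", sequence=_random_seq(rng, PROBE_LENGTH))
            for j in range(arch.n_probes)
        )
        probesets.append(ProbeSet(probeset_id=psid, probes=probes))
        probe_meta[psid] = {"arch": arch, "gene": None, "starts": [], "overlaps": []}

    db = TranscriptDB(sequences=sequences, gene_of=gene_of)
    if not _validate(probesets, probe_meta, db, cross_allowed):
        return None

    expected = tuple(
        _expected_scores(ps, probe_meta[ps.probeset_id], db, spec.p) for ps in probesets
    )
    return FixtureBundle(probesets=tuple(probesets), db=db, expected=expected)


def _validate(
    probesets: list[ProbeSet],
    probe_meta: dict[str, dict],
    db: TranscriptDB,
    cross_allowed: dict[str, tuple[str, int, int]],
) -> bool:
    """Reject accidental 16-base sharing outside the planted loci.

    Occurrences anywhere within the probe's own gene are harmless (the best
    own-gene alignment is the planted perfect match); everywhere else a
    probe 16-mer may appear only inside that probe set's pasted
    cross-hybridization block.
    """
    from .core import revcomp

    for ps in probesets:
        meta = probe_meta[ps.probeset_id]
        own_gene = meta["gene"]
        allowed_paste = cross_allowed.get(ps.probeset_id)
        for probe in ps.probes:
            windows = set()
            for seq in (probe.sequence, revcomp(probe.sequence)):
                for w in range(len(seq) - _CHECK_WORD + 1):
                    windows.add(seq[w : w + _CHECK_WORD])
            for tid, tseq in db.sequences.items():
                if own_gene is not None and db.gene_of[tid] == own_gene:
                    continue
                paste = None
                if allowed_paste is not None and allowed_paste[0] == tid:
                    paste = (allowed_paste[1], allowed_paste[2])
                for w in windows:
                    start = tseq.find(w)
                    while start != -1:
                        inside = (
                            paste is not None
                            and start >= paste[0]
                            and start + _CHECK_WORD - 1 <= paste[1]
                        )
                        if not inside:
                            return False
                        start = tseq.find(w, start + 1)
    return True


def _expected_scores(
    ps: ProbeSet, meta: dict, db: TranscriptDB, p: float
) -> ProbeSetScores:
    """Scores implied by the construction (tier rules applied to planted
    coordinates; no alignment is run)."""
    arch: ArchetypeSpec = meta["arch"]
    gene = meta["gene"]
    if gene is None:  # orphan
        return ProbeSetScores(
            probeset_id=ps.probeset_id,
            targeted_gene=None,
            n_probes=ps.n_probes,
            specificity=0.0,
            coverage=0.0,
            proc_requirement=None,
            robustness=0.0,
            overall=0.0,
        )
    n = arch.n_probes
    n_nonspecific = sum(1 for ov in meta["overlaps"] if ov >= _CHECK_WORD)
    s_s = (n - n_nonspecific) / n

    planted = [tid for tid in db.transcripts_of(gene) if _is_planted(tid, meta, db)]
    s_c = len(planted) / len(db.transcripts_of(gene))

    procs = [
        arch.distance_from_3prime + arch.tile_step * i + PROBE_LENGTH
        for i in range(n)
        for _ in planted
    ]
    n_req = median(procs)
    s_r = (1.0 - p) ** n_req
    return ProbeSetScores(
        probeset_id=ps.probeset_id,
        targeted_gene=gene,
        n_probes=n,
        specificity=s_s,
        coverage=s_c,
        proc_requirement=n_req,
        robustness=s_r,
        overall=s_s * s_c * s_r,
    )


def _is_planted(tid: str, meta: dict, db: TranscriptDB) -> bool:
    """True when the probes were planted on this transcript.

    Only isoform_partial genes have unplanted isoforms (every isoform of
    the other archetypes shares the probe-bearing 3' block).
    """
    if meta["arch"].archetype != "isoform_partial":
        return True
    return tid.endswith(".1")


def write_bundle(bundle: FixtureBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as plain-text files and return their paths.

    Probe-tab + FASTA for probes, FASTA + gene map for transcripts, and the
    analytically expected scores as a score CSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "probe_tab": out / "probes.probe_tab.tsv",
        "probe_fasta": out / "probes.fasta",
        "transcripts": out / "transcripts.fasta",
        "gene_map": out / "gene_map.tsv",
        "expected_scores": out / "expected_scores.csv",
    }
    probesets = list(bundle.probesets)
    pio.write_probe_tab(probesets, paths["probe_tab"])
    pio.write_probe_fasta(probesets, paths["probe_fasta"])
    pio.write_transcriptome(bundle.db, paths["transcripts"], paths["gene_map"])
    pio.write_scores(list(bundle.expected), paths["expected_scores"])
    return paths
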