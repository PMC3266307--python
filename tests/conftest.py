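import numpy as np
import pytest

from probemap.core import Probe, ProbeSet, TranscriptDB
from probemap.fixtures import FixtureSpec, generate


@pytest.fixture(scope="session")
def bundle7():
    """Default five-archetype fixture bundle for seed 7."""
    return generate(FixtureSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)


def make_probeset(probeset_id, sequences):
    return ProbeSet(
        probeset_id=probeset_id,
        probes=tuple(
            Probe(probe_id=f"{probeset_id}:{i}", sequence=s)
            for i, s in enumerate(sequences, start=1)
        ),
    )


def make_db(entries):
    """entries: {transcript_id: (sequence_or_length, gene_id)}.

    An int stands for a dummy sequence of that length (only lengths matter
    for hand-built hit lists).
    """
    sequences = {}
    gene_of = {}
    for tid, (seq, gene) in entries.items():
        if isinstance(seq, int):
            seq = ("ACGT" * (seq // 4 + 1))[:seq]
        sequences[tid] = seq
        gene_of[tid] = gene
    return TranscriptDB(sequences=sequences, gene_of=gene_of)
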