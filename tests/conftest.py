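from __future__ import annotations

import numpy as np
import pytest

from duplexseq.energy import DEFAULT_MODEL
from duplexseq.seqio import ReadRecord, Transcript


@pytest.fixture(scope="session")
def model():
    return DEFAULT_MODEL


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)


def random_rna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGU"), size=length, p=probs))


def make_transcript(
    tid: str,
    seq: str,
    gene: str | None = None,
    gene_class: str = "mRNA",
    interval: tuple | None = None,
) -> Transcript:
    return Transcript(
        transcript_id=tid,
        gene_id=gene or f"gene_{tid}",
        gene_class=gene_class,
        seq=seq,
        interval=interval or ("chr1", 0, len(seq), "+"),
    )


def make_read(rid: str, seq: str, q: int = 40) -> ReadRecord:
    return ReadRecord(rid, seq, (q,) * len(seq))
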