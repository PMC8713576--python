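"""Minimal FASTQ plumbing shared by the generators and the pipelines."""

from __future__ import annotations

import os
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

Record = tuple[str, str, str]  # (title, sequence, quality)

DEFAULT_QUAL = "I"  # constant phred-33 quality for synthetic reads


def read_fastq(path: str | os.PathLike) -> Iterator[Record]:
    with open(path) as handle:
        yield from FastqGeneralIterator(handle)


def write_fastq(path: str | os.PathLike, records: Iterable[Record]) -> int:
    n = 0
    with open(path, "w") as handle:
        for title, seq, qual in records:
            handle.write(f"@{title}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def index_of(title: str) -> str:
    """Sample index from an Illumina-style title line ``name 1:N:0:INDEX``."""
    return title.rsplit(":", 1)[-1]
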