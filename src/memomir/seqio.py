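"""Thin FASTA/FASTQ helpers built on Biopython.

All sequences are handled in DNA space (T, not U); reference files written by
the simulator use the same convention so tags from reads compare directly.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAATGCAA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} dict (DNA upper-case)."""
    return {rec.id: to_dna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) from a Phred+33 FASTQ file."""
    with open(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq(path: str | os.PathLike, records: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for title, seq, qual in records:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")
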