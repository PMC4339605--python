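"""Thin FASTA/FASTQ helpers over Bio.SeqIO.

Sequences circulate inside the package as plain upper-case strings keyed by
identifier; Biopython handles the on-disk formats (FASTA wrapped at 60
columns, FASTQ with Phred+33 qualities).
"""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an insertion-ordered {id: sequence} dict."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: dict[str, str], path: str | os.PathLike) -> None:
    """Write {id: sequence} as FASTA, wrapped at 60 columns."""
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTQ file as a list of (name, sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[tuple[str, str]], path: str | os.PathLike, quality: int = 40) -> None:
    """Write (name, sequence) pairs as FASTQ with a constant quality ('I' = Q40)."""
    def _records():
        for name, seq in reads:
            rec = SeqRecord(Seq(seq), id=name, description="")
            rec.letter_annotations["phred_quality"] = [quality] * len(seq)
            yield rec

    SeqIO.write(_records(), str(path), "fastq")
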