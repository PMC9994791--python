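"""FASTA reading and writing.

Reading is gzip-transparent and goes through Biopython; a contig's name is
the first whitespace-delimited token of its header.  Output is written at
80 columns with deterministic record order.
"""

from __future__ import annotations

import gzip
import os
from typing import IO, Iterable

from Bio import SeqIO

from .model import Genome
from .sequence import ingest

LINE_WIDTH = 80


def genome_stem(path: str) -> str:
    """Sample name from a FASTA path: basename minus .gz/.fa/.fasta/.fna."""
    base = os.path.basename(path)
    if base.endswith(".gz"):
        base = base[:-3]
    for suffix in (".fa", ".fasta", ".fna"):
        if base.endswith(suffix):
            return base[: -len(suffix)]
    return os.path.splitext(base)[0] or base


def read_fasta(path: str) -> list[tuple[str, bytes]]:
    """Parse a (possibly gzipped) FASTA file into (name, upper-cased seq)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    records = []
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            records.append((rec.id, ingest(bytes(rec.seq))))
    return records


def load_genome(path: str, name: str | None = None) -> Genome:
    return Genome(name or genome_stem(path), read_fasta(path))


def write_fasta(records: Iterable[tuple[str, bytes]], handle: IO[str]) -> None:
    for name, seq in records:
        handle.write(f">{name}\n")
        for i in range(0, len(seq), LINE_WIDTH):
            handle.write(seq[i : i + LINE_WIDTH].decode("ascii"))
            handle.write("\n")
        if not seq:
            handle.write("\n")


def write_genome(genome: Genome, path: str) -> None:
    with open(path, "w") as handle:
        write_fasta(genome.contigs, handle)
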