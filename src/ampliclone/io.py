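"""Read records and FASTQ/TSV plumbing (Biopython-backed)."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read: id, bases, Phred qualities, free-text tags."""

    id: str
    seq: str
    quals: tuple[int, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise InputError(f"read {self.id}: sequence/quality length mismatch")

    def strip_prefix(self, n: int) -> "ReadRecord":
        return replace(self, seq=self.seq[n:], quals=self.quals[n:])

    def reverse_complement(self) -> "ReadRecord":
        return replace(
            self,
            seq=str(Seq(self.seq).reverse_complement()),
            quals=tuple(reversed(self.quals)),
        )


ReadPair = tuple[ReadRecord, ReadRecord]


def _to_seqrecord(read: ReadRecord) -> SeqRecord:
    rec = SeqRecord(Seq(read.seq), id=read.id, description=read.description)
    rec.letter_annotations["phred_quality"] = list(read.quals)
    return rec


def _from_seqrecord(rec: SeqRecord) -> ReadRecord:
    desc = rec.description
    if desc.startswith(rec.id):
        desc = desc[len(rec.id):].strip()
    return ReadRecord(
        id=rec.id,
        seq=str(rec.seq),
        quals=tuple(rec.letter_annotations["phred_quality"]),
        description=desc,
    )


def write_fastq(reads: Iterable[ReadRecord], path: str) -> int:
    return SeqIO.write((_to_seqrecord(r) for r in reads), path, "fastq")


def read_fastq(path: str) -> Iterator[ReadRecord]:
    for rec in SeqIO.parse(path, "fastq"):
        yield _from_seqrecord(rec)


def write_fastq_pairs(pairs: Iterable[ReadPair], r1_path: str, r2_path: str) -> int:
    n = 0
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for r1, r2 in pairs:
            SeqIO.write([_to_seqrecord(r1)], f1, "fastq")
            SeqIO.write([_to_seqrecord(r2)], f2, "fastq")
            n += 1
    return n


def read_fastq_pairs(r1_path: str, r2_path: str) -> Iterator[ReadPair]:
    it1 = SeqIO.parse(r1_path, "fastq")
    it2 = SeqIO.parse(r2_path, "fastq")
    for rec1, rec2 in zip(it1, it2, strict=True):
        yield _from_seqrecord(rec1), _from_seqrecord(rec2)


def sha256_of(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
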