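"""Core containers shared across the pipeline.

Reads are kept as plain Python strings with numpy quality arrays: at
genome-skimming scale (10^3–10^6 reads per species) this is fast enough
and keeps every stage transparent to inspect.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class Read:
    """A single sequencing read.

    ``qual`` is a phred-score array (one int per base) or ``None`` for
    FASTA input. ``family`` carries the generating repeat family for
    synthetic reads ("" for real data / background).
    """

    id: str
    seq: str
    qual: np.ndarray | None = None
    species: str = ""
    family: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadSet:
    """An ordered collection of reads, optionally all from one species."""

    reads: list[Read] = field(default_factory=list)
    species: str = ""

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def __getitem__(self, i: int) -> Read:
        return self.reads[i]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(r) for r in self.reads], dtype=int)

    def uniform_length(self) -> int:
        """Common read length; raises if reads are not uniform."""
        lens = {len(r) for r in self.reads}
        if len(lens) != 1:
            raise ValueError(f"reads are not uniform length: {sorted(lens)}")
        return lens.pop()


def _open_maybe_gz(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path, species: str = "") -> ReadSet:
    """Load a FASTQ (optionally gzipped) into a ReadSet.

    A ``family=<name>`` token in the description (written by the
    synthetic generator) is parsed into ``Read.family``.
    """
    reads = []
    with _open_maybe_gz(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            fam = _family_from_description(rec.description)
            reads.append(
                Read(
                    id=rec.id,
                    seq=str(rec.seq).upper(),
                    qual=np.array(rec.letter_annotations["phred_quality"], dtype=np.int16),
                    species=species,
                    family=fam,
                )
            )
    return ReadSet(reads=reads, species=species)


def read_fasta(path: str | Path, species: str = "") -> ReadSet:
    reads = []
    with _open_maybe_gz(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            fam = _family_from_description(rec.description)
            reads.append(Read(id=rec.id, seq=str(rec.seq).upper(), qual=None,
                              species=species, family=fam))
    return ReadSet(reads=reads, species=species)


def _family_from_description(desc: str) -> str:
    for tok in desc.split():
        if tok.startswith("family="):
            return tok[len("family="):]
    return ""


def write_fastq(readset: ReadSet, path: str | Path) -> None:
    with _open_maybe_gz(path, "wt") as fh:
        for r in readset:
            if r.qual is None:
                raise ValueError(f"read {r.id} has no qualities; write FASTA instead")
            rec = SeqRecord(Seq(r.seq), id=r.id, description=f"family={r.family}" if r.family else "")
            rec.letter_annotations["phred_quality"] = [int(q) for q in r.qual]
            SeqIO.write(rec, fh, "fastq")


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(name, sequence)`` pairs as FASTA."""
    with _open_maybe_gz(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def read_fasta_records(path: str | Path) -> list[tuple[str, str, str]]:
    """Read FASTA into ``(id, description, sequence)`` tuples."""
    out = []
    with _open_maybe_gz(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            out.append((rec.id, rec.description, str(rec.seq).upper()))
    return out
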