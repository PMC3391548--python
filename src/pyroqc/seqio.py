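"""Reading and writing quality-scored amplicon reads.

Supported formats are FASTA plus a paired ``.qual`` file of whitespace
separated integer Phred scores (the native 454 output convention) and
four-line FASTQ with Phred+33 encoding. Files ending in ``.gz`` are read
and written through transparent gzip.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from itertools import zip_longest
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

from Bio import SeqIO

PathLike = Union[str, Path]

MAX_PHRED = 40


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass
class QualifiedRead:
    """One read: bases, per-base Phred scores and optional ground-truth labels.

    Invariants enforced at construction: ``len(bases) == len(quals)`` and
    every quality value lies in [0, 40]. Bases are stored uppercase.
    """

    read_id: str
    bases: str
    quals: tuple[int, ...]
    taxon: Optional[str] = None
    template_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.bases = self.bases.upper()
        self.quals = tuple(int(q) for q in self.quals)
        if len(self.bases) != len(self.quals):
            raise FormatError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )
        for q in self.quals:
            if not 0 <= q <= MAX_PHRED:
                raise FormatError(
                    f"read {self.read_id!r}: quality value {q} outside "
                    f"[0, {MAX_PHRED}] (wrong FASTQ offset?)"
                )

    def __len__(self) -> int:
        return len(self.bases)

    def mean_quality(self) -> float:
        if not self.quals:
            raise ValueError(f"read {self.read_id!r} is empty")
        return sum(self.quals) / len(self.quals)


@dataclass
class ReadSet:
    """An ordered collection of :class:`QualifiedRead` with unique ids."""

    reads: list[QualifiedRead] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.reads:
            if r.read_id in seen:
                raise FormatError(f"duplicate read id {r.read_id!r}")
            seen.add(r.read_id)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[QualifiedRead]:
        return iter(self.reads)

    def __getitem__(self, read_id: str) -> QualifiedRead:
        for r in self.reads:
            if r.read_id == read_id:
                return r
        raise KeyError(read_id)

    def ids(self) -> list[str]:
        return [r.read_id for r in self.reads]

    def subset(self, read_ids: Iterable[str], provenance: str = "") -> "ReadSet":
        wanted = set(read_ids)
        return ReadSet(
            [r for r in self.reads if r.read_id in wanted],
            provenance or self.provenance,
        )

    def with_provenance(self, note: str) -> "ReadSet":
        joined = f"{self.provenance}; {note}" if self.provenance else note
        return ReadSet(list(self.reads), joined)


def _open_text(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta_qual(fasta_path: PathLike, qual_path: PathLike) -> ReadSet:
    """Parse paired FASTA and QUAL files into a :class:`ReadSet`.

    Records must appear in the same order with matching identifiers; the
    first mismatch is reported by name.
    """
    reads: list[QualifiedRead] = []
    with _open_text(fasta_path) as fh_f, _open_text(qual_path) as fh_q:
        fasta_iter = SeqIO.parse(fh_f, "fasta")
        qual_iter = SeqIO.parse(fh_q, "qual")
        for frec, qrec in zip_longest(fasta_iter, qual_iter):
            if frec is None or qrec is None:
                present = frec if frec is not None else qrec
                raise FormatError(
                    f"record count mismatch between {fasta_path} and "
                    f"{qual_path}; unpaired record {present.id!r}"
                )
            if frec.id != qrec.id:
                raise FormatError(
                    f"identifier mismatch: FASTA record {frec.id!r} vs "
                    f"QUAL record {qrec.id!r}"
                )
            reads.append(
                QualifiedRead(
                    frec.id,
                    str(frec.seq),
                    tuple(qrec.letter_annotations["phred_quality"]),
                )
            )
    return ReadSet(reads, provenance=f"read_fasta_qual({fasta_path}, {qual_path})")


def read_fastq(path: PathLike) -> ReadSet:
    """Parse a Phred+33 FASTQ file into a :class:`ReadSet`.

    Decoded quality values outside [0, 40] raise :class:`FormatError`
    rather than being clipped, to surface dialect errors early.
    """
    reads: list[QualifiedRead] = []
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                reads.append(
                    QualifiedRead(
                        rec.id,
                        str(rec.seq),
                        tuple(rec.letter_annotations["phred_quality"]),
                    )
                )
        except FormatError:
            raise
        except ValueError as exc:  # malformed FASTQ from the Bio parser
            raise FormatError(f"{path}: {exc}") from exc
    return ReadSet(reads, provenance=f"read_fastq({path})")


def write_fasta_qual(
    read_set: ReadSet, fasta_path: PathLike, qual_path: PathLike
) -> None:
    """Write a ReadSet as FASTA plus QUAL; round-trips exactly through
    :func:`read_fasta_qual`."""
    with _open_text(fasta_path, "wt") as fh_f, _open_text(qual_path, "wt") as fh_q:
        for r in read_set:
            fh_f.write(f">{r.read_id}\n{r.bases}\n")
            fh_q.write(f">{r.read_id}\n{' '.join(str(q) for q in r.quals)}\n")


def write_fastq(read_set: ReadSet, path: PathLike) -> None:
    """Write a ReadSet as Phred+33 FASTQ."""
    with _open_text(path, "wt") as fh:
        for r in read_set:
            qline = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{qline}\n")
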