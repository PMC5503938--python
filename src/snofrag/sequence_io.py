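"""Sequence input/output and basic nucleotide utilities.

Handles the three kinds of sequence data the sdRNA pipeline touches:

* snoRNA reference catalogs (multi-record FASTA),
* adapter-trimmed small RNA-seq libraries (FASTA or FASTQ, auto-detected),
* query sequences (single-record FASTA).

Catalogs exported as RNA interoperate with DNA reads: ``U`` is mapped to
``T`` on ingest and everything is case-folded to upper. Small-RNA libraries
are length-filtered to the size-selection window of the sequencing protocol
(17-35 nt by default); the pre-filter read count is retained because it is
the denominator of counts-per-million.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")

#: Size-selection window of the small RNA-seq libraries (inclusive, nt).
DEFAULT_MIN_READ_LEN = 17
DEFAULT_MAX_READ_LEN = 35


class SequenceFormatError(ValueError):
    """Raised for malformed FASTA/FASTQ input."""


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""


def normalize_sequence(raw: str, *, context: str = "sequence") -> str:
    """Upper-case ``raw``, map U->T, and validate the {A,C,G,T,N} alphabet."""
    seq = raw.strip().upper().replace("U", "T")
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise AlphabetError(
            f"{context} contains non-nucleotide characters: {sorted(bad)}"
        )
    return seq


@dataclass(frozen=True)
class SnoRNARecord:
    """A named reference sequence (snoRNA, miRNA hairpin, or query)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceFormatError("record has an empty id")
        if not self.sequence:
            raise SequenceFormatError(f"record '{self.id}' has an empty sequence")
        object.__setattr__(
            self, "sequence", normalize_sequence(self.sequence, context=self.id)
        )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SmallRNARead:
    """A single adapter-trimmed small RNA-seq read."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceFormatError(f"read '{self.id}' has an empty sequence")
        object.__setattr__(
            self, "sequence", normalize_sequence(self.sequence, context=self.id)
        )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SampleLibrary:
    """One sample's small RNA-seq library after length filtering.

    ``total_reads`` is the read count *before* length filtering (the CPM
    denominator of the raw library); ``reads`` holds only the reads inside
    the length window, in input order.
    """

    sample_id: str
    total_reads: int
    reads: list[SmallRNARead] = field(default_factory=list)
    subtype_label: str = ""

    def __post_init__(self) -> None:
        if self.total_reads < len(self.reads):
            raise ValueError(
                f"library '{self.sample_id}': total_reads ({self.total_reads}) "
                f"< retained reads ({len(self.reads)})"
            )


def read_fasta(path: str | Path) -> list[SnoRNARecord]:
    """Parse a (possibly wrapped) multi-record FASTA into a catalog.

    U is mapped to T and case folded; ids must be unique within the file.
    An empty file yields an empty catalog with a logged warning.
    """
    path = Path(path)
    text_head = _first_significant_char(path)
    if text_head is None:
        log.warning("FASTA file %s is empty; returning empty catalog", path)
        return []
    if text_head != ">":
        raise SequenceFormatError(
            f"{path}: first record line does not start with '>' "
            f"(found {text_head!r})"
        )
    records: list[SnoRNARecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if not rec.id:
            raise SequenceFormatError(f"{path}: record {i} has an empty header")
        if str(rec.seq) == "":
            raise SequenceFormatError(
                f"{path}: record {i} ('{rec.id}') has an empty sequence"
            )
        if rec.id in seen:
            raise SequenceFormatError(f"{path}: duplicate record id '{rec.id}'")
        seen.add(rec.id)
        # SeqIO's description repeats the id for bare headers; a header that
        # is exactly the id round-trips as an empty description
        description = "" if rec.description == rec.id else rec.description
        records.append(
            SnoRNARecord(id=rec.id, sequence=str(rec.seq), description=description)
        )
    return records


def write_fasta(records: Iterable[SnoRNARecord], path: str | Path) -> None:
    """Write a catalog as unwrapped FASTA (one sequence line per record)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            if not header.startswith(rec.id):
                header = f"{rec.id} {rec.description}"
            fh.write(f">{header}\n{rec.sequence}\n")


def read_reads(
    path: str | Path,
    min_len: int = DEFAULT_MIN_READ_LEN,
    max_len: int = DEFAULT_MAX_READ_LEN,
    sample_id: str | None = None,
    subtype_label: str = "",
) -> SampleLibrary:
    """Load a small RNA-seq library from FASTA or FASTQ (auto-detected).

    Reads outside [min_len, max_len] (inclusive) are dropped from
    ``reads`` but still counted in ``total_reads``. FASTQ qualities are
    discarded; no quality filtering is performed.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    head = _first_significant_char(path)
    if head is None:
        log.warning("read file %s is empty", path)
        return SampleLibrary(sample_id=sample_id, total_reads=0, reads=[],
                             subtype_label=subtype_label)
    if head == ">":
        fmt = "fasta"
    elif head == "@":
        fmt = "fastq"
    else:
        raise SequenceFormatError(
            f"{path}: unrecognized read format (first character {head!r}; "
            "expected '>' for FASTA or '@' for FASTQ)"
        )
    total = 0
    kept: list[SmallRNARead] = []
    for rec in SeqIO.parse(str(path), fmt):
        total += 1
        seq = str(rec.seq)
        if min_len <= len(seq) <= max_len:
            kept.append(SmallRNARead(id=rec.id, sequence=seq))
    return SampleLibrary(
        sample_id=sample_id, total_reads=total, reads=kept,
        subtype_label=subtype_label,
    )


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution (N maps to N)."""
    seq = sequence.upper()
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise AlphabetError(
            f"cannot reverse-complement characters: {sorted(bad)}"
        )
    # kept equivalent to str(Seq(seq).reverse_complement()); translate avoids
    # round-tripping through Bio.Seq for hot inner loops
    return seq.translate(_COMPLEMENT)[::-1]


def _first_significant_char(path: Path) -> str | None:
    with path.open() as fh:
        for line in fh:
            stripped = line.strip()
            if stripped:
                return stripped[0]
    return None


__all__ = [
    "SnoRNARecord",
    "SmallRNARead",
    "SampleLibrary",
    "SequenceFormatError",
    "AlphabetError",
    "read_fasta",
    "write_fasta",
    "read_reads",
    "reverse_complement",
    "normalize_sequence",
    "DEFAULT_MIN_READ_LEN",
    "DEFAULT_MAX_READ_LEN",
]
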