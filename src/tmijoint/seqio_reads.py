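"""Read-level I/O: SAM flag filtering, quality control and FASTA/FASTQ writing.

Extracts host-unmapped ("foreign") reads from alignments by SAM flag
arithmetic, applies base-quality / N-content / length filters, and pairs
surviving singletons with their reverse complement so that downstream
remapping always sees read pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

# SAM flag bits used here
FLAG_PAIRED = 0x1
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_SECONDARY = 0x100

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")


class MalformedRecordError(ValueError):
    """A read record violates basic structural constraints (e.g. bad flag)."""


class InvalidSequenceError(ValueError):
    """Sequence contains characters outside the {A,C,G,T,N} alphabet."""


@dataclass
class ReadRecord:
    """One sequencing read with its SAM flag and optional qualities."""

    read_id: str
    sequence: str
    qualities: Sequence[int] | None = None
    flag: int = 0
    mate_role: str = "unpaired"  # {"first", "second", "unpaired"}

    def __post_init__(self) -> None:
        if not isinstance(self.flag, int) or isinstance(self.flag, bool) or self.flag < 0:
            raise MalformedRecordError(
                f"read {self.read_id!r}: flag must be a non-negative integer, got {self.flag!r}"
            )
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise MalformedRecordError(
                f"read {self.read_id!r}: {len(self.qualities)} quality values for "
                f"{len(self.sequence)} bases"
            )
        if self.mate_role not in ("first", "second", "unpaired"):
            raise MalformedRecordError(
                f"read {self.read_id!r}: bad mate_role {self.mate_role!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class QcPolicy:
    """Quality-control thresholds for foreign reads.

    A read is kept when its length is at least ``min_length``, it contains at
    most ``max_n_count`` N bases, and at most ``max_low_quality_fraction`` of
    its bases fall below ``phred_threshold``.
    """

    phred_threshold: int = 15
    max_low_quality_fraction: float = 0.40
    max_n_count: int = 5
    min_length: int = 36

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_low_quality_fraction <= 1.0:
            raise ValueError("max_low_quality_fraction must be within [0, 1]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass
class QcReport:
    """Per-reason drop counts from one QC pass."""

    n_input: int = 0
    n_kept: int = 0
    dropped_short: int = 0
    dropped_n: int = 0
    dropped_quality: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def _check_flag(record: ReadRecord) -> int:
    flag = record.flag
    if not isinstance(flag, int) or isinstance(flag, bool) or flag < 0:
        raise MalformedRecordError(
            f"read {record.read_id!r}: flag must be a non-negative integer"
        )
    return flag


def is_unmapped_single(flag: int) -> bool:
    """``samtools view -f 4 -F 264`` predicate: read unmapped, mate mapped, primary."""
    return bool(flag & FLAG_UNMAPPED) and not flag & (FLAG_MATE_UNMAPPED | FLAG_SECONDARY)


def is_unmapped_both(flag: int) -> bool:
    """``samtools view -f 12 -F 256`` predicate: both ends unmapped, primary."""
    want = FLAG_UNMAPPED | FLAG_MATE_UNMAPPED
    return (flag & want) == want and not flag & FLAG_SECONDARY


def extract_unmapped_single(records: Iterable[ReadRecord]) -> Iterator[ReadRecord]:
    """Yield primary records whose read is unmapped but whose mate is mapped."""
    for rec in records:
        if is_unmapped_single(_check_flag(rec)):
            yield rec


def extract_unmapped_pairs(
    records: Iterable[ReadRecord],
) -> tuple[list[tuple[ReadRecord, ReadRecord]], list[ReadRecord]]:
    """Collect primary records with both ends unmapped, grouped into mate pairs.

    Returns ``(pairs, orphans)``; records whose mate never shows up (truncated
    input, filtered mate) are demoted to the orphan list with a logged warning
    rather than raising.
    """
    pending: dict[str, ReadRecord] = {}
    pairs: list[tuple[ReadRecord, ReadRecord]] = []
    for rec in records:
        if not is_unmapped_both(_check_flag(rec)):
            continue
        mate = pending.pop(rec.read_id, None)
        if mate is None:
            pending[rec.read_id] = rec
        else:
            first, second = (mate, rec) if mate.mate_role != "second" else (rec, mate)
            pairs.append((first, second))
    orphans = list(pending.values())
    for rec in orphans:
        logger.warning("orphaned mate for read %s; routed to singleton stream", rec.read_id)
    return pairs, orphans


def qc_filter(
    reads: Iterable[ReadRecord], policy: QcPolicy | None = None
) -> tuple[list[ReadRecord], QcReport]:
    """Apply length / N-count / low-quality-fraction filters.

    Checks run in that order and a read is charged to the first failing
    reason. Reads without quality strings pass the quality criterion.
    """
    policy = policy or QcPolicy()
    kept: list[ReadRecord] = []
    report = QcReport()
    for read in reads:
        report.n_input += 1
        if len(read) < policy.min_length:
            report.dropped_short += 1
            continue
        if read.sequence.count("N") > policy.max_n_count:
            report.dropped_n += 1
            continue
        if read.qualities is not None and len(read) > 0:
            n_low = sum(q < policy.phred_threshold for q in read.qualities)
            if n_low / len(read) > policy.max_low_quality_fraction:
                report.dropped_quality += 1
                continue
        kept.append(read)
        report.n_kept += 1
    return kept, report


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    bad = set(sequence) - _VALID_BASES
    if bad:
        raise InvalidSequenceError(
            f"sequence contains non-ACGTN characters: {sorted(bad)}"
        )
    return sequence.translate(_COMPLEMENT)[::-1]


def pair_singleton_with_revcomp(read: ReadRecord) -> tuple[ReadRecord, ReadRecord]:
    """Give an unpaired read a synthetic mate carrying its reverse complement.

    The mate reuses the read id with ``mate_role='second'`` and mirrors the
    quality string (reversed) so FASTQ output stays well-formed.
    """
    if read.mate_role == "second":
        raise ValueError(f"read {read.read_id!r} already is a second mate")
    mate = ReadRecord(
        read_id=read.read_id,
        sequence=reverse_complement(read.sequence),
        qualities=None if read.qualities is None else list(read.qualities)[::-1],
        flag=read.flag,
        mate_role="second",
    )
    first = ReadRecord(
        read_id=read.read_id,
        sequence=read.sequence,
        qualities=read.qualities,
        flag=read.flag,
        mate_role="first",
    )
    return first, mate


# ---------------------------------------------------------------------------
# SAM / FASTQ / FASTA adapters
# ---------------------------------------------------------------------------

def _mate_role_from_flag(flag: int) -> str:
    if not flag & FLAG_PAIRED:
        return "unpaired"
    if flag & FLAG_FIRST and not flag & FLAG_SECOND:
        return "first"
    if flag & FLAG_SECOND and not flag & FLAG_FIRST:
        return "second"
    return "unpaired"


def read_sam(path: str | Path) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a SAM or BAM file (flags + sequences only)."""
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as handle:
        for aln in handle.fetch(until_eof=True):
            quals = None if aln.query_qualities is None else list(aln.query_qualities)
            yield ReadRecord(
                read_id=aln.query_name,
                sequence=aln.query_sequence or "",
                qualities=quals,
                flag=aln.flag,
                mate_role=_mate_role_from_flag(aln.flag),
            )


def _to_seqrecord(read: ReadRecord, with_quality: bool) -> SeqRecord:
    rec = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
    if with_quality:
        quals = read.qualities if read.qualities is not None else [40] * len(read)
        rec.letter_annotations["phred_quality"] = list(quals)
    return rec


def _disambiguate(reads: Iterable[ReadRecord]) -> Iterator[ReadRecord]:
    seen: dict[str, int] = {}
    for read in reads:
        count = seen.get(read.read_id, 0)
        seen[read.read_id] = count + 1
        if count == 0:
            yield read
        else:
            new_id = f"{read.read_id}.{count + 1}"
            warnings.warn(
                f"duplicate read id {read.read_id!r}; renamed to {new_id!r}",
                stacklevel=2,
            )
            yield ReadRecord(new_id, read.sequence, read.qualities, read.flag, read.mate_role)


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    """Write Phred+33 FASTQ; colliding ids get numeric suffixes with a warning."""
    records = (_to_seqrecord(r, with_quality=True) for r in _disambiguate(reads))
    return SeqIO.write(records, str(path), "fastq")


def write_fasta(reads: Iterable[ReadRecord], path: str | Path) -> int:
    """Write FASTA (qualities discarded)."""
    records = (_to_seqrecord(r, with_quality=False) for r in _disambiguate(reads))
    return SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield ReadRecord(
            read_id=rec.id,
            sequence=str(rec.seq),
            qualities=list(rec.letter_annotations["phred_quality"]),
            flag=FLAG_UNMAPPED,
        )


def read_fasta(path: str | Path) -> Iterator[ReadRecord]:
    for rec in SeqIO.parse(str(path), "fasta"):
        yield ReadRecord(read_id=rec.id, sequence=str(rec.seq), flag=FLAG_UNMAPPED)
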