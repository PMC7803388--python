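"""SAM alignment records, CIGAR arithmetic and SA-tag parsing.

The integration-site caller consumes local alignments of captured reads
against a reference in which the linearized transfection vector is appended
to the genome assembly as one extra named scaffold.  This module holds the
record model for those alignments and the exact coordinate semantics the
caller relies on:

* SAM coordinates are 1-based; ``pos`` is the leftmost aligned reference
  base of the record.
* CIGAR reference consumption counts M, D, N, ``=`` and X.  Soft (S) and
  hard (H) clips consume no reference and may appear only as a single run
  at each end of the CIGAR, with H outermost.
* The SA:Z optional tag lists a read's chimeric partner alignments as
  semicolon-terminated ``rname,pos,strand,CIGAR,mapQ,NM`` entries, the
  dialect emitted by BWA-MEM.

Record decoding is delegated to pysam; SA-tag fields and standalone CIGAR
strings are tokenised here because pysam exposes no API for them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import pysam

from .errors import MalformedCigarError, ReferenceMismatchError, SamParseError

CIGAR_OPS = frozenset("MIDNSHP=X")
#: operations that consume reference bases
REF_CONSUMING = frozenset("MDN=X")
#: operations that consume read (query) bases; soft clips do, hard clips do not
QUERY_CONSUMING = frozenset("MIS=X")
CLIP_OPS = frozenset("SH")

_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")
_CIGAR_FULL = re.compile(r"(?:\d+[MIDNSHP=X])+\Z")
# pysam cigartuples encode the operation as an index into this string
_PYSAM_OPS = "MIDNSHP=X"

__all__ = [
    "CigarOp",
    "SupplementaryEntry",
    "AlignmentRecord",
    "ReferenceSet",
    "parse_cigar",
    "cigar_to_string",
    "reference_span",
    "query_span",
    "clip_lengths",
    "parse_sa_tag",
    "parse_alignment_line",
    "read_sam",
]


@dataclass(frozen=True)
class CigarOp:
    """One CIGAR operation: an op code and a positive base count."""

    op: str
    length: int

    def __post_init__(self) -> None:
        if self.op not in CIGAR_OPS:
            raise MalformedCigarError(f"unknown CIGAR op {self.op!r}")
        if self.length < 1:
            raise MalformedCigarError(
                f"CIGAR op {self.op} has non-positive length {self.length}"
            )

    def __str__(self) -> str:
        return f"{self.length}{self.op}"


def parse_cigar(text: str) -> tuple[CigarOp, ...]:
    """Parse a CIGAR string into operations, validating clip placement."""
    if not text or text == "*":
        raise MalformedCigarError(f"empty CIGAR {text!r}")
    if not _CIGAR_FULL.match(text):
        raise MalformedCigarError(f"malformed CIGAR {text!r}")
    ops = tuple(
        CigarOp(op, int(length)) for length, op in _CIGAR_TOKEN.findall(text)
    )
    clip_lengths(ops)  # raises on interior clips / misplaced H
    return ops


def cigar_to_string(cigar: Iterable[CigarOp]) -> str:
    return "".join(str(op) for op in cigar)


def reference_span(cigar: Iterable[CigarOp]) -> int:
    """Total reference bases consumed (M, D, N, =, X)."""
    return sum(op.length for op in cigar if op.op in REF_CONSUMING)


def query_span(cigar: Iterable[CigarOp]) -> int:
    """Total read bases accounted for, soft clips included (M, I, S, =, X)."""
    return sum(op.length for op in cigar if op.op in QUERY_CONSUMING)


def clip_lengths(cigar: tuple[CigarOp, ...] | list[CigarOp]) -> tuple[int, int]:
    """Summed S+H clip lengths at the (left, right) ends of a CIGAR.

    Clips are legal only as one run at each end, hard clips outermost;
    anything else raises :class:`MalformedCigarError`.
    """
    ops = tuple(cigar)
    if not ops:
        raise MalformedCigarError("empty CIGAR")
    left = right = 0
    i, j = 0, len(ops)
    seen_soft = False
    while i < j and ops[i].op in CLIP_OPS:
        if ops[i].op == "H" and seen_soft:
            raise MalformedCigarError("H clip inside S clip at left end")
        seen_soft = seen_soft or ops[i].op == "S"
        left += ops[i].length
        i += 1
    seen_soft = False
    while j > i and ops[j - 1].op in CLIP_OPS:
        if ops[j - 1].op == "H" and seen_soft:
            raise MalformedCigarError("H clip inside S clip at right end")
        seen_soft = seen_soft or ops[j - 1].op == "S"
        right += ops[j - 1].length
        j -= 1
    if any(op.op in CLIP_OPS for op in ops[i:j]):
        raise MalformedCigarError(
            f"clip operation interior to CIGAR {cigar_to_string(ops)!r}"
        )
    if i == len(ops):  # all-clip CIGAR: the whole read counts as one end
        raise MalformedCigarError(
            f"CIGAR {cigar_to_string(ops)!r} has no aligned bases"
        )
    return left, right


@dataclass(frozen=True)
class SupplementaryEntry:
    """One chimeric partner alignment from an SA:Z tag entry."""

    rname: str
    pos: int  # 1-based leftmost aligned base
    strand: str  # "+" or "-"
    cigar: tuple[CigarOp, ...]
    mapq: int
    nm: int

    def to_sa_field(self) -> str:
        return (
            f"{self.rname},{self.pos},{self.strand},"
            f"{cigar_to_string(self.cigar)},{self.mapq},{self.nm}"
        )


def parse_sa_tag(value: str) -> tuple[SupplementaryEntry, ...]:
    """Parse an SA:Z tag value ("rname,pos,strand,CIGAR,mapQ,NM;...")."""
    entries = []
    for chunk in value.split(";"):
        if not chunk:
            continue
        fields = chunk.split(",")
        if len(fields) != 6:
            raise SamParseError(f"SA entry {chunk!r} does not have 6 fields")
        rname, pos, strand, cigar, mapq, nm = fields
        if strand not in ("+", "-"):
            raise SamParseError(f"SA entry {chunk!r} has bad strand {strand!r}")
        entries.append(
            SupplementaryEntry(
                rname=rname,
                pos=int(pos),
                strand=strand,
                cigar=parse_cigar(cigar),
                mapq=int(mapq),
                nm=int(nm),
            )
        )
    return tuple(entries)


@dataclass(frozen=True)
class ReferenceSet:
    """Genome scaffolds plus the one reserved vector scaffold.

    ``scaffold_lengths`` maps genome scaffold name -> length and must not
    contain ``vector_name``; the vector is the extra scaffold appended to
    the assembly before alignment.
    """

    scaffold_lengths: Mapping[str, int]
    vector_name: str
    vector_length: int

    def __post_init__(self) -> None:
        if self.vector_name in self.scaffold_lengths:
            raise ReferenceMismatchError(
                f"vector scaffold {self.vector_name!r} collides with a genome scaffold"
            )

    @property
    def scaffold_names(self) -> frozenset[str]:
        return frozenset(self.scaffold_lengths)

    @property
    def all_names(self) -> frozenset[str]:
        return self.scaffold_names | {self.vector_name}

    def is_vector(self, name: str) -> bool:
        return name == self.vector_name

    def length(self, name: str) -> int:
        if name == self.vector_name:
            return self.vector_length
        return self.scaffold_lengths[name]

    def to_pysam_header(self) -> pysam.AlignmentHeader:
        names = list(self.scaffold_lengths) + [self.vector_name]
        lengths = [self.scaffold_lengths[n] for n in self.scaffold_lengths]
        lengths.append(self.vector_length)
        return pysam.AlignmentHeader.from_references(names, lengths)

    @classmethod
    def from_sam_header(
        cls, header: pysam.AlignmentHeader, vector_name: str
    ) -> "ReferenceSet":
        names = list(header.references)
        lengths = dict(zip(names, header.lengths))
        if vector_name not in lengths:
            raise ReferenceMismatchError(
                f"vector scaffold {vector_name!r} not in header; "
                f"observed scaffolds: {', '.join(names)}"
            )
        vector_length = lengths.pop(vector_name)
        return cls(
            scaffold_lengths=lengths,
            vector_name=vector_name,
            vector_length=vector_length,
        )


# SAM FLAG bits
_PAIRED = 0x1
_UNMAPPED = 0x4
_MATE_UNMAPPED = 0x8
_REVERSE = 0x10
_FIRST = 0x40
_SECOND = 0x80
_SECONDARY = 0x100
_DUPLICATE = 0x400
_SUPPLEMENTARY = 0x800


@dataclass(frozen=True)
class AlignmentRecord:
    """One parsed SAM record, restricted to the fields the pipeline consumes.

    ``pos`` is 1-based (SAM convention); ``nm`` is ``None`` when the record
    carries no NM tag, which is distinct from ``nm == 0``.
    """

    qname: str
    flag: int
    refname: str | None
    pos: int | None
    mapq: int
    cigar: tuple[CigarOp, ...] | None
    nm: int | None = None
    sa_entries: tuple[SupplementaryEntry, ...] = field(default_factory=tuple)

    # -- FLAG decodes -------------------------------------------------
    @property
    def is_paired(self) -> bool:
        return bool(self.flag & _PAIRED)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & _UNMAPPED)

    @property
    def mate_unmapped(self) -> bool:
        return bool(self.flag & _MATE_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & _REVERSE)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & _SECONDARY)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & _DUPLICATE)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & _SUPPLEMENTARY)

    @property
    def mate(self) -> int:
        """Mate index in {1, 2}; unpaired reads count as mate 1."""
        return 2 if self.flag & _SECOND else 1

    @property
    def strand(self) -> str:
        return "-" if self.is_reverse else "+"

    # -- construction -------------------------------------------------
    @classmethod
    def from_pysam(cls, seg: pysam.AlignedSegment) -> "AlignmentRecord":
        if seg.is_unmapped:
            return cls(
                qname=seg.query_name,
                flag=seg.flag,
                refname=None,
                pos=None,
                mapq=seg.mapping_quality,
                cigar=None,
            )
        cigar = tuple(
            CigarOp(_PYSAM_OPS[code], length)
            for code, length in (seg.cigartuples or ())
        )
        nm = int(seg.get_tag("NM")) if seg.has_tag("NM") else None
        sa = (
            parse_sa_tag(str(seg.get_tag("SA"))) if seg.has_tag("SA") else ()
        )
        return cls(
            qname=seg.query_name,
            flag=seg.flag,
            refname=seg.reference_name,
            pos=seg.reference_start + 1,  # pysam is 0-based
            mapq=seg.mapping_quality,
            cigar=cigar,
            nm=nm,
            sa_entries=sa,
        )

    def to_sam_line(self) -> str:
        """Serialize the consumed fields back to a minimal SAM record line."""
        rname = self.refname if self.refname is not None else "*"
        pos = self.pos if self.pos is not None else 0
        cig = cigar_to_string(self.cigar) if self.cigar else "*"
        fields = [
            self.qname,
            str(self.flag),
            rname,
            str(pos),
            str(self.mapq),
            cig,
            "*",
            "0",
            "0",
            "*",
            "*",
        ]
        if self.nm is not None:
            fields.append(f"NM:i:{self.nm}")
        if self.sa_entries:
            sa = "".join(e.to_sa_field() + ";" for e in self.sa_entries)
            fields.append(f"SA:Z:{sa}")
        return "\t".join(fields)


def parse_alignment_line(
    line: str,
    refs: ReferenceSet | pysam.AlignmentHeader,
    line_number: int | None = None,
) -> AlignmentRecord:
    """Parse one non-header SAM text line into an :class:`AlignmentRecord`.

    Raises :class:`SamParseError` (naming the line number when given) for
    malformed records and :class:`ReferenceMismatchError` when the RNAME is
    not in the reference dictionary.  pysam downgrades unknown reference
    names to unmapped, so the RNAME check happens before delegation.
    """
    header = refs.to_pysam_header() if isinstance(refs, ReferenceSet) else refs
    line = line.rstrip("\n")
    fields = line.split("\t")
    if len(fields) < 11:
        raise SamParseError(
            f"SAM record has {len(fields)} fields (11 required)", line_number
        )
    rname = fields[2]
    if rname != "*" and rname not in header.references:
        raise ReferenceMismatchError(
            f"line {line_number}: unknown scaffold {rname!r}"
            if line_number is not None
            else f"unknown scaffold {rname!r}"
        )
    try:
        seg = pysam.AlignedSegment.fromstring(line, header)
    except ValueError as exc:
        raise SamParseError(f"unparseable SAM record ({exc})", line_number) from exc
    return AlignmentRecord.from_pysam(seg)


def read_sam(path: str, vector_name: str) -> tuple[ReferenceSet, Iterator[AlignmentRecord]]:
    """Open a SAM or BAM file and yield parsed records.

    Returns the :class:`ReferenceSet` derived from the header (the vector
    scaffold must be present) and a lazy record iterator.
    """
    handle = pysam.AlignmentFile(path, check_sq=False)
    refs = ReferenceSet.from_sam_header(handle.header, vector_name)

    def _iter() -> Iterator[AlignmentRecord]:
        with handle:
            for seg in handle.fetch(until_eof=True):
                yield AlignmentRecord.from_pysam(seg)

    return refs, _iter()
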