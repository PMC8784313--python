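"""Splice-junction read filter: keep only alignments whose CIGAR contains N.

Junctionless reads in nuclear RNA preps are dominated by genomic-DNA
background; restricting analysis to junction-spanning records removes it.
Header lines pass through untouched; secondary/supplementary alignments are
dropped before the junction test (configurable).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from .errors import SamParseError

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_CIGAR_FULL_RE = re.compile(r"^(?:\d+[MIDNSHP=X])+$")

FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800

_REF_CONSUMING = frozenset("MDN=X")


def parse_cigar(cigar: str, *, context: str = "") -> tuple[tuple[int, str], ...]:
    """Parse a CIGAR string into (length, op) tuples; '*' yields ()."""
    if cigar == "*":
        return ()
    if not _CIGAR_FULL_RE.match(cigar):
        where = f" in {context}" if context else ""
        raise SamParseError(f"malformed CIGAR string {cigar!r}{where}")
    return tuple((int(n), op) for n, op in _CIGAR_RE.findall(cigar))


@dataclass(frozen=True)
class AlignedRead:
    """A parsed SAM alignment record (mandatory columns only)."""

    qname: str
    flag: int
    chrom: str
    pos: int  # 1-based leftmost mapping position
    cigar: tuple[tuple[int, str], ...]

    @property
    def strand(self) -> str:
        return "-" if self.flag & FLAG_REVERSE else "+"

    @property
    def is_mapped(self) -> bool:
        return not self.flag & FLAG_UNMAPPED and bool(self.cigar)

    @property
    def reference_length(self) -> int:
        return sum(n for n, op in self.cigar if op in _REF_CONSUMING)

    @classmethod
    def from_sam_line(cls, line: str, *, lineno: int | None = None) -> "AlignedRead":
        fields = line.rstrip("\n").split("\t")
        where = f"line {lineno}" if lineno is not None else f"record {fields[0]!r}"
        if len(fields) < 11:
            raise SamParseError(
                f"truncated SAM record ({len(fields)} fields) at {where}"
            )
        try:
            flag = int(fields[1])
            pos = int(fields[3])
        except ValueError as exc:
            raise SamParseError(f"non-numeric FLAG/POS at {where}") from exc
        return cls(
            qname=fields[0],
            flag=flag,
            chrom=fields[2],
            pos=pos,
            cigar=parse_cigar(fields[5], context=where),
        )


def is_junction_spanning(read: AlignedRead) -> bool:
    """True iff at least one CIGAR operation is N (reference skip)."""
    if not read.cigar:  # unmapped / CIGAR "*"
        return False
    return any(op == "N" for _, op in read.cigar)


@dataclass
class FilterStats:
    total: int = 0
    kept: int = 0
    dropped_no_junction: int = 0
    dropped_secondary: int = 0

    @property
    def dropped(self) -> int:
        return self.dropped_no_junction + self.dropped_secondary


def filter_sam(
    lines: Iterable[str],
    *,
    keep_secondary: bool = False,
) -> tuple[list[str], FilterStats]:
    """Filter a SAM text stream to junction-spanning records.

    Header lines ("@"-prefixed) pass through byte-identical and in order;
    alignment records are kept iff their CIGAR contains an N op.  Secondary
    and supplementary alignments are discarded before the junction test
    unless ``keep_secondary``.
    """
    out: list[str] = []
    stats = FilterStats()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        if line.startswith("@"):
            out.append(line)
            continue
        stats.total += 1
        read = AlignedRead.from_sam_line(line, lineno=lineno)
        if not keep_secondary and read.flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY):
            stats.dropped_secondary += 1
            continue
        if is_junction_spanning(read):
            stats.kept += 1
            out.append(line)
        else:
            stats.dropped_no_junction += 1
    return out, stats


def iter_alignments(lines: Iterable[str]) -> Iterator[AlignedRead]:
    """Parse alignment records from SAM text, skipping header lines."""
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("@"):
            continue
        yield AlignedRead.from_sam_line(line, lineno=lineno)


def read_sam(path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh]
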