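"""SGA-format I/O and annotation interval reading.

SGA (Simple Genome Annotation) is a 5-column tab-delimited text format for
mapped-tag data: chromosome, feature name, position, strand, count.  The
position is the 1-based chromosomal coordinate of the 5' end of a mapped
tag; the strand is ``+`` or ``-`` for oriented tags and ``0`` for centered
(unoriented) records; the count is the number of tags mapping to that exact
position and strand.  Files are sorted by (chromosome, position, strand) so
downstream tools can process them in a single sequential sweep.

Annotation intervals (repeat families, exons, upstream regions) are carried
as 1-based inclusive spans internally; BED input is converted on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

__all__ = [
    "TagRecord",
    "GenomicInterval",
    "SgaParseError",
    "read_sga",
    "write_sga",
    "sga_to_bed",
    "read_intervals",
    "read_wiggle",
    "sort_key",
    "is_sorted",
]

_STRANDS = ("+", "-", "0")
# + sorts before -, which sorts before 0, at equal (chrom, pos)
_STRAND_RANK = {"+": 0, "-": 1, "0": 2}


class SgaParseError(ValueError):
    """Raised for malformed SGA or interval lines; carries the line number."""


@dataclass(frozen=True, slots=True)
class TagRecord:
    """One SGA line: a tag count at a single genomic position and strand."""

    chrom: str
    feature: str
    pos: int
    strand: str
    count: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """An annotation span, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int
    name: str = ""
    class_label: str | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) must be >= start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def sort_key(record: TagRecord, chrom_order: Sequence[str] | None = None):
    """SGA ordering key: chromosome, position, strand (+ before - before 0).

    Chromosomes sort lexicographically unless an explicit ``chrom_order``
    list is supplied.
    """
    if chrom_order is None:
        chrom_key: object = record.chrom
    else:
        try:
            chrom_key = chrom_order.index(record.chrom)
        except ValueError:
            raise ValueError(f"chromosome {record.chrom!r} not in chrom_order")
    return (chrom_key, record.pos, _STRAND_RANK[record.strand])


def is_sorted(records: Sequence[TagRecord],
              chrom_order: Sequence[str] | None = None) -> bool:
    keys = [sort_key(r, chrom_order) for r in records]
    return all(a <= b for a, b in zip(keys, keys[1:]))


def _open_maybe(path_or_file, mode: str):
    if isinstance(path_or_file, (str, Path)):
        return open(path_or_file, mode), True
    return path_or_file, False


def read_sga(path_or_file, *, resort: bool = False,
             chrom_order: Sequence[str] | None = None) -> list[TagRecord]:
    """Parse an SGA file into a sorted list of :class:`TagRecord`.

    Parameters
    ----------
    path_or_file
        Path or open text handle of a tab-delimited file with at least
        five fields per line.
    resort
        If True, unsorted input is re-sorted; if False (default) it is
        rejected, because every downstream sweep relies on the ordering.
    chrom_order
        Optional explicit chromosome ordering used for the sort check.

    Raises
    ------
    SgaParseError
        On a malformed line (wrong field count, non-integer position or
        count, unknown strand), naming the offending line number.
    """
    handle, close = _open_maybe(path_or_file, "r")
    records: list[TagRecord] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise SgaParseError(
                    f"line {lineno}: expected >= 5 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, feature, pos_s, strand, count_s = fields[:5]
            try:
                pos = int(pos_s)
                count = int(count_s)
            except ValueError:
                raise SgaParseError(
                    f"line {lineno}: non-integer position or count"
                ) from None
            try:
                records.append(TagRecord(chrom, feature, pos, strand, count))
            except ValueError as exc:
                raise SgaParseError(f"line {lineno}: {exc}") from None
    finally:
        if close:
            handle.close()

    if not is_sorted(records, chrom_order):
        if not resort:
            raise SgaParseError(
                "input is not sorted by (chrom, pos, strand); "
                "pass resort=True to sort on read"
            )
        records.sort(key=lambda r: sort_key(r, chrom_order))
    return records


def write_sga(records: Sequence[TagRecord], path_or_file, *,
              sort: bool = False,
              chrom_order: Sequence[str] | None = None) -> None:
    """Write records as SGA. Input must be sorted unless ``sort`` is set."""
    if not is_sorted(records, chrom_order):
        if not sort:
            raise ValueError("records are not sorted; pass sort=True")
        records = sorted(records, key=lambda r: sort_key(r, chrom_order))
    handle, close = _open_maybe(path_or_file, "w")
    try:
        for r in records:
            handle.write(f"{r.chrom}\t{r.feature}\t{r.pos}\t{r.strand}\t{r.count}\n")
    finally:
        if close:
            handle.close()


def sga_to_bed(records: Iterable[TagRecord], span: int = 1) -> list[str]:
    """Convert SGA records to BED6 lines.

    Each record maps to the 0-based half-open interval
    ``[pos - 1, pos - 1 + span)``; the count goes in the score column and
    the strand in column 6 (``.`` for centered records).  The feature name
    fills the name column when non-empty.
    """
    if span < 1:
        raise ValueError(f"span must be >= 1, got {span}")
    lines = []
    for r in records:
        strand = r.strand if r.strand in ("+", "-") else "."
        name = r.feature if r.feature else "."
        lines.append(
            f"{r.chrom}\t{r.pos - 1}\t{r.pos - 1 + span}\t{name}\t{r.count}\t{strand}"
        )
    return lines


def read_intervals(path_or_file, *, fmt: str = "bed") -> list[GenomicInterval]:
    """Read annotation intervals from BED or 1-based TSV.

    ``fmt='bed'``: 0-based half-open (chrom, start, end, [name], [score],
    [strand], [class]); converted to 1-based inclusive on read.
    ``fmt='tsv'``: already 1-based inclusive (chrom, start, end, name,
    [class]).
    """
    if fmt not in ("bed", "tsv"):
        raise ValueError(f"fmt must be 'bed' or 'tsv', got {fmt!r}")
    handle, close = _open_maybe(path_or_file, "r")
    out: list[GenomicInterval] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SgaParseError(
                    f"line {lineno}: expected >= 3 fields, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError:
                raise SgaParseError(f"line {lineno}: non-integer coordinates") from None
            name = fields[3] if len(fields) > 3 else ""
            if fmt == "bed":
                # BED [start, end) 0-based -> [start+1, end] 1-based
                start1, end1 = start + 1, end
                class_label = fields[6] if len(fields) > 6 else None
            else:
                start1, end1 = start, end
                class_label = fields[4] if len(fields) > 4 else None
            if end1 < start1:
                raise SgaParseError(
                    f"line {lineno}: empty or inverted interval after conversion"
                )
            out.append(GenomicInterval(chrom, start1, end1, name, class_label))
    finally:
        if close:
            handle.close()
    return out


def read_wiggle(path_or_file) -> list[tuple[str, int, float]]:
    """Read a fixed-step wiggle track into (chrom, pos, value) triples.

    Supports ``fixedStep chrom=... start=... [step=...]`` blocks with
    1-based start coordinates.
    """
    handle, close = _open_maybe(path_or_file, "r")
    out: list[tuple[str, int, float]] = []
    chrom, pos, step = None, 1, 1
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                attrs = dict(f.split("=", 1) for f in line.split()[1:])
                chrom = attrs["chrom"]
                pos = int(attrs.get("start", 1))
                step = int(attrs.get("step", 1))
                continue
            if chrom is None:
                raise SgaParseError(
                    f"line {lineno}: data before a fixedStep declaration"
                )
            out.append((chrom, pos, float(line)))
            pos += step
    finally:
        if close:
            handle.close()
    return out
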