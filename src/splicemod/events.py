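"""Cassette-exon splicing event identifiers.

A cassette (skipped) exon event is written as three ``@``-separated blocks,

    chrom:start:end:strand@chrom:start:end:strand@chrom:start:end:strand

with the upstream exon, the cassette exon and the downstream exon in listed
order.  The *middle* block is always the alternatively spliced exon, whatever
the genomic ordering of the coordinates — minus-strand events occur with blocks
listed in either ascending or descending genomic order.  Coordinates are
1-based inclusive and are stored verbatim; no genome arithmetic is performed.

Identifier strings found in the wild frequently carry stray spaces and
line-break artifacts inside the blocks, so the parser discards *all*
whitespace before splitting.  The original text is kept on ``raw``;
:func:`format_event_id` always emits the canonical whitespace-free form, and
``parse_event_id(format_event_id(ev)) == ev`` holds for every valid event.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["SplicingEventID", "EventParseError", "parse_event_id", "format_event_id"]


class EventParseError(ValueError):
    """Raised when an event identifier string cannot be parsed."""


_BLOCK_RE = re.compile(r"^(?P<chrom>[^:@]+):(?P<start>\d+):(?P<end>\d+):(?P<strand>[+-])$")


@dataclass(frozen=True)
class SplicingEventID:
    """A parsed three-exon cassette event.

    Parameters
    ----------
    chrom
        Chromosome name shared by all three blocks.
    blocks
        Exactly three ``(start, end)`` pairs, 1-based inclusive, in listed
        order (upstream exon, cassette exon, downstream exon).
    strand
        ``'+'`` or ``'-'``, shared by all three blocks.
    raw
        The original identifier string, verbatim.  Empty for events built
        programmatically; :attr:`canonical` is then the identifier of record.
    """

    chrom: str
    blocks: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    strand: str
    raw: str = ""

    def __post_init__(self) -> None:
        if len(self.blocks) != 3:
            raise EventParseError(
                f"expected exactly 3 blocks, got {len(self.blocks)}"
            )
        if self.strand not in ("+", "-"):
            raise EventParseError(f"invalid strand {self.strand!r}")
        for i, (start, end) in enumerate(self.blocks, start=1):
            if start > end:
                raise EventParseError(
                    f"start > end ({start} > {end}) in block {i}"
                )
        object.__setattr__(self, "blocks", tuple(tuple(b) for b in self.blocks))

    @property
    def cassette(self) -> tuple[int, int]:
        """The alternatively spliced exon: always the middle listed block."""
        return self.blocks[1]

    @property
    def canonical(self) -> str:
        """Canonical whitespace-free identifier string."""
        return format_event_id(self)

    def __eq__(self, other: object) -> bool:
        # `raw` is provenance, not identity: two spellings of the same event
        # (whitespace artifacts) compare equal.
        if not isinstance(other, SplicingEventID):
            return NotImplemented
        return (
            self.chrom == other.chrom
            and self.blocks == other.blocks
            and self.strand == other.strand
        )

    def __hash__(self) -> int:
        return hash((self.chrom, self.blocks, self.strand))

    def to_bed6(self, name: str | None = None) -> str:
        """Cassette exon as a BED6 line (0-based half-open)."""
        start, end = self.cassette
        return "\t".join(
            [self.chrom, str(start - 1), str(end), name or self.canonical, "0", self.strand]
        )


def format_event_id(event: SplicingEventID) -> str:
    """Format an event in the canonical ``chrom:start:end:strand@...`` form."""
    return "@".join(
        f"{event.chrom}:{start}:{end}:{event.strand}" for start, end in event.blocks
    )


def parse_event_id(text: str) -> SplicingEventID:
    """Parse a three-block cassette-exon identifier.

    Whitespace anywhere in the string (around or inside blocks) is tolerated
    and discarded.  Raises :class:`EventParseError` naming the offending block
    on malformed input: wrong block count, non-integer coordinates,
    inconsistent chromosome or strand across blocks, or start > end.
    """
    if not text or not text.strip():
        raise EventParseError("empty event identifier")
    compact = re.sub(r"\s+", "", text)
    parts = compact.split("@")
    if len(parts) != 3:
        raise EventParseError(
            f"expected 3 '@'-separated blocks, got {len(parts)} in {text!r}"
        )
    chrom: str | None = None
    strand: str | None = None
    blocks: list[tuple[int, int]] = []
    for i, part in enumerate(parts, start=1):
        m = _BLOCK_RE.match(part)
        if m is None:
            raise EventParseError(f"malformed block {i}: {part!r}")
        b_chrom = m.group("chrom")
        start, end = int(m.group("start")), int(m.group("end"))
        b_strand = m.group("strand")
        if start > end:
            raise EventParseError(f"start > end ({start} > {end}) in block {i}")
        if chrom is None:
            chrom, strand = b_chrom, b_strand
        else:
            if b_chrom != chrom:
                raise EventParseError(
                    f"inconsistent chromosome in block {i}: {b_chrom!r} != {chrom!r}"
                )
            if b_strand != strand:
                raise EventParseError(
                    f"inconsistent strand in block {i}: {b_strand!r} != {strand!r}"
                )
        blocks.append((start, end))
    assert chrom is not None and strand is not None
    return SplicingEventID(
        chrom=chrom,
        blocks=(blocks[0], blocks[1], blocks[2]),
        strand=strand,
        raw=text,
    )
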