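"""Genomic interval primitives.

All coordinates are 0-based, half-open ([start, end)), the convention shared
by Bedgraph, BED and UCSC refGene tables.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval, optionally stranded.

    Parameters
    ----------
    chrom : chromosome / contig name.
    start : 0-based inclusive start.
    end : 0-based exclusive end; must satisfy ``end > start`` for a
        non-empty interval.
    strand : ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)
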