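"""Gene-level read counting, RPKM conversion and expression classes.

Counting follows HTSeq-count union semantics at the gene level: a read is
assigned to a gene when any of its blocks overlaps that gene's exonic union
by at least one base; reads touching exons of more than one gene are
discarded as ambiguous; intron-only overlaps are never counted.  Counts are
converted to RPKM (reads per kilobase of exon model per million mapped
reads) and classed as inactive (RPKM < 1), active (>= 1) or highly expressed
(> 5).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence, TextIO, Union

import pandas as pd
from intervaltree import IntervalTree

from .annotations import AnalysisParams, GeneModel
from .intervals import GenomicInterval

INACTIVE, ACTIVE, HIGH = "inactive", "active", "high"


@dataclass(frozen=True)
class Read:
    """One sequenced read: one block, or several for a spliced alignment."""

    name: str
    blocks: tuple[GenomicInterval, ...]


@dataclass(frozen=True)
class CountStats:
    assigned: int
    ambiguous: int
    no_feature: int

    @property
    def total(self) -> int:
        return self.assigned + self.ambiguous + self.no_feature


@dataclass(frozen=True)
class ExpressionRecord:
    gene: str
    read_count: int
    exonic_length_bp: int
    rpkm: float
    activity_class: str


def read_bed_reads(source: Union[str, TextIO, Iterable[str]]) -> list[Read]:
    """Read BED6 alignments; rows sharing a name are blocks of one read."""
    if hasattr(source, "read") or isinstance(source, str):
        if hasattr(source, "read"):
            stream: Iterator[str] = iter(source)  # type: ignore[arg-type]
        elif str(source).endswith(".gz"):
            stream = iter(gzip.open(source, "rt"))
        else:
            stream = iter(open(source, "rt"))
    else:
        stream = iter(source)

    by_name: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    anon = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ValueError(f"line {lineno}: expected >= 3 BED columns")
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
        if name is None:
            anon += 1
            name = f"_read{anon}"
        iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
        if name not in by_name:
            order.append(name)
            by_name[name] = []
        by_name[name].append(iv)
    return [Read(name=n, blocks=tuple(by_name[n])) for n in order]


def count_reads(
    reads: Sequence[Read],
    genes: Sequence[GeneModel],
) -> tuple[dict[str, int], CountStats]:
    """Union-exon gene-level counts with ambiguous-read discarding."""
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        for ex in g.exons:
            tree.addi(ex.start, ex.end, g.name)

    counts = {g.name: 0 for g in genes}
    assigned = ambiguous = no_feature = 0
    for read in reads:
        hits: set[str] = set()
        for block in read.blocks:
            tree = trees.get(block.chrom)
            if tree is not None:
                hits.update(iv.data for iv in tree.overlap(block.start, block.end))
        if len(hits) == 1:
            counts[hits.pop()] += 1
            assigned += 1
        elif len(hits) > 1:
            ambiguous += 1
        else:
            no_feature += 1
    return counts, CountStats(assigned=assigned, ambiguous=ambiguous, no_feature=no_feature)


def rpkm(count: int, exonic_length_bp: int, total_mapped: int) -> float:
    """RPKM = count * 1e9 / (exonic_length_bp * total_mapped)."""
    if exonic_length_bp <= 0:
        raise ValueError("exonic_length_bp must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return count * 1e9 / (exonic_length_bp * total_mapped)


def classify(value: float, params: AnalysisParams = AnalysisParams()) -> str:
    """Expression class: inactive (< active cutoff), high (> high cutoff), else active.

    Boundary values land in 'active': RPKM exactly 1 is active (the inactive
    class is strictly below the cutoff), and RPKM exactly 5 is active rather
    than high (the high class is strictly above).
    """
    if value < 0:
        raise ValueError("RPKM must be non-negative")
    if value < params.rpkm_active:
        return INACTIVE
    if value > params.rpkm_high:
        return HIGH
    return ACTIVE


def expression_table(
    reads: Sequence[Read],
    genes: Sequence[GeneModel],
    params: AnalysisParams = AnalysisParams(),
    *,
    total_mapped: int | None = None,
) -> tuple[pd.DataFrame, CountStats]:
    """Count, convert to RPKM and class every gene; returns a tidy table.

    ``total_mapped`` defaults to the number of input reads (all reads in the
    library are mapped in this representation).
    """
    counts, stats = count_reads(reads, genes)
    total = total_mapped if total_mapped is not None else len(reads)
    if total <= 0:
        raise ValueError("total mapped reads must be positive")
    rows = []
    for g in genes:
        value = rpkm(counts[g.name], g.exonic_length, total)
        rows.append(
            {
                "gene": g.name,
                "name2": g.name2,
                "read_count": counts[g.name],
                "exonic_length_bp": g.exonic_length,
                "rpkm": value,
                "activity_class": classify(value, params),
            }
        )
    return pd.DataFrame(rows), stats
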