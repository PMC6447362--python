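"""Gene annotations: refGene parsing, intron/triplet derivation, gene filters.

The annotation unit is a transcription unit (one refGene row): an ordered,
non-overlapping set of exons tiling the transcript span together with the
introns between them.  Downstream analyses consume

* isolated genes (no neighbour within a configurable distance of the
  flank-extended span), so that flanking-region signal is unambiguous, and
* exon–intron–exon triplets, the unit of the exon/intron occupancy
  comparison, optionally restricted to introns longer than a cutoff.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO, Union

from .intervals import GenomicInterval


class RefGeneParseError(ValueError):
    """Raised for malformed refGene rows; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass(frozen=True)
class GeneModel:
    """One transcription unit with its ordered exon structure."""

    name: str
    name2: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.name}: gene model requires at least one exon")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.span.chrom:
                raise ValueError(f"{self.name}: exon chromosome differs from span")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"{self.name}: exons unsorted or overlapping")
            prev_end = ex.end
        if self.exons[0].start != self.span.start or self.exons[-1].end != self.span.end:
            raise ValueError(f"{self.name}: exons do not tile the transcript span ends")

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware; '-' genes start at span.end)."""
        return self.span.start if self.strand != "-" else self.span.end

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass(frozen=True)
class ExonIntronTriplet:
    """An intron with its two immediately adjacent exons, in genomic order."""

    gene_name: str
    left_exon: GenomicInterval
    intron: GenomicInterval
    right_exon: GenomicInterval

    def __post_init__(self) -> None:
        if self.left_exon.end != self.intron.start or self.intron.end != self.right_exon.start:
            raise ValueError(f"{self.gene_name}: triplet intervals are not contiguous")

    # Strand-aware accessors; left/right above are genomic orientation.
    @property
    def upstream_exon(self) -> GenomicInterval:
        return self.left_exon if self.intron.strand != "-" else self.right_exon

    @property
    def downstream_exon(self) -> GenomicInterval:
        return self.right_exon if self.intron.strand != "-" else self.left_exon


@dataclass(frozen=True)
class AnalysisParams:
    """Shared analysis constants.

    flank_bp
        Single-base-resolution flank on each side of the gene body (500).
    n_bins
        Number of gene-body bins in scaled profiles (16).
    min_intron_bp
        Triplets are kept only for introns strictly longer than this (100).
    rpkm_active / rpkm_high
        Expression-class boundaries: RPKM < rpkm_active is inactive,
        RPKM > rpkm_high is highly expressed.
    min_separation_bp
        Required gap between flank-extended spans of neighbouring genes for
        a gene to count as isolated.
    read_length_bp
        Sequenced read length, used as the mapped-read proxy when a track
        declares no read total.
    """

    flank_bp: int = 500
    n_bins: int = 16
    min_intron_bp: int = 100
    rpkm_active: float = 1.0
    rpkm_high: float = 5.0
    min_separation_bp: int = 1000
    read_length_bp: int = 50

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        for name in ("flank_bp", "min_intron_bp", "min_separation_bp", "read_length_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rpkm_active <= 0 or self.rpkm_high <= 0:
            raise ValueError("RPKM thresholds must be positive")


# --------------------------------------------------------------------------
# refGene I/O
# --------------------------------------------------------------------------

def _open_text(source: Union[str, TextIO]) -> TextIO:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    if str(source).endswith(".gz"):
        return gzip.open(source, "rt")
    return open(source, "rt")


def _parse_comma_list(text: str, lineno: int, what: str) -> list[int]:
    items = [t for t in text.strip().split(",") if t != ""]
    try:
        return [int(t) for t in items]
    except ValueError as exc:
        raise RefGeneParseError(lineno, f"non-integer {what}: {text!r}") from exc


def parse_refgene(source: Union[str, TextIO, Iterable[str]]) -> list[GeneModel]:
    """Parse a UCSC refGene-style tab-delimited table into gene models.

    The leading numeric ``bin`` column present in UCSC database dumps is
    autodetected from the position of the strand field.  Exon start/end
    comma lists are paired positionally and validated against ``exonCount``;
    any malformed row raises :class:`RefGeneParseError` naming its line.
    """
    if hasattr(source, "read") or isinstance(source, (str,)):
        stream: Iterator[str] = iter(_open_text(source))  # type: ignore[arg-type]
    else:
        stream = iter(source)

    genes: list[GeneModel] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 10:
            raise RefGeneParseError(lineno, f"expected >= 10 tab-separated fields, got {len(fields)}")
        if fields[2] in ("+", "-"):
            off = 0  # name chrom strand txStart ...
        elif len(fields) >= 11 and fields[3] in ("+", "-"):
            off = 1  # leading bin column
        else:
            raise RefGeneParseError(lineno, "cannot locate strand column (expected '+'/'-')")

        name = fields[off + 0]
        chrom = fields[off + 1]
        strand = fields[off + 2]
        try:
            tx_start = int(fields[off + 3])
            tx_end = int(fields[off + 4])
            exon_count = int(fields[off + 7])
        except ValueError as exc:
            raise RefGeneParseError(lineno, f"non-integer coordinate field: {exc}") from exc
        exon_starts = _parse_comma_list(fields[off + 8], lineno, "exonStarts")
        exon_ends = _parse_comma_list(fields[off + 9], lineno, "exonEnds")
        name2 = fields[off + 11] if len(fields) > off + 11 else name

        if len(exon_starts) != exon_count or len(exon_ends) != exon_count:
            raise RefGeneParseError(
                lineno,
                f"exonCount={exon_count} disagrees with list lengths "
                f"({len(exon_starts)} starts, {len(exon_ends)} ends)",
            )
        if sorted(exon_starts) != exon_starts:
            raise RefGeneParseError(lineno, "exonStarts not sorted")
        try:
            exons = tuple(
                GenomicInterval(chrom, s, e, strand) for s, e in zip(exon_starts, exon_ends)
            )
            span = GenomicInterval(chrom, tx_start, tx_end, strand)
            genes.append(GeneModel(name=name, name2=name2, span=span, exons=exons))
        except ValueError as exc:
            raise RefGeneParseError(lineno, str(exc)) from exc
    return genes


_REFGENE_COLUMNS = (
    "name chrom strand txStart txEnd cdsStart cdsEnd exonCount "
    "exonStarts exonEnds score name2 cdsStartStat cdsEndStat exonFrames"
).split()


def write_refgene(genes: Sequence[GeneModel], stream: TextIO) -> None:
    """Write gene models as a refGene-style table (no leading bin column)."""
    for g in genes:
        starts = ",".join(str(e.start) for e in g.exons) + ","
        ends = ",".join(str(e.end) for e in g.exons) + ","
        frames = ",".join("-1" for _ in g.exons) + ","
        row = [
            g.name, g.chrom, g.strand, str(g.span.start), str(g.span.end),
            str(g.span.start), str(g.span.end), str(len(g.exons)),
            starts, ends, "0", g.name2, "none", "none", frames,
        ]
        stream.write("\t".join(row) + "\n")


# --------------------------------------------------------------------------
# Feature derivation and gene filters
# --------------------------------------------------------------------------

def derive_features(
    gene: GeneModel,
    params: AnalysisParams = AnalysisParams(),
    *,
    filter_short: bool = True,
) -> tuple[list[GenomicInterval], list[ExonIntronTriplet]]:
    """Derive introns and exon–intron–exon triplets from one gene model.

    Introns are the gaps between consecutive exons (zero-length gaps are
    never emitted).  One triplet is produced per retained intron together
    with its immediately adjacent exons, in genomic left-to-right order.
    With ``filter_short`` (the default) triplets are restricted to introns
    strictly longer than ``params.min_intron_bp``; the returned intron list
    is always unfiltered.
    """
    introns: list[GenomicInterval] = []
    triplets: list[ExonIntronTriplet] = []
    for left, right in zip(gene.exons, gene.exons[1:]):
        if right.start == left.end:
            continue  # abutting exons, no intron
        intron = GenomicInterval(gene.chrom, left.end, right.start, gene.strand)
        introns.append(intron)
        if filter_short and len(intron) <= params.min_intron_bp:
            continue
        triplets.append(
            ExonIntronTriplet(gene_name=gene.name, left_exon=left, intron=intron, right_exon=right)
        )
    return introns, triplets


def derive_all_triplets(
    genes: Sequence[GeneModel],
    params: AnalysisParams = AnalysisParams(),
    *,
    filter_short: bool = True,
    deduplicate: bool = False,
) -> list[ExonIntronTriplet]:
    """All triplets across genes.

    With ``deduplicate``, triplets whose three intervals coincide (shared
    intron structure of transcript isoforms) are emitted once, keeping the
    first transcript's attribution; otherwise one triplet per transcript.
    """
    out: list[ExonIntronTriplet] = []
    seen: set[tuple] = set()
    for g in genes:
        for t in derive_features(g, params, filter_short=filter_short)[1]:
            if deduplicate:
                key = (t.intron.chrom, t.left_exon.start, t.intron.start,
                       t.intron.end, t.right_exon.end)
                if key in seen:
                    continue
                seen.add(key)
            out.append(t)
    return out


def filter_genes(
    genes: Sequence[GeneModel],
    params: AnalysisParams = AnalysisParams(),
) -> list[GeneModel]:
    """Keep uniquely named, isolated genes.

    Two rules, applied in order, both conservative:

    1. every entry whose ``name`` occurs more than once is removed (all
       copies, not keep-first), because downstream cross-referencing between
       datasets is by the name field;
    2. every gene whose span, extended by ``params.flank_bp`` on both sides,
       comes within ``params.min_separation_bp`` of another gene's extended
       span on the same chromosome is removed (both parties), so flanking
       signal cannot bleed between neighbours.

    Input order is preserved; the operation is idempotent.
    """
    counts: dict[str, int] = {}
    for g in genes:
        counts[g.name] = counts.get(g.name, 0) + 1
    unique = [g for g in genes if counts[g.name] == 1]

    # Sweep per chromosome over flank-extended spans; a pair conflicts when
    # the gap between extended spans is < min_separation_bp.
    flank = params.flank_bp
    sep = params.min_separation_bp
    crowded: set[int] = set()
    by_chrom: dict[str, list[int]] = {}
    for idx, g in enumerate(unique):
        by_chrom.setdefault(g.chrom, []).append(idx)
    for idxs in by_chrom.values():
        order = sorted(idxs, key=lambda i: unique[i].span.start)
        active: list[int] = []  # indices whose extended end + sep may still reach
        for i in order:
            ext_start = unique[i].span.start - flank
            ext_end = unique[i].span.end + flank
            active = [j for j in active if unique[j].span.end + flank + sep > ext_start]
            if active:
                crowded.add(i)
                crowded.update(active)
            active.append(i)
    return [g for i, g in enumerate(unique) if i not in crowded]


def write_triplets_tsv(triplets: Sequence[ExonIntronTriplet], stream: TextIO) -> None:
    stream.write(
        "gene\tchrom\tleft_start\tleft_end\tintron_start\tintron_end\t"
        "right_start\tright_end\tstrand\n"
    )
    for t in triplets:
        stream.write(
            f"{t.gene_name}\t{t.intron.chrom}\t{t.left_exon.start}\t{t.left_exon.end}\t"
            f"{t.intron.start}\t{t.intron.end}\t{t.right_exon.start}\t{t.right_exon.end}\t"
            f"{t.intron.strand}\n"
        )
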