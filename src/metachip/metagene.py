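"""Scaled gene-body occupancy profiles and averaged metagene curves.

Each gene contributes a vector of ``flank + n_bins + flank`` positions:
single-base resolution over the two 500 bp flanks and, between them, the
gene body partitioned into 16 contiguous bins so genes of different lengths
are comparable.  Vectors are oriented 5'→3' (minus-strand genes are
reversed), averaged pointwise across genes, and scaled per million mapped
reads of the originating library.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TextIO

import numpy as np

from .annotations import AnalysisParams, GeneModel
from .coverage import CoverageTrack, TrackSummary


class GeneTooShort(ValueError):
    """Gene body shorter than the bin count; the gene cannot be profiled."""


@dataclass(frozen=True)
class GeneProfile:
    gene: str
    vector: np.ndarray  # length 2*flank_bp + n_bins, oriented 5'->3'


@dataclass(frozen=True)
class MetageneProfile:
    mean: np.ndarray
    n_genes: int
    scale_per_million: float
    stratum: str = ""


def body_bin_edges(start: int, end: int, n_bins: int, *, remainder_first: bool = True) -> np.ndarray:
    """Contiguous bin edges over [start, end); the remainder of length
    ``L mod n_bins`` is spread one base each over the earliest bins.

    ``remainder_first=False`` widens the latest bins instead; profiles use
    it for minus-strand genes so the widened bins sit at the 5' end after
    reversal, which makes profiling strand-mirror symmetric.
    """
    length = end - start
    base, rem = divmod(length, n_bins)
    sizes = np.full(n_bins, base, dtype=np.int64)
    if rem:
        if remainder_first:
            sizes[:rem] += 1
        else:
            sizes[-rem:] += 1
    return start + np.concatenate(([0], np.cumsum(sizes)))


def gene_profile(
    track: CoverageTrack,
    gene: GeneModel,
    params: AnalysisParams = AnalysisParams(),
) -> GeneProfile:
    """Profile one gene: per-base flanks around binned gene-body means.

    Genomic positions before the start of the chromosome read as zero.
    Raises :class:`GeneTooShort` when the gene body has fewer bases than
    bins.
    """
    span = gene.span
    if len(span) < params.n_bins:
        raise GeneTooShort(f"{gene.name}: length {len(span)} < {params.n_bins} bins")
    flank = params.flank_bp
    chrom = gene.chrom

    up = _flank_values(track, chrom, span.start - flank, span.start)
    edges = body_bin_edges(
        span.start, span.end, params.n_bins, remainder_first=gene.strand != "-"
    )
    body = track.interval_means(chrom, edges[:-1], edges[1:])
    down = _flank_values(track, chrom, span.end, span.end + flank)

    vec = np.concatenate([up, body, down])
    if gene.strand == "-":
        vec = vec[::-1]
    return GeneProfile(gene=gene.name, vector=vec)


def _flank_values(track: CoverageTrack, chrom: str, start: int, end: int) -> np.ndarray:
    if start >= 0:
        if chrom not in track._chroms:
            return np.zeros(end - start)
        return track._chroms[chrom].dense(start, end)
    pad = -start
    out = np.zeros(end - start)
    if end > 0 and chrom in track._chroms:
        out[pad:] = track._chroms[chrom].dense(0, end)
    return out


def gene_profiles(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    params: AnalysisParams = AnalysisParams(),
) -> tuple[list[GeneProfile], list[tuple[str, str]]]:
    """Profile many genes; returns (profiles, skipped [(gene, reason), ...])."""
    profiles: list[GeneProfile] = []
    skipped: list[tuple[str, str]] = []
    for g in genes:
        try:
            profiles.append(gene_profile(track, g, params))
        except GeneTooShort as exc:
            skipped.append((g.name, str(exc)))
    return profiles, skipped


def metagene_average(
    profiles: Sequence[GeneProfile],
    track_summary: TrackSummary,
    *,
    stratum: str = "",
) -> MetageneProfile:
    """Pointwise mean of gene profiles, scaled per million mapped reads."""
    if not profiles:
        raise ValueError("metagene_average requires at least one profile")
    lengths = {p.vector.shape[0] for p in profiles}
    if len(lengths) != 1:
        raise ValueError("profiles have mixed lengths")
    stack = np.stack([p.vector for p in profiles])
    mean = stack.mean(axis=0) * track_summary.scale_per_million
    return MetageneProfile(
        mean=mean,
        n_genes=len(profiles),
        scale_per_million=track_summary.scale_per_million,
        stratum=stratum,
    )


def position_labels(params: AnalysisParams = AnalysisParams()) -> list[str]:
    """Axis labels: -flank..-1, bin1..binN, +1..+flank."""
    flank, n_bins = params.flank_bp, params.n_bins
    return (
        [str(-i) for i in range(flank, 0, -1)]
        + [f"bin{i}" for i in range(1, n_bins + 1)]
        + [f"+{i}" for i in range(1, flank + 1)]
    )


def write_metagene_tsv(
    profiles: Sequence[MetageneProfile],
    stream: TextIO,
    params: AnalysisParams = AnalysisParams(),
) -> None:
    labels = position_labels(params)
    stream.write("position\tmean\tstratum\tn_genes\n")
    for prof in profiles:
        for label, value in zip(labels, prof.mean):
            stream.write(f"{label}\t{value:.6g}\t{prof.stratum}\t{prof.n_genes}\n")
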