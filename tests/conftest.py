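import numpy as np
import pytest

from metachip import CoverageTrack, GeneModel, GenomicInterval


def make_track(steps, *, chrom="chr1", total_mapped_reads=None, label=""):
    """Build a track from [(start, end, value), ...] on one chromosome."""
    starts = np.array([s for s, _, _ in steps], dtype=np.int64)
    ends = np.array([e for _, e, _ in steps], dtype=np.int64)
    values = np.array([v for _, _, v in steps], dtype=np.float64)
    return CoverageTrack(
        {chrom: (starts, ends, values)},
        total_mapped_reads=total_mapped_reads,
        label=label,
    )


def dense_of(steps, length, *, dtype=np.float64):
    """Independent per-base expansion of a step list (test oracle)."""
    arr = np.zeros(length, dtype=dtype)
    for s, e, v in steps:
        arr[s:e] = v
    return arr


def mirror_steps(steps, length):
    """Reflect steps around the midpoint of a chromosome of given length."""
    return sorted((length - e, length - s, v) for s, e, v in steps)


def make_gene(exon_pairs, *, name="g1", chrom="chr1", strand="+", name2=None):
    exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_pairs)
    span = GenomicInterval(chrom, exon_pairs[0][0], exon_pairs[-1][1], strand)
    return GeneModel(name=name, name2=name2 or name, span=span, exons=exons)


def mirror_gene(gene, length):
    """The same gene on the reflected chromosome, with flipped strand."""
    pairs = sorted((length - e.end, length - e.start) for e in gene.exons)
    strand = "-" if gene.strand == "+" else "+"
    return make_gene(pairs, name=gene.name, chrom=gene.chrom, strand=strand)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
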