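"""Synthetic annotation, coverage-track and read generator with ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: non-overlapping multi-exon transcription units on one chromosome;
an input (control) library of uniform per-base element rate; a UPF1-like
ChIP library whose per-base element rate is multiplied by ``f_exon`` on
exons relative to introns; a Ser2 Pol II-like ChIP library with a Gaussian
occupancy peak at the transcription start site; and single-end RNA reads
sampled from exonic sequence in proportion to each gene's expression level,
which spans the RPKM <1 / 1–5 / >5 classes.

Coverage is produced by pileup of fixed-length sequenced elements (default
50 bp, the read length) centred on Poisson-sampled binding positions, so
tracks carry read-scale autocorrelation rather than i.i.d. per-base noise;
``element_bp`` of 200 or 500 emulates fragment-scale smoothing for
sensitivity studies of boundary resolution.  Every draw is fixed by the
spec's seed (PCG64 integer-state generator), and total signal mass equals
(number of elements) x element_bp exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .annotations import GeneModel, write_refgene
from .coverage import CoverageTrack, write_bedgraph
from .expression import Read
from .intervals import GenomicInterval


@dataclass(frozen=True)
class SimulationSpec:
    """Generative parameters; every field has a documented unit.

    Rates are expected sequenced elements per base; lengths in bp.
    ``f_exon`` is the exonic occupancy multiplier of the UPF1-like track
    (introns have multiplier 1).  ``tss_peak_weight`` is the Pol II peak
    amplitude relative to the gene-body elongation rate, with Gaussian
    s.d. ``tss_peak_sd_bp``.
    """

    seed: int = 0
    n_genes: int = 200
    chrom: str = "chrSim"
    chrom_length: Optional[int] = None  # None: sized to fit the genes
    exon_count_range: tuple[int, int] = (1, 8)
    exon_bp_range: tuple[float, float] = (200.0, 2000.0)      # log-uniform
    intron_bp_range: tuple[float, float] = (60.0, 5000.0)     # log-uniform
    gap_bp_range: tuple[float, float] = (3000.0, 12000.0)     # log-uniform
    expression_meanlog: float = 0.5
    expression_sdlog: float = 1.5
    input_rate: float = 0.4            # elements/bp, uniform
    background_rate: float = 0.002     # ChIP elements/bp off-gene
    upf1_scale: float = 0.1            # ChIP elements/bp per expression unit
    f_exon: float = 3.0
    pol2_scale: float = 0.05
    tss_peak_weight: float = 6.0
    tss_peak_sd_bp: float = 100.0
    element_bp: int = 50               # piled-up sequenced element length
    rna_read_rate: float = 0.002       # RNA reads/bp of exon per expression unit
    rna_read_bp: int = 50

    def __post_init__(self) -> None:
        for name in ("input_rate", "background_rate", "upf1_scale", "pol2_scale",
                     "f_exon", "tss_peak_weight", "rna_read_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.element_bp < 1 or self.rna_read_bp < 1:
            raise ValueError("element lengths must be >= 1")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Deterministic per-gene truth for parameter-recovery tests."""

    expression: dict[str, float]
    f_exon: float
    tss_peak_weight: float
    tss_peak_sd_bp: float
    upf1_exon_rate: dict[str, float]
    upf1_intron_rate: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class SimulatedDataset:
    spec: SimulationSpec
    genes: list[GeneModel]
    chrom_length: int
    tracks: dict[str, CoverageTrack]
    rna_reads: list[Read]
    truth: GroundTruth
    rna_declared_total: int = 0
    """Declared RNA library size. The simulated chromosome is one window of
    a larger library, so RPKM uses the library total, chosen such that the
    expected RPKM of a gene equals its true expression level:
    reads/gene = E * exonic_len * rna_read_rate, hence total = rna_read_rate * 1e9."""


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def simulate_annotation(spec: SimulationSpec) -> list[GeneModel]:
    """Draw a sorted, non-overlapping annotation; deterministic in the seed.

    Genes are laid left to right with log-uniform intergenic gaps and
    alternate strand; exon counts are uniform on ``exon_count_range`` and
    exon/intron lengths log-uniform on their stated ranges.  Raises
    ``ValueError`` when an explicit ``chrom_length`` cannot hold ``n_genes``.
    """
    rng = np.random.default_rng([spec.seed, 11])
    genes: list[GeneModel] = []
    cursor = 1000  # left margin so flanks stay on-chromosome
    for k in range(spec.n_genes):
        cursor += int(round(_log_uniform(rng, *spec.gap_bp_range)))
        n_ex = int(rng.integers(spec.exon_count_range[0], spec.exon_count_range[1] + 1))
        exon_lens = np.round(_log_uniform(rng, *spec.exon_bp_range, size=n_ex)).astype(int)
        intron_lens = np.round(_log_uniform(rng, *spec.intron_bp_range, size=max(n_ex - 1, 0))).astype(int)
        strand = "+" if k % 2 == 0 else "-"
        exons = []
        pos = cursor
        for i in range(n_ex):
            exons.append(GenomicInterval(spec.chrom, pos, pos + int(exon_lens[i]), strand))
            pos += int(exon_lens[i])
            if i < n_ex - 1:
                pos += int(intron_lens[i])
        span = GenomicInterval(spec.chrom, cursor, exons[-1].end, strand)
        genes.append(
            GeneModel(name=f"g{k + 1:05d}", name2=f"SIM{k + 1}", span=span, exons=tuple(exons))
        )
        cursor = span.end
        if spec.chrom_length is not None and cursor + 1000 > spec.chrom_length:
            raise ValueError(
                f"chromosome length {spec.chrom_length} too short for {spec.n_genes} genes"
            )
    return genes


def resolved_chrom_length(spec: SimulationSpec, genes: Sequence[GeneModel]) -> int:
    if spec.chrom_length is not None:
        return spec.chrom_length
    last_end = genes[-1].span.end if genes else 0
    return last_end + 5000


def _pileup(rate: np.ndarray, rng: np.random.Generator, element_bp: int) -> tuple[np.ndarray, int]:
    """Poisson-sample element centres from a per-base rate and pile them up.

    The rate is zeroed where an element would overhang the chromosome, so
    total coverage mass is exactly n_elements * element_bp.
    """
    length = rate.shape[0]
    half = element_bp // 2
    rate = rate.copy()
    rate[:half] = 0.0
    tail = element_bp - half
    if tail > 0:
        rate[length - tail :] = 0.0
    counts = rng.poisson(rate)
    idx = np.flatnonzero(counts)
    diff = np.zeros(length + 1)
    np.add.at(diff, idx - half, counts[idx])
    np.add.at(diff, idx - half + element_bp, -counts[idx])
    coverage = np.cumsum(diff[:-1])
    return coverage, int(counts.sum())


def simulate_tracks(
    spec: SimulationSpec,
    genes: Sequence[GeneModel],
    include: Sequence[str] = ("upf1", "pol2", "input", "rna"),
) -> SimulatedDataset:
    """Generate coverage tracks, RNA reads and ground truth for an annotation."""
    length = resolved_chrom_length(spec, genes)
    rng_expr = np.random.default_rng([spec.seed, 23])
    expression = np.exp(rng_expr.normal(spec.expression_meanlog, spec.expression_sdlog, len(genes)))

    exon_mult = np.zeros(length)   # f_exon on exons, 1 on introns, 0 off-gene
    expr_base = np.zeros(length)   # per-base expression level of covering gene
    for g, e in zip(genes, expression):
        expr_base[g.span.start : g.span.end] = e
        exon_mult[g.span.start : g.span.end] = 1.0
        for ex in g.exons:
            exon_mult[ex.start : ex.end] = spec.f_exon

    tracks: dict[str, CoverageTrack] = {}
    if "upf1" in include:
        rng = np.random.default_rng([spec.seed, 31])
        rate = spec.background_rate + spec.upf1_scale * expr_base * exon_mult
        cov, n = _pileup(rate, rng, spec.element_bp)
        tracks["upf1"] = CoverageTrack.from_dense(
            {spec.chrom: cov}, label="chip_upf1", total_mapped_reads=n
        )
    if "pol2" in include:
        rng = np.random.default_rng([spec.seed, 37])
        rate = spec.background_rate + spec.pol2_scale * expr_base
        sd = spec.tss_peak_sd_bp
        win = int(4 * sd)
        for g, e in zip(genes, expression):
            lo = max(g.tss - win, 0)
            hi = min(g.tss + win, length)
            x = np.arange(lo, hi)
            rate[lo:hi] += (
                spec.pol2_scale * e * spec.tss_peak_weight
                * np.exp(-((x - g.tss) ** 2) / (2 * sd**2))
            )
        cov, n = _pileup(rate, rng, spec.element_bp)
        tracks["pol2"] = CoverageTrack.from_dense(
            {spec.chrom: cov}, label="chip_pol2", total_mapped_reads=n
        )
    if "input" in include:
        rng = np.random.default_rng([spec.seed, 41])
        rate = np.full(length, spec.input_rate)
        cov, n = _pileup(rate, rng, spec.element_bp)
        tracks["input"] = CoverageTrack.from_dense(
            {spec.chrom: cov}, label="input", total_mapped_reads=n
        )

    rna_reads: list[Read] = []
    if "rna" in include:
        rng = np.random.default_rng([spec.seed, 43])
        for g, e in zip(genes, expression):
            exonic_len = g.exonic_length
            if exonic_len < spec.rna_read_bp:
                continue
            n_reads = int(rng.poisson(e * exonic_len * spec.rna_read_rate))
            if n_reads == 0:
                continue
            starts_tx = rng.integers(0, exonic_len - spec.rna_read_bp + 1, size=n_reads)
            for j, s in enumerate(np.sort(starts_tx)):
                blocks = _transcript_to_genomic(g, int(s), int(s) + spec.rna_read_bp)
                rna_reads.append(Read(name=f"r_{g.name}_{j}", blocks=tuple(blocks)))

    truth = GroundTruth(
        expression={g.name: float(e) for g, e in zip(genes, expression)},
        f_exon=spec.f_exon,
        tss_peak_weight=spec.tss_peak_weight,
        tss_peak_sd_bp=spec.tss_peak_sd_bp,
        upf1_exon_rate={
            g.name: float(spec.background_rate + spec.upf1_scale * e * spec.f_exon)
            for g, e in zip(genes, expression)
        },
        upf1_intron_rate={
            g.name: float(spec.background_rate + spec.upf1_scale * e)
            for g, e in zip(genes, expression)
        },
    )
    return SimulatedDataset(
        spec=spec,
        genes=list(genes),
        chrom_length=length,
        tracks=tracks,
        rna_reads=rna_reads,
        truth=truth,
        rna_declared_total=int(round(spec.rna_read_rate * 1e9)),
    )


def _transcript_to_genomic(gene: GeneModel, tx_start: int, tx_end: int) -> list[GenomicInterval]:
    """Map a transcript-coordinate interval onto genomic exon blocks."""
    blocks: list[GenomicInterval] = []
    offset = 0
    for ex in gene.exons:
        ex_len = len(ex)
        lo = max(tx_start - offset, 0)
        hi = min(tx_end - offset, ex_len)
        if hi > lo:
            blocks.append(GenomicInterval(ex.chrom, ex.start + lo, ex.start + hi, ex.strand))
        offset += ex_len
        if offset >= tx_end:
            break
    return blocks


def simulate(spec: SimulationSpec, include: Sequence[str] = ("upf1", "pol2", "input", "rna")) -> SimulatedDataset:
    """Annotation + tracks in one call."""
    return simulate_tracks(spec, simulate_annotation(spec), include=include)


def write_dataset(data: SimulatedDataset, outdir: str | Path) -> dict[str, str]:
    """Write annotation, Bedgraph tracks, BED reads and ground-truth JSON.

    Every text output carries the generating seed in a header comment for
    provenance.  Returns a name -> path manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    ann_path = outdir / "annotation.refgene.txt"
    with open(ann_path, "w") as fh:
        fh.write(f"#seed={data.spec.seed}\n")
        write_refgene(data.genes, fh)
    paths["annotation"] = str(ann_path)

    for name, track in data.tracks.items():
        p = outdir / f"{name}.bedgraph"
        with open(p, "w") as fh:
            fh.write(f"#seed={data.spec.seed}\n")
            write_bedgraph(track, fh)
        paths[name] = str(p)

    reads_path = outdir / "rna_reads.bed"
    with open(reads_path, "w") as fh:
        fh.write(f"#seed={data.spec.seed}\n")
        fh.write(f"#library_total_mapped={data.rna_declared_total}\n")
        for read in data.rna_reads:
            for b in read.blocks:
                fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{read.name}\t0\t{b.strand}\n")
    paths["rna_reads"] = str(reads_path)

    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(data.truth.to_json())
    paths["ground_truth"] = str(truth_path)
    return paths
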