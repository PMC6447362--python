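"""Input-normalised exon/intron occupancy enrichment and its statistics.

The central quantity is per-feature ChIP occupancy corrected for
fragmentation and sequencing bias: mean per-base ChIP coverage divided by
mean per-base input coverage, both scaled per million mapped reads of their
library.  For each exon–intron–exon triplet this yields three normalised
values whose contrasts (left exon vs intron, right exon vs intron, left vs
right exon) are compared with the two-sided unpaired Wilcoxon rank-sum
(Mann–Whitney U) test.  Feature-scaled "percent of full length" enrichment
profiles and cross-track exon correlations complete the module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotations import ExonIntronTriplet, GeneModel
from .coverage import CoverageTrack, track_total
from .intervals import GenomicInterval


# --------------------------------------------------------------------------
# Rank-sum test
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RankSumResult:
    """Two-sided unpaired Mann–Whitney U / Wilcoxon rank-sum result."""

    u_statistic: float
    z_value: Optional[float]
    p_value: float
    method: str  # 'exact' or 'normal_tie_corrected'
    n1: int
    n2: int


def rank_sum_test(x, y, *, method: str = "auto", exact_max_n: int = 12) -> RankSumResult:
    """Two-sided unpaired rank-sum test via midranks.

    The exact null distribution (full enumeration over rank assignments) is
    used when both samples have at most ``exact_max_n`` observations and the
    pooled data contain no ties; otherwise the normal approximation with the
    tie-corrected variance and a 0.5 continuity correction is used.
    ``method`` may force ``'exact'`` or ``'normal'``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires non-empty samples")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size

    if method == "auto":
        use_exact = n1 <= exact_max_n and n2 <= exact_max_n and not has_ties
    elif method == "exact":
        if has_ties:
            raise ValueError("exact method is undefined with ties")
        use_exact = True
    elif method == "normal":
        use_exact = False
    else:
        raise ValueError(f"unknown method {method!r}")

    if use_exact:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return RankSumResult(
            u_statistic=float(res.statistic),
            z_value=None,
            p_value=float(min(res.pvalue, 1.0)),
            method="exact",
            n1=n1,
            n2=n2,
        )

    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=True)
    u = float(res.statistic)
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = math.sqrt(sigma2) if sigma2 > 0 else 0.0
    if sigma == 0.0:
        z = 0.0
    else:
        z = (u - mu - 0.5 * np.sign(u - mu)) / sigma if u != mu else 0.0
    return RankSumResult(
        u_statistic=u,
        z_value=float(z),
        p_value=float(min(res.pvalue, 1.0)),
        method="normal_tie_corrected",
        n1=n1,
        n2=n2,
    )


# --------------------------------------------------------------------------
# Triplet enrichment
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentRecord:
    gene: str
    triplet_id: str
    chip_left: float
    chip_intron: float
    chip_right: float
    input_left: float
    input_intron: float
    input_right: float
    norm_left: float
    norm_intron: float
    norm_right: float
    log2fc_left: float   # log2(norm_left / norm_intron)
    log2fc_right: float  # log2(norm_right / norm_intron)


@dataclass(frozen=True)
class EnrichmentResult:
    records: list[EnrichmentRecord]
    n_dropped_zero_input: int
    n_dropped_zero_chip: int

    @property
    def n_retained(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])


def triplet_enrichment(
    chip: CoverageTrack,
    input_track: CoverageTrack,
    triplets: Sequence[ExonIntronTriplet],
    *,
    read_length_bp: int = 50,
    pseudocount: float = 0.0,
) -> EnrichmentResult:
    """Input-normalised per-feature occupancy for exon–intron–exon triplets.

    Per feature, the mean per-base coverage in the ChIP and input tracks is
    scaled per million mapped reads of its library before the ratio, so the
    normalised value is invariant when both libraries are rescaled together.
    Triplets with zero input coverage on any of the three features are
    dropped and counted (unless ``pseudocount`` > 0, in which case it is
    added to both scaled means); triplets with zero ChIP coverage on any
    feature are likewise dropped so normalised values stay positive and
    log fold-changes finite.
    """
    if not triplets:
        raise ValueError("triplet_enrichment requires at least one triplet")
    scale_c = track_total(chip, read_length_bp=read_length_bp).scale_per_million
    scale_i = track_total(input_track, read_length_bp=read_length_bp).scale_per_million

    # Vectorised means, grouped per chromosome.
    by_chrom: dict[str, list[int]] = {}
    for i, t in enumerate(triplets):
        by_chrom.setdefault(t.intron.chrom, []).append(i)

    chip_means = np.empty((len(triplets), 3))
    input_means = np.empty((len(triplets), 3))
    for chrom, idxs in by_chrom.items():
        for col, part in enumerate(("left_exon", "intron", "right_exon")):
            starts = np.array([getattr(triplets[i], part).start for i in idxs])
            ends = np.array([getattr(triplets[i], part).end for i in idxs])
            chip_means[idxs, col] = chip.interval_means(chrom, starts, ends)
            input_means[idxs, col] = input_track.interval_means(chrom, starts, ends)

    chip_means *= scale_c
    input_means *= scale_i

    records: list[EnrichmentRecord] = []
    dropped_input = dropped_chip = 0
    for i, t in enumerate(triplets):
        c = chip_means[i] + pseudocount
        v = input_means[i] + pseudocount
        if np.any(v == 0.0):
            dropped_input += 1
            continue
        if np.any(c == 0.0):
            dropped_chip += 1
            continue
        norm = c / v
        records.append(
            EnrichmentRecord(
                gene=t.gene_name,
                triplet_id=f"{t.gene_name}:{t.intron.start}-{t.intron.end}",
                chip_left=c[0], chip_intron=c[1], chip_right=c[2],
                input_left=v[0], input_intron=v[1], input_right=v[2],
                norm_left=norm[0], norm_intron=norm[1], norm_right=norm[2],
                log2fc_left=float(np.log2(norm[0] / norm[1])),
                log2fc_right=float(np.log2(norm[2] / norm[1])),
            )
        )
    return EnrichmentResult(
        records=records,
        n_dropped_zero_input=dropped_input,
        n_dropped_zero_chip=dropped_chip,
    )


def box_stats(values) -> dict[str, float]:
    """Box-plot statistics: type-7 quartiles, whiskers at +/- 1.5 IQR.

    Whiskers are the most extreme data points inside the 1.5*IQR fences, as
    drawn by standard box plots.
    """
    v = np.asarray(values, dtype=np.float64)
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation = type 7
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_low": float(inside.min()) if inside.size else float(q1),
        "whisker_high": float(inside.max()) if inside.size else float(q3),
        "n": int(v.size),
    }


def exon_vs_intron_summary(result: EnrichmentResult) -> dict:
    """Rank-sum contrasts and box statistics over normalised triplet values.

    Tests left exon vs intron, right exon vs intron and left vs right exon
    (two-sided, unpaired) on the input-normalised per-feature values.
    """
    if result.n_retained < 2:
        raise ValueError("need at least 2 enrichment records")
    left = np.array([r.norm_left for r in result.records])
    intron = np.array([r.norm_intron for r in result.records])
    right = np.array([r.norm_right for r in result.records])
    tests = {
        "left_vs_intron": rank_sum_test(left, intron),
        "right_vs_intron": rank_sum_test(right, intron),
        "left_vs_right": rank_sum_test(left, right),
    }
    return {
        "tests": tests,
        "box": {
            "left_exon": box_stats(left),
            "intron": box_stats(intron),
            "right_exon": box_stats(right),
        },
        "n_triplets": result.n_retained,
        "n_dropped_zero_input": result.n_dropped_zero_input,
        "n_dropped_zero_chip": result.n_dropped_zero_chip,
    }


# --------------------------------------------------------------------------
# Percent-of-length profiles
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PercentProfile:
    mean: np.ndarray  # 100 points
    feature_class: str
    n_features: int


def percent_length_profile(
    chip: CoverageTrack,
    input_track: CoverageTrack,
    features: Sequence[GenomicInterval],
    *,
    feature_class: str = "",
    read_length_bp: int = 50,
) -> PercentProfile:
    """Average per-base ChIP/input enrichment rescaled to percent of length.

    Each feature's per-base ratio vector (positions with zero input are
    masked) is resampled onto 100 percent bins by assigning every base
    centre to its nearest percent bin and averaging; features are then
    averaged pointwise (ignoring bins a short feature leaves empty).
    Minus-strand features are flipped so index 0 is the 5' end.
    """
    if not features:
        raise ValueError("percent_length_profile requires at least one feature")
    scale_c = track_total(chip, read_length_bp=read_length_bp).scale_per_million
    scale_i = track_total(input_track, read_length_bp=read_length_bp).scale_per_million

    sums = np.zeros(100)
    counts = np.zeros(100)
    used = 0
    for feat in features:
        c, _ = chip.query(feat)
        v, _ = input_track.query(feat)
        mask = v > 0
        if not mask.any():
            continue
        ratio = np.zeros_like(c)
        ratio[mask] = (c[mask] * scale_c) / (v[mask] * scale_i)
        if feat.strand == "-":
            ratio = ratio[::-1]
            mask = mask[::-1]
        length = len(feat)
        idx = ((2 * np.arange(length) + 1) * 100) // (2 * length)  # base centre -> bin
        sums += np.bincount(idx[mask], weights=ratio[mask], minlength=100)
        counts += np.bincount(idx[mask], minlength=100)
        used += 1
    if used == 0:
        raise ValueError("no feature had nonzero input coverage")
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return PercentProfile(mean=mean, feature_class=feature_class, n_features=used)


# --------------------------------------------------------------------------
# Cross-track exon correlation
# --------------------------------------------------------------------------

def exon_correlation(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    genes: Sequence[GeneModel],
    *,
    pseudocount: float = 0.1,
    read_length_bp: int = 50,
) -> dict:
    """Correlation of per-exon normalised coverage between two tracks.

    Per exon, the mean per-base coverage in each track is scaled per million
    mapped reads; Pearson r is computed on log10(x + pseudocount) (coverage
    spans orders of magnitude), with Spearman rank correlation on the raw
    values reported alongside.  Degenerate (constant) vectors yield NaN
    correlations flagged in the report.
    """
    rows = []
    for g in genes:
        starts = np.array([e.start for e in g.exons])
        ends = np.array([e.end for e in g.exons])
        a = track_a.interval_means(g.chrom, starts, ends)
        b = track_b.interval_means(g.chrom, starts, ends)
        for k in range(len(g.exons)):
            rows.append((g.name, k, a[k], b[k]))
    table = pd.DataFrame(rows, columns=["gene", "exon_index", "mean_a", "mean_b"])
    n_genes_nonzero = (
        table.groupby("gene")[["mean_a", "mean_b"]].sum().gt(0).all(axis=1).sum()
    )
    if n_genes_nonzero < 3:
        raise ValueError("exon_correlation requires >= 3 genes with signal in both tracks")

    scale_a = track_total(track_a, read_length_bp=read_length_bp).scale_per_million
    scale_b = track_total(track_b, read_length_bp=read_length_bp).scale_per_million
    table["norm_a"] = table["mean_a"] * scale_a
    table["norm_b"] = table["mean_b"] * scale_b

    la = np.log10(table["norm_a"].to_numpy() + pseudocount)
    lb = np.log10(table["norm_b"].to_numpy() + pseudocount)
    degenerate = np.all(la == la[0]) or np.all(lb == lb[0])
    if degenerate:
        pearson_r = pearson_p = spearman_r = spearman_p = float("nan")
    else:
        pearson_r, pearson_p = sps.pearsonr(la, lb)
        spearman_r, spearman_p = sps.spearmanr(
            table["norm_a"].to_numpy(), table["norm_b"].to_numpy()
        )
    return {
        "pearson_r": float(pearson_r),
        "pearson_p": float(pearson_p),
        "spearman_r": float(spearman_r),
        "spearman_p": float(spearman_p),
        "n_exons": int(len(table)),
        "degenerate": bool(degenerate),
        "pseudocount": pseudocount,
        "table": table,
    }
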