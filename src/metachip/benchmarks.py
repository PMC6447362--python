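"""Self-contained benchmark experiments on simulated data.

These are the quantitative experiments the package uses to validate itself:
exon-multiplier recovery, null calibration of the rank-sum contrast, its
power under an exon-biased model, RPKM rank recovery, and metagene shape
diagnostics.  Both the test suite and the reporting script call them, so the
numbers they produce are always recomputed from scratch.
"""

from __future__ import annotations


import numpy as np
from scipy import stats as sps

from .annotations import AnalysisParams, derive_all_triplets, filter_genes
from .coverage import track_total
from .enrichment import exon_vs_intron_summary, rank_sum_test, triplet_enrichment
from .expression import expression_table
from .metagene import gene_profiles, metagene_average
from .simulate import SimulationSpec, simulate


def recovered_exon_intron_ratio(seed: int, f_exon: float, *, n_genes: int = 500) -> dict:
    """Simulate an exon-biased ChIP library and recover the exon multiplier.

    Returns the median, over retained triplets, of the input-normalised
    exon/intron ratio (left and right exons pooled), plus the left-vs-intron
    rank-sum p-value at this effect size.
    """
    spec = SimulationSpec(seed=seed, n_genes=n_genes, f_exon=f_exon)
    data = simulate(spec, include=("upf1", "input"))
    params = AnalysisParams()
    triplets = derive_all_triplets(filter_genes(data.genes, params), params)
    result = triplet_enrichment(
        data.tracks["upf1"], data.tracks["input"], triplets,
        read_length_bp=params.read_length_bp,
    )
    left = np.array([r.norm_left for r in result.records])
    right = np.array([r.norm_right for r in result.records])
    intron = np.array([r.norm_intron for r in result.records])
    ratio = np.concatenate([left / intron, right / intron])
    summary = exon_vs_intron_summary(result)
    return {
        "f_exon": f_exon,
        "median_ratio": float(np.median(ratio)),
        "n_triplets": result.n_retained,
        "p_left_vs_intron": summary["tests"]["left_vs_intron"].p_value,
        "p_right_vs_intron": summary["tests"]["right_vs_intron"].p_value,
        "p_left_vs_right": summary["tests"]["left_vs_right"].p_value,
    }


def null_pvalue_replicates(seed: int, *, n_replicates: int = 200, n_genes: int = 40) -> np.ndarray:
    """Left-exon-vs-intron p-values under a no-enrichment model (f_exon = 1).

    Expression is held constant across genes so the pooled exon and intron
    values are exchangeable — the null under which the rank-sum p-value is
    uniform.  (With heterogeneous expression, features of the same gene share
    its expression level, the two samples are positively dependent, and the
    test is conservative; see the methods note.)
    """
    ps = []
    for rep in range(n_replicates):
        spec = SimulationSpec(
            seed=seed + rep, n_genes=n_genes, f_exon=1.0, expression_sdlog=0.0
        )
        data = simulate(spec, include=("upf1", "input"))
        triplets = derive_all_triplets(data.genes)
        result = triplet_enrichment(data.tracks["upf1"], data.tracks["input"], triplets)
        summary = exon_vs_intron_summary(result)
        ps.append(summary["tests"]["left_vs_intron"].p_value)
    return np.asarray(ps)


def rejection_power(seed: int, *, f_exon: float = 2.0, alpha: float = 1e-3,
                    n_replicates: int = 10, n_genes: int = 500) -> dict:
    """Fraction of replicates in which exon > intron is detected at alpha."""
    rejected = 0
    ps = []
    for rep in range(n_replicates):
        res = recovered_exon_intron_ratio(seed + 1000 + rep, f_exon, n_genes=n_genes)
        ps.append(res["p_left_vs_intron"])
        rejected += res["p_left_vs_intron"] < alpha
    return {"power": rejected / n_replicates, "alpha": alpha,
            "n_replicates": n_replicates, "median_p": float(np.median(ps))}


def ranksum_type1_error(seed: int, *, n_sims: int = 2000, n: int = 25,
                        alpha: float = 0.05) -> float:
    """Empirical type-I error of the rank-sum test on iid null samples."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        if rank_sum_test(x, y).p_value < alpha:
            rejections += 1
    return rejections / n_sims


def rpkm_rank_recovery(seed: int, *, n_genes: int = 200) -> dict:
    """Spearman correlation between true expression and recovered RPKM."""
    data = simulate(SimulationSpec(seed=seed, n_genes=n_genes), include=("rna",))
    table, _ = expression_table(
        data.rna_reads, data.genes, total_mapped=data.rna_declared_total
    )
    true = np.array([data.truth.expression[g] for g in table["gene"]])
    r, _ = sps.spearmanr(true, table["rpkm"].to_numpy())
    classes = table["activity_class"].value_counts().to_dict()
    return {"spearman_r": float(r), "n_genes": n_genes, "classes": classes}


def metagene_shape(seed: int, *, n_genes: int = 120) -> dict:
    """Metagene diagnostics on simulated Pol II-like and exon-uniform tracks.

    Reports the argmax position of the Pol II-like metagene (expected at or
    just upstream of the first gene-body bin, i.e. the TSS) and the
    body-to-flank contrast of the UPF1-like metagene (expected > 1).
    """
    params = AnalysisParams()
    data = simulate(SimulationSpec(seed=seed, n_genes=n_genes), include=("upf1", "pol2", "input"))
    genes = filter_genes(data.genes, params)
    out: dict = {}
    for name in ("pol2", "upf1"):
        track = data.tracks[name]
        profiles, _ = gene_profiles(track, genes, params)
        mg = metagene_average(profiles, track_total(track, read_length_bp=params.read_length_bp))
        flank, n_bins = params.flank_bp, params.n_bins
        vec = mg.mean
        body = vec[flank : flank + n_bins]
        out[name] = {
            "argmax": int(np.argmax(vec)),
            "body_mean": float(body.mean()),
            "upstream_flank_mean": float(vec[:flank].mean()),
            "downstream_flank_mean": float(vec[flank + n_bins :].mean()),
            "n_genes": mg.n_genes,
        }
    return out


def cross_track_correlation(seed: int, *, n_genes: int = 150) -> dict:
    """Exon-level correlation between the two simulated ChIP tracks."""
    from .enrichment import exon_correlation

    params = AnalysisParams()
    data = simulate(SimulationSpec(seed=seed, n_genes=n_genes), include=("upf1", "pol2"))
    genes = filter_genes(data.genes, params)
    report = exon_correlation(
        data.tracks["upf1"], data.tracks["pol2"], genes,
        read_length_bp=params.read_length_bp,
    )
    report.pop("table")
    return report
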