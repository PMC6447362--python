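"""Input-normalised exon/intron enrichment, percent profiles, correlation."""

import numpy as np
import pytest

from metachip import (
    AnalysisParams,
    GenomicInterval,
    derive_features,
    exon_correlation,
    exon_vs_intron_summary,
    percent_length_profile,
    triplet_enrichment,
)
from metachip.enrichment import box_stats

from conftest import dense_of, make_gene, make_track, mirror_steps

TRIPLET_GENE = make_gene([(100, 300), (600, 1100)], name="g1")
(TRIPLET,) = derive_features(TRIPLET_GENE, AnalysisParams(min_intron_bp=100))[1]

# Declared equal library sizes make the per-million scales cancel, so the
# normalised values below are plain coverage ratios.
EQ = dict(total_mapped_reads=10**6)


class TestTripletEnrichment:
    def test_uniform_ratio_two(self):
        chip = make_track([(0, 2000, 4.0)], **EQ)
        inp = make_track([(0, 2000, 2.0)], **EQ)
        result = triplet_enrichment(chip, inp, [TRIPLET])
        (rec,) = result.records
        assert (rec.norm_left, rec.norm_intron, rec.norm_right) == (2.0, 2.0, 2.0)
        assert rec.log2fc_left == 0.0 and rec.log2fc_right == 0.0

    def test_exon_biased_steps(self):
        chip = make_track([(100, 300, 6.0), (300, 600, 2.0), (600, 1100, 6.0)], **EQ)
        inp = make_track([(0, 2000, 2.0)], **EQ)
        (rec,) = triplet_enrichment(chip, inp, [TRIPLET]).records
        assert (rec.norm_left, rec.norm_intron, rec.norm_right) == (3.0, 1.0, 3.0)
        assert rec.log2fc_left == pytest.approx(np.log2(3))
        assert rec.log2fc_right == pytest.approx(np.log2(3))

    def test_zero_input_on_intron_drops_record(self):
        chip = make_track([(0, 2000, 4.0)], **EQ)
        inp = make_track([(100, 300, 2.0), (600, 1100, 2.0)], **EQ)  # intron uncovered
        result = triplet_enrichment(chip, inp, [TRIPLET])
        assert result.n_retained == 0 and result.n_dropped_zero_input == 1

    def test_pseudocount_mode_keeps_record(self):
        chip = make_track([(0, 2000, 4.0)], **EQ)
        inp = make_track([(100, 300, 2.0), (600, 1100, 2.0)], **EQ)
        result = triplet_enrichment(chip, inp, [TRIPLET], pseudocount=0.5)
        assert result.n_retained == 1

    def test_empty_triplet_list_rejected(self):
        chip = make_track([(0, 2000, 4.0)], **EQ)
        with pytest.raises(ValueError):
            triplet_enrichment(chip, chip, [])

    def test_scale_invariance(self):
        chip = make_track([(100, 300, 6.0), (300, 600, 2.0), (600, 1100, 6.0)])
        inp = make_track([(0, 2000, 2.0)])
        base = triplet_enrichment(chip, inp, [TRIPLET]).records[0]
        scaled = triplet_enrichment(chip.scaled(7.0), inp.scaled(7.0), [TRIPLET]).records[0]
        assert scaled.norm_left == pytest.approx(base.norm_left)
        assert scaled.norm_intron == pytest.approx(base.norm_intron)
        assert scaled.log2fc_left == pytest.approx(base.log2fc_left)


class TestSummary:
    def _result(self, chip_steps, n=6):
        genes = []
        for k in range(n):
            off = 2000 * k
            genes.append(make_gene([(100 + off, 300 + off), (600 + off, 1100 + off)], name=f"g{k}"))
        triplets = [derive_features(g)[1][0] for g in genes]
        steps = []
        for k in range(n):
            steps.extend([(s + 2000 * k, e + 2000 * k, v) for s, e, v in chip_steps])
        chip = make_track(steps, **EQ)
        inp = make_track([(0, 2000 * n, 2.0)], **EQ)
        return triplet_enrichment(chip, inp, triplets)

    def test_equal_exon_intron_values_give_p_one(self):
        summary = exon_vs_intron_summary(self._result([(100, 1100, 4.0)]))
        for test in summary["tests"].values():
            assert test.p_value == 1.0

    def test_exon_bias_pattern(self):
        summary = exon_vs_intron_summary(
            self._result([(100, 300, 6.0), (300, 600, 2.0), (600, 1100, 6.0)])
        )
        assert summary["tests"]["left_vs_intron"].p_value < 0.01
        assert summary["tests"]["right_vs_intron"].p_value < 0.01
        assert summary["tests"]["left_vs_right"].p_value == 1.0

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            exon_vs_intron_summary(self._result([(100, 1100, 4.0)], n=1))

    def test_type7_quartiles_and_whiskers(self):
        stats = box_stats([1.0, 2.0, 3.0, 4.0])
        assert stats["q1"] == 1.75 and stats["median"] == 2.5 and stats["q3"] == 3.25
        assert stats["whisker_low"] == 1.0 and stats["whisker_high"] == 4.0
        with_outlier = box_stats([1.0, 2.0, 3.0, 4.0, 50.0])
        assert with_outlier["whisker_high"] == 4.0  # 50 sits outside the 1.5 IQR fence


class TestPercentProfile:
    def test_uniform_ratio_constant_profile(self):
        chip = make_track([(0, 1000, 6.0)], **EQ)
        inp = make_track([(0, 1000, 2.0)], **EQ)
        prof = percent_length_profile(chip, inp, [GenomicInterval("chr1", 100, 400)])
        assert prof.mean.shape == (100,)
        assert np.allclose(prof.mean, 3.0)

    def test_linear_ramp_strictly_increasing(self):
        steps = [(i, i + 1, float(i - 99)) for i in range(100, 300)]
        chip = make_track(steps, **EQ)
        inp = make_track([(0, 1000, 1.0)], **EQ)
        prof = percent_length_profile(chip, inp, [GenomicInterval("chr1", 100, 300)])
        assert np.all(np.diff(prof.mean) > 0)

    def test_binning_matches_brute_force(self):
        rng = np.random.default_rng(7)
        steps = [(i, i + 1, float(v)) for i, v in enumerate(rng.integers(1, 9, size=230))]
        chip = make_track(steps, **EQ)
        inp = make_track([(0, 230, 2.0)], **EQ)
        feat = GenomicInterval("chr1", 10, 217)
        prof = percent_length_profile(chip, inp, [feat])
        dense = dense_of(steps, 230)[10:217] / 2.0
        length = 217 - 10
        expected = np.full(100, np.nan)
        idx = ((2 * np.arange(length) + 1) * 100) // (2 * length)
        for b in range(100):
            sel = dense[idx == b]
            if sel.size:
                expected[b] = sel.mean()
        assert np.allclose(prof.mean, expected, equal_nan=True)

    def test_minus_strand_mirror_equality(self):
        length = 1000
        steps = [(100, 150, 2.0), (150, 300, 5.0)]
        chip_fwd = make_track(steps, **EQ)
        chip_rev = make_track(mirror_steps(steps, length), **EQ)
        inp = make_track([(0, length, 1.0)], **EQ)
        fwd = percent_length_profile(chip_fwd, inp, [GenomicInterval("chr1", 100, 300, "+")])
        rev = percent_length_profile(chip_rev, inp, [GenomicInterval("chr1", 700, 900, "-")])
        assert np.allclose(fwd.mean, rev.mean)

    def test_zero_input_positions_masked(self):
        chip = make_track([(0, 200, 4.0)], **EQ)
        inp = make_track([(0, 100, 2.0)], **EQ)  # second half uncovered
        prof = percent_length_profile(chip, inp, [GenomicInterval("chr1", 0, 200)])
        assert np.allclose(prof.mean[:50], 2.0)
        assert np.all(np.isnan(prof.mean[50:]))

    def test_empty_feature_list_rejected(self):
        chip = make_track([(0, 100, 1.0)])
        with pytest.raises(ValueError):
            percent_length_profile(chip, chip, [])


class TestExonCorrelation:
    def _genes(self, n=6):
        return [
            make_gene([(2000 * k, 2000 * k + 400), (2000 * k + 800, 2000 * k + 1200)], name=f"g{k}")
            for k in range(n)
        ]

    def test_proportional_tracks_correlate_perfectly(self, rng):
        genes = self._genes()
        steps = [(g.exons[j].start, g.exons[j].end, float(rng.integers(1, 50)))
                 for g in genes for j in range(2)]
        a = make_track(steps, **EQ)
        b = a.scaled(2.0)
        report = exon_correlation(a, b, genes, pseudocount=0.0)
        assert report["pearson_r"] == pytest.approx(1.0)
        assert report["spearman_r"] == pytest.approx(1.0)

    def test_anti_monotone_spearman_minus_one(self):
        genes = self._genes()
        vals = [float(v) for v in range(1, 13)]
        steps_a, steps_b = [], []
        for i, (g, v) in enumerate(zip((g for g in genes for _ in range(2)), vals)):
            exon = g.exons[i % 2]
            steps_a.append((exon.start, exon.end, v))
            steps_b.append((exon.start, exon.end, 13.0 - v))
        a = make_track(steps_a, **EQ)
        b = make_track(steps_b, **EQ)
        report = exon_correlation(a, b, genes)
        assert report["spearman_r"] == pytest.approx(-1.0)

    def test_degenerate_constant_track_flagged(self):
        genes = self._genes()
        a = make_track([(0, 12000, 2.0)], **EQ)
        steps = [(g.exons[j].start, g.exons[j].end, float(1 + j)) for g in genes for j in range(2)]
        b = make_track(steps, **EQ)
        report = exon_correlation(a, b, genes)
        assert report["degenerate"] and np.isnan(report["pearson_r"])

    def test_too_few_genes_rejected(self):
        genes = self._genes(2)
        a = make_track([(0, 4000, 2.0)], **EQ)
        with pytest.raises(ValueError):
            exon_correlation(a, a, genes)
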