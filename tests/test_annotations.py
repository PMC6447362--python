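"""Gene-table parsing, intron/triplet derivation and gene filters."""

import io

import pytest

from metachip import AnalysisParams, derive_features, filter_genes, parse_refgene, write_refgene
from metachip.annotations import RefGeneParseError, write_triplets_tsv

from conftest import make_gene


def refgene_line(name="tx1", chrom="chr1", strand="+", tx=(100, 1100),
                 exon_starts="100,600,", exon_ends="300,1100,", exon_count=2,
                 name2="G1", with_bin=False):
    fields = [name, chrom, strand, str(tx[0]), str(tx[1]), str(tx[0]), str(tx[1]),
              str(exon_count), exon_starts, exon_ends, "0", name2, "none", "none", ""]
    if with_bin:
        fields = ["585"] + fields
    return "\t".join(fields)


class TestParseRefgene:
    @pytest.mark.parametrize("with_bin", [False, True], ids=["no-bin", "ucsc-bin"])
    def test_field_mapping_with_bin_autodetect(self, with_bin):
        genes = parse_refgene([refgene_line(with_bin=with_bin)])
        (g,) = genes
        assert g.name == "tx1" and g.name2 == "G1"
        assert (g.span.start, g.span.end, g.strand) == (100, 1100, "+")
        assert [(e.start, e.end) for e in g.exons] == [(100, 300), (600, 1100)]

    def test_empty_input_gives_empty_list(self):
        assert parse_refgene([]) == []
        assert parse_refgene(io.StringIO("")) == []

    def test_exon_count_mismatch_reports_line_number(self):
        bad = refgene_line(exon_starts="100,400,600,", exon_ends="300,500,1100,", exon_count=2)
        with pytest.raises(RefGeneParseError, match="line 2"):
            parse_refgene([refgene_line(), bad])

    def test_unsorted_exons_rejected(self):
        bad = refgene_line(exon_starts="600,100,", exon_ends="1100,300,")
        with pytest.raises(RefGeneParseError, match="not sorted"):
            parse_refgene([bad])

    def test_exons_must_tile_span_ends(self):
        bad = refgene_line(tx=(50, 1100))
        with pytest.raises(RefGeneParseError, match="span"):
            parse_refgene([bad])

    def test_round_trip_through_writer(self):
        genes = parse_refgene([refgene_line(), refgene_line(name="tx2", strand="-")])
        buf = io.StringIO()
        write_refgene(genes, buf)
        again = parse_refgene(io.StringIO(buf.getvalue()))
        assert again == genes


class TestDeriveFeatures:
    def test_two_exon_gene_yields_intron_and_triplet(self):
        gene = make_gene([(100, 300), (600, 1100)])
        introns, triplets = derive_features(gene, AnalysisParams(min_intron_bp=100))
        assert [(i.start, i.end) for i in introns] == [(300, 600)]
        (t,) = triplets
        assert (t.left_exon.start, t.left_exon.end) == (100, 300)
        assert (t.intron.start, t.intron.end) == (300, 600)
        assert (t.right_exon.start, t.right_exon.end) == (600, 1100)

    def test_single_exon_gene_is_empty(self):
        introns, triplets = derive_features(make_gene([(100, 300)]))
        assert introns == [] and triplets == []

    @pytest.mark.parametrize(
        "intron_len,kept",
        [(100, False), (101, True)],
        ids=["exactly-100-excluded", "101-retained"],
    )
    def test_min_intron_rule_is_strictly_greater(self, intron_len, kept):
        gene = make_gene([(0, 200), (200 + intron_len, 400 + intron_len)])
        _, triplets = derive_features(gene, AnalysisParams(min_intron_bp=100))
        assert bool(triplets) is kept

    def test_abutting_exons_emit_no_zero_length_intron(self):
        gene = make_gene([(0, 100), (100, 200), (500, 700)])
        introns, _ = derive_features(gene)
        assert [(i.start, i.end) for i in introns] == [(200, 500)]

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_exons_and_introns_tile_the_span(self, strand, rng):
        # property: concatenating exons and introns in order covers the span exactly
        for _ in range(25):
            n_ex = int(rng.integers(1, 6))
            pairs, pos = [], int(rng.integers(0, 1000))
            for i in range(n_ex):
                length = int(rng.integers(1, 300))
                pairs.append((pos, pos + length))
                pos += length + int(rng.integers(1, 500)) if i < n_ex - 1 else length
            gene = make_gene(pairs, strand=strand)
            introns, _ = derive_features(gene)
            pieces = sorted(
                [(e.start, e.end) for e in gene.exons] + [(i.start, i.end) for i in introns]
            )
            assert pieces[0][0] == gene.span.start and pieces[-1][1] == gene.span.end
            assert all(a[1] == b[0] for a, b in zip(pieces, pieces[1:]))

    def test_strand_aware_accessors(self):
        minus = make_gene([(100, 300), (600, 1100)], strand="-")
        (t,) = derive_features(minus)[1]
        assert t.upstream_exon == t.right_exon  # 5' of a '-' gene is genomic right
        assert t.downstream_exon == t.left_exon
        plus = make_gene([(100, 300), (600, 1100)], strand="+")
        (tp,) = derive_features(plus)[1]
        assert tp.upstream_exon == tp.left_exon

    def test_deduplicated_triplets_collapse_shared_introns(self):
        from metachip import derive_all_triplets

        iso1 = make_gene([(100, 300), (600, 1100)], name="tx1")
        iso2 = make_gene([(100, 300), (600, 1100)], name="tx2")
        assert len(derive_all_triplets([iso1, iso2])) == 2
        assert len(derive_all_triplets([iso1, iso2], deduplicate=True)) == 1

    def test_triplet_tsv_writer(self):
        gene = make_gene([(100, 300), (600, 1100)], strand="-")
        _, triplets = derive_features(gene)
        buf = io.StringIO()
        write_triplets_tsv(triplets, buf)
        lines = buf.getvalue().splitlines()
        assert lines[0].split("\t")[:2] == ["gene", "chrom"]
        assert lines[1].split("\t") == [
            "g1", "chr1", "100", "300", "300", "600", "600", "1100", "-",
        ]

    def test_strand_independent_genomic_order(self):
        plus = make_gene([(100, 300), (600, 1100)], strand="+")
        minus = make_gene([(100, 300), (600, 1100)], strand="-")
        _, tp = derive_features(plus)
        _, tm = derive_features(minus)
        assert (tp[0].left_exon.start, tp[0].right_exon.end) == (
            tm[0].left_exon.start, tm[0].right_exon.end,
        )


class TestFilterGenes:
    params = AnalysisParams(flank_bp=500, min_separation_bp=1000)

    def test_duplicate_names_all_removed(self):
        g1 = make_gene([(0, 1000)], name="g1")
        g2 = make_gene([(50000, 51000)], name="g1")
        g3 = make_gene([(100000, 101000)], name="g3")
        assert [g.name for g in filter_genes([g1, g2, g3], self.params)] == ["g3"]

    def test_distant_genes_kept(self):
        g1 = make_gene([(0, 1000)], name="a")
        g2 = make_gene([(11000, 12000)], name="b")  # 10 kb apart
        assert len(filter_genes([g1, g2], self.params)) == 2

    def test_flank_extended_overlap_removes_both(self):
        g1 = make_gene([(1000, 2000)], name="a")
        g2 = make_gene([(2600, 3600)], name="b")  # extended spans overlap
        assert filter_genes([g1, g2], self.params) == []

    def test_gap_just_below_separation_removes_both(self):
        # extended spans end at 2500 and start at 3400: gap 900 < 1000
        g1 = make_gene([(1000, 2000)], name="a")
        g2 = make_gene([(3900, 4900)], name="b")
        assert filter_genes([g1, g2], self.params) == []

    def test_gap_at_separation_keeps_both(self):
        # extended spans (500,2500) and (3500,5000): gap exactly 1000 suffices
        g1 = make_gene([(1000, 2000)], name="a")
        g2 = make_gene([(4000, 4500)], name="b")
        assert len(filter_genes([g1, g2], self.params)) == 2

    def test_other_chromosome_never_conflicts(self):
        g1 = make_gene([(1000, 2000)], name="a", chrom="chr1")
        g2 = make_gene([(1000, 2000)], name="b", chrom="chr2")
        assert len(filter_genes([g1, g2], self.params)) == 2

    def test_nested_crowding_is_detected(self):
        # b is nested inside a's neighbourhood; c conflicts with a but not b
        a = make_gene([(1000, 30000)], name="a")
        b = make_gene([(5000, 5100)], name="b")
        c = make_gene([(30500, 31500)], name="c")
        assert filter_genes([a, b, c], self.params) == []

    def test_idempotent_subset_stable_order(self, rng):
        genes = []
        pos = 0
        for i in range(30):
            pos += int(rng.integers(100, 20000))
            length = int(rng.integers(100, 5000))
            genes.append(make_gene([(pos, pos + length)], name=f"g{i}"))
            pos += length
        once = filter_genes(genes, self.params)
        assert filter_genes(once, self.params) == once
        names = [g.name for g in genes]
        assert [g.name for g in once] == [n for n in names if n in {g.name for g in once}]
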