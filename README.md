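# metachip

Metagene profiling and exon/intron occupancy enrichment for ChIP-seq
coverage tracks, with a ground-truth synthetic-data generator.

## The problem

RNA-binding proteins that travel with nascent transcripts leave a footprint
in ChIP-seq coverage that tracks transcription: occupancy rises over active
gene bodies, and when intron recognition interferes with the protein's
association, occupancy is systematically higher over exons than over the
introns between them.  Establishing that pattern genome-wide takes a chain
of unglamorous but error-prone steps — filtering gene annotations so
neighbouring genes cannot contaminate each other's signal, normalising
coverage by library size, scaling unequal gene lengths onto a common
metagene axis, dividing ChIP by input per feature, and testing exon/intron
contrasts nonparametrically.  `metachip` implements that chain as a typed,
tested Python library for anyone analysing protein occupancy on nascent
transcripts (or any exon-structured ChIP signal), and pairs it with a
simulator that generates annotations, coverage tracks and RNA reads with
*known* parameters, so every stage can be validated by parameter recovery
rather than by eyeballing browser shots.

## The statistics at the core

* **Metagene profile.**  Each gene contributes a vector of 500 upstream
  flank bases, 16 gene-body bins of ⌊L/16⌋ or ⌈L/16⌉ bases, and 500
  downstream flank bases, oriented 5'→3'; curves are pointwise means across
  genes scaled per million mapped reads, stratified by expression class
  (RPKM < 1 inactive, ≥ 1 active, > 5 high; RPKM = count·10⁹ / (exonic
  length · total mapped reads)).
* **Exon/intron enrichment.**  For every exon–intron–exon triplet with
  intron length > 100 bp, each feature's value is
  (mean ChIP coverage) / (mean input coverage), both per-million-scaled.
  Left exon vs intron, right exon vs intron and left vs right exon are
  compared with the two-sided unpaired Wilcoxon rank-sum (Mann–Whitney U)
  test — exact for small untied samples, tie-corrected normal approximation
  with continuity correction otherwise.
* **Percent-of-length profiles and correlation.**  Per-base ChIP/input
  ratios rescaled to 100 percent bins per feature; per-exon correlation
  between libraries as Pearson on log10(x + 0.1) with Spearman alongside.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data (seed 1, 200 genes) and write their tables under `results/` (bulky
per-row tables and raw tracks go to `scratch/`).  For example:

```
$ python analysis/04_exon_intron_enrichment.py
640 triplets retained (0 dropped for zero input, 1 for zero ChIP)
  left_vs_intron   U=    279357 p=1.74e-29 (normal_tie_corrected)
  right_vs_intron  U=    279655 p=1.04e-29 (normal_tie_corrected)
  left_vs_right    U=    204400 p=0.952 (normal_tie_corrected)
mean enrichment across percent bins: exon 2.80, intron 1.21
exon-multiplier recovery (500 genes per setting):
  f_exon=1: median exon/intron ratio 0.999 over 1545 triplets
  f_exon=2: median exon/intron ratio 1.920 over 1547 triplets
  f_exon=3: median exon/intron ratio 2.792 over 1548 triplets
```

Reading: with a generative exon multiplier of 3, both flanking exons are
overwhelmingly more enriched than their intron (p ≈ 10⁻²⁹) while the two
exons are indistinguishable (p = 0.95) — the directional signature of
exon-biased occupancy — and the median input-normalised exon/intron ratio
recovers the simulated multiplier to within a few percent at every effect
size (the residual shortfall is read-scale boundary smoothing; see the
methods note).

The same stages are available programmatically and as a CLI:

```python
from metachip import SimulationSpec, simulate, filter_genes, \
    derive_all_triplets, triplet_enrichment, exon_vs_intron_summary

data = simulate(SimulationSpec(seed=1, n_genes=200), include=("upf1", "input"))
genes = filter_genes(data.genes)
result = triplet_enrichment(data.tracks["upf1"], data.tracks["input"],
                            derive_all_triplets(genes))
summary = exon_vs_intron_summary(result)
print(summary["tests"]["left_vs_intron"].p_value)
```

```
metachip simulate --seed 1 --n-genes 50 --out demo/
metachip enrich --chip demo/upf1.bedgraph --input demo/input.bedgraph \
    --annotation demo/annotation.refgene.txt --min-intron 100
metachip run --config examples/demo_config.yaml
```

On real data, point `metachip enrich` / `metachip metagene` / `metachip
rpkm` at Bedgraph tracks made with `genomeCoverageBed -bga -ibam`, a UCSC
refGene table, and BED-format alignments.

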