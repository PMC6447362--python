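# Methods

`metachip` reimplements, as a tested pipeline over synthetic data, the
downstream analysis used to characterise genome-wide, exon-biased protein
occupancy on nascent transcripts from ChIP-seq coverage tracks: gene-model
filtering, library-size normalisation, metagene profiling, exon–intron–exon
enrichment statistics, RPKM expression classing, and cross-library
correlation.  This note records the model, the defaults and why, the
numerical choices, and what the synthetic data do and do not establish.

## Coordinates and data model

All coordinates are 0-based half-open (Bedgraph/BED/refGene convention).  A
coverage track is a set of sorted, non-overlapping `(start, end, value)`
steps per chromosome with implicit zeros in gaps — exactly the semantics of
`genomeCoverageBed -bga` output once its explicit zero rows are folded away.
Interval means are computed from cumulative step mass, so they equal the
brute-force per-base average exactly (the test suite checks this identity on
random tracks).

A gene model is one transcription unit: ordered non-overlapping exons whose
first/last boundaries coincide with the transcript span (rows violating this
are rejected at parse time with their line number).  Introns are the gaps
between consecutive exons; the unit of the occupancy comparison is the
exon–intron–exon triplet, restricted by default to introns strictly longer
than 100 bp.  Short introns are excluded because read-scale smoothing makes
coverage in an intron shorter than about two read lengths largely a mixture
of its neighbours' signal (see *Resolution* below).

## Gene filters

Two filters precede all profile/enrichment steps:

1. **Unique names.**  Every entry whose `name` occurs more than once is
   dropped (all copies).  Cross-referencing between expression and occupancy
   tables is by this field, and keeping an arbitrary copy of a duplicated
   name would silently misattribute signal; dropping is conservative.
2. **Isolation.**  A gene is kept only when its span, extended by the
   500 bp profile flank, is at least `min_separation_bp` (default 1000 bp)
   away from every other gene's extended span on the same chromosome.  The
   default exceeds the flank so that flanking-region signal cannot include a
   neighbour's gene body.  Both members of a crowded pair are removed.

Both filters are idempotent and order-preserving.

## Library-size normalisation

Each library is scaled per million mapped reads.  When a track declares its
mapped-read count (the simulator always does) that count is the normaliser;
otherwise it is approximated by total signal mass divided by the read length
(50 bp single-end reads contribute exactly 50 bases of mass each, so this
recovers the read count of an alignment-derived track).  A mapped-bases
normaliser is available as an option (`basis="bases"`); reads is the default
because sequencing depth is conventionally counted in reads.

## Metagene profiles

Each gene contributes a vector of 500 per-base upstream-flank values, 16
gene-body bin means, and 500 per-base downstream-flank values, oriented
5'→3' (minus-strand vectors are reversed).  Binning partitions the gene body
into contiguous bins of ⌊L/16⌋ or ⌈L/16⌉ bases; the L mod 16 wider bins are
placed at the 5' end *in transcript orientation*.  Placing them by genomic
position instead would break strand symmetry: mirroring the genome and
flipping every strand must leave the metagene unchanged, and the suite
asserts exactly that.  Genes shorter than 16 bp cannot be binned and are
skipped with a logged reason.  Curves are pointwise means across genes,
multiplied by the per-million scale; input-track curves are computed
identically and reported alongside rather than used as a divisor.

## Exon/intron enrichment

For each triplet feature (left exon, intron, right exon) the statistic is
the mean per-base ChIP coverage divided by the mean per-base input coverage,
both per-million-scaled, which corrects position-specific fragmentation and
sequencing bias and is invariant under joint rescaling of the two libraries.
Triplets with zero input mean on any feature are dropped and counted (ratio
semantics; a pseudocount mode is available), as are the rare triplets with
zero ChIP mean on a feature, so retained normalised values are positive and
log2 fold-changes finite.

Contrasts (left exon vs intron, right exon vs intron, left vs right exon)
use the two-sided unpaired Wilcoxon rank-sum (Mann–Whitney U) test: the
exact enumeration null when both samples have ≤ 12 untied observations,
otherwise the normal approximation with tie-corrected variance and 0.5
continuity correction.  The threshold of 12 keeps exact enumeration cheap
while the approximation error is already below 0.02 there (asserted by the
suite).  Box summaries use type-7 (linear-interpolation) quartiles with
whiskers at the most extreme points inside ±1.5 IQR.

**Calibration caveat.**  Across triplets of the same gene, exon and intron
normalised values share that gene's expression level, so the two pooled
samples are positively dependent and the rank-sum p-value is *conservative*
when expression is heterogeneous — on null simulations with log-normal
expression the p-values pile up near 1.  The calibration experiment
(`null_pvalue_replicates`) therefore holds expression constant across genes,
making pooled exon and intron values exchangeable; under that null the
p-values are uniform and the empirical type-I error matches the nominal
level.  Significance reported on heterogeneous data errs on the safe side.

Percent-of-length profiles divide each feature's per-base ChIP/input ratio
(zero-input bases masked) into 100 percent bins by assigning each base
centre to its nearest bin, average within feature, then across features
(bins a short feature leaves empty are ignored in its average), 5'→3'.

Cross-library exon correlation uses per-exon per-million mean coverage,
Pearson on log10(x + 0.1) — coverage spans orders of magnitude and the
pseudocount keeps silent exons finite — with Spearman on raw values
reported alongside; constant inputs yield an explicit "degenerate" flag
rather than a number.

## RPKM and expression classes

Counting is union-exon at gene level (HTSeq-count-compatible): a read
(spliced reads are one read with several blocks) is assigned to a gene when
any block overlaps the gene's exonic union by ≥ 1 base, discarded as
ambiguous when it touches exons of more than one gene, and unassigned when
it only touches introns or intergenic sequence.  RPKM =
count · 10⁹ / (exonic length · total mapped reads); the exonic union, not
the transcript span, is the denominator, consistent with the counting rule.
Classes: inactive (RPKM < 1), active (≥ 1), highly expressed (> 5); the
boundaries follow the class definitions, so exactly 1 is active and exactly
5 is active, not high.

## Synthetic-data generator

The generator emulates the structure the analysis assumes, with known
ground truth:

| parameter | default | rationale |
|---|---|---|
| exon count | uniform 1–8 | multi-exon genes with a single-exon tail |
| exon length | log-uniform 200–2000 bp | typical exon scale, heavy right tail |
| intron length | log-uniform 60–5000 bp | spans the >100 bp filter on both sides |
| intergenic gap | log-uniform 3–12 kb | exceeds 2·flank + separation, so simulated genes survive the isolation filter |
| expression | log-normal(μ=0.5, σ=1.5) | spans the RPKM <1 / 1–5 / >5 classes (≈37% / 40% / 23%) |
| input rate λ_in | 0.4 elements/bp | ≈20× per-base input coverage; feature-mean ratios sit in the moderate-count Poisson regime where the null test is calibrated |
| UPF1-like rate | 0.002 + 0.1·E·(f_exon on exons, 1 on introns) | small occupancy-independent background; exon multiplier f_exon is the recovered parameter (default 3) |
| Pol II-like rate | 0.002 + 0.05·E·(1 + 6·exp(−(x−TSS)²/2·100²)) | elongation signal plus a TSS-proximal peak |
| element length | 50 bp | the sequenced single-end read length (see below) |
| RNA reads | Poisson(E · exonic length · 0.002), uniform over the exonic union, 50 bp, spliced across junctions | expected RPKM equals E exactly |

Coverage is produced by **pileup of fixed-length elements** centred on
Poisson-sampled binding positions — not i.i.d. per-base noise — so tracks
carry the autocorrelation of real alignment coverage.  The element is the
50 bp sequenced read, which is what a Bedgraph made from single-end BAMs
piles up.  This choice is also what makes exon-multiplier recovery
feasible: boundary smoothing inflates an intron's mean by roughly
(f−1)·ℓ/(4·L_intron) for a centred element of length ℓ, about 3–4% at
ℓ = 50 with the intron lengths above but 30–40% at ℓ = 200, which would
push the recovered ratio for f = 3 toward 2.  Setting `element_bp` to 200
or 500 reproduces sonication-fragment-scale smoothing for exactly this kind
of sensitivity study of the >100 bp intron filter.  Element rates are zeroed
where an element would overhang the chromosome, so total signal mass equals
n_elements × element_bp exactly (asserted).

The declared RNA library size is `rna_read_rate · 10⁹` (2 × 10⁶ at
default): the simulated chromosome is treated as one window of a larger
library, and with that total the expected RPKM of a gene equals its true
expression level, so class proportions land where the expression
distribution puts them.

All randomness flows through seeded PCG64 generators with fixed stream
offsets per output, so every artefact is byte-reproducible from the seed.

**What the simulation does not emulate:** mappability and GC bias,
chromatin-accessibility structure in the input, isoform overlap and shared
exons, paired-end fragments, strand-specific RNA protocols, and biological
covariation between expression and intron number.  Passing tests establish
the pipeline's arithmetic, calibration and parameter recovery under the
stated generative model — not that any particular biological dataset will
show exon-biased occupancy.

## Problem sizes and determinism

The self-validation experiments use 500 genes (≈1500 triplets) for
multiplier recovery and power, 200 replicates of 40 genes for null
calibration, 2000 draws for rank-sum type-I error, and 200 genes for the
RPKM pathway; these sizes put Monte-Carlo error comfortably inside the
asserted bands.  All tests and `scripts/acceptance.py` are seeded and
deterministic; the acceptance script derives every stream from its `--seed`
argument.

## Known limitations

* The exact rank-sum route requires untied data; heavily tied small samples
  fall back to the tie-corrected normal approximation even below n = 12.
* Percent-of-length profiles of features much shorter than 100 bp populate
  only a subset of percent bins per feature; single-feature profiles can
  contain NaN bins (averaged profiles over many features generally do not).
* Gene filtering treats each transcript independently; overlapping isoforms
  of one locus are removed by the isolation filter rather than collapsed
  into a union model (isoform collapsing is out of scope).
* With real (heterogeneous-expression) data the rank-sum contrasts are
  conservative, as discussed above.
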