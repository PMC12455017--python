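# Methods

## Scope and data model

eccmirkit starts from eccDNA interval calls, not raw reads: alignment and
circle detection (BWA-MEM + Circle-Map in a typical workflow) are upstream
of the package. Calls arrive as a Circle-Map-style BED dialect
(`chrom start end discordant split [concordant]`); all coordinates are held
internally as 0-based half-open intervals, with SAM (1-based) and GFF3/GTF
(1-based inclusive) shifted on read. Circles are double-stranded, so no
eccDNA operation is strand-aware; gene and pre-miR features keep their
strand. `(ecc_id, sample_id)` identifies a call, with
`ecc_id = chrom:start-end`.

Reads are classified by flag logic mirroring samblaster's definitions:
split if a supplementary alignment exists (or an SA tag), else discordant
if paired and not a proper pair, else concordant if a proper pair;
unpaired reads without supplementary alignments stay unassigned. When
recounting support from alignments, a read counts toward **every** circle
it overlaps by ≥ 1 bp — the behaviour of interval-overlap counting with
BEDTools-style semantics; the minimum overlap is configurable as a future
extension but defaults to 1 bp because no stricter threshold is standard.
Read deduplication is not implemented; counts are taken as provided.

## Filtering and abundance

The high-confidence filter keeps calls with split ≥ 2 AND discordant ≥ 2
AND length strictly < 50 Mb (the bound is read literally as "<"). Failures
are attributed to the first violated rule in that order, so the report
partitions the input exactly.

Abundance is the length- and depth-normalised per-million measure:
RPK = total count / (length in kb), TPM = RPK / Σ RPK × 1e6 per sample,
reported alongside log10(TPM + 1). A sample whose RPK sum is zero gets
zero TPM everywhere rather than NaN. Because TPM is compositional, a
fold change planted on *every* circle cancels entirely after
normalisation, and a fold change planted on a *subset* depresses the
apparent abundance of unchanged circles — both effects are visible in the
simulation studies below and are inherent to per-million scaling, not
artefacts of the implementation.

Group abundance summaries count distinct detected circles (total count
> 0) per sample and report per-group means and their ratio, the quantity
behind "mean circles per sample" comparisons between tumour and normal
groups.

## Junctional microhomology

Four flank windows of k = 20 bp (configurable; 20 is the conventional
junction window) are extracted around the start and end coordinates.
Microhomology is defined as exact-match breakpoint ambiguity: the
right-flush length is the longest m ≤ k with
genome[start:start+m] == genome[end:end+m]; the left-flush length is the
suffix analogue; their sum (mh_total) is the headline statistic, with
per-side values retained. Mismatch-tolerant or gapped homology is
deliberately not implemented. Flanks containing N are flagged and
excluded from homology statistics, standing in for masked-genome
filtering; flanks clipped at chromosome edges are marked truncated and
excluded from position-frequency matrices.

PFMs report per-offset base fractions over offsets −20…−1, +1…+20 for
either junction side plus the overall window GC fraction. Homology-length
histograms use closed integer bins {0, 1–5, 6–10, 11–20} by default, with
an automatic overflow bin (mh_total can reach 40) so proportions always
sum to 1.

The size–homology association is Spearman rank correlation between
mh_total and log10(length), with average ranks for ties. For n ≤ 9 the
two-sided p comes from full permutation enumeration; above that, the
large-sample t approximation. Zero variance in either variable raises
rather than returning a meaningless coefficient.

## Genomic annotation

Each gene contributes derived intervals: a strand-aware upstream-only
promoter window (default 3,000 bp before the TSS), a downstream window
(default 300 bp past the TES), exons, the gaps between them as introns,
and UTRs as given. A circle collects every category its whole interval
overlaps by ≥ 1 bp and takes the highest-priority one
(promoter > 5′UTR > 3′UTR > exon > intron > downstream); a circle hitting
nothing is distal intergenic. Whole-interval overlap (rather than
midpoint assignment, as some annotators use) was chosen because a circle
genuinely spans multiple features and the priority rule exists precisely
to resolve that; a two-sided TSS window is the main alternative promoter
convention and would shift promoter shares upward. Group size summaries
use the lower-median convention for even n.

## Differential abundance and eccMIRs

The two-group test is a Wilcoxon rank-sum on per-sample TPM — exact by
enumeration when the pooled sample size is ≤ 10 with no ties, otherwise
the normal approximation with tie and continuity corrections — with
Benjamini–Hochberg step-up FDR across all circles tested and
log2FC = log2((mean₁ + ε)/(mean₂ + ε)), ε = 1. Direction calls default to
|log2FC| ≥ 1 and q ≤ 0.05; asymmetric thresholds (e.g. up at logFC > 2,
down at logFC > 0.5) are available through the same configuration. A
negative-binomial count model (edgeR-style) is intentionally not used;
the nonparametric route is self-contained and its exactness properties
are testable by enumeration. Identical values across both groups
degenerate to p = 1.

An eccMIR is a circle that fully contains ≥ 1 pre-miR interval on the
same chromosome — partial overlap never qualifies, since a truncated
hairpin cannot be transcribed into a functional precursor. Upregulation
flags use the two-sided rank-sum p < α (default .05) with the direction
read post hoc from group means. Note the small-sample limit: with 3 vs 3
samples the smallest achievable exact two-sided p is 0.1, so no 3 vs 3
eccMIR can be flagged at α = .05; five samples per group is the practical
minimum.

## The synthetic generator

The generator emulates the features the analyses consume and nothing
more. Genomes are i.i.d. bases at a configurable GC fraction (default
0.5) over two 400 kb chromosomes by default. Circles (default 200) are
placed without overlap — real eccDNAs do overlap, but disjoint placement
makes planted truth unambiguous — keeping 25 bp off chromosome edges and
≥ 50 bp gaps so that each junction's 20 bp windows and the planted edit
region are independent; chromosomes are chosen per circle with
probability proportional to remaining capacity, which balances placement.
Sizes are log-uniform over 10^2–10^4 bp by default, the dominant size
range for somatic eccDNA. Each circle draws a repair-pathway label from
weights (0.6, 0.25, 0.15) for MMEJ/NHEJ/HR — MMEJ-dominant, matching the
biology being modelled — and a homology length uniform in the pathway's
range: MMEJ 1–10, NHEJ 0–1, HR 11–20 bp (the published evidence is
binned, so uniform-within-bin is the least-informative choice).
Microhomology is planted by copying m bases from the start junction onto
the end junction and forcing a mismatch at position m, so the measured
right-flush length equals the planted value exactly; with
`mh_size_coupling` the homology is instead drawn from a ±2 window around
20 × (size rank fraction), giving a strong planted rank dependence for
correlation power studies.

Copy numbers are integers in 2–20 by default; read counts per class are
Poisson with mean copy number × per-copy rates (split 1, discordant 1,
concordant 3 — tens of supporting reads per circle, typical of
high-confidence Circle-seq calls). The first sample group multiplies copy
numbers of elevated circles by 2^planted_log2fc (default: all circles at
log2FC 1; a subset via `n_up_circles`). Reads are emitted as
already-classified alignments (optionally as SAM text) rather than FASTQ:
alignment is upstream of the package. Split reads end at the circle end
and carry a supplementary alignment continuing at the circle start; a
discordant record stands for one aberrant pair. Pre-miR loci are 90 bp
intervals placed strictly inside a chosen subset of circles. Everything is
a pure function of the config seed; per-sample streams derive from the
seed plus a CRC-32 of the sample id, and knockdown populations use
seed + 1 so paired conditions are independent draws.

Knockdown contrasts scale the targeted pathway's weight by a depletion
factor (default 0.3). Silencing MMEJ renormalises the remainder over
NHEJ/HR and halves circle yield; silencing NHEJ or HR hands the freed
weight to MMEJ (the dominant route) and raises yield (×1.5 and ×1.2
respectively — the HR factor is a modelling choice, as is the whole
reallocation rule; only the MMEJ/NHEJ directions are constrained by the
modelled biology).

What the generator does **not** model: sequencing error and base
qualities, rolling-circle amplification bias, overlapping circles,
duplicate reads, GC-coverage bias, and real genomic sequence composition
(repeats, true motif structure). Passing recovery tests therefore
demonstrates correctness of the measurement and inference machinery under
the stated generative model, not robustness to those real-data artefacts.

## Study conditions used by the validation suites

Problem sizes are chosen so each property is measured where its
statistical argument holds: microhomology recovery and knockdown
contrasts use 500 circles; the size–homology correlation uses 500 coupled
circles plus 1,000 independent-draw nulls of 100 pairs each (rejection
rate expected in 3–7% at α = .05); detected-circle fold recovery uses the
sparse-detection regime (per-copy rates 0.008/0.008/0.014, copy numbers
1–2, 1,000 circles, 4 samples/group), where the expected number of
detected circles is nearly linear in copy number and the group ratio
converges to 2^log2FC; differential recovery uses 300 circles, 4 vs 4
samples and 50 circles planted at log2FC 2. In that last design the
planted circles' TPM fold is compressed to ≈ 2^1.4 and unchanged circles
shift down ≈ 2^−0.6 by compositionality; both effects leave planted
circles above the |log2FC| ≥ 1 call threshold and unchanged circles below
it, and the many near-perfectly separated circles let the BH step-up
clear the exact-p granularity floor of 4 vs 4 rank tests.

## Known limitations

- TPM compositionality (above) means global abundance shifts are
  invisible by design; spike-in or count-based normalisation would be
  needed to detect them.
- Annotation reproduces the priority rule, not any specific annotator's
  internals; promoter-definition differences (one- vs two-sided TSS
  windows) move category shares by a few percent.
- Exact rank-sum p-values are granular at small n (minimum 0.1 at 3 vs 3,
  0.0079 at 5 vs 5), which bounds what any FDR threshold can call.
- SAM input is text-only; BAM/CRAM should be converted upstream
  (`samtools view`).
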