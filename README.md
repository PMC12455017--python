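# eccmirkit

Characterization toolkit for extrachromosomal circular DNA (eccDNA) from
Circle-seq experiments, built around the analyses used to profile eccDNA in
tumour versus normal tissue: high-confidence call filtering, per-circle
abundance quantification, junctional microhomology profiling (the
MMEJ/NHEJ/HR repair signature), priority-ordered genomic annotation,
nonparametric differential abundance, and identification of **eccMIRs** —
circles that fully contain a precursor-miRNA locus and can therefore act as
promoter-independent miRNA templates.

It is aimed at genomics analysts who already have eccDNA interval calls
(Circle-Map-style BED with split/discordant read support), a reference
FASTA, gene models and a miRBase-dialect GFF3, and want a tested,
deterministic reimplementation of the downstream characterization — plus a
synthetic Circle-seq generator with fully recoverable planted truth for
validating every stage.

## The statistics at the core

**High-confidence filter.** A call is retained iff it has ≥ 2 supporting
split reads, ≥ 2 supporting discordant read pairs, and length < 50 Mb.

**Abundance.** For circle *i* in sample *s* with total supporting reads
*c* = split + discordant + concordant and length *L* (bp):

```
RPK_i = c_i / (L_i / 1000)
TPM_i = RPK_i / Σ_j RPK_j × 1,000,000         (per sample)
logTPM = log10(TPM + 1)
```

**Junctional microhomology.** With the genome as *g* and a circle
[start, end), the right-flush homology is the largest *m* ≤ 20 with
`g[start:start+m] == g[end:end+m]`; the left-flush length mirrors it
upstream. Their sum is the breakpoint-ambiguity span: 0 suggests NHEJ,
1–10 bp is the MMEJ signature, longer homologies point to HR.

**Annotation.** Each circle takes the highest-priority category its
interval overlaps: promoter (3 kb upstream of the TSS, strand-aware) >
5′UTR > 3′UTR > exon > intron > downstream (300 bp past the TES) > distal
intergenic.

**Differential abundance / eccMIRs.** Per circle, a two-sided Wilcoxon
rank-sum test on per-sample TPM (exact for small tie-free samples),
Benjamini–Hochberg FDR across circles, and
log2FC = log2((mean₁+1)/(mean₂+1)); direction calls need |log2FC| ≥ 1 and
q ≤ 0.05 by default. An eccMIR is a circle fully containing a pre-miR
interval; it is flagged upregulated when Wilcoxon p < .05 with a higher
case-group mean.

## Worked example

Run the whole pipeline on a simulated two-group experiment (80 circles,
3 tumour + 3 normal samples, 8 pre-miR-carrying circles):

```
$ cat pipe.yaml
outdir: run
seed: 3
simulate: {n_circles: 80, n_mir_circles: 8, seed: 3}

$ ecc-mir-kit run --config pipe.yaml
```

prints (abridged):

```
n_input_records              480
n_pass_filter                467
mean_detected_tumour         79.333
mean_detected_normal         76.333
abundance_ratio              1.039
median_size_tumour           679.0
mh_size_spearman_rho         0.0289
n_up                         0
n_down                       0
n_altered                    0
n_eccmir                     8
n_eccmir_up                  0

microhomology length bins (proportion):
  tumour: 0: 0.076, 1-5: 0.399, 6-10: 0.353, 11-20: 0.172
```

480 per-sample calls (80 circles × 6 samples) yield 467 high-confidence
records; both groups detect essentially every circle (ratio ≈ 1 — the
default design plants the same fold change on every circle, which TPM
normalization cancels, so no circle is differentially abundant); the
homology-length bins reflect the configured pathway mix (60% MMEJ, 25%
NHEJ, 15% HR); all 8 planted pre-miR circles are recovered as eccMIRs.
The output directory also holds `abundance.tsv`, `junctions.tsv`,
`annotation.tsv`, `diff.tsv`, `eccmir.tsv`, the simulated inputs, and a
`manifest.json` of SHA-256 checksums (byte-identical across reruns of the
same config).

Every stage is also available as a library function
(`eccmirkit.quantify.compute_tpm`, `eccmirkit.junctions.measure_microhomology`,
…) and as individual subcommands (`simulate`, `filter`, `quantify`,
`junctions`, `annotate`, `diff`, `eccmir`).

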