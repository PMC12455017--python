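"""Priority-ordered genomic annotation of eccDNA intervals.

Each circle is assigned the single highest-priority category among all
features its whole interval overlaps by >=1 bp, in the order
promoter > 5'UTR > 3'UTR > exon > intron > downstream > distal intergenic.
Promoter windows are strand-aware and upstream-only (default 3 kb before
the TSS); downstream windows extend 300 bp past the TES.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import CATEGORY_PRIORITY, EccRecord, GeneModel, SampleSheet

DEFAULT_PROMOTER_BP = 3_000
DEFAULT_DOWNSTREAM_BP = 300


@dataclass
class AnnotationConfig:
    promoter_upstream_bp: int = DEFAULT_PROMOTER_BP
    downstream_bp: int = DEFAULT_DOWNSTREAM_BP
    priority: tuple[str, ...] = CATEGORY_PRIORITY

    def __post_init__(self) -> None:
        if sorted(self.priority) != sorted(CATEGORY_PRIORITY):
            raise ValueError(f"priority must be a permutation of {CATEGORY_PRIORITY}")
        if self.promoter_upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("window sizes must be nonnegative")


def gene_feature_intervals(
    gene: GeneModel, cfg: AnnotationConfig
) -> list[tuple[str, int, int]]:
    """Derived (category, start, end) intervals for one gene, 0-based half-open.

    On the plus strand the promoter covers [tss - P, tss) and downstream
    [tes + 1, tes + 1 + D); minus-strand genes mirror both windows to the
    higher-coordinate side.  Introns are the gaps between consecutive exons.
    """
    span_lo, span_hi = gene.span
    for s, e in gene.exons:
        if s < span_lo or e > span_hi:
            raise ValueError(f"{gene.gene_id}: exon [{s},{e}) outside gene span")
    out: list[tuple[str, int, int]] = []
    P, D = cfg.promoter_upstream_bp, cfg.downstream_bp
    if gene.strand == "+":
        if P:
            out.append(("promoter", max(0, gene.tss - P), gene.tss))
        if D:
            out.append(("downstream", gene.tes + 1, gene.tes + 1 + D))
    else:
        if P:
            out.append(("promoter", gene.tss + 1, gene.tss + 1 + P))
        if D:
            out.append(("downstream", max(0, gene.tes - D), gene.tes))
    for s, e in gene.exons:
        out.append(("exon", s, e))
    exons = sorted(gene.exons)
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 > e1:
            out.append(("intron", e1, s2))
    for s, e in gene.utr5:
        out.append(("utr5", s, e))
    for s, e in gene.utr3:
        out.append(("utr3", s, e))
    return [(c, s, e) for c, s, e in out if e > s]


@dataclass
class FeatureIndex:
    """Per-chromosome interval index of derived gene features."""

    trees: dict[str, IntervalTree]
    cfg: AnnotationConfig

    def categories_overlapping(self, chrom: str, start: int, end: int) -> set[str]:
        tree = self.trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}


def build_feature_index(
    genes: Sequence[GeneModel], cfg: AnnotationConfig | None = None
) -> FeatureIndex:
    cfg = cfg or AnnotationConfig()
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        tree = trees.setdefault(gene.chrom, IntervalTree())
        for category, s, e in gene_feature_intervals(gene, cfg):
            tree.addi(s, e, category)
    return FeatureIndex(trees=trees, cfg=cfg)


def annotate_ecc(rec: EccRecord, index: FeatureIndex) -> str:
    """Highest-priority category overlapping the circle; distal_intergenic if none."""
    hits = index.categories_overlapping(rec.chrom, rec.start, rec.end)
    for category in index.cfg.priority:
        if category in hits:
            return category
    return "distal_intergenic"


def annotate_many(records: Sequence[EccRecord], index: FeatureIndex) -> dict[str, str]:
    """Category per distinct ecc_id."""
    labels: dict[str, str] = {}
    for rec in records:
        if rec.ecc_id not in labels:
            labels[rec.ecc_id] = annotate_ecc(rec, index)
    return labels


@dataclass
class CategorySummary:
    """Counts and percentages per category (percentages to 2 decimals)."""

    group: str
    counts: dict[str, int]
    percentages: dict[str, float]
    n: int


def summarize_categories(labels: Iterable[str], group: str = "") -> CategorySummary:
    labels = list(labels)
    if not labels:
        raise ValueError("no labels to summarize")
    counts = Counter(labels)
    n = len(labels)
    ordered = {c: counts.get(c, 0) for c in CATEGORY_PRIORITY if c in counts}
    for c in counts:
        ordered.setdefault(c, counts[c])
    percentages = {c: round(v / n * 100, 2) for c, v in ordered.items()}
    return CategorySummary(group=group, counts=ordered, percentages=percentages, n=n)


def per_chromosome_counts(records: Sequence[EccRecord]) -> dict[str, int]:
    """Number of distinct circles per chromosome."""
    seen: set[str] = set()
    counts: Counter[str] = Counter()
    for rec in records:
        if rec.ecc_id in seen:
            continue
        seen.add(rec.ecc_id)
        counts[rec.chrom] += 1
    return dict(counts)


def lower_median(values: Sequence[float]) -> float:
    """Median with the lower-of-the-two convention for even n."""
    s = sorted(values)
    if not s:
        raise ValueError("empty input")
    return s[(len(s) - 1) // 2]


@dataclass
class SizeDistribution:
    medians: dict[str, float]  # group -> median length (bp)
    histogram: pd.DataFrame  # group x log10-size bin counts
    bin_edges: np.ndarray


def size_distribution(
    records: Sequence[EccRecord],
    sheet: SampleSheet,
    bin_edges: Sequence[float] | None = None,
) -> SizeDistribution:
    """Per-group median circle size and log10-size histogram.

    Circles are deduplicated by ecc_id within each group; a circle present
    in both groups contributes to both.
    """
    edges = np.asarray(bin_edges if bin_edges is not None else np.arange(2.0, 8.5, 0.5))
    by_group: dict[str, dict[str, int]] = {}
    for rec in records:
        group = sheet.groups.get(rec.sample_id)
        if group is None:
            raise ValueError(f"sample {rec.sample_id!r} absent from sheet")
        by_group.setdefault(group, {})[rec.ecc_id] = rec.length
    medians = {}
    hist_rows = {}
    for group, lengths in by_group.items():
        values = list(lengths.values())
        if not values:
            raise ValueError(f"group {group!r} has no records")
        medians[group] = float(lower_median(values))
        hist, _ = np.histogram(np.log10(values), bins=edges)
        hist_rows[group] = hist
    labels = [f"[{a:g},{b:g})" for a, b in zip(edges[:-1], edges[1:])]
    histogram = pd.DataFrame.from_dict(hist_rows, orient="index", columns=labels)
    histogram.index.name = "group"
    return SizeDistribution(medians=medians, histogram=histogram, bin_edges=edges)
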