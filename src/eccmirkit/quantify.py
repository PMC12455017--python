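"""High-confidence eccDNA filtering and TPM abundance quantification.

The abundance unit is the length- and depth-normalised "per million" measure
used for Circle-seq circles: for each circle the total supporting read count
(split + discordant + concordant) is divided by the circle length in kb to
give RPK, and each RPK is divided by the sample's RPK sum and scaled to one
million.  Downstream statistics work on log10(TPM + 1).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import EccRecord, ReadAlignment, SampleSheet, classify_read

DEFAULT_MIN_SPLIT = 2
DEFAULT_MIN_DISCORDANT = 2
DEFAULT_MAX_LEN_BP = 50_000_000


@dataclass
class FilterReport:
    """Tally of the high-confidence filter with first-failing-rule attribution."""

    n_input: int
    n_pass: int
    n_fail_split: int
    n_fail_discordant: int
    n_fail_length: int

    def __post_init__(self) -> None:
        total = self.n_pass + self.n_fail_split + self.n_fail_discordant + self.n_fail_length
        if total != self.n_input:
            raise ValueError("filter report does not partition the input")


def total_count(rec: EccRecord) -> int:
    """Total supporting reads: split + discordant + concordant."""
    return rec.split_count + rec.discordant_count + rec.concordant_count


def filter_high_confidence(
    records: Sequence[EccRecord],
    min_split: int = DEFAULT_MIN_SPLIT,
    min_discordant: int = DEFAULT_MIN_DISCORDANT,
    max_len_bp: int = DEFAULT_MAX_LEN_BP,
) -> tuple[list[EccRecord], FilterReport]:
    """Keep circles with >=min_split split reads, >=min_discordant discordant
    pairs and length strictly below ``max_len_bp``.

    Each failing record is attributed to the first violated rule, in the
    order split, discordant, length.
    """
    passing: list[EccRecord] = []
    fail_split = fail_disc = fail_len = 0
    for rec in records:
        if rec.split_count < min_split:
            fail_split += 1
        elif rec.discordant_count < min_discordant:
            fail_disc += 1
        elif rec.length >= max_len_bp:
            fail_len += 1
        else:
            passing.append(rec)
    report = FilterReport(
        n_input=len(records),
        n_pass=len(passing),
        n_fail_split=fail_split,
        n_fail_discordant=fail_disc,
        n_fail_length=fail_len,
    )
    return passing, report


def count_reads_per_ecc(
    records: Sequence[EccRecord], reads: Iterable[ReadAlignment]
) -> list[EccRecord]:
    """Recount per-class read support by interval overlap.

    A read is assigned to every eccDNA it overlaps by >=1 bp on the same
    chromosome (a read spanning two overlapping circles counts toward both).
    The returned records carry the recomputed counts; input counts are
    discarded.
    """
    trees: dict[str, IntervalTree] = {}
    counts: dict[str, dict[str, int]] = {
        rec.ecc_id: {"split": 0, "discordant": 0, "concordant": 0} for rec in records
    }
    for i, rec in enumerate(records):
        trees.setdefault(rec.chrom, IntervalTree()).addi(rec.start, rec.end, rec.ecc_id)
    for read in reads:
        cls = classify_read(read)
        if cls == "unassigned" or read.chrom not in trees:
            continue
        for iv in trees[read.chrom].overlap(read.start, read.end):
            counts[iv.data][cls] += 1
    return [
        dataclasses.replace(
            rec,
            split_count=counts[rec.ecc_id]["split"],
            discordant_count=counts[rec.ecc_id]["discordant"],
            concordant_count=counts[rec.ecc_id]["concordant"],
        )
        for rec in records
    ]


@dataclass
class AbundanceMatrix:
    """eccDNA x sample abundance: counts, RPK, TPM and log10(TPM+1).

    Frames share the same (ecc_id x sample_id) shape; ``lengths`` holds the
    circle length in bp per ecc_id.  Circles absent from a sample's call set
    have count 0 there.
    """

    total_count: pd.DataFrame
    rpk: pd.DataFrame
    tpm: pd.DataFrame
    log_tpm: pd.DataFrame
    lengths: pd.Series

    @property
    def ecc_ids(self) -> list[str]:
        return list(self.total_count.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.total_count.columns)

    def to_long(self) -> pd.DataFrame:
        """Long-format table: ecc_id, sample_id, total_count, rpk, tpm, log_tpm."""
        frames = {
            "total_count": self.total_count,
            "rpk": self.rpk,
            "tpm": self.tpm,
            "log_tpm": self.log_tpm,
        }
        long = None
        for name, frame in frames.items():
            melted = frame.reset_index(names="ecc_id").melt(
                id_vars="ecc_id", var_name="sample_id", value_name=name
            )
            long = melted if long is None else long.merge(melted, on=["ecc_id", "sample_id"])
        return long.sort_values(["ecc_id", "sample_id"], kind="mergesort").reset_index(drop=True)


def compute_tpm(records: Sequence[EccRecord]) -> AbundanceMatrix:
    """Build the abundance matrix from per-sample eccDNA calls.

    rpk = total_count / (length / 1000); tpm = rpk / sum(sample rpk) * 1e6.
    A sample whose RPK sum is zero gets TPM 0 everywhere (and so the
    per-sample TPM total is 1e6 exactly when any count is positive).
    """
    if not records:
        raise ValueError("no records to quantify")
    rows = []
    lengths: dict[str, int] = {}
    for rec in records:
        if rec.length <= 0:
            raise ValueError(f"{rec.ecc_id}: nonpositive length")
        if lengths.setdefault(rec.ecc_id, rec.length) != rec.length:
            raise ValueError(f"{rec.ecc_id}: inconsistent length across samples")
        rows.append((rec.ecc_id, rec.sample_id, total_count(rec)))
    df = pd.DataFrame(rows, columns=["ecc_id", "sample_id", "count"])
    counts = (
        df.pivot_table(index="ecc_id", columns="sample_id", values="count", fill_value=0, aggfunc="sum")
        .sort_index(axis=0)
        .sort_index(axis=1)
        .astype(int)
    )
    counts.index.name = "ecc_id"
    counts.columns.name = "sample_id"
    len_series = pd.Series(lengths, name="length").reindex(counts.index)
    rpk = counts.div(len_series / 1000.0, axis=0)
    sums = rpk.sum(axis=0)
    safe = sums.replace(0.0, np.nan)
    tpm = rpk.div(safe, axis=1).mul(1e6).fillna(0.0)
    log_tpm = np.log10(tpm + 1.0)
    return AbundanceMatrix(
        total_count=counts, rpk=rpk, tpm=tpm, log_tpm=log_tpm, lengths=len_series
    )


@dataclass
class GroupAbundance:
    """Mean number of detected circles per sample, by group, and their ratio."""

    mean_detected: dict[str, float]
    ratio: float
    order: tuple[str, str]


def fold_ratio(mean_a: float, mean_b: float, ndigits: int = 0) -> float:
    """Ratio of group means, rounded to ``ndigits`` (0 -> nearest integer)."""
    if mean_b == 0:
        raise ZeroDivisionError("denominator group mean is zero")
    r = mean_a / mean_b
    return round(r, ndigits) if ndigits else round(r)


def group_abundance_summary(
    matrix: AbundanceMatrix,
    sheet: SampleSheet,
    order: tuple[str, str] | None = None,
) -> GroupAbundance:
    """Per-group mean count of distinct detected circles per sample.

    A circle counts as detected in a sample when its total read count is
    positive.  ``order`` fixes the (numerator, denominator) groups for the
    fold ratio; default is sheet order.
    """
    g1, g2 = order if order is not None else sheet.require_two_groups()
    means = {}
    for group in (g1, g2):
        samples = [s for s in sheet.samples_in(group) if s in matrix.total_count.columns]
        if not samples:
            raise ValueError(f"group {group!r} has no samples in the matrix")
        means[group] = float((matrix.total_count[samples] > 0).sum(axis=0).mean())
    if means[g2] == 0:
        raise ZeroDivisionError(f"group {g2!r} has no detected circles")
    return GroupAbundance(
        mean_detected=means, ratio=means[g1] / means[g2], order=(g1, g2)
    )
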