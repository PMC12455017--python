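"""Junctional sequence analysis: flanks, microhomology, PFMs, binning.

A circle [start, end) on the reference is formed by ligating the end of the
interval back to its start.  The breakpoint is therefore characterised by
four 20 bp windows: up/downstream of the start coordinate and up/downstream
of the end coordinate.  Junctional microhomology is the exact-match
breakpoint ambiguity: the right-flush length is the longest m with
genome[start:start+m] == genome[end:end+m] and the left-flush length the
longest m with genome[start-m:start] == genome[end-m:end].  Their sum
(mh_total) spans the interval over which the breakpoint could equivalently
be placed — the signature separating MMEJ (short homologies) from NHEJ
(none) and HR (long) repair products.

Flanks containing N are flagged and excluded from microhomology statistics.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import EccRecord, GenomeSequence

DEFAULT_FLANK_K = 20
DEFAULT_MH_BINS: tuple[tuple[int, int], ...] = ((0, 0), (1, 5), (6, 10), (11, 20))


@dataclass
class JunctionStats:
    """Per-circle junction flanks and microhomology lengths.

    ``mh_left``/``mh_right``/``mh_total`` are None when a flank contains N
    (``has_n``).  ``truncated`` marks circles whose flanks were clipped at a
    chromosome edge.
    """

    ecc_id: str
    flank_5p_up: str
    flank_5p_down: str
    flank_3p_up: str
    flank_3p_down: str
    truncated: bool
    has_n: bool = False
    mh_left: int | None = None
    mh_right: int | None = None

    @property
    def mh_total(self) -> int | None:
        if self.mh_left is None or self.mh_right is None:
            return None
        return self.mh_left + self.mh_right


def extract_flanks(rec: EccRecord, genome: GenomeSequence, k: int = DEFAULT_FLANK_K) -> JunctionStats:
    """Extract the four k-bp windows around the start and end junctions.

    Windows are clipped at chromosome edges; clipping is recorded in
    ``truncated``.
    """
    if rec.chrom not in genome:
        raise KeyError(f"chromosome {rec.chrom!r} not in genome")
    chrom_len = genome.lengths[rec.chrom]
    f5u = genome.fetch(rec.chrom, rec.start - k, rec.start)
    f5d = genome.fetch(rec.chrom, rec.start, rec.start + k)
    f3u = genome.fetch(rec.chrom, rec.end - k, rec.end)
    f3d = genome.fetch(rec.chrom, rec.end, rec.end + k)
    truncated = rec.start - k < 0 or rec.end + k > chrom_len or rec.length < k
    has_n = any("N" in f for f in (f5u, f5d, f3u, f3d))
    return JunctionStats(
        ecc_id=rec.ecc_id,
        flank_5p_up=f5u,
        flank_5p_down=f5d,
        flank_3p_up=f3u,
        flank_3p_down=f3d,
        truncated=truncated,
        has_n=has_n,
    )


def _common_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def measure_microhomology(
    rec: EccRecord, genome: GenomeSequence, k_max: int = DEFAULT_FLANK_K
) -> JunctionStats:
    """Measure left- and right-flush junction microhomology, capped at k_max.

    mh_right compares the sequences downstream of the start and end
    junctions (prefix match); mh_left compares the upstream sequences
    (suffix match).  Circles with N in any flank keep mh as None.
    """
    stats = extract_flanks(rec, genome, k=k_max)
    if stats.has_n:
        return stats
    stats.mh_right = _common_prefix(stats.flank_5p_down, stats.flank_3p_down)
    stats.mh_left = _common_prefix(stats.flank_5p_up[::-1], stats.flank_3p_up[::-1])
    return stats


def measure_many(
    records: Sequence[EccRecord], genome: GenomeSequence, k_max: int = DEFAULT_FLANK_K
) -> list[JunctionStats]:
    """Microhomology stats for distinct circles (one entry per ecc_id)."""
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.ecc_id in seen:
            continue
        seen.add(rec.ecc_id)
        out.append(measure_microhomology(rec, genome, k_max=k_max))
    return out


# ---------------------------------------------------------------------------
# position-frequency matrices


@dataclass
class PositionFrequencyMatrix:
    """Base fractions at offsets -k..-1, +1..+k around one junction side.

    ``freqs`` is indexed by signed offset with columns A/C/G/T; rows sum to
    1 over the records counted.  ``gc_fraction`` is the overall GC content
    of the +/- k window.
    """

    side: str
    freqs: pd.DataFrame
    n_records: int
    gc_fraction: float


def junction_pfm(
    stats: Sequence[JunctionStats], side: str, k: int = DEFAULT_FLANK_K
) -> PositionFrequencyMatrix:
    """Build the PFM for the start or end junction from full-length flanks.

    Truncated and N-containing records are excluded; an empty usable set is
    an error.
    """
    if side not in ("start", "end"):
        raise ValueError("side must be 'start' or 'end'")
    usable = [
        s
        for s in stats
        if not s.truncated
        and not s.has_n
        and len(s.flank_5p_up if side == "start" else s.flank_3p_up) == k
        and len(s.flank_5p_down if side == "start" else s.flank_3p_down) == k
    ]
    if not usable:
        raise ValueError("no usable (non-truncated, N-free) junction records")
    offsets = list(range(-k, 0)) + list(range(1, k + 1))
    bases = "ACGT"
    counts = np.zeros((2 * k, 4), dtype=float)
    base_idx = {b: i for i, b in enumerate(bases)}
    for s in usable:
        window = (s.flank_5p_up + s.flank_5p_down) if side == "start" else (s.flank_3p_up + s.flank_3p_down)
        for pos, base in enumerate(window):
            counts[pos, base_idx[base]] += 1
    freqs = pd.DataFrame(counts / len(usable), index=pd.Index(offsets, name="offset"), columns=list(bases))
    gc = float(freqs[["G", "C"]].to_numpy().sum() / (2 * k))
    return PositionFrequencyMatrix(side=side, freqs=freqs, n_records=len(usable), gc_fraction=gc)


# ---------------------------------------------------------------------------
# microhomology-length binning


@dataclass
class MHBinning:
    """Per-group histogram of total microhomology length over integer bins."""

    edges: tuple[tuple[int, int], ...]
    counts: pd.DataFrame  # group x bin label
    proportions: pd.DataFrame

    @property
    def bin_labels(self) -> list[str]:
        return list(self.counts.columns)


def _bin_label(lo: int, hi: int) -> str:
    return str(lo) if lo == hi else f"{lo}-{hi}"


def bin_mh_lengths(
    groups: Mapping[str, Sequence[JunctionStats]],
    edges: Sequence[tuple[int, int]] = DEFAULT_MH_BINS,
) -> MHBinning:
    """Histogram mh_total per group over closed integer bins.

    Values above the last bin fall into an automatic overflow bin so that
    proportions always sum to 1.  Groups with no non-null mh are an error.
    """
    edges = tuple((int(lo), int(hi)) for lo, hi in edges)
    top = max(hi for _, hi in edges)
    labels = [_bin_label(lo, hi) for lo, hi in edges]
    overflow = f">{top}"
    rows = {}
    need_overflow = False
    for group, stats in groups.items():
        values = [s.mh_total for s in stats if s.mh_total is not None]
        if not values:
            raise ValueError(f"group {group!r} has no microhomology values")
        row = {label: 0 for label in labels}
        row[overflow] = 0
        for v in values:
            for (lo, hi), label in zip(edges, labels):
                if lo <= v <= hi:
                    row[label] += 1
                    break
            else:
                row[overflow] += 1
                need_overflow = True
        rows[group] = row
    counts = pd.DataFrame.from_dict(rows, orient="index")
    if not need_overflow:
        counts = counts.drop(columns=[overflow])
    counts.index.name = "group"
    proportions = counts.div(counts.sum(axis=1), axis=0)
    return MHBinning(edges=edges, counts=counts, proportions=proportions)


# ---------------------------------------------------------------------------
# microhomology-size correlation


@dataclass
class SpearmanResult:
    rho: float
    pvalue: float
    n: int
    method: str  # "exact" or "t-approx"


def _spearman_exact(xr: np.ndarray, yr: np.ndarray) -> tuple[float, float]:
    """Two-sided permutation p for the rank correlation, by full enumeration.

    Valid for small n (n! permutations); ties enter through average ranks.
    """
    n = len(xr)
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = math.sqrt(float((xc**2).sum() * (yc**2).sum()))
    obs = float((xc * yc).sum() / denom)
    perms = np.array(list(itertools.permutations(range(n))))
    stats = (yc[perms] @ xc) / denom
    p = float(np.mean(np.abs(stats) >= abs(obs) - 1e-12))
    return obs, p


def mh_size_correlation(
    stats: Sequence[JunctionStats], records: Sequence[EccRecord]
) -> SpearmanResult:
    """Spearman correlation between mh_total and log10 circle length.

    Pairs are matched by ecc_id; N-flagged circles are dropped.  For n <= 9
    the two-sided p comes from exact permutation enumeration; otherwise from
    the large-sample t approximation.  Zero variance in either variable is
    an error (rho undefined).
    """
    lengths = {}
    for rec in records:
        lengths[rec.ecc_id] = rec.length
    pairs = [
        (float(s.mh_total), math.log10(lengths[s.ecc_id]))
        for s in stats
        if s.mh_total is not None and s.ecc_id in lengths
    ]
    if len(pairs) < 3:
        raise ValueError("need >=3 paired observations")
    mh = np.array([p[0] for p in pairs])
    size = np.array([p[1] for p in pairs])
    if np.ptp(mh) == 0 or np.ptp(size) == 0:
        raise ValueError("zero variance: Spearman rho undefined")
    xr = sps.rankdata(mh)
    yr = sps.rankdata(size)
    if len(pairs) <= 9:
        rho, p = _spearman_exact(xr, yr)
        return SpearmanResult(rho=rho, pvalue=p, n=len(pairs), method="exact")
    res = sps.spearmanr(mh, size)
    return SpearmanResult(
        rho=float(res.statistic), pvalue=float(res.pvalue), n=len(pairs), method="t-approx"
    )


def junction_table(
    stats: Sequence[JunctionStats], records: Sequence[EccRecord]
) -> pd.DataFrame:
    """Flat per-circle junction table for TSV output."""
    lengths = {rec.ecc_id: rec.length for rec in records}
    rows = []
    for s in stats:
        rows.append(
            {
                "ecc_id": s.ecc_id,
                "length": lengths.get(s.ecc_id, pd.NA),
                "mh_left": s.mh_left if s.mh_left is not None else pd.NA,
                "mh_right": s.mh_right if s.mh_right is not None else pd.NA,
                "mh_total": s.mh_total if s.mh_total is not None else pd.NA,
                "flank_5p_up": s.flank_5p_up,
                "flank_5p_down": s.flank_5p_down,
                "flank_3p_up": s.flank_3p_up,
                "flank_3p_down": s.flank_3p_down,
                "truncated": s.truncated,
                "has_n": s.has_n,
            }
        )
    return pd.DataFrame(rows).sort_values("ecc_id", kind="mergesort").reset_index(drop=True)
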