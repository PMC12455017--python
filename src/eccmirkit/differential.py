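"""Two-group differential eccDNA abundance and eccMIR identification.

Differential abundance uses a Wilcoxon rank-sum test on per-sample TPM with
Benjamini-Hochberg FDR control and a log2 fold change on pseudocounted group
means.  An eccMIR is a circle whose interval fully contains at least one
precursor-miRNA locus; upregulated eccMIRs are flagged by a Wilcoxon p below
alpha together with a higher mean TPM in the case group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io_formats import EccRecord, PreMiR, SampleSheet
from .quantify import AbundanceMatrix


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon-Mann-Whitney U (of x) with a two-sided p.

    Exact p by enumeration when n_x + n_y <= 10 and there are no ties;
    otherwise the normal approximation with tie and continuity corrections.
    Identical values throughout both groups degenerate to p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        u = len(x) * len(y) / 2.0
        return u, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DiffThresholds:
    """Direction-call thresholds (defaults: |log2FC| >= 1, q <= .05)."""

    log2fc_up: float = 1.0
    log2fc_down: float = 1.0
    q_max: float = 0.05
    epsilon: float = 1.0


@dataclass
class DiffResult:
    ecc_id: str
    mean_tpm: dict[str, float]
    log2fc: float
    p: float
    q: float
    direction: str  # up / down / ns


def differential_abundance(
    matrix: AbundanceMatrix,
    sheet: SampleSheet,
    contrast: tuple[str, str] | None = None,
    thresholds: DiffThresholds | None = None,
) -> list[DiffResult]:
    """Per-circle differential abundance between two groups.

    ``contrast`` is (numerator, denominator); default is sheet group order.
    log2fc = log2((mean_tpm_num + eps) / (mean_tpm_den + eps)); p from the
    rank-sum test on per-sample TPM, q by BH across all circles tested.
    """
    thresholds = thresholds or DiffThresholds()
    g1, g2 = contrast if contrast is not None else sheet.require_two_groups()
    s1 = [s for s in sheet.samples_in(g1) if s in matrix.tpm.columns]
    s2 = [s for s in sheet.samples_in(g2) if s in matrix.tpm.columns]
    if not s1 or not s2:
        raise ValueError(f"missing samples for contrast ({g1!r}, {g2!r})")
    eps = thresholds.epsilon
    results: list[DiffResult] = []
    pvals = []
    for ecc_id in matrix.tpm.index:
        x = matrix.tpm.loc[ecc_id, s1].to_numpy(dtype=float)
        y = matrix.tpm.loc[ecc_id, s2].to_numpy(dtype=float)
        m1, m2 = float(x.mean()), float(y.mean())
        lfc = math.log2((m1 + eps) / (m2 + eps))
        _, p = wilcoxon_rank_sum(x, y)
        pvals.append(p)
        results.append(
            DiffResult(
                ecc_id=ecc_id,
                mean_tpm={g1: m1, g2: m2},
                log2fc=lfc,
                p=p,
                q=float("nan"),
                direction="ns",
            )
        )
    qvals = benjamini_hochberg(pvals)
    for res, q in zip(results, qvals):
        res.q = float(q)
        if res.q <= thresholds.q_max and res.log2fc >= thresholds.log2fc_up:
            res.direction = "up"
        elif res.q <= thresholds.q_max and res.log2fc <= -thresholds.log2fc_down:
            res.direction = "down"
    return results


def diff_frame(results: Sequence[DiffResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        (g1, m1), (g2, m2) = r.mean_tpm.items()
        rows.append(
            {
                "ecc_id": r.ecc_id,
                f"mean_tpm_{g1}": m1,
                f"mean_tpm_{g2}": m2,
                "log2fc": r.log2fc,
                "p": r.p,
                "q": r.q,
                "direction": r.direction,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# eccMIRs


@dataclass
class EccMIRCall:
    """A circle fully containing >=1 pre-miR locus, with group statistics."""

    ecc_id: str
    chrom: str
    start: int
    end: int
    mir_ids: tuple[str, ...]
    tpm_by_group: dict[str, list[float]] = field(default_factory=dict)
    wilcoxon_p: float | None = None
    is_upregulated: bool | None = None


def find_eccmirs(records: Sequence[EccRecord], mirs: Sequence[PreMiR]) -> list[EccMIRCall]:
    """Circles that fully contain at least one pre-miR (partial overlap is not enough).

    Containment: same chromosome, circle.start <= mir.start and
    mir.end <= circle.end.  Circle strand is undefined; the miR strand is
    irrelevant to containment.
    """
    trees: dict[str, IntervalTree] = {}
    for mir in mirs:
        trees.setdefault(mir.chrom, IntervalTree()).addi(mir.start, mir.end, mir)
    calls: list[EccMIRCall] = []
    seen: set[str] = set()
    for rec in records:
        if rec.ecc_id in seen:
            continue
        seen.add(rec.ecc_id)
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        contained = sorted(
            (
                iv.data.mir_id
                for iv in tree.overlap(rec.start, rec.end)
                if rec.start <= iv.data.start and iv.data.end <= rec.end
            )
        )
        if contained:
            calls.append(
                EccMIRCall(
                    ecc_id=rec.ecc_id,
                    chrom=rec.chrom,
                    start=rec.start,
                    end=rec.end,
                    mir_ids=tuple(contained),
                )
            )
    return calls


def test_eccmir_upregulation(
    calls: Sequence[EccMIRCall],
    matrix: AbundanceMatrix,
    sheet: SampleSheet,
    alpha: float = 0.05,
    contrast: tuple[str, str] | None = None,
) -> list[EccMIRCall]:
    """Flag eccMIRs upregulated in the case group.

    Per call: two-sided rank-sum on per-sample TPM; upregulated iff
    p < alpha and the case-group mean exceeds the control mean (direction
    assessed post hoc).
    """
    g1, g2 = contrast if contrast is not None else sheet.require_two_groups()
    s1 = [s for s in sheet.samples_in(g1) if s in matrix.tpm.columns]
    s2 = [s for s in sheet.samples_in(g2) if s in matrix.tpm.columns]
    if not s1 or not s2:
        raise ValueError(f"missing samples for contrast ({g1!r}, {g2!r})")
    out = []
    for call in calls:
        if call.ecc_id not in matrix.tpm.index:
            continue
        x = matrix.tpm.loc[call.ecc_id, s1].to_numpy(dtype=float)
        y = matrix.tpm.loc[call.ecc_id, s2].to_numpy(dtype=float)
        _, p = wilcoxon_rank_sum(x, y)
        call.tpm_by_group = {g1: list(x), g2: list(y)}
        call.wilcoxon_p = p
        call.is_upregulated = bool(p < alpha and x.mean() > y.mean())
        out.append(call)
    return out


def eccmir_frame(calls: Sequence[EccMIRCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "ecc_id": c.ecc_id,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "n_mirs": len(c.mir_ids),
                "mir_ids": ",".join(c.mir_ids),
                "wilcoxon_p": c.wilcoxon_p if c.wilcoxon_p is not None else pd.NA,
                "is_upregulated": c.is_upregulated if c.is_upregulated is not None else pd.NA,
            }
        )
    return pd.DataFrame(rows)
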