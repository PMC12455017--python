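"""Synthetic Circle-seq data with planted, fully recoverable ground truth.

The generator emulates the study conditions the downstream stages are
validated against: a random genome; non-overlapping circles whose sizes are
log-uniform over orders of magnitude; a repair-pathway label per circle
(MMEJ / NHEJ / HR) drawn from configurable weights, with a junctional
microhomology of the pathway-typical length planted by editing the genome at
the end junction so that exactly ``planted_mh`` bases match and the next
base mismatches; per-circle copy numbers that drive Poisson split /
discordant / concordant read counts; a two-group sample design in which the
elevated group's copy numbers are multiplied by 2**planted_log2fc; and a
90 bp pre-miR interval placed strictly inside a subset of circles.

Every output is a pure function of the config (seeded numpy Generators;
per-sample streams derive from the seed and a stable hash of the sample id).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    EccRecord,
    GeneModel,
    GenomeSequence,
    PreMiR,
    ReadAlignment,
    SampleSheet,
    ecc_id_for,
    stable_hash,
)

PATHWAYS = ("MMEJ", "NHEJ", "HR")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# placement margins: flank windows are 20 bp and the end-junction edit
# touches [end, end+mh+1), so circles keep >=25 bp off chromosome edges and
# >=50 bp between each other to make every planted junction independent.
_EDGE_MARGIN = 25
_MIN_GAP = 50
MIR_LENGTH = 90


@dataclass
class SimConfig:
    """Study conditions for one simulation (all randomness flows from seed)."""

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (400_000, 400_000)
    gc_fraction: float = 0.5
    n_circles: int = 200
    pathway_weights: tuple[float, float, float] = (0.6, 0.25, 0.15)  # MMEJ, NHEJ, HR
    mh_params: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"MMEJ": (1, 10), "NHEJ": (0, 1), "HR": (11, 20)}
    )
    size_log10_range: tuple[float, float] = (2.0, 4.0)
    copy_number_range: tuple[int, int] = (2, 20)
    n_samples_per_group: int = 3
    group_labels: tuple[str, str] = ("tumour", "normal")  # first group is elevated
    planted_log2fc: float = 1.0
    n_up_circles: int | None = None  # None: every circle carries the fold change
    reads_per_copy: tuple[float, float, float] = (1.0, 1.0, 3.0)  # split, disc, conc
    n_mir_circles: int = 20
    mh_size_coupling: bool = False  # plant mh increasing with size rank

    def validate(self) -> None:
        w = np.asarray(self.pathway_weights, dtype=float)
        if w.size != 3 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("pathway_weights must be 3 nonnegative values summing to 1")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chrom_lengths must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        for pw, (lo, hi) in self.mh_params.items():
            if pw not in PATHWAYS or lo > hi or lo < 0 or hi > 20:
                raise ValueError(f"bad mh range for {pw}: ({lo}, {hi})")
        if self.size_log10_range[0] > self.size_log10_range[1]:
            raise ValueError("empty size range")
        if self.copy_number_range[0] < 1 or self.copy_number_range[0] > self.copy_number_range[1]:
            raise ValueError("copy_number_range must be integers >= 1")
        if any(r < 0 for r in self.reads_per_copy):
            raise ValueError("reads_per_copy rates must be nonnegative")
        if self.n_mir_circles > self.n_circles:
            raise ValueError("n_mir_circles exceeds n_circles")


@dataclass
class SimTruth:
    """Planted circle table: coordinates, pathway, microhomology, copy number,
    elevation flag and any contained pre-miR."""

    frame: pd.DataFrame
    config: SimConfig

    @property
    def n_circles(self) -> int:
        return len(self.frame)

    def premirs(self) -> list[PreMiR]:
        out = []
        for row in self.frame.itertuples():
            if row.contains_mir:
                out.append(
                    PreMiR(
                        mir_id=row.mir_id,
                        chrom=row.chrom,
                        strand=row.mir_strand,
                        start=int(row.mir_start),
                        end=int(row.mir_end),
                    )
                )
        return out

    def copy_number(self, row, group: str) -> float:
        """Expected copy number of a truth row in the given sample group."""
        cn = float(row.base_copy_number)
        if group == self.config.group_labels[0] and row.is_elevated:
            cn *= 2.0 ** self.config.planted_log2fc
        return cn

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genome


def simulate_genome(cfg: SimConfig) -> GenomeSequence:
    """I.i.d. bases with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 0])
    gc = cfg.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    sequences = {}
    for i, length in enumerate(cfg.chrom_lengths, start=1):
        idx = rng.choice(4, size=length, p=probs)
        sequences[f"chr{i}"] = _BASES[idx].tobytes().decode("ascii")
    return GenomeSequence(sequences)


# ---------------------------------------------------------------------------
# circle population (distributions shared by planting and by calibration draws)


def sample_circle_population(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw sizes, pathway labels and planted microhomology lengths.

    With ``mh_size_coupling`` the microhomology is instead drawn from a
    +/-2 window around 20 * (size rank fraction), producing a positive
    rank dependence between size and homology length.
    """
    lo, hi = cfg.size_log10_range
    sizes = np.round(10 ** rng.uniform(lo, hi, size=cfg.n_circles)).astype(int)
    sizes = np.maximum(sizes, 50)
    pathways = rng.choice(PATHWAYS, size=cfg.n_circles, p=np.asarray(cfg.pathway_weights))
    mh = np.empty(cfg.n_circles, dtype=int)
    if cfg.mh_size_coupling:
        order = sizes.argsort(kind="stable").argsort(kind="stable")
        frac = order / max(cfg.n_circles - 1, 1)
        center = np.round(frac * 20).astype(int)
        jitter = rng.integers(-2, 3, size=cfg.n_circles)
        mh = np.clip(center + jitter, 0, 20)
    else:
        for pw in PATHWAYS:
            mask = pathways == pw
            plo, phi = cfg.mh_params[pw]
            mh[mask] = rng.integers(plo, phi + 1, size=int(mask.sum()))
    return pd.DataFrame({"size": sizes, "pathway": pathways, "planted_mh": mh})


def plant_circles(genome: GenomeSequence, cfg: SimConfig) -> tuple[GenomeSequence, SimTruth]:
    """Place non-overlapping circles and edit the genome to plant each
    circle's junctional microhomology.

    For a circle with planted length m the end-junction copy is edited so
    genome[start:start+m] == genome[end:end+m] exactly while
    genome[start+m] != genome[end+m]; for m = 0 a mismatch at the first base
    is forced.  Circles keep margins so edits never touch another circle's
    flank windows.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 1])
    pop = sample_circle_population(cfg, rng)

    chrom_names = list(genome.sequences)
    arrays = {c: np.frombuffer(genome.sequences[c].encode(), dtype=np.uint8).copy() for c in chrom_names}
    cursors = {c: _EDGE_MARGIN for c in chrom_names}
    placements: list[tuple[str, int, int]] = []
    for size in pop["size"]:
        size = int(size)
        weights = []
        for c in chrom_names:
            free = len(arrays[c]) - _EDGE_MARGIN - cursors[c] - _MIN_GAP - size
            weights.append(max(free, 0))
        total = float(sum(weights))
        if total == 0:
            raise ValueError(
                "infeasible packing: genome too small for the requested circles "
                "(reduce n_circles or size range, or enlarge chrom_lengths)"
            )
        c = rng.choice(chrom_names, p=np.asarray(weights, dtype=float) / total)
        slack = len(arrays[c]) - _EDGE_MARGIN - cursors[c] - _MIN_GAP - size
        gap = _MIN_GAP + int(rng.integers(0, min(slack, 100) + 1))
        start = cursors[c] + gap
        placements.append((c, start, start + size))
        cursors[c] = start + size

    # plant microhomology at the end junction
    complement_pick = rng.integers(0, 3, size=len(placements))
    for i, ((chrom, start, end), m) in enumerate(zip(placements, pop["planted_mh"])):
        arr = arrays[chrom]
        m = int(m)
        if m > 0:
            arr[end : end + m] = arr[start : start + m]
        if arr[end + m] == arr[start + m]:
            others = _BASES[_BASES != arr[start + m]]
            arr[end + m] = others[complement_pick[i] % len(others)]

    # copy numbers and group elevation
    cn_lo, cn_hi = cfg.copy_number_range
    base_cn = rng.integers(cn_lo, cn_hi + 1, size=len(placements))
    elevated = np.ones(len(placements), dtype=bool)
    if cfg.n_up_circles is not None:
        elevated[:] = False
        elevated[rng.choice(len(placements), size=cfg.n_up_circles, replace=False)] = True

    # pre-miR placement strictly inside a subset of sufficiently large circles
    mir_cols = {
        "contains_mir": np.zeros(len(placements), dtype=bool),
        "mir_id": [""] * len(placements),
        "mir_start": np.full(len(placements), -1),
        "mir_end": np.full(len(placements), -1),
        "mir_strand": [""] * len(placements),
    }
    if cfg.n_mir_circles:
        eligible = [i for i, (_, s, e) in enumerate(placements) if e - s >= MIR_LENGTH + 2]
        if len(eligible) < cfg.n_mir_circles:
            raise ValueError("not enough circles large enough to host a pre-miR")
        chosen = rng.choice(eligible, size=cfg.n_mir_circles, replace=False)
        for j, i in enumerate(sorted(chosen)):
            chrom, s, e = placements[i]
            ms = int(rng.integers(s + 1, e - MIR_LENGTH))
            mir_cols["contains_mir"][i] = True
            mir_cols["mir_id"][i] = f"sim-mir-{j + 1}"
            mir_cols["mir_start"][i] = ms
            mir_cols["mir_end"][i] = ms + MIR_LENGTH
            mir_cols["mir_strand"][i] = "+" if rng.integers(0, 2) else "-"

    frame = pd.DataFrame(
        {
            "ecc_id": [ecc_id_for(c, s, e) for c, s, e in placements],
            "chrom": [c for c, _, _ in placements],
            "start": [s for _, s, _ in placements],
            "end": [e for _, _, e in placements],
            "size": pop["size"].to_numpy(),
            "pathway": pop["pathway"].to_numpy(),
            "planted_mh": pop["planted_mh"].to_numpy(),
            "base_copy_number": base_cn,
            "is_elevated": elevated,
            **mir_cols,
        }
    )
    edited = GenomeSequence({c: arrays[c].tobytes().decode("ascii") for c in chrom_names})
    return edited, SimTruth(frame=frame, config=cfg)


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    genome: GenomeSequence,
    truth: SimTruth,
    cfg: SimConfig,
    sample_id: str,
    group: str,
) -> tuple[list[ReadAlignment], list[EccRecord]]:
    """Poisson read counts per circle and class, realised as alignments.

    Expected class counts are copy_number * reads_per_copy (copy number
    scaled by 2**planted_log2fc for elevated circles in the first group).
    Split reads end at the circle end and carry a supplementary alignment
    continuing at the circle start; discordant records stand for one
    aberrant pair; concordant records are proper-pair fragments inside the
    circle.
    """
    if group not in cfg.group_labels:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 2, stable_hash(sample_id)])
    r_split, r_disc, r_conc = cfg.reads_per_copy
    reads: list[ReadAlignment] = []
    records: list[EccRecord] = []
    for row in truth.frame.itertuples():
        cn = truth.copy_number(row, group)
        n_split = int(rng.poisson(cn * r_split))
        n_disc = int(rng.poisson(cn * r_disc))
        n_conc = int(rng.poisson(cn * r_conc))
        size = row.end - row.start
        for j in range(n_split):
            a = int(rng.integers(10, 21))  # bases aligned left of the junction
            b = int(rng.integers(10, 21))  # bases continuing at the circle start
            reads.append(
                ReadAlignment(
                    read_id=f"{sample_id}|{row.ecc_id}|split{j}|{b}",
                    chrom=row.chrom,
                    start=row.end - a,
                    end=row.end,
                    is_paired=True,
                    is_proper_pair=False,
                    has_supplementary=True,
                )
            )
        for j in range(n_disc):
            frag = min(100, size)
            pos = row.start + int(rng.integers(0, size - frag + 1))
            reads.append(
                ReadAlignment(
                    read_id=f"{sample_id}|{row.ecc_id}|disc{j}",
                    chrom=row.chrom,
                    start=pos,
                    end=pos + frag,
                    is_paired=True,
                    is_proper_pair=False,
                    has_supplementary=False,
                )
            )
        for j in range(n_conc):
            frag = min(300, size)
            pos = row.start + int(rng.integers(0, size - frag + 1))
            reads.append(
                ReadAlignment(
                    read_id=f"{sample_id}|{row.ecc_id}|conc{j}",
                    chrom=row.chrom,
                    start=pos,
                    end=pos + frag,
                    is_paired=True,
                    is_proper_pair=True,
                    has_supplementary=False,
                )
            )
        records.append(
            EccRecord(
                ecc_id=row.ecc_id,
                sample_id=sample_id,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                split_count=n_split,
                discordant_count=n_disc,
                concordant_count=n_conc,
            )
        )
    return reads, records


def write_reads_sam(
    reads: Sequence[ReadAlignment], genome: GenomeSequence, path: str | Path
) -> None:
    """Write simulated alignments as SAM text (split reads get a
    supplementary line at the junction partner position encoded in the id)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in genome.lengths.items()],
    }
    ref_ids = {name: i for i, name in enumerate(genome.lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            seg = pysam.AlignedSegment()
            seg.query_name = read.read_id
            seg.reference_id = ref_ids[read.chrom]
            seg.reference_start = read.start
            seg.cigarstring = f"{read.end - read.start}M"
            seg.mapping_quality = 60
            flag = 0
            if read.is_paired:
                flag |= 0x1 | 0x40
                if read.is_proper_pair:
                    flag |= 0x2
            seg.flag = flag
            if read.has_supplementary:
                seg.set_tag("SA", f"{read.chrom},{read.start + 1},+,{read.end - read.start}M,60,0;")
            out.write(seg)


# ---------------------------------------------------------------------------
# sample sets and knockdown contrasts


@dataclass
class SimDataset:
    """A full simulated experiment: genome, truth, per-sample reads/calls."""

    genome: GenomeSequence
    truth: SimTruth
    sheet: SampleSheet
    records: list[EccRecord]
    reads_by_sample: dict[str, list[ReadAlignment]]


def simulate_sample_set(cfg: SimConfig) -> SimDataset:
    """Generate genome, truth and both sample groups in one call."""
    genome = simulate_genome(cfg)
    genome, truth = plant_circles(genome, cfg)
    groups: dict[str, str] = {}
    records: list[EccRecord] = []
    reads_by_sample: dict[str, list[ReadAlignment]] = {}
    for group in cfg.group_labels:
        for i in range(cfg.n_samples_per_group):
            sample_id = f"{group}{i + 1}"
            groups[sample_id] = group
            reads, recs = simulate_reads(genome, truth, cfg, sample_id, group)
            reads_by_sample[sample_id] = reads
            records.extend(recs)
    return SimDataset(
        genome=genome,
        truth=truth,
        sheet=SampleSheet(groups),
        records=records,
        reads_by_sample=reads_by_sample,
    )


KNOCKDOWN_CONDITIONS = ("WT", "siMMEJ", "siNHEJ", "siHR")
DEFAULT_DEPLETION = 0.3
DEFAULT_CIRCLE_SCALE = {"WT": 1.0, "siMMEJ": 0.5, "siNHEJ": 1.5, "siHR": 1.2}


def knockdown_config(
    cfg: SimConfig,
    condition: str,
    depletion: float = DEFAULT_DEPLETION,
    circle_scale: dict[str, float] | None = None,
) -> SimConfig:
    """Derive the pathway weights and circle yield for a knockdown condition.

    The targeted pathway's weight is multiplied by ``depletion``; for siMMEJ
    the remainder renormalises over NHEJ/HR, while siNHEJ and siHR hand the
    freed weight to MMEJ (the dominant biogenesis route).  Circle yield is
    scaled per condition.
    """
    if condition not in KNOCKDOWN_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {KNOCKDOWN_CONDITIONS}")
    scale = (circle_scale or DEFAULT_CIRCLE_SCALE)[condition]
    w = dict(zip(PATHWAYS, cfg.pathway_weights))
    if condition == "siMMEJ":
        w["MMEJ"] *= depletion
    elif condition == "siNHEJ":
        freed = w["NHEJ"] * (1 - depletion)
        w["NHEJ"] *= depletion
        w["MMEJ"] += freed
    elif condition == "siHR":
        freed = w["HR"] * (1 - depletion)
        w["HR"] *= depletion
        w["MMEJ"] += freed
    total = sum(w.values())
    weights = tuple(w[p] / total for p in PATHWAYS)
    n = max(1, round(cfg.n_circles * scale))
    n_mir = min(cfg.n_mir_circles, n)
    return dataclasses.replace(cfg, pathway_weights=weights, n_circles=n, n_mir_circles=n_mir)


@dataclass
class KnockdownContrast:
    condition: str
    wt_genome: GenomeSequence
    wt_truth: SimTruth
    kd_genome: GenomeSequence
    kd_truth: SimTruth


def simulate_knockdown_contrast(
    cfg: SimConfig,
    condition: str,
    depletion: float = DEFAULT_DEPLETION,
    circle_scale: dict[str, float] | None = None,
) -> KnockdownContrast:
    """Paired WT / knockdown circle populations on independent genomes."""
    wt_genome, wt_truth = plant_circles(simulate_genome(cfg), cfg)
    kd_cfg = knockdown_config(cfg, condition, depletion=depletion, circle_scale=circle_scale)
    kd_cfg = dataclasses.replace(kd_cfg, seed=(cfg.seed + 1) & 0x7FFFFFFF)
    kd_genome, kd_truth = plant_circles(simulate_genome(kd_cfg), kd_cfg)
    return KnockdownContrast(
        condition=condition,
        wt_genome=wt_genome,
        wt_truth=wt_truth,
        kd_genome=kd_genome,
        kd_truth=kd_truth,
    )


# ---------------------------------------------------------------------------
# synthetic gene models (pipeline plumbing, labelled synthetic)


def simulate_genes(
    genome: GenomeSequence, cfg: SimConfig, n_genes: int = 40
) -> list[GeneModel]:
    """Random non-overlapping synthetic gene models for annotation stages.

    Genes are 2-4 exon structures with short UTRs at the transcript ends,
    placed left to right with random gaps; purely synthetic plumbing so the
    annotation stage has features to hit.
    """
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 3])
    genes: list[GeneModel] = []
    chroms = list(genome.lengths)
    per_chrom = max(1, n_genes // len(chroms))
    gid = 0
    for chrom in chroms:
        cursor = 4_000
        length = genome.lengths[chrom]
        for _ in range(per_chrom):
            span = int(rng.integers(2_000, 8_000))
            gap = int(rng.integers(4_000, 9_000))
            start = cursor + gap
            end = start + span
            if end + 4_000 > length:
                break
            n_ex = int(rng.integers(2, 5))
            cuts = np.sort(rng.choice(np.arange(start + 50, end - 50), size=2 * (n_ex - 1), replace=False))
            bounds = [start, *cuts.tolist(), end]
            exons = tuple((bounds[2 * i], bounds[2 * i + 1]) for i in range(n_ex))
            strand = "+" if rng.integers(0, 2) else "-"
            tss, tes = (start, end - 1) if strand == "+" else (end - 1, start)
            first, last = exons[0], exons[-1]
            utr_len = 30
            if strand == "+":
                utr5 = ((first[0], min(first[0] + utr_len, first[1])),)
                utr3 = ((max(last[1] - utr_len, last[0]), last[1]),)
            else:
                utr5 = ((max(last[1] - utr_len, last[0]), last[1]),)
                utr3 = ((first[0], min(first[0] + utr_len, first[1])),)
            gid += 1
            genes.append(
                GeneModel(
                    gene_id=f"simgene{gid}",
                    chrom=chrom,
                    strand=strand,
                    tss=tss,
                    tes=tes,
                    exons=exons,
                    utr5=utr5,
                    utr3=utr3,
                )
            )
            cursor = end
    return genes
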