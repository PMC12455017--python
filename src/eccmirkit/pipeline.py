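"""End-to-end orchestration: simulate/load -> filter -> quantify -> junctions
-> annotate -> differential/eccMIR, with TSV outputs, a JSON manifest and a
run report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import annotate as ann
from . import differential as diff
from . import junctions as jx
from . import quantify as qt
from . import simulate as sim
from .io_formats import (
    EccRecord,
    SampleSheet,
    read_ecc_bed,
    read_fasta,
    read_gene_table,
    read_gtf,
    read_premir_gff3,
    read_sample_sheet,
    write_ecc_bed,
    write_fasta,
    write_gene_table,
    write_premir_gff3,
    write_sample_sheet,
)

logger = logging.getLogger("eccmirkit")


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    # either a simulation block or explicit input paths
    simulate: sim.SimConfig | None = None
    genome: Path | None = None
    bed_dir: Path | None = None
    genes: Path | None = None
    mirs: Path | None = None
    samples: Path | None = None
    # stage parameters
    min_split: int = qt.DEFAULT_MIN_SPLIT
    min_discordant: int = qt.DEFAULT_MIN_DISCORDANT
    max_len_bp: int = qt.DEFAULT_MAX_LEN_BP
    flank_k: int = jx.DEFAULT_FLANK_K
    promoter_upstream_bp: int = ann.DEFAULT_PROMOTER_BP
    downstream_bp: int = ann.DEFAULT_DOWNSTREAM_BP
    log2fc_up: float = 1.0
    log2fc_down: float = 1.0
    q_max: float = 0.05
    epsilon: float = 1.0
    eccmir_alpha: float = 0.05
    contrast: tuple[str, str] | None = None
    log_level: str = "INFO"


_SIM_KEYS = {f.name for f in dataclasses.fields(sim.SimConfig)}
_CFG_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse + strictly validate a pipeline YAML; all violations reported."""
    errors: list[str] = []
    try:
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
    except OSError as exc:
        raise ConfigError([f"cannot read config: {exc}"]) from None
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a YAML mapping"])
    unknown = set(raw) - _CFG_KEYS
    for key in sorted(unknown):
        errors.append(f"unknown key {key!r}")
    if "outdir" not in raw:
        errors.append("missing required key 'outdir'")
    sim_cfg = None
    sim_block = raw.get("simulate")
    if sim_block is not None:
        if not isinstance(sim_block, dict):
            errors.append("'simulate' must be a mapping")
        else:
            bad = set(sim_block) - _SIM_KEYS
            for key in sorted(bad):
                errors.append(f"simulate: unknown key {key!r}")
            if not bad:
                block = dict(sim_block)
                for key in ("chrom_lengths", "pathway_weights", "group_labels",
                            "size_log10_range", "copy_number_range", "reads_per_copy"):
                    if key in block and isinstance(block[key], list):
                        block[key] = tuple(block[key])
                block.setdefault("seed", raw.get("seed", 0))
                try:
                    sim_cfg = sim.SimConfig(**block)
                    sim_cfg.validate()
                except (TypeError, ValueError) as exc:
                    errors.append(f"simulate: {exc}")
    if sim_block is None:
        for key in ("genome", "bed_dir", "samples"):
            if key not in raw:
                errors.append(f"missing input path {key!r} (no 'simulate' block given)")
            elif not Path(raw[key]).exists():
                errors.append(f"{key}: path {raw[key]!r} does not exist")
        for key in ("genes", "mirs"):
            if key in raw and not Path(raw[key]).exists():
                errors.append(f"{key}: path {raw[key]!r} does not exist")
    for key in ("min_split", "min_discordant", "max_len_bp", "flank_k",
                "promoter_upstream_bp", "downstream_bp"):
        if key in raw and (not isinstance(raw[key], int) or raw[key] < 0):
            errors.append(f"{key} must be a nonnegative integer")
    for key in ("q_max", "eccmir_alpha"):
        if key in raw and not (0 < float(raw[key]) <= 1):
            errors.append(f"{key} must lie in (0, 1]")
    if errors:
        raise ConfigError(errors)
    kwargs = {k: v for k, v in raw.items() if k in _CFG_KEYS and k != "simulate"}
    kwargs["outdir"] = Path(raw["outdir"])
    for key in ("genome", "bed_dir", "genes", "mirs", "samples"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = Path(kwargs[key])
    if "contrast" in kwargs and kwargs["contrast"] is not None:
        kwargs["contrast"] = tuple(kwargs["contrast"])
    return PipelineConfig(simulate=sim_cfg, **kwargs)


@dataclass
class RunReport:
    """Summary tallies of one pipeline run (the paper-style figure tables)."""

    n_input_records: int
    filter_report: qt.FilterReport
    n_samples: int
    group_means: dict[str, float]
    abundance_ratio: float | None
    median_size: dict[str, float]
    per_chromosome: dict[str, int]
    category_summary: dict[str, dict[str, float]] | None
    mh_binning: dict[str, dict[str, float]] | None
    mh_size_rho: float | None
    mh_size_p: float | None
    n_up: int
    n_down: int
    n_altered: int
    n_tested: int
    n_eccmir: int
    n_eccmir_up: int

    def __post_init__(self) -> None:
        if self.n_up + self.n_down != self.n_altered:
            raise ValueError("tally inconsistency: n_up + n_down != n_altered")

    def to_rows(self) -> list[tuple[str, Any]]:
        rows: list[tuple[str, Any]] = [
            ("n_input_records", self.n_input_records),
            ("n_pass_filter", self.filter_report.n_pass),
            ("n_fail_split", self.filter_report.n_fail_split),
            ("n_fail_discordant", self.filter_report.n_fail_discordant),
            ("n_fail_length", self.filter_report.n_fail_length),
            ("n_samples", self.n_samples),
        ]
        for group, mean in self.group_means.items():
            rows.append((f"mean_detected_{group}", round(mean, 3)))
        if self.abundance_ratio is not None:
            rows.append(("abundance_ratio", round(self.abundance_ratio, 3)))
        for group, med in self.median_size.items():
            rows.append((f"median_size_{group}", med))
        if self.mh_size_rho is not None:
            rows.append(("mh_size_spearman_rho", round(self.mh_size_rho, 4)))
            rows.append(("mh_size_spearman_p", self.mh_size_p))
        rows += [
            ("n_up", self.n_up),
            ("n_down", self.n_down),
            ("n_altered", self.n_altered),
            ("n_tested", self.n_tested),
            ("n_eccmir", self.n_eccmir),
            ("n_eccmir_up", self.n_eccmir_up),
        ]
        return rows

    def to_text(self) -> str:
        lines = ["eccmirkit run report", "====================", ""]
        for key, value in self.to_rows():
            lines.append(f"{key:28s} {value}")
        if self.category_summary:
            lines.append("")
            lines.append("genomic categories (count, %):")
            for cat, vals in self.category_summary.items():
                lines.append(f"  {cat:20s} {int(vals['count']):8d}  {vals['pct']:6.2f}%")
        if self.mh_binning:
            lines.append("")
            lines.append("microhomology length bins (proportion):")
            for group, bins in self.mh_binning.items():
                parts = ", ".join(f"{b}: {p:.3f}" for b, p in bins.items())
                lines.append(f"  {group}: {parts}")
        return "\n".join(lines) + "\n"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    # ---- inputs -----------------------------------------------------------
    if cfg.simulate is not None:
        logger.info("stage simulate: %d circles", cfg.simulate.n_circles)
        dataset = sim.simulate_sample_set(cfg.simulate)
        genome, sheet, records = dataset.genome, dataset.sheet, dataset.records
        genes = sim.simulate_genes(genome, cfg.simulate)
        mirs = dataset.truth.premirs()
        write_fasta(genome, outdir / "genome.fa")
        dataset.truth.to_tsv(outdir / "truth.tsv")
        write_sample_sheet(sheet, outdir / "samples.tsv")
        write_gene_table(genes, outdir / "genes.tsv")
        write_premir_gff3(mirs, outdir / "mirs.gff3")
        for sample_id, reads in dataset.reads_by_sample.items():
            write_ecc_bed(
                [r for r in records if r.sample_id == sample_id],
                outdir / f"{sample_id}.ecc.bed",
            )
            sim.write_reads_sam(reads, genome, outdir / f"{sample_id}.reads.sam")
        outputs += sorted(outdir.glob("*.bed")) + sorted(outdir.glob("*.sam"))
        outputs += [outdir / n for n in ("genome.fa", "truth.tsv", "samples.tsv", "genes.tsv", "mirs.gff3")]
    else:
        genome = read_fasta(cfg.genome)
        sheet = read_sample_sheet(cfg.samples)
        records = []
        for sample_id in sheet.groups:
            bed = Path(cfg.bed_dir) / f"{sample_id}.ecc.bed"
            records.extend(read_ecc_bed(bed, sample_id))
        if cfg.genes:
            genes = read_gtf(cfg.genes) if str(cfg.genes).endswith((".gtf", ".gff")) else read_gene_table(cfg.genes)
        else:
            genes = []
        mirs = read_premir_gff3(cfg.mirs) if cfg.mirs else []
    sheet.check_covers(records)

    # ---- filter -----------------------------------------------------------
    passing, report = qt.filter_high_confidence(
        records, min_split=cfg.min_split, min_discordant=cfg.min_discordant, max_len_bp=cfg.max_len_bp
    )
    logger.info("stage filter: %d/%d records pass", report.n_pass, report.n_input)

    empty = not passing

    # ---- quantify ---------------------------------------------------------
    group_means: dict[str, float] = {}
    ratio = None
    medians: dict[str, float] = {}
    per_chrom: dict[str, int] = {}
    category_summary = None
    mh_binning = None
    rho = p_rho = None
    n_up = n_down = n_tested = 0
    n_eccmir = n_eccmir_up = 0

    if not empty:
        matrix = qt.compute_tpm(passing)
        matrix.to_long().to_csv(outdir / "abundance.tsv", sep="\t", index=False)
        outputs.append(outdir / "abundance.tsv")
        two_groups = len(sheet.group_labels) == 2
        if two_groups:
            try:
                summary = qt.group_abundance_summary(matrix, sheet, order=cfg.contrast)
                group_means, ratio = summary.mean_detected, summary.ratio
            except (ValueError, ZeroDivisionError) as exc:
                logger.warning("group abundance summary skipped: %s", exc)
        sizes = ann.size_distribution(passing, sheet)
        medians = sizes.medians
        per_chrom = ann.per_chromosome_counts(passing)

        # ---- junctions ----------------------------------------------------
        stats = jx.measure_many(passing, genome, k_max=cfg.flank_k)
        jx.junction_table(stats, passing).to_csv(outdir / "junctions.tsv", sep="\t", index=False)
        outputs.append(outdir / "junctions.tsv")
        by_group: dict[str, list] = {}
        stats_by_id = {s.ecc_id: s for s in stats}
        for rec in passing:
            group = sheet.groups[rec.sample_id]
            by_group.setdefault(group, []).append(stats_by_id[rec.ecc_id])
        try:
            binning = jx.bin_mh_lengths(by_group)
            mh_binning = {
                g: {b: float(v) for b, v in row.items()}
                for g, row in binning.proportions.iterrows()
            }
        except ValueError as exc:
            logger.warning("mh binning skipped: %s", exc)
        try:
            corr = jx.mh_size_correlation(stats, passing)
            rho, p_rho = corr.rho, corr.pvalue
        except ValueError as exc:
            logger.warning("mh-size correlation skipped: %s", exc)

        # ---- annotate -----------------------------------------------------
        if genes:
            index = ann.build_feature_index(
                genes,
                ann.AnnotationConfig(
                    promoter_upstream_bp=cfg.promoter_upstream_bp, downstream_bp=cfg.downstream_bp
                ),
            )
            labels = ann.annotate_many(passing, index)
            pd.DataFrame(
                sorted(labels.items()), columns=["ecc_id", "category"]
            ).to_csv(outdir / "annotation.tsv", sep="\t", index=False)
            outputs.append(outdir / "annotation.tsv")
            summary_cat = ann.summarize_categories(labels.values())
            category_summary = {
                c: {"count": float(summary_cat.counts[c]), "pct": summary_cat.percentages[c]}
                for c in summary_cat.counts
            }

        # ---- differential + eccMIR ---------------------------------------
        if two_groups:
            thresholds = diff.DiffThresholds(
                log2fc_up=cfg.log2fc_up, log2fc_down=cfg.log2fc_down,
                q_max=cfg.q_max, epsilon=cfg.epsilon,
            )
            results = diff.differential_abundance(
                matrix, sheet, contrast=cfg.contrast, thresholds=thresholds
            )
            frame = diff.diff_frame(results)
            frame.to_csv(outdir / "diff.tsv", sep="\t", index=False)
            outputs.append(outdir / "diff.tsv")
            n_tested = len(results)
            n_up = sum(r.direction == "up" for r in results)
            n_down = sum(r.direction == "down" for r in results)
            if mirs:
                calls = diff.find_eccmirs(passing, mirs)
                calls = diff.test_eccmir_upregulation(
                    calls, matrix, sheet, alpha=cfg.eccmir_alpha, contrast=cfg.contrast
                )
                diff.eccmir_frame(calls).to_csv(outdir / "eccmir.tsv", sep="\t", index=False)
                outputs.append(outdir / "eccmir.tsv")
                n_eccmir = len(calls)
                n_eccmir_up = sum(bool(c.is_upregulated) for c in calls)
    else:
        # forced-empty path: still emit valid (header-only) downstream tables
        for name, cols in (
            ("abundance.tsv", ["ecc_id", "sample_id", "total_count", "rpk", "tpm", "log_tpm"]),
            ("junctions.tsv", ["ecc_id", "length", "mh_left", "mh_right", "mh_total"]),
            ("diff.tsv", ["ecc_id", "log2fc", "p", "q", "direction"]),
        ):
            pd.DataFrame(columns=cols).to_csv(outdir / name, sep="\t", index=False)
            outputs.append(outdir / name)

    report_obj = RunReport(
        n_input_records=report.n_input,
        filter_report=report,
        n_samples=len(sheet.groups),
        group_means=group_means,
        abundance_ratio=ratio,
        median_size=medians,
        per_chromosome=per_chrom,
        category_summary=category_summary,
        mh_binning=mh_binning,
        mh_size_rho=rho,
        mh_size_p=p_rho,
        n_up=n_up,
        n_down=n_down,
        n_altered=n_up + n_down,
        n_tested=n_tested,
        n_eccmir=n_eccmir,
        n_eccmir_up=n_eccmir_up,
    )
    (outdir / "report.txt").write_text(report_obj.to_text())
    with open(outdir / "report.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        for key, value in report_obj.to_rows():
            fh.write(f"{key}\t{value}\n")
    outputs += [outdir / "report.txt", outdir / "report.tsv"]
    manifest = {
        str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(outputs)) if p.exists()
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return report_obj
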