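"""Readers and writers for the formats the eccDNA pipeline touches.

All coordinates are held internally as 0-based half-open intervals (the BED
convention).  SAM (1-based) and GFF3/GTF (1-based inclusive) inputs are
shifted on read; human-readable report tables convert back on write.

eccDNA calls use a Circle-Map-style BED dialect::

    chrom  start  end  discordant_count  split_count  [concordant_count]

Note the caller's column order: discordant before split.  eccDNA circles are
double-stranded, so no strand column exists and every circle-level operation
is strand-agnostic; gene and pre-miR features keep their strand.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

_VALID_BASES = frozenset("ACGTN")

CATEGORY_PRIORITY = (
    "promoter",
    "utr5",
    "utr3",
    "exon",
    "intron",
    "downstream",
    "distal_intergenic",
)


class FormatError(ValueError):
    """Malformed input file (carries file/line context in the message)."""


# ---------------------------------------------------------------------------
# genome


@dataclass
class GenomeSequence:
    """Uppercase A/C/G/T/N sequences keyed by chromosome name."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise FormatError("genome contains no sequences")
        for name, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"chromosome {name!r} has empty sequence")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FormatError(
                    f"chromosome {name!r} contains invalid bases {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return sequence on ``[start, end)``, clipped to chromosome bounds."""
        if chrom not in self.sequences:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        seq = self.sequences[chrom]
        return seq[max(start, 0) : min(end, len(seq))]


def read_fasta(path: str | Path) -> GenomeSequence:
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate chromosome name {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    return GenomeSequence(sequences)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# eccDNA calls


@dataclass(frozen=True)
class EccRecord:
    """One eccDNA call in one sample, with read-class support counts."""

    ecc_id: str
    sample_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    split_count: int = 0
    discordant_count: int = 0
    concordant_count: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"{self.ecc_id}: end ({self.end}) <= start ({self.start})"
            )
        for name in ("split_count", "discordant_count", "concordant_count"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{self.ecc_id}: {name} must be a nonnegative integer")

    @property
    def length(self) -> int:
        return self.end - self.start


def ecc_id_for(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


def read_ecc_bed(path: str | Path, sample_id: str) -> list[EccRecord]:
    """Parse the Circle-Map-style eccDNA BED dialect (see module docstring)."""
    records: list[EccRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(
                    f"{path}:{lineno}: expected >=5 tab-separated columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                discordant, split = int(fields[3]), int(fields[4])
                concordant = int(fields[5]) if len(fields) > 5 else 0
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start ({end} <= {start})")
            eid = ecc_id_for(chrom, start, end)
            if eid in seen:
                raise FormatError(f"{path}:{lineno}: duplicate eccDNA {eid}")
            seen.add(eid)
            records.append(
                EccRecord(
                    ecc_id=eid,
                    sample_id=sample_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    split_count=split,
                    discordant_count=discordant,
                    concordant_count=concordant,
                )
            )
    return records


def write_ecc_bed(records: Iterable[EccRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t"
                f"{rec.discordant_count}\t{rec.split_count}\t{rec.concordant_count}\n"
            )


# ---------------------------------------------------------------------------
# read alignments


@dataclass(frozen=True)
class ReadAlignment:
    """A primary alignment footprint with the flags read classification needs."""

    read_id: str
    chrom: str
    start: int
    end: int
    is_paired: bool = False
    is_proper_pair: bool = False
    has_supplementary: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"read {self.read_id}: end <= start")


def classify_read(rec: ReadAlignment) -> str:
    """Classify a read as split / discordant / concordant / unassigned.

    Split (a supplementary alignment exists) takes precedence; then paired
    reads are discordant or concordant by proper-pair status; unpaired reads
    without supplementary alignments are unassigned.
    """
    if rec.has_supplementary:
        return "split"
    if rec.is_paired:
        return "concordant" if rec.is_proper_pair else "discordant"
    return "unassigned"


def read_sam_text(path: str | Path) -> list[ReadAlignment]:
    """Read SAM text into primary-alignment records.

    Unmapped reads are skipped.  Supplementary / secondary lines are folded
    into their primary record's ``has_supplementary`` flag (as is an SA tag
    on the primary itself).  Mates of a pair stay separate records.
    """
    import pysam

    # htslib silently downgrades reads whose RNAME lacks an @SQ line to
    # unmapped; surface that as the format error it is.
    declared: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    for field in line.rstrip("\n").split("\t")[1:]:
                        if field.startswith("SN:"):
                            declared.add(field[3:])
                continue
            fields = line.split("\t")
            if len(fields) > 2 and fields[2] not in ("*", "") and fields[2] not in declared:
                raise FormatError(
                    f"{path}:{lineno}: read {fields[0]!r} maps to {fields[2]!r} "
                    f"which has no @SQ header line"
                )

    primaries: dict[tuple[str, int], dict] = {}
    order: list[tuple[str, int]] = []
    supp_keys: set[tuple[str, int]] = set()
    try:
        with pysam.AlignmentFile(str(path), "r") as sam:
            for seg in sam:
                if seg.is_unmapped:
                    continue
                mate = 2 if (seg.is_paired and seg.is_read2) else 1
                key = (seg.query_name, mate)
                if seg.is_supplementary or seg.is_secondary:
                    supp_keys.add(key)
                    continue
                info = {
                    "chrom": seg.reference_name,
                    "start": seg.reference_start,
                    "end": seg.reference_end,
                    "is_paired": seg.is_paired,
                    "is_proper_pair": seg.is_proper_pair,
                    "sa": seg.has_tag("SA"),
                }
                if key not in primaries:
                    order.append(key)
                primaries[key] = info
    except ValueError as exc:
        raise FormatError(
            f"{path}: SAM parse error (is every read's chromosome declared "
            f"in an @SQ header line?): {exc}"
        ) from None
    out = []
    for key in order:
        info = primaries[key]
        qname, mate = key
        out.append(
            ReadAlignment(
                read_id=f"{qname}/{mate}" if info["is_paired"] else qname,
                chrom=info["chrom"],
                start=info["start"],
                end=info["end"],
                is_paired=info["is_paired"],
                is_proper_pair=info["is_proper_pair"],
                has_supplementary=info["sa"] or key in supp_keys,
            )
        )
    return out


# ---------------------------------------------------------------------------
# gene models


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS/TES and exon/UTR structure.

    ``tss`` and ``tes`` are 0-based positions of the first and last
    transcribed base; on the minus strand ``tss > tes``.  Interval lists are
    0-based half-open.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: tuple[tuple[int, int], ...]
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = e
        lo, hi = self.span
        for name, ivs in (("utr5", self.utr5), ("utr3", self.utr3)):
            for s, e in ivs:
                if s < lo or e > hi:
                    raise ValueError(f"{self.gene_id}: {name} outside gene span")

    @property
    def span(self) -> tuple[int, int]:
        return min(self.tss, self.tes), max(self.tss, self.tes) + 1


def _parse_interval_list(text: str) -> tuple[tuple[int, int], ...]:
    text = text.strip()
    if not text or text == ".":
        return ()
    out = []
    for chunk in text.split(","):
        a, b = chunk.split("-")
        out.append((int(a), int(b)))
    return tuple(out)


def _format_interval_list(ivs: Sequence[tuple[int, int]]) -> str:
    return ",".join(f"{a}-{b}" for a, b in ivs) or "."


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read the 8-column gene table TSV.

    Columns: gene_id, chrom, strand, tss, tes, exons, utr5, utr3 where
    interval lists are comma-separated ``start-end`` pairs (0-based
    half-open), ``.`` for empty.  A header line starting with ``gene_id``
    is skipped.
    """
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "gene_id":
                continue
            if len(fields) != 8:
                raise FormatError(f"{path}:{lineno}: expected 8 columns, got {len(fields)}")
            try:
                genes.append(
                    GeneModel(
                        gene_id=fields[0],
                        chrom=fields[1],
                        strand=fields[2],
                        tss=int(fields[3]),
                        tes=int(fields[4]),
                        exons=_parse_interval_list(fields[5]),
                        utr5=_parse_interval_list(fields[6]),
                        utr3=_parse_interval_list(fields[7]),
                    )
                )
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\ttes\texons\tutr5\tutr3\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.tes}\t"
                f"{_format_interval_list(g.exons)}\t{_format_interval_list(g.utr5)}\t"
                f"{_format_interval_list(g.utr3)}\n"
            )


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF (Ensembl-style feature types)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_gene: dict[str, dict] = {}
    for feat in db.all_features():
        ftype = feat.featuretype.lower()
        gid = (feat.attributes.get("gene_id") or [feat.id])[0]
        entry = by_gene.setdefault(
            gid,
            {"chrom": feat.seqid, "strand": feat.strand, "exons": [], "utr5": [], "utr3": [], "span": None},
        )
        iv = (feat.start - 1, feat.end)  # GTF 1-based inclusive -> half-open
        if ftype == "gene":
            entry["span"] = iv
        elif ftype == "exon":
            entry["exons"].append(iv)
        elif ftype in ("five_prime_utr", "5utr"):
            entry["utr5"].append(iv)
        elif ftype in ("three_prime_utr", "3utr"):
            entry["utr3"].append(iv)
    genes = []
    for gid, e in by_gene.items():
        if e["strand"] not in ("+", "-"):
            raise FormatError(f"{path}: gene {gid} lacks a usable strand")
        ivs = e["exons"] or ([e["span"]] if e["span"] else [])
        if not ivs:
            raise FormatError(f"{path}: gene {gid} has no exons and no gene span")
        span = e["span"] or (min(s for s, _ in ivs), max(t for _, t in ivs))
        lo, hi = span
        tss, tes = (lo, hi - 1) if e["strand"] == "+" else (hi - 1, lo)
        exons = _merge_intervals(e["exons"]) if e["exons"] else ((lo, hi),)
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=e["chrom"],
                strand=e["strand"],
                tss=tss,
                tes=tes,
                exons=exons,
                utr5=tuple(_merge_intervals(e["utr5"])),
                utr3=tuple(_merge_intervals(e["utr3"])),
            )
        )
    return genes


def _merge_intervals(ivs: Sequence[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    if not ivs:
        return ()
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


# ---------------------------------------------------------------------------
# pre-miRs


@dataclass(frozen=True)
class PreMiR:
    """A precursor-miRNA locus (0-based half-open)."""

    mir_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.mir_id}: empty interval")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_premir_gff3(
    path: str | Path, feature_type: str = "miRNA_primary_transcript"
) -> list[PreMiR]:
    """Read pre-miR loci from a miRBase-dialect GFF3.

    Pre-miR hairpins typically span 60–120 bp; loci outside that range are
    accepted with a warning.
    """
    import warnings

    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    mirs = []
    for feat in db.features_of_type(feature_type):
        attrs = feat.attributes
        mir_id = (attrs.get("Name") or attrs.get("ID") or [feat.id])[0]
        mir = PreMiR(
            mir_id=mir_id,
            chrom=feat.seqid,
            strand=feat.strand if feat.strand in ("+", "-") else "+",
            start=feat.start - 1,
            end=feat.end,
        )
        if not (60 <= mir.length <= 120):
            warnings.warn(
                f"pre-miR {mir_id} spans {mir.length} bp, outside the typical 60-120 bp",
                stacklevel=2,
            )
        mirs.append(mir)
    return mirs


def write_premir_gff3(mirs: Iterable[PreMiR], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in mirs:
            fh.write(
                f"{m.chrom}\t.\tmiRNA_primary_transcript\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t.\tID={m.mir_id};Name={m.mir_id}\n"
            )


# ---------------------------------------------------------------------------
# sample sheet


@dataclass
class SampleSheet:
    """Sample → group-label map; differential stages require two groups."""

    groups: dict[str, str]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("sample sheet is empty")

    @property
    def group_labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for g in self.groups.values():
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    def require_two_groups(self) -> tuple[str, str]:
        labels = self.group_labels
        if len(labels) != 2:
            raise ValueError(f"exactly two groups required, found {labels}")
        return labels[0], labels[1]

    def check_covers(self, records: Iterable[EccRecord]) -> None:
        missing = {r.sample_id for r in records} - set(self.groups)
        if missing:
            raise ValueError(f"samples absent from sheet: {sorted(missing)}")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    groups: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "sample_id":
                continue
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected sample_id<TAB>group")
            if fields[0] in groups:
                raise FormatError(f"{path}:{lineno}: duplicate sample {fields[0]!r}")
            groups[fields[0]] = fields[1]
    return SampleSheet(groups)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s, g in sheet.groups.items():
            fh.write(f"{s}\t{g}\n")


def stable_hash(text: str) -> int:
    """Deterministic 31-bit hash for deriving per-sample RNG streams."""
    return zlib.crc32(text.encode()) & 0x7FFFFFFF
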