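"""Readers and writers for every on-disk format the pipeline touches.

All coordinates are 0-based half-open throughout the package; a single helper
(:func:`from_one_based`) converts 1-based inclusive external coordinates.
Gzip is supported transparently by every reader (by file suffix).

Dialects defined here:

* BED6 — standard; the name column carries the promoter id, scores are ignored.
* Alignment-status TSV — 9 columns: promoter_id, target_species, source,
  status, target_chrom, target_start, target_end, target_strand,
  aligned_fraction, with ``.`` for absent fields.
* Promoter annotation TSV — promoter_id, class, gene_id (``.`` for none).
* Expression matrix TSV — promoter ids as the index, sample ids as columns.
* Sample sheet TSV — sample_id, species, tissue_type, replicate_group,
  tissue_category.
* Variant TSV — chrom, pos (0-based), ref, alt, ancestral, alt_freq; or a
  minimal VCF with INFO keys ``AA`` (ancestral allele) and ``AF``.
* bedGraph — chrom, start, end, score runs.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
import pandas as pd

DIALECT_VERSION = "ptk-dialect/1"

STRANDS = ("+", "-", ".")
STATUSES = ("ALIGNED", "GAPPED", "UNMAPPED", "MULTI")
PROMOTER_CLASSES = ("coding", "noncoding", "anonymous")
TISSUE_CATEGORIES = ("testis", "immunity", "brain", "other")

ALIGNMENT_STATUS_COLUMNS = [
    "promoter_id", "target_species", "source", "status",
    "target_chrom", "target_start", "target_end", "target_strand",
    "aligned_fraction",
]


class ParseError(ValueError):
    """Malformed line or header in an input file."""


class ValidationError(ValueError):
    """Well-formed input that violates a dialect invariant."""


# ---------------------------------------------------------------------------
# Core containers


@dataclass(frozen=True)
class GenomeInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomeInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def from_one_based(chrom: str, start1: int, end1: int, strand: str = ".") -> GenomeInterval:
    """Convert 1-based inclusive coordinates to the package convention."""
    return GenomeInterval(chrom, start1 - 1, end1, strand)


@dataclass(frozen=True)
class PromoterRecord:
    """A TSS-cluster interval: the unit of evolutionary classification."""

    promoter_id: str
    interval: GenomeInterval
    species: str
    promoter_class: str = "anonymous"
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.promoter_class not in PROMOTER_CLASSES:
            raise ValidationError(
                f"unknown promoter class {self.promoter_class!r}"
            )


@dataclass(frozen=True)
class AlignmentStatus:
    """Projection outcome of one promoter into one target species by one source."""

    promoter_id: str
    target_species: str
    source: str  # msa | pairwise
    status: str  # ALIGNED | GAPPED | UNMAPPED | MULTI
    target_interval: GenomeInterval | None = None
    aligned_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValidationError(f"unknown status {self.status!r}")
        if self.source not in ("msa", "pairwise"):
            raise ValidationError(f"unknown alignment source {self.source!r}")
        if (self.status == "ALIGNED") != (self.target_interval is not None):
            raise ValidationError(
                f"{self.promoter_id}->{self.target_species} [{self.source}]: "
                "target coordinates are required iff status is ALIGNED"
            )
        if not (0.0 <= self.aligned_fraction <= 1.0):
            raise ValidationError(
                f"aligned_fraction {self.aligned_fraction} outside [0, 1]"
            )


@dataclass(frozen=True)
class VariantRecord:
    """A bi-allelic SNP with ancestral-allele annotation and population frequency."""

    chrom: str
    position: int  # 0-based
    ref_allele: str
    alt_allele: str
    ancestral_allele: str  # single base, or "." when unresolved
    alt_frequency: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alt_frequency <= 1.0):
            raise ValidationError(
                f"allele frequency {self.alt_frequency} outside [0, 1] at "
                f"{self.chrom}:{self.position}"
            )

    @property
    def ancestral_resolved(self) -> bool:
        return self.ancestral_allele in ("A", "C", "G", "T")


@dataclass
class SampleSheet:
    """Sample metadata for an expression matrix."""

    table: pd.DataFrame  # sample_id, species, tissue_type, replicate_group, tissue_category

    REQUIRED = ["sample_id", "species", "tissue_type", "replicate_group", "tissue_category"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in sample sheet")
        bad = set(self.table["tissue_category"]) - set(TISSUE_CATEGORIES)
        if bad:
            raise ValidationError(f"unknown tissue categories: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def tissue_of(self) -> dict[str, str]:
        return dict(zip(self.table["sample_id"], self.table["tissue_type"]))

    def replicate_groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, grp in zip(self.table["sample_id"], self.table["replicate_group"]):
            out.setdefault(grp, []).append(sid)
        return out

    def tissue_categories(self) -> dict[str, str]:
        """tissue_type -> category (must be consistent across samples)."""
        out: dict[str, str] = {}
        for tt, cat in zip(self.table["tissue_type"], self.table["tissue_category"]):
            if out.setdefault(tt, cat) != cat:
                raise ValidationError(f"tissue type {tt} has conflicting categories")
        return out


@dataclass
class DropCounter:
    """Counts of records discarded while reading variants."""

    non_snp: int = 0
    multiallelic: int = 0

    @property
    def total(self) -> int:
        return self.non_snp + self.multiallelic


# ---------------------------------------------------------------------------
# Low-level helpers


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _data_lines(handle: Iterable[str]) -> Iterator[tuple[int, str]]:
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        yield lineno, line


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path, expect_strand: bool = False) -> list[GenomeInterval]:
    """Read a BED file into :class:`GenomeInterval` objects (name/score kept aside).

    Use :func:`read_promoter_bed` when the name column is a promoter id.
    """
    out: list[GenomeInterval] = []
    with _open_text(path) as fh:
        for lineno, line in _data_lines(fh):
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            if expect_strand and len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 expected (strand required)")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                out.append(GenomeInterval(fields[0], start, end, strand))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def read_promoter_bed(
    path: str | Path,
    species: str,
    annotation: str | Path | None = None,
) -> list[PromoterRecord]:
    """Read promoters from BED6 plus an optional class/gene annotation TSV."""
    classes: dict[str, str] = {}
    genes: dict[str, str | None] = {}
    if annotation is not None:
        ann = pd.read_csv(annotation, sep="\t", comment="#", dtype=str)
        for col in ("promoter_id", "class", "gene_id"):
            if col not in ann.columns:
                raise ValidationError(f"{annotation}: missing column {col!r}")
        classes = dict(zip(ann["promoter_id"], ann["class"]))
        genes = {
            pid: (None if g in (".", "", None) or pd.isna(g) else g)
            for pid, g in zip(ann["promoter_id"], ann["gene_id"])
        }
    records: list[PromoterRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in _data_lines(fh):
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 required for promoters")
            pid = fields[3]
            if pid in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate promoter id {pid!r}")
            seen.add(pid)
            interval = GenomeInterval(fields[0], int(fields[1]), int(fields[2]), fields[5])
            records.append(
                PromoterRecord(
                    promoter_id=pid,
                    interval=interval,
                    species=species,
                    promoter_class=classes.get(pid, "anonymous"),
                    gene_id=genes.get(pid),
                )
            )
    return records


def write_bed(intervals: Iterable[GenomeInterval], path: str | Path,
              names: Iterable[str] | None = None,
              extra: Iterable[str] | None = None) -> None:
    """Write BED6 (+1 optional extra column, e.g. a repeat family)."""
    names = list(names) if names is not None else None
    extra = list(extra) if extra is not None else None
    with _open_text(path, "wt") as fh:
        fh.write(f"# {DIALECT_VERSION} bed\n")
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            cols = [iv.chrom, str(iv.start), str(iv.end), name, "0", iv.strand]
            if extra is not None:
                cols.append(extra[i])
            fh.write("\t".join(cols) + "\n")


def write_promoter_bed(promoters: Iterable[PromoterRecord], bed_path: str | Path,
                       annotation_path: str | Path | None = None) -> None:
    promoters = list(promoters)
    write_bed([p.interval for p in promoters], bed_path,
              names=[p.promoter_id for p in promoters])
    if annotation_path is not None:
        with _open_text(annotation_path, "wt") as fh:
            fh.write(f"# {DIALECT_VERSION} promoter-annotation\n")
            fh.write("promoter_id\tclass\tgene_id\n")
            for p in promoters:
                fh.write(f"{p.promoter_id}\t{p.promoter_class}\t{p.gene_id or '.'}\n")


# ---------------------------------------------------------------------------
# Alignment-status dialect


def read_alignment_status(path: str | Path) -> list[AlignmentStatus]:
    """Read the 9-column alignment-status dialect; duplicates rejected."""
    out: list[AlignmentStatus] = []
    seen: set[tuple[str, str, str]] = set()
    with _open_text(path) as fh:
        header: list[str] | None = None
        for lineno, line in _data_lines(fh):
            fields = line.split("\t")
            if header is None:
                header = fields
                if header != ALIGNMENT_STATUS_COLUMNS:
                    raise ParseError(
                        f"{path}:{lineno}: bad alignment-status header {header}"
                    )
                continue
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns")
            pid, target, source, status = fields[:4]
            key = (pid, target, source)
            if key in seen:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate (promoter, target, source) {key}"
                )
            seen.add(key)
            interval = None
            if fields[4] != ".":
                interval = GenomeInterval(
                    fields[4], int(fields[5]), int(fields[6]), fields[7]
                )
            try:
                out.append(
                    AlignmentStatus(
                        promoter_id=pid,
                        target_species=target,
                        source=source,
                        status=status,
                        target_interval=interval,
                        aligned_fraction=float(fields[8]),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
        if header is None:
            raise ParseError(f"{path}: empty alignment-status file (header required)")
    return out


def write_alignment_status(rows: Iterable[AlignmentStatus], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(f"# {DIALECT_VERSION} alignment-status\n")
        fh.write("\t".join(ALIGNMENT_STATUS_COLUMNS) + "\n")
        for r in rows:
            if r.target_interval is None:
                coords = [".", ".", ".", "."]
            else:
                iv = r.target_interval
                coords = [iv.chrom, str(iv.start), str(iv.end), iv.strand]
            fh.write(
                "\t".join(
                    [r.promoter_id, r.target_species, r.source, r.status]
                    + coords
                    + [f"{r.aligned_fraction:.6g}"]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Expression matrix + sample sheet


def read_expression(matrix_path: str | Path, sheet_path: str | Path) -> tuple[pd.DataFrame, SampleSheet]:
    """Read a TPM matrix (promoters x samples) with its sample sheet."""
    matrix = pd.read_csv(matrix_path, sep="\t", comment="#", index_col=0)
    sheet = SampleSheet(pd.read_csv(sheet_path, sep="\t", comment="#", dtype=str))
    unmatched = [c for c in matrix.columns if c not in set(sheet.sample_ids)]
    if unmatched:
        raise ValidationError(f"matrix columns absent from sample sheet: {unmatched}")
    if matrix.isna().any().any():
        raise ValidationError("expression matrix contains NaN cells")
    if (matrix.to_numpy() < 0).any():
        raise ValidationError("expression matrix contains negative TPM values")
    return matrix, sheet


def write_expression(matrix: pd.DataFrame, sheet: SampleSheet,
                     matrix_path: str | Path, sheet_path: str | Path) -> None:
    with _open_text(matrix_path, "wt") as fh:
        fh.write(f"# {DIALECT_VERSION} expression-matrix\n")
        matrix.to_csv(fh, sep="\t", float_format="%.6g")
    with _open_text(sheet_path, "wt") as fh:
        fh.write(f"# {DIALECT_VERSION} sample-sheet\n")
        sheet.table.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variants


def _variant_from_fields(chrom: str, pos0: int, ref: str, alt: str,
                         aa: str, af: float, drops: DropCounter) -> VariantRecord | None:
    if "," in alt:
        drops.multiallelic += 1
        return None
    if len(ref) != 1 or len(alt) != 1:
        drops.non_snp += 1
        return None
    aa = aa.upper() if aa not in (".", "", "N") else "."
    return VariantRecord(chrom, pos0, ref.upper(), alt.upper(), aa, af)


def read_variants(path: str | Path) -> tuple[list[VariantRecord], DropCounter]:
    """Read variants from the TSV dialect or a minimal VCF (AA/AF INFO keys).

    Indels and multi-allelic records are dropped (counted); unresolved
    ancestral states are retained and flagged — downstream polarization
    discards them.
    """
    path = Path(path)
    drops = DropCounter()
    out: list[VariantRecord] = []
    is_vcf = ".vcf" in path.suffixes or path.suffix == ".vcf"
    with _open_text(path) as fh:
        if is_vcf:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 8:
                    raise ParseError(f"{path}:{lineno}: short VCF record")
                info = dict(
                    kv.split("=", 1) if "=" in kv else (kv, "")
                    for kv in fields[7].split(";")
                )
                af = float(info.get("AF", "nan"))
                if not np.isfinite(af):
                    raise ParseError(f"{path}:{lineno}: missing AF INFO field")
                rec = _variant_from_fields(
                    fields[0], int(fields[1]) - 1, fields[3], fields[4],
                    info.get("AA", "."), af, drops,
                )
                if rec is not None:
                    out.append(rec)
        else:
            header: list[str] | None = None
            for lineno, line in _data_lines(fh):
                fields = line.split("\t")
                if header is None:
                    header = fields
                    expected = ["chrom", "pos", "ref", "alt", "ancestral", "alt_freq"]
                    if header != expected:
                        raise ParseError(
                            f"{path}:{lineno}: bad variant header {header}"
                        )
                    continue
                rec = _variant_from_fields(
                    fields[0], int(fields[1]), fields[2], fields[3],
                    fields[4], float(fields[5]), drops,
                )
                if rec is not None:
                    out.append(rec)
    return out, drops


def write_variants(variants: Iterable[VariantRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(f"# {DIALECT_VERSION} variants\n")
        fh.write("chrom\tpos\tref\talt\tancestral\talt_freq\n")
        for v in variants:
            fh.write(
                f"{v.chrom}\t{v.position}\t{v.ref_allele}\t{v.alt_allele}"
                f"\t{v.ancestral_allele}\t{v.alt_frequency:.8g}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph score track


def read_bedgraph(path: str | Path) -> dict[str, list[tuple[int, int, float]]]:
    """Read a bedGraph into per-chromosome (start, end, score) runs."""
    out: dict[str, list[tuple[int, int, float]]] = {}
    with _open_text(path) as fh:
        for lineno, line in _data_lines(fh):
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
            start, end = int(fields[1]), int(fields[2])
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: empty bedGraph run")
            out.setdefault(fields[0], []).append((start, end, float(fields[3])))
    return out


def write_bedgraph(runs: dict[str, list[tuple[int, int, float]]], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(f"# {DIALECT_VERSION} bedgraph\n")
        for chrom in sorted(runs):
            for start, end, score in runs[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\t{score:.6g}\n")


def track_from_runs(runs: dict[str, list[tuple[int, int, float]]],
                    chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Expand bedGraph runs into dense per-base arrays (NaN where uncovered)."""
    track = {c: np.full(n, np.nan) for c, n in chrom_lengths.items()}
    for chrom, segs in runs.items():
        if chrom not in track:
            continue
        arr = track[chrom]
        for start, end, score in segs:
            arr[start:min(end, len(arr))] = score
    return track
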