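"""Readers and writers for the standard formats the pipeline touches.

All genomic intervals are held internally as 0-based half-open coordinates.
Formats that use 1-based inclusive coordinates (GFF3, VCF) are converted at
the boundary on read and converted back on write, so downstream modules never
deal with more than one convention.

Strand-aware coverage is stored as separate forward and reverse
:class:`CoverageTrack` objects, matching stranded sequencing libraries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


@dataclass
class CoverageTrack:
    """Per-nucleotide coverage over one strand of one replicon.

    ``values[i]`` is the depth at 0-based genomic position ``origin + i``.
    """

    replicon_id: str
    strand: str
    values: np.ndarray
    origin: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("coverage values must be a non-empty 1-D array")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")

    def __len__(self) -> int:
        return self.values.size

    @property
    def end(self) -> int:
        """One past the last covered position (0-based half-open)."""
        return self.origin + self.values.size


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene; ``start``/``end`` are 0-based half-open."""

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    kind: str = "coding"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")


@dataclass(frozen=True)
class SvRecord:
    """One structural-variant call as read from a VCF.

    ``pos`` keeps the VCF's 1-based convention so records can be traced back
    to the source file; mobilome clustering works on relative distances and
    is unaffected by the offset.
    """

    replicon_id: str
    pos: int
    sv_class: str  # insertion | excision | other
    sequence: str
    library_id: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF position must be >= 1, got {self.pos}")
        if self.sv_class in ("insertion", "excision") and not self.sequence:
            raise ValueError(f"{self.sv_class} record at {self.pos} lacks a sequence")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path, strand: str = "+") -> CoverageTrack:
    """Read a bedGraph file into a per-nucleotide :class:`CoverageTrack`.

    bedGraph intervals are 0-based half-open; positions not listed in the
    file are filled with 0. Overlapping intervals and negative values are
    rejected. The file must describe a single replicon.
    """
    intervals: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative coverage value {value}")
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            intervals.append((chrom, start, end, value))
    if not intervals:
        raise ValueError(f"{path}: no intervals")
    replicons = {chrom for chrom, *_ in intervals}
    if len(replicons) > 1:
        raise ValueError(f"{path}: multiple replicons in one bedGraph: {sorted(replicons)}")
    intervals.sort(key=lambda iv: iv[1])
    for (_, _, prev_end, _), (_, start, _, _) in zip(intervals, intervals[1:]):
        if start < prev_end:
            raise ValueError(f"{path}: overlapping intervals at position {start}")
    origin = intervals[0][1]
    span = intervals[-1][2] - origin
    values = np.zeros(span, dtype=float)
    for _, start, end, value in intervals:
        values[start - origin : end - origin] = value
    return CoverageTrack(replicon_id=replicons.pop(), strand=strand, values=values, origin=origin)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a coverage track as run-length-encoded bedGraph intervals.

    Zero runs are omitted, matching the read-side gap-fill convention.
    """
    values = track.values
    with open(path, "w") as fh:
        run_start = 0
        for i in range(1, len(values) + 1):
            if i == len(values) or values[i] != values[run_start]:
                v = values[run_start]
                if v != 0:
                    fh.write(
                        f"{track.replicon_id}\t{track.origin + run_start}\t"
                        f"{track.origin + i}\t{v:g}\n"
                    )
                run_start = i


# ---------------------------------------------------------------------------
# VCF structural variants
# ---------------------------------------------------------------------------

_SVTYPE_TO_CLASS = {"INS": "insertion", "DEL": "excision"}


def read_vcf_sv(path: str | Path, library_id: str) -> list[SvRecord]:
    """Read structural-variant records from a VCF file.

    SVTYPE=INS becomes ``insertion`` and SVTYPE=DEL becomes ``excision``
    (a deletion relative to the reference removes an IS copy present there);
    any other SVTYPE is kept with class ``other`` and dropped downstream.
    Records without an SVTYPE tag are skipped with a warning.
    """
    records: list[SvRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            if svtype is None:
                logger.warning("%s: record at %s:%d has no SVTYPE; skipped", path, rec.chrom, rec.pos)
                continue
            if isinstance(svtype, tuple):
                svtype = svtype[0]
            sv_class = _SVTYPE_TO_CLASS.get(str(svtype), "other")
            if sv_class == "insertion":
                alt = rec.alts[0] if rec.alts else ""
                ref = rec.ref or ""
                # strip the shared VCF anchor base where the padded
                # REF/ALT convention is used
                seq = alt[len(ref):] if len(ref) == 1 and alt.startswith(ref) else alt
            elif sv_class == "excision":
                # deleted sequence is carried by the REF allele
                ref = rec.ref or ""
                alt = rec.alts[0] if rec.alts else ""
                seq = ref[len(alt):] if len(alt) == 1 and ref.startswith(alt) else ref
            else:
                seq = ""
            records.append(
                SvRecord(
                    replicon_id=rec.chrom,
                    pos=rec.pos,
                    sv_class=sv_class,
                    sequence=str(seq).upper(),
                    library_id=library_id,
                )
            )
    return records


def write_vcf_sv(records: Sequence[SvRecord], path: str | Path, contigs: dict[str, int] | None = None) -> None:
    """Write SV records as a minimal VCF 4.2 file with SVTYPE INFO tags."""
    if contigs is None:
        contigs = {}
        for rec in records:
            need = rec.pos + len(rec.sequence) + 1
            contigs[rec.replicon_id] = max(contigs.get(rec.replicon_id, 0), need)
    class_to_svtype = {"insertion": "INS", "excision": "DEL"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">\n')
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, rec in enumerate(sorted(records, key=lambda r: (r.replicon_id, r.pos))):
            svtype = class_to_svtype.get(rec.sv_class, "BND")
            if rec.sv_class == "insertion":
                ref, alt, svlen = "N", "N" + rec.sequence, len(rec.sequence)
            elif rec.sv_class == "excision":
                ref, alt, svlen = "N" + rec.sequence, "N", -len(rec.sequence)
            else:
                ref, alt, svlen = "N", "<SV>", 0
            fh.write(
                f"{rec.replicon_id}\t{rec.pos}\tsv{i}\t{ref}\t{alt}\t.\tPASS\t"
                f"SVTYPE={svtype};SVLEN={svlen}\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, sequence)`` pairs; duplicate ids error."""
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        out.append((rec.id, str(rec.seq).upper()))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(regions: Iterable, path: str | Path) -> None:
    """Write regions as BED6. Accepts any objects with ``replicon_id``,
    ``start``, ``end`` and ``strand`` attributes; a ``name`` or score is
    synthesized where absent."""
    with open(path, "w") as fh:
        for i, region in enumerate(regions):
            name = getattr(region, "gene_id", None) or getattr(region, "name", None) or f"region{i}"
            score = getattr(region, "min_lfc_in_region", 0.0)
            fh.write(
                f"{region.replicon_id}\t{region.start}\t{region.end}\t"
                f"{name}\t{score:g}\t{region.strand}\n"
            )


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, float, str]]:
    """Read a BED file back into (replicon, start, end, name, score, strand)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"region{lineno}"
            score = float(parts[4]) if len(parts) > 4 else 0.0
            strand = parts[5] if len(parts) > 5 else "+"
            rows.append((chrom, start, end, name, score, strand))
    return rows


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_CODING_TYPES = {"CDS", "gene", "mRNA"}


def read_gff3(path: str | Path, feature_types: set[str] | None = None) -> list[GeneRecord]:
    """Read gene features from a GFF3 file.

    GFF3 coordinates are 1-based inclusive; they are converted to the
    internal 0-based half-open convention (start-1, end). The gene id is
    taken from the ``locus_tag``, ``ID`` or ``Name`` attribute, in that
    order of preference.
    """
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = parts
            if feature_types is not None and ftype not in feature_types:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in STRANDS:
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            attributes = dict(
                kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
            )
            gene_id = (
                attributes.get("locus_tag")
                or attributes.get("ID")
                or attributes.get("Name")
            )
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: feature has no locus_tag/ID/Name")
            kind = "coding" if ftype in _CODING_TYPES else "noncoding"
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    replicon_id=seqid,
                    start=start_i - 1,
                    end=end_i,
                    strand=strand,
                    kind=kind,
                )
            )
    return genes


def write_gff3(genes: Sequence[GeneRecord], path: str | Path, source: str = "haloatlas") -> None:
    """Write gene records back to GFF3, restoring 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            ftype = "gene" if g.kind == "coding" else "ncRNA"
            fh.write(
                f"{g.replicon_id}\t{source}\t{ftype}\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id};locus_tag={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_table(path: str | Path, schema: dict[str, type] | None = None, index_col=0) -> pd.DataFrame:
    """Read a TSV table with a header row; optionally enforce a column schema."""
    df = pd.read_csv(path, sep="\t", index_col=index_col)
    if schema is not None:
        missing = set(schema) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
        for col, dtype in schema.items():
            df[col] = df[col].astype(dtype)
    return df


def write_table(df: pd.DataFrame, path: str | Path, index_label: str | None = "gene_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)
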