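"""Genomic file I/O and the shared coordinate-carrying types.

All internal coordinates are 0-based half-open ([start, end)), the BED
convention. GFF3 input (1-based closed) is converted on read. Chromosome
names are matched by exact string equality throughout the package; a rename
map can be applied at read time for inputs that use a different naming
scheme.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import pandas as pd

logger = logging.getLogger(__name__)

#: Condition labels used across the pipeline.
LOW_CU = "low_cu"
CONTROL_CU = "control_cu"
CONDITIONS = (LOW_CU, CONTROL_CU)

#: Genotype labels: the epitope-tagged line whose ChIP enriches the factor,
#: and the untagged line used as the mock / negative control.
TAGGED = "tagged"
UNTAGGED_CONTROL = "untagged_control"


class ParseError(ValueError):
    """Malformed record in an input file; carries file and line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic segment in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        """Mid-point of the segment; half-integer for odd lengths."""
        return (self.start + self.end) / 2

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Bases shared with ``other``; 0 when on different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_length(other) > 0

    def contains_point(self, chrom: str, pos: float) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True)
class Peak:
    """One peak call from one replicate of one (condition, genotype)."""

    interval: GenomicInterval
    replicate_id: str
    condition: str
    genotype: str
    score: Optional[float] = None
    summit_offset: Optional[int] = None
    name: Optional[str] = None

    def __post_init__(self):
        if self.score is not None and self.score < 0:
            raise ValueError(f"peak score must be >= 0, got {self.score}")

    @property
    def peak_id(self) -> str:
        iv = self.interval
        return f"{self.replicate_id}:{iv.chrom}:{iv.start}-{iv.end}"


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene; TSS/TTS derive from the strand.

    TSS is the first transcribed base: ``start`` on the + strand,
    ``end - 1`` on the - strand (both 0-based genomic positions).
    """

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be + or -, "
                f"got {self.interval.strand!r}"
            )

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def tts(self) -> int:
        iv = self.interval
        return iv.end - 1 if iv.strand == "+" else iv.start

    @property
    def length(self) -> int:
        return self.interval.length

    def oriented_offset(self, pos: float) -> float:
        """Signed distance from the TSS in transcription direction.

        Negative values are upstream of the TSS, positive values
        downstream (into or past the gene body).
        """
        if self.strand == "+":
            return pos - self.tss
        return self.tss - pos


@dataclass(frozen=True)
class DERecord:
    """One gene x contrast row of a differential-expression table.

    ``log2fc`` is oriented so that positive means higher expression in the
    wild type than in the mutant. A missing adjusted p-value stays missing
    (``None``); it is never coerced to 1.
    """

    gene_id: str
    contrast: str
    log2fc: float
    padj: Optional[float] = None
    base_mean: float = 0.0

    def __post_init__(self):
        if self.padj is not None and not (0.0 <= self.padj <= 1.0):
            raise ValueError(
                f"{self.gene_id}/{self.contrast}: padj {self.padj} not in [0,1]"
            )
        if self.base_mean < 0:
            raise ValueError("base_mean must be nonnegative")


def _rename(chrom: str, chrom_map: Optional[Mapping[str, str]]) -> str:
    if chrom_map is None:
        return chrom
    return chrom_map.get(chrom, chrom)


def read_peaks(
    path,
    replicate_id: str,
    condition: str,
    genotype: str,
    chrom_map: Optional[Mapping[str, str]] = None,
) -> list[Peak]:
    """Read peaks from a BED3+/BED6/ENCODE narrowPeak file.

    Coordinates are 0-based half-open as in the file. narrowPeak's 10th
    column, when present and nonnegative, is kept as ``summit_offset``
    (bp from peak start). Records with ``end <= start`` raise a
    :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, f"expected >=3 tab-separated fields, got {len(fields)}")
            chrom = _rename(fields[0], chrom_map)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-integer coordinates: {exc}") from None
            if end <= start:
                raise ParseError(path, lineno, f"end ({end}) must exceed start ({start})")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: Optional[float] = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise ParseError(path, lineno, f"non-numeric score {fields[4]!r}") from None
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            summit: Optional[int] = None
            if len(fields) >= 10:  # narrowPeak: col 10 is summit offset, -1 if absent
                try:
                    cand = int(fields[9])
                except ValueError:
                    cand = -1
                if cand >= 0:
                    summit = cand
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end, strand),
                    replicate_id=replicate_id,
                    condition=condition,
                    genotype=genotype,
                    score=score,
                    summit_offset=summit,
                    name=name,
                )
            )
    if not peaks:
        logger.warning("no peak records in %s", path)
    return peaks


def read_gff3_genes(
    path, chrom_map: Optional[Mapping[str, str]] = None
) -> list[GeneModel]:
    """Read gene records from a GFF3 file into :class:`GeneModel` objects.

    Only rows whose feature type is ``gene`` are consumed; everything else
    (mRNA, exon, CDS, ...) is skipped and the skip count logged. GFF3's
    1-based closed coordinates become 0-based half-open. A gene without an
    ``ID`` attribute, or with strand ``.``, is an error naming the line.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    skipped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(path, lineno, f"expected 9 GFF3 columns, got {len(fields)}")
            if fields[2] != "gene":
                skipped += 1
                continue
            chrom = _rename(fields[0], chrom_map)
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-integer coordinates: {exc}") from None
            strand = fields[6]
            if strand not in ("+", "-"):
                raise ParseError(path, lineno, f"gene strand must be + or -, got {strand!r}")
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            if "ID" not in attrs or not attrs["ID"]:
                raise ParseError(path, lineno, "gene record lacks an ID attribute")
            genes.append(
                GeneModel(
                    gene_id=attrs["ID"],
                    interval=GenomicInterval(chrom, start1 - 1, end1, strand),
                )
            )
    logger.info("read %d genes from %s (%d non-gene rows skipped)", len(genes), path, skipped)
    return genes


def read_de_table(
    path,
    gene_col: str = "gene_id",
    contrast_col: str = "contrast",
    log2fc_col: str = "log2fc",
    padj_col: str = "padj",
    base_mean_col: str = "base_mean",
) -> list[DERecord]:
    """Read a per-gene differential-expression table (TSV with header).

    One row per (gene, contrast); duplicates are an error. Missing padj
    values (``NA``, empty) are preserved as missing.
    """
    df = pd.read_csv(path, sep="\t")
    required = [gene_col, contrast_col, log2fc_col, padj_col]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    dup = df.duplicated(subset=[gene_col, contrast_col])
    if dup.any():
        first = df.loc[dup, [gene_col, contrast_col]].iloc[0]
        raise ValueError(
            f"{path}: duplicate (gene, contrast) row, e.g. "
            f"({first[gene_col]}, {first[contrast_col]})"
        )
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        padj = d[padj_col]
        padj = None if padj is None or (isinstance(padj, float) and math.isnan(padj)) else float(padj)
        base_mean = float(d.get(base_mean_col, 0.0)) if base_mean_col in df.columns else 0.0
        records.append(
            DERecord(
                gene_id=str(d[gene_col]),
                contrast=str(d[contrast_col]),
                log2fc=float(d[log2fc_col]),
                padj=padj,
                base_mean=base_mean,
            )
        )
    return records


def write_bed(records: Iterable, path) -> None:
    """Write interval-bearing records as sorted BED6.

    Accepts bare :class:`GenomicInterval` objects or anything exposing an
    ``interval`` attribute; ``name``/``score``/``support`` attributes feed
    the BED name and score columns when present. Output is sorted by
    (chrom, start, end) and round-trips through :func:`read_peaks`
    losslessly for the interval fields.
    """

    def _key(rec):
        iv = getattr(rec, "interval", rec)
        return (iv.chrom, iv.start, iv.end)

    with open(path, "w") as fh:
        for rec in sorted(records, key=_key):
            iv = getattr(rec, "interval", rec)
            name = getattr(rec, "name", None) or getattr(rec, "peak_id", None) or "."
            score = getattr(rec, "score", None)
            if score is None:
                score = getattr(rec, "support", 0)
            score = 0 if score is None else score
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )
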