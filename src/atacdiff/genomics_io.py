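"""Domain types and readers/writers for the standard genomic text formats.

Coordinates are 0-based half-open everywhere (BED native). Any 1-based
dialect must be converted at the boundary before objects are built; nothing
downstream re-interprets coordinates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """A file line could not be parsed; message names the line number."""


class ValidationError(ValueError):
    """Parsed values violate a domain invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Chromosome-anchored half-open span [start, end); the universal region currency."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """A called region of enriched cleavage with its maximum-signal base (summit)."""

    interval: GenomicInterval
    summit: int
    score: float
    qvalue: float  # -log10 scale

    def __post_init__(self):
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValidationError(
                f"summit {self.summit} outside {self.interval.chrom}:"
                f"{self.interval.start}-{self.interval.end}"
            )
        if self.score < 0:
            raise ValidationError("score must be >= 0")


@dataclass
class CleavageTrack:
    """Per-sample multiset of single-base Tn5 cleavage positions.

    Positions are stored per chromosome as sorted int64 arrays (with
    multiplicity), which makes window counting a pair of searchsorted calls.
    """

    sample_id: str
    positions: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for chrom, pos in self.positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.size and arr.min() < 0:
                raise ValidationError(
                    f"negative cleavage position on {chrom} in {self.sample_id}"
                )
            clean[chrom] = np.sort(arr)
        self.positions = clean

    @property
    def library_size(self) -> int:
        return int(sum(arr.size for arr in self.positions.values()))

    @property
    def chroms(self) -> List[str]:
        return sorted(self.positions)

    def events(self) -> Iterator[Tuple[str, int]]:
        for chrom in self.chroms:
            for pos in self.positions[chrom]:
                yield chrom, int(pos)

    @classmethod
    def from_events(cls, sample_id: str, events: Iterable[Tuple[str, int]]) -> "CleavageTrack":
        by_chrom: Dict[str, list] = {}
        for chrom, pos in events:
            by_chrom.setdefault(chrom, []).append(pos)
        return cls(sample_id, {c: np.asarray(p) for c, p in by_chrom.items()})

    def count_in(self, interval: GenomicInterval) -> int:
        arr = self.positions.get(interval.chrom)
        if arr is None:
            return 0
        lo = np.searchsorted(arr, interval.start, side="left")
        hi = np.searchsorted(arr, interval.end, side="left")
        return int(hi - lo)


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its TSS and transcript span; optional exon sub-intervals."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    span: GenomicInterval
    exons: Tuple[GenomicInterval, ...] = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if not self.span.contains(self.chrom, self.tss):
            raise ValidationError(f"gene {self.gene_id}: TSS outside span")


@dataclass
class ExpressionTable:
    """Genes x samples expression values with an explicit unit label.

    Backed by a pandas DataFrame (genes as index, samples as columns);
    duplicate gene or sample labels are rejected.
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self):
        if not self.unit:
            raise ValidationError("expression unit must be declared")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")

    @property
    def genes(self) -> List[str]:
        return list(self.values.index)

    @property
    def samples(self) -> List[str]:
        return list(self.values.columns)

    def value(self, gene: str, sample: str) -> float:
        return float(self.values.at[gene, sample])


# ---------------------------------------------------------------------------
# BED


def _data_lines(path: str) -> Iterator[Tuple[int, List[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_bed(path: str) -> List[GenomicInterval]:
    """Read BED3/BED6 into intervals, preserving input order."""
    out = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
        try:
            out.append(GenomicInterval(fields[0], start, end, strand))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str,
              names: Optional[Sequence[str]] = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is not None or iv.strand != ".":
                name = names[i] if names is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# narrowPeak (ENCODE 10-column)


def read_narrowpeak(path: str) -> List[Peak]:
    """Read an ENCODE narrowPeak file.

    Column 10 is the summit offset from start; an offset of -1 (caller did
    not report a summit) falls back to the interval midpoint.
    """
    peaks = []
    for lineno, fields in _data_lines(path):
        if len(fields) != 10:
            raise ParseError(
                f"{path}:{lineno}: narrowPeak requires 10 columns, got {len(fields)}"
            )
        try:
            start, end = int(fields[1]), int(fields[2])
            score = float(fields[6])
            qvalue = float(fields[8])
            offset = int(fields[9])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: malformed numeric field") from exc
        strand = fields[5] if fields[5] in STRANDS else "."
        iv = GenomicInterval(fields[0], start, end, strand)
        summit = iv.midpoint if offset == -1 else start + offset
        try:
            peaks.append(Peak(iv, summit, score, qvalue))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_narrowpeak(peaks: Sequence[Peak], path: str) -> None:
    with open(path, "w") as fh:
        for i, pk in enumerate(peaks):
            iv = pk.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i + 1}\t"
                f"{min(1000, int(round(pk.score * 10)))}\t{iv.strand}\t"
                f"{pk.score:.5f}\t-1\t{pk.qvalue:.5f}\t{pk.summit - iv.start}\n"
            )


# ---------------------------------------------------------------------------
# Cleavage events


def read_cleavage_bed(path: str, sample_id: str,
                      apply_tn5_shift: bool = False) -> CleavageTrack:
    """Read per-sample Tn5 cleavage events from BED.

    Single-base rows (end == start + 1) yield one event at start. Fragment
    rows yield two events, one per fragment end (start and end - 1). The
    ATAC +4/-5 Tn5 shift is assumed already applied upstream; pass
    ``apply_tn5_shift=True`` only for raw fragment coordinates, in which case
    the forward end is shifted +4 and the reverse end -5.
    """
    by_chrom: Dict[str, list] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        if start < 0 or end <= start:
            raise ValidationError(f"{path}:{lineno}: invalid interval [{start},{end})")
        chrom = fields[0]
        dest = by_chrom.setdefault(chrom, [])
        if end == start + 1:
            dest.append(start)
        else:
            left, right = start, end - 1
            if apply_tn5_shift:
                left, right = start + 4, end - 1 - 5
            if right < left:  # degenerate after shifting a tiny fragment
                right = left
            dest.extend((left, right))
    return CleavageTrack(sample_id, {c: np.asarray(p) for c, p in by_chrom.items()})


def write_cleavage_bed(track: CleavageTrack, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            for pos in track.positions[chrom]:
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")


# ---------------------------------------------------------------------------
# Gene and expression tables (TSV with header)


GENE_COLUMNS = ["gene_id", "chrom", "strand", "start", "end"]


def read_gene_table(path: str) -> List[GeneRecord]:
    """Read a gene TSV (gene_id, chrom, strand, start, end[, exon_starts, exon_sizes]).

    TSS is derived from the strand: span.start on +, span.end - 1 on -.
    Optional BED12-style exon block columns are comma-separated offsets/sizes
    relative to span.start.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValidationError(f"{path}: duplicate gene_id {dups[:5]}")
    genes = []
    has_exons = "exon_starts" in df.columns and "exon_sizes" in df.columns
    for row in df.itertuples(index=False):
        if row.strand not in ("+", "-"):
            raise ValidationError(f"{path}: gene {row.gene_id}: unknown strand {row.strand!r}")
        span = GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)
        tss = span.start if row.strand == "+" else span.end - 1
        exons: Tuple[GenomicInterval, ...] = ()
        if has_exons and isinstance(row.exon_starts, str) and row.exon_starts:
            starts = [int(x) for x in row.exon_starts.rstrip(",").split(",")]
            sizes = [int(x) for x in row.exon_sizes.rstrip(",").split(",")]
            exons = tuple(
                GenomicInterval(row.chrom, span.start + s, span.start + s + w, row.strand)
                for s, w in zip(starts, sizes)
            )
        genes.append(GeneRecord(str(row.gene_id), row.chrom, row.strand, tss, span, exons))
    return genes


def write_gene_table(genes: Sequence[GeneRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_COLUMNS) + "\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.span.start}\t{g.span.end}\n")


def read_expression_table(path: str, unit: str) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionTable(df, unit)


def write_expression_table(table: ExpressionTable, path: str) -> None:
    table.values.to_csv(path, sep="\t", index_label="gene_id",
                        float_format="%.6g", lineterminator="\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str) -> Dict[str, str]:
    """Load a (small) FASTA into an in-memory chrom -> uppercase sequence map."""
    from pyfaidx import Fasta

    with Fasta(path, rebuild=True, build_index=not os.path.exists(path + ".fai")) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(genome: Dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def chrom_sizes(genome: Dict[str, str]) -> Dict[str, int]:
    return {c: len(s) for c, s in genome.items()}
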