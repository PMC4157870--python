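"""Domain types and readers/writers for the standard formats the pipeline touches.

Coordinates are 0-based half-open (BED convention) throughout. ChIP-seq peaks
are unstranded (strand ``.``); gene models carry ``+``/``-`` and derive their
TSS from the span boundary consistent with strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

PEAK_DIALECTS = ("bed3", "bed6", "narrowPeak")


class ParseError(ValueError):
    """A line in an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span [start, end) on ``chrom``; 0-based."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"strand must be one of + - ., got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Edge-to-edge gap in bp; 0 when the intervals overlap or abut."""
        if self.chrom != other.chrom:
            raise ValidationError("gap undefined across chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass
class PeakSet:
    """A set of ChIP-seq peak intervals from one factor/cell line/replicate."""

    intervals: list[GenomicInterval]
    factor: str
    cell_line: str | None = None
    replicate_id: str | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def sorted(self) -> "PeakSet":
        return replace(self, intervals=sorted(self.intervals))


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    tss: int
    strand: str
    span: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"gene strand must be + or -, got {self.strand!r}")
        expected = self.span.start if self.strand == "+" else self.span.end - 1
        if self.tss != expected:
            raise ValidationError(
                f"tss {self.tss} inconsistent with {self.strand} strand span "
                f"[{self.span.start}, {self.span.end})"
            )


@dataclass(frozen=True)
class PWM:
    """Position frequency model over A/C/G/T, rows 0..L-1 summing to 1."""

    name: str
    freqs: np.ndarray  # shape (L, 4), rows sum to 1
    pseudo: float = 0.0

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", f)
        if f.ndim != 2 or f.shape[1] != 4 or f.shape[0] < 1:
            raise ValidationError(f"freqs must be (L, 4) with L >= 1, got {f.shape}")
        if (f < 0).any():
            raise ValidationError("frequencies must be non-negative")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("each position's frequencies must sum to 1")
        if self.pseudo < 0:
            raise ValidationError("pseudocount must be non-negative")

    def __len__(self) -> int:
        return self.freqs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freqs.argmax(axis=1))


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP record; ``maf`` is None when unknown."""

    rsid: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValidationError(
                f"{self.rsid}: minor-allele frequency must lie in [0, 0.5], "
                f"got {self.maf}"
            )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_peaks(
    path: str | Path,
    dialect: str = "bed3",
    factor: str = "",
    cell_line: str | None = None,
    replicate_id: str | None = None,
) -> PeakSet:
    """Read a BED3/BED6/narrowPeak peak file into a :class:`PeakSet`.

    Comment/track lines are skipped; input order is preserved. Columns beyond
    chrom/start/end (and strand for bed6/narrowPeak) are ignored.
    """
    if dialect not in PEAK_DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; use one of {PEAK_DIALECTS}")
    min_cols = {"bed3": 3, "bed6": 6, "narrowPeak": 10}[dialect]
    intervals: list[GenomicInterval] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < min_cols:
            raise ParseError(
                f"{path}:{lineno}: expected >= {min_cols} tab-separated fields "
                f"for {dialect}, got {len(fields)}"
            )
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        strand = "."
        if dialect in ("bed6", "narrowPeak") and len(fields) > 5 and fields[5] in "+-":
            strand = fields[5]
        try:
            intervals.append(GenomicInterval(fields[0], start, end, strand))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(intervals, factor=factor, cell_line=cell_line, replicate_id=replicate_id)


def write_peaks(peaks: PeakSet, path: str | Path, name_prefix: str = "peak") -> None:
    """Write a PeakSet as BED6 (score 0; strand as stored)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(peaks.intervals):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name_prefix}{i}\t0\t{iv.strand}\n"
            )


def read_gene_annotation(path: str | Path) -> list[GeneModel]:
    """Read a TSV of gene_id, chrom, start, end, strand into gene models.

    The TSS is derived from the strand: span start for ``+``, span end - 1 for
    ``-``. Duplicate gene ids are kept with a warning.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for lineno, fields in _data_lines(path):
        if fields[0] == "gene_id":  # header
            continue
        if len(fields) < 5:
            raise ParseError(f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
        gene_id, chrom, strand = fields[0], fields[1], fields[4]
        if strand not in {"+", "-"}:
            raise ValidationError(f"{path}:{lineno}: unknown strand {strand!r}")
        span = GenomicInterval(chrom, int(fields[2]), int(fields[3]), strand)
        tss = span.start if strand == "+" else span.end - 1
        if gene_id in seen:
            log.warning("duplicate gene_id %s at %s:%d; keeping both", gene_id, path, lineno)
        seen.add(gene_id)
        genes.append(GeneModel(gene_id, chrom, tss, strand, span))
    return genes


def read_pwm_transfac(path: str | Path, pseudo: float = 0.0) -> list[PWM]:
    """Parse TRANSFAC-format matrix blocks into frequency PWMs.

    Each per-position count row gets ``pseudo`` added to every cell before
    normalization, so zero counts can be regularized away when scanning.
    """
    if pseudo < 0:
        raise ValidationError("pseudocount must be non-negative")
    pwms: list[PWM] = []
    name: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal name, rows
        if name is not None and rows:
            counts = np.asarray(rows, dtype=float) + pseudo
            totals = counts.sum(axis=1)
            if (totals <= 0).any():
                bad = int(np.flatnonzero(totals <= 0)[0]) + 1
                raise ValidationError(
                    f"matrix {name}: position {bad} has non-positive total count"
                )
            pwms.append(PWM(name, counts / totals[:, None], pseudo=pseudo))
        name, rows = None, []

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            tag = line.split(maxsplit=1)[0]
            if tag == "//":
                flush()
            elif tag in ("ID", "NA"):
                # prefer ID; NA only if no ID seen for this block
                if tag == "ID" or name is None:
                    name = line.split(maxsplit=1)[1].strip()
            elif tag in ("P0", "PO", "AC", "XX", "BF", "DE", "CC"):
                continue
            elif tag[:2].isdigit() or tag.isdigit():
                parts = line.split()
                rows.append([float(x) for x in parts[1:5]])
    flush()
    return pwms


def write_pwm_transfac(pwms: Sequence[PWM], path: str | Path, scale: int = 100) -> None:
    """Write PWMs as TRANSFAC count blocks (frequencies scaled to integers)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f"ID {pwm.name}\nP0\tA\tC\tG\tT\n")
            for i, row in enumerate(pwm.freqs, start=1):
                counts = "\t".join(str(int(round(x * scale))) for x in row)
                fh.write(f"{i:02d}\t{counts}\n")
            fh.write("//\n")


def read_snp_table(path: str | Path, one_based: bool = False) -> list[Variant]:
    """Read a dbSNP-style TSV: rsid, chrom, pos, ref, alt, maf (maf optional).

    Unknown MAFs are kept and flagged as None. Duplicate rsids are an error.
    """
    variants: list[Variant] = []
    seen: dict[str, int] = {}
    dups: list[str] = []
    for lineno, fields in _data_lines(path):
        if fields[0] == "rsid":
            continue
        if len(fields) < 5:
            raise ParseError(f"{path}:{lineno}: expected >= 5 fields, got {len(fields)}")
        rsid = fields[0]
        maf: float | None = None
        if len(fields) >= 6 and fields[5] not in ("", "NA", "."):
            maf = float(fields[5])
        pos = int(fields[2]) - (1 if one_based else 0)
        try:
            v = Variant(rsid, fields[1], pos, fields[3], fields[4], maf)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
        if rsid in seen:
            dups.append(rsid)
        seen[rsid] = lineno
        variants.append(v)
    if dups:
        raise ValidationError(f"{path}: duplicate rsids: {sorted(set(dups))}")
    return variants


def write_snp_table(variants: Sequence[Variant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rsid\tchrom\tpos\tref\talt\tmaf\n")
        for v in variants:
            maf = "" if v.maf is None else f"{v.maf:g}"
            fh.write(f"{v.rsid}\t{v.chrom}\t{v.pos}\t{v.ref_allele}\t{v.alt_allele}\t{maf}\n")


def load_genome(path: str | Path) -> "GenomeSource":
    """Open a FASTA genome for region extraction (indexed via pyfaidx)."""
    from pyfaidx import Fasta

    return GenomeSource(Fasta(str(path), as_raw=True, sequence_always_upper=True))


class GenomeSource:
    """Thin mapping-style wrapper giving uppercase sequence for an interval."""

    def __init__(self, backend) -> None:
        self._backend = backend

    def fetch(self, interval: GenomicInterval) -> str:
        return str(self._backend[interval.chrom][interval.start : interval.end])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._backend


class DictGenome:
    """In-memory genome (chrom -> sequence string); used by the simulators."""

    def __init__(self, seqs: dict[str, str]) -> None:
        self._seqs = {c: s.upper() for c, s in seqs.items()}

    def fetch(self, interval: GenomicInterval) -> str:
        return self._seqs[interval.chrom][interval.start : interval.end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self._seqs.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
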