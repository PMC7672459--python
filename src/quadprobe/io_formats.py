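"""Readers and writers for the text formats the pipeline touches.

All coordinates everywhere in this package are 0-based, half-open,
BED-style: an interval ``[start, end)`` covers ``end - start`` bases.
Every parser normalizes into that convention; nothing is ever shifted.

Supported formats: multi-record FASTA, BED3/BED6, ENCODE narrowPeak
(10 columns), bedGraph, and two-column ``chrom.sizes`` tables.
bigWig/bigBed are deliberately not required; bedGraph is the coverage
dialect of record here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence, TextIO, Union

import numpy as np

VALID_STRANDS = {"+", "-", "."}
FASTA_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """Malformed input file content."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over {A,C,G,T,N}, uppercase."""

    name: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open stranded genomic interval.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``strand`` is one
    of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise FormatError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise FormatError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise FormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", min_nt: int = 1) -> bool:
        """True when the two spans share at least ``min_nt`` bases (strand ignored)."""
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_nt

    @property
    def midpoint(self) -> int:
        """Integer midpoint, ties toward start."""
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Peak:
    """A called enrichment peak with its caller-reported fold enrichment.

    ``fold_enrichment`` is taken verbatim from narrowPeak column 7 and is
    never recomputed here; ``qvalue`` is the caller's -log10 q-value.
    """

    interval: GenomicInterval
    fold_enrichment: float
    qvalue: Optional[float] = None
    summit_offset: Optional[int] = None
    name: str = "."

    def __post_init__(self) -> None:
        if not np.isfinite(self.fold_enrichment) or self.fold_enrichment < 0:
            raise FormatError(f"non-finite or negative fold enrichment {self.fold_enrichment}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise FormatError(
                f"summit offset {self.summit_offset} outside interval of length "
                f"{len(self.interval)}"
            )


@dataclass(frozen=True)
class GeneModel:
    """A transcript with strand-aware TSS/TES anchors.

    For a ``+`` gene the TSS is ``start`` and the TES is ``end - 1``;
    for a ``-`` gene the two are swapped.
    """

    interval: GenomicInterval
    name: str = "."

    def __post_init__(self) -> None:
        if self.interval.strand not in {"+", "-"}:
            raise FormatError(
                f"gene {self.name} has strand {self.interval.strand!r}; "
                "TSS is undefined without orientation"
            )

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _as_lines(stream: Union[str, TextIO, Iterable[str]]) -> Iterator[str]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    return iter(stream)


def parse_fasta(stream: Union[str, TextIO, Iterable[str]]) -> list[SequenceRecord]:
    """Parse multi-record FASTA into uppercase :class:`SequenceRecord` objects.

    Mixed case is folded to upper; multi-line bodies are concatenated; an
    empty body is allowed. Sequence text before the first header, or any
    character outside {A,C,G,T,N}, raises :class:`FormatError` naming the
    offending position.
    """
    records: list[SequenceRecord] = []
    name: Optional[str] = None
    chunks: list[str] = []

    def flush() -> None:
        if name is None:
            return
        seq = "".join(chunks).upper()
        bad = set(seq) - FASTA_ALPHABET
        if bad:
            pos = min(seq.index(c) for c in bad)
            raise FormatError(
                f"illegal character {seq[pos]!r} at position {pos} in record {name!r}"
            )
        records.append(SequenceRecord(name, seq))

    for lineno, raw in enumerate(_as_lines(stream), start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].split()[0] if line[1:].split() else ""
            if not name:
                raise FormatError(f"empty record name at line {lineno}")
            chunks = []
        else:
            if name is None:
                raise FormatError(f"sequence before first header at line {lineno}")
            chunks.append(line.strip())
    flush()
    return records


def write_fasta(records: Sequence[SequenceRecord], stream: TextIO, width: int = 60) -> None:
    for rec in records:
        stream.write(f">{rec.name}\n")
        for i in range(0, len(rec.sequence), width):
            stream.write(rec.sequence[i : i + width] + "\n")
        if not rec.sequence:
            stream.write("\n")


# ---------------------------------------------------------------------------
# interval files
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("track", "browser", "#")

IntervalLike = Union[GenomicInterval, Peak, GeneModel]


def _data_lines(stream) -> Iterator[tuple[int, list[str]]]:
    for lineno, raw in enumerate(_as_lines(stream), start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.startswith(_SKIP_PREFIXES):
            continue
        yield lineno, line.split("\t")


def parse_interval_file(stream, dialect: str) -> list[IntervalLike]:
    """Parse a BED-family file in one of four dialects.

    ``bed3`` yields unstranded :class:`GenomicInterval`; ``bed6`` takes
    strand from column 6; ``narrowPeak`` yields :class:`Peak` (fold
    enrichment from column 7, -log10 q-value from column 9, summit offset
    from column 10); ``gene_bed`` yields :class:`GeneModel` (BED6 with a
    mandatory oriented strand).
    """
    if dialect not in {"bed3", "bed6", "narrowPeak", "gene_bed"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    out: list[IntervalLike] = []
    for lineno, cols in _data_lines(stream):
        try:
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"line {lineno}: malformed coordinates") from exc
        try:
            if dialect == "bed3":
                out.append(GenomicInterval(chrom, start, end, "."))
            elif dialect == "bed6":
                strand = cols[5] if len(cols) > 5 else "."
                out.append(GenomicInterval(chrom, start, end, strand))
            elif dialect == "gene_bed":
                if len(cols) < 6:
                    raise FormatError(f"line {lineno}: gene records need 6 columns")
                name = cols[3] if len(cols) > 3 else "."
                out.append(GeneModel(GenomicInterval(chrom, start, end, cols[5]), name))
            else:  # narrowPeak
                if len(cols) < 10:
                    raise FormatError(
                        f"line {lineno}: narrowPeak needs 10 columns, got {len(cols)}"
                    )
                strand = cols[5] if cols[5] in VALID_STRANDS else "."
                qval = float(cols[8])
                summit = int(cols[9])
                out.append(
                    Peak(
                        GenomicInterval(chrom, start, end, strand),
                        fold_enrichment=float(cols[6]),
                        qvalue=None if qval < 0 else qval,
                        summit_offset=None if summit < 0 else summit,
                        name=cols[3],
                    )
                )
        except FormatError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
    return out


def parse_chrom_sizes(stream) -> dict[str, int]:
    """Parse a two-column ``chrom<TAB>size`` table."""
    sizes: dict[str, int] = {}
    for lineno, cols in _data_lines(stream):
        if len(cols) < 2:
            raise FormatError(f"line {lineno}: chrom.sizes needs 2 columns")
        try:
            size = int(cols[1])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: bad size {cols[1]!r}") from exc
        if size <= 0:
            raise FormatError(f"line {lineno}: non-positive chromosome size")
        sizes[cols[0]] = size
    return sizes


def write_bed(items: Iterable, stream: TextIO) -> None:
    """Serialize motifs, peaks, genes or plain intervals as BED6 lines.

    PQS motifs get ``name`` = subtype labels joined by ``|`` (sorted) and
    ``score`` = number of G-tracts capped at 1000. Round-trips through
    :func:`parse_interval_file` preserve coordinates, strand and name.
    """
    for item in items:
        if hasattr(item, "subtypes"):  # PqsMotif (duck-typed to avoid an import cycle)
            iv = item.interval
            name = "|".join(sorted(item.subtypes))
            score = min(len(item.tracts), 1000) if item.tracts else 0
        elif isinstance(item, Peak):
            iv = item.interval
            name = item.name
            score = min(int(round(item.fold_enrichment * 10)), 1000)
        elif isinstance(item, GeneModel):
            iv = item.interval
            name = item.name
            score = 0
        else:
            iv = item
            name = getattr(item, "name", ".")
            score = 0
        stream.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def write_narrowpeak(peaks: Iterable[Peak], stream: TextIO) -> None:
    """Serialize peaks as 10-column ENCODE narrowPeak."""
    for p in peaks:
        iv = p.interval
        q = -1.0 if p.qvalue is None else p.qvalue
        summit = -1 if p.summit_offset is None else p.summit_offset
        stream.write(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t0\t{iv.strand}\t"
            f"{p.fold_enrichment:g}\t-1\t{q:g}\t{summit}\n"
        )


# ---------------------------------------------------------------------------
# bedGraph / coverage
# ---------------------------------------------------------------------------


def parse_bedgraph(stream, chrom_sizes: dict[str, int]):
    """Read a bedGraph into a :class:`~quadprobe.signal_profile.CoverageTrack`.

    Unspecified bases are 0. Intervals must be non-overlapping per
    chromosome and lie within the chromosome; violations raise
    :class:`FormatError`.
    """
    from .signal_profile import CoverageTrack  # local import: avoid cycle

    arrays = {c: np.zeros(n, dtype=np.float64) for c, n in chrom_sizes.items()}
    covered = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}
    for lineno, cols in _data_lines(stream):
        if len(cols) < 4:
            raise FormatError(f"line {lineno}: bedGraph needs 4 columns")
        chrom, start, end, value = cols[0], int(cols[1]), int(cols[2]), float(cols[3])
        if chrom not in arrays:
            raise FormatError(f"line {lineno}: unknown chromosome {chrom!r}")
        if start < 0 or start >= end or end > chrom_sizes[chrom]:
            raise FormatError(
                f"line {lineno}: interval [{start},{end}) outside chromosome "
                f"{chrom} of size {chrom_sizes[chrom]}"
            )
        if not np.isfinite(value):
            raise FormatError(f"line {lineno}: non-finite value")
        if covered[chrom][start:end].any():
            raise FormatError(f"line {lineno}: overlapping bedGraph intervals on {chrom}")
        covered[chrom][start:end] = True
        arrays[chrom][start:end] = value
    return CoverageTrack(arrays)


def write_bedgraph(track, stream: TextIO) -> None:
    """Write a coverage track as run-length-merged bedGraph (zero runs skipped)."""
    for chrom in sorted(track.values):
        vals = track.values[chrom]
        if len(vals) == 0:
            continue
        boundaries = np.flatnonzero(np.diff(vals)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(vals)]))
        for s, e in zip(starts, ends):
            v = vals[s]
            if v != 0.0:
                stream.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
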