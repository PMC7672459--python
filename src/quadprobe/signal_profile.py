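"""Coverage-track algebra, metaprofile/heatmap matrices and the shuffle null.

Tracks are per-chromosome base-resolution arrays. Matrices are computed
deeptools-style: one row per anchored region, columns are fixed-width
bins, values are bin means; rows of minus-strand anchors are reversed so
that "downstream" is always rightward. Bases outside the chromosome
contribute 0 (documented choice; masking would change profile tails).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_formats import GeneModel, GenomicInterval


@dataclass
class CoverageTrack:
    """Per-chromosome base-resolution signal.

    ``values`` maps chromosome name to a float array of per-base signal.
    ``total_mapped_reads`` and ``read_length`` are needed only for RPKM
    normalization. ``mode`` records the comparison that produced the
    track ("raw", "subtract" or "ratio").
    """

    values: dict
    total_mapped_reads: Optional[int] = None
    read_length: Optional[int] = None
    mode: str = "raw"

    def chrom_sizes(self) -> dict:
        return {c: len(v) for c, v in self.values.items()}

    def total_signal(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end), zero-padded outside the chromosome."""
        arr = self.values[chrom]
        out = np.zeros(end - start, dtype=np.float64)
        lo, hi = max(start, 0), min(end, len(arr))
        if lo < hi:
            out[lo - start : hi - start] = arr[lo:hi]
        return out


@dataclass
class SignalMatrix:
    """A regions x bins matrix of bin-mean signal.

    ``mode`` is ``reference_point`` or ``scale_regions``; ``row_ids``
    keeps the anchoring region identifiers in row order so an ordering
    derived from one matrix can be applied to another over the same
    regions.
    """

    values: np.ndarray
    row_ids: list
    bin_size: int
    mode: str
    bin_labels: list = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def column_profile(self) -> np.ndarray:
        """Mean over rows: the metaprofile curve."""
        return self.values.mean(axis=0)


def rpkm_normalize(track: CoverageTrack, bin_size: int) -> CoverageTrack:
    """Convert base coverage to RPKM in fixed-width bins.

    Each bin's value is (read-equivalents in bin) / (bin kb x million
    mapped reads), with read-equivalents = summed base coverage divided
    by the read length. The result is expanded back to base resolution
    (each base carries its bin's RPKM value).
    """
    if track.total_mapped_reads is None or track.read_length is None:
        raise ValueError("RPKM needs total_mapped_reads and read_length")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    scale = (bin_size / 1000.0) * (track.total_mapped_reads / 1e6)
    out = {}
    for chrom, vals in track.values.items():
        n = len(vals)
        nbins = (n + bin_size - 1) // bin_size
        padded = np.zeros(nbins * bin_size)
        padded[:n] = vals
        per_bin = padded.reshape(nbins, bin_size).sum(axis=1) / track.read_length / scale
        out[chrom] = np.repeat(per_bin, bin_size)[:n]
    return CoverageTrack(out, track.total_mapped_reads, track.read_length, mode="rpkm")


def compare_tracks(
    a: CoverageTrack, b: CoverageTrack, mode: str = "subtract", pseudocount: float = 1.0
) -> CoverageTrack:
    """Combine two tracks base-by-base: ``a - b`` or ``(a+p)/(b+p)``."""
    if mode not in {"subtract", "ratio"}:
        raise ValueError(f"unknown mode {mode!r}")
    if set(a.values) != set(b.values):
        raise ValueError("tracks cover different chromosome sets")
    out = {}
    for chrom in a.values:
        va, vb = a.values[chrom], b.values[chrom]
        if len(va) != len(vb):
            raise ValueError(f"length mismatch on {chrom}")
        out[chrom] = va - vb if mode == "subtract" else (va + pseudocount) / (vb + pseudocount)
    return CoverageTrack(out, a.total_mapped_reads, a.read_length, mode=mode)


def _anchor_point_strand(anchor) -> tuple:
    """(chrom, point, strand) for an anchor: GeneModel uses its TSS."""
    if isinstance(anchor, GeneModel):
        return anchor.interval.chrom, anchor.tss, anchor.strand
    if isinstance(anchor, GenomicInterval):
        return anchor.chrom, anchor.midpoint, anchor.strand
    iv = anchor.interval  # Peak / PqsMotif
    return iv.chrom, iv.midpoint, iv.strand


def reference_point_matrix(
    track: CoverageTrack,
    anchors: Sequence,
    half_width: int = 3000,
    bin_size: int = 50,
) -> SignalMatrix:
    """Bin-mean signal in [anchor - half_width, anchor + half_width).

    One row per anchor. Minus-strand rows are column-reversed so the
    right half of the matrix is always downstream of the anchor.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if half_width % bin_size:
        raise ValueError("half_width must be a multiple of bin_size")
    nbins = 2 * half_width // bin_size
    rows = np.zeros((len(anchors), nbins))
    row_ids = []
    for r, anchor in enumerate(anchors):
        chrom, point, strand = _anchor_point_strand(anchor)
        win = track.window(chrom, point - half_width, point + half_width)
        binned = win.reshape(nbins, bin_size).mean(axis=1)
        if strand == "-":
            binned = binned[::-1]
        rows[r] = binned
        row_ids.append(getattr(anchor, "name", None) or f"row{r}")
    labels = [(-half_width + i * bin_size) for i in range(nbins)]
    return SignalMatrix(rows, row_ids, bin_size, "reference_point", labels)


def _scaled_body_bins(win: np.ndarray, body_bins: int) -> np.ndarray:
    """Mean signal in ``body_bins`` equal fractional slices of ``win``.

    Exact step-function integration: a gene shorter than ``body_bins``
    still contributes every base to at least one bin and preserves the
    overall mean.
    """
    L = len(win)
    cum = np.concatenate(([0.0], np.cumsum(win)))
    edges = np.linspace(0.0, L, body_bins + 1)
    integrals = np.interp(edges, np.arange(L + 1), cum)
    widths = np.diff(edges)
    return np.diff(integrals) / widths


def scale_regions_matrix(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    body_bins: int = 100,
    flank: int = 2000,
    bin_size: int = 50,
) -> SignalMatrix:
    """Gene bodies rescaled to a common bin count, with fixed-size flanks.

    The body is linearly rescaled onto ``body_bins``; the upstream and
    downstream flanks are binned at ``bin_size`` as in
    :func:`reference_point_matrix`. Minus-strand rows are reversed.
    """
    if flank % bin_size:
        raise ValueError("flank must be a multiple of bin_size")
    fbins = flank // bin_size
    nbins = body_bins + 2 * fbins
    rows = np.zeros((len(genes), nbins))
    row_ids = []
    for r, g in enumerate(genes):
        iv = g.interval
        left = track.window(iv.chrom, iv.start - flank, iv.start)
        body = track.window(iv.chrom, iv.start, iv.end)
        right = track.window(iv.chrom, iv.end, iv.end + flank)
        row = np.concatenate(
            [
                left.reshape(fbins, bin_size).mean(axis=1),
                _scaled_body_bins(body, body_bins),
                right.reshape(fbins, bin_size).mean(axis=1),
            ]
        )
        if g.strand == "-":
            row = row[::-1]
        rows[r] = row
        row_ids.append(g.name)
    return SignalMatrix(rows, row_ids, bin_size, "scale_regions")


def heatmap_scale(matrix: np.ndarray) -> np.ndarray:
    """Linearly map the matrix's global min/max onto [0, 255].

    A constant matrix maps to all zeros (degenerate-case decision).
    """
    values = np.asarray(matrix, dtype=np.float64)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) * (255.0 / (hi - lo))


def sort_rows(
    matrix: SignalMatrix, key: str = "max", descending: bool = True
) -> tuple:
    """Stable row sort by per-row mean or max.

    Returns (sorted SignalMatrix, row order) where the order is an index
    array applicable to other matrices over the same regions (shared
    ordering across heatmaps of different tracks).
    """
    if key not in {"mean", "max"}:
        raise ValueError(f"unknown sort key {key!r}")
    stat = matrix.values.mean(axis=1) if key == "mean" else matrix.values.max(axis=1)
    order = np.argsort(-stat if descending else stat, kind="stable")
    sorted_matrix = SignalMatrix(
        matrix.values[order],
        [matrix.row_ids[i] for i in order],
        matrix.bin_size,
        matrix.mode,
        matrix.bin_labels,
    )
    return sorted_matrix, order


def apply_row_order(matrix: SignalMatrix, order: np.ndarray) -> SignalMatrix:
    """Permute a matrix's rows by an order returned from :func:`sort_rows`."""
    return SignalMatrix(
        matrix.values[order],
        [matrix.row_ids[i] for i in order],
        matrix.bin_size,
        matrix.mode,
        matrix.bin_labels,
    )


def shuffle_intervals(
    intervals: Sequence[GenomicInterval],
    chrom_sizes: dict,
    exclusion: Sequence[GenomicInterval],
    seed: int,
    max_tries: int = 1000,
) -> list:
    """Relocate each interval uniformly at random on its own chromosome.

    Relocated spans may overlap neither the exclusion intervals (for the
    PQS-free null: all PQS spans) nor one another; lengths and
    chromosomes are preserved, and the output is deterministic for a
    given seed. Raises RuntimeError naming the interval when no feasible
    placement is found within ``max_tries`` draws.
    """
    rng = np.random.default_rng(seed)
    blocked = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}
    for iv in exclusion:
        if iv.chrom in blocked:
            blocked[iv.chrom][max(0, iv.start) : iv.end] = True
    out = []
    for iv in intervals:
        size = chrom_sizes[iv.chrom]
        length = len(iv)
        mask = blocked[iv.chrom]
        placed = None
        for _ in range(max_tries):
            start = int(rng.integers(0, size - length + 1))
            if not mask[start : start + length].any():
                placed = start
                break
        if placed is None:
            raise RuntimeError(
                f"no PQS-free placement found for {iv.chrom}:{iv.start}-{iv.end} "
                f"after {max_tries} tries"
            )
        mask[placed : placed + length] = True  # keep shuffled intervals disjoint
        out.append(GenomicInterval(iv.chrom, placed, placed + length, iv.strand))
    return out
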