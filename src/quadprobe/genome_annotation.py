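"""Gene models, TSS/TES anchors and the four-region genome partition.

The genome is partitioned into promoter (TSS +/- flank), TES flank
(TES +/- flank), intragenic, and intergenic regions. Where windows of
different genes overlap, labels are assigned with the precedence
promoter > TES flank > intragenic > intergenic, so that every base of
every chromosome carries exactly one label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io_formats import GeneModel, GenomicInterval

REGION_LABELS = ("promoter", "tes_flank", "intragenic", "intergenic")
_LABEL_CODE = {label: i for i, label in enumerate(REGION_LABELS)}

ASSIGN_RULES = ("midpoint", "any_overlap")


def load_genes(intervals: Iterable[GeneModel]) -> list[GeneModel]:
    """Deduplicate gene records by exact (chrom, start, end, strand).

    Records must be stranded (``gene_bed`` dialect); duplicates collapse
    to one gene, and the result is ordered by coordinate. The same span
    on opposite strands stays as two genes.
    """
    seen = {}
    for g in intervals:
        if not isinstance(g, GeneModel):
            g = GeneModel(g)  # raises FormatError for strand "."
        key = (g.interval.chrom, g.interval.start, g.interval.end, g.strand)
        if key not in seen:
            seen[key] = g
    return sorted(
        seen.values(), key=lambda g: (g.interval.chrom, g.interval.start, g.interval.end, g.strand)
    )


@dataclass
class RegionPartition:
    """Per-chromosome base-resolution labels for the four functional regions."""

    labels: dict  # chrom -> np.ndarray of uint8 codes
    flank: int

    def label_at(self, chrom: str, pos: int) -> str:
        return REGION_LABELS[self.labels[chrom][pos]]

    def nucleotide_counts(self) -> dict:
        counts = {label: 0 for label in REGION_LABELS}
        for arr in self.labels.values():
            binc = np.bincount(arr, minlength=len(REGION_LABELS))
            for label, code in _LABEL_CODE.items():
                counts[label] += int(binc[code])
        return counts

    def nucleotide_fractions(self) -> dict:
        counts = self.nucleotide_counts()
        total = sum(counts.values())
        return {label: counts[label] / total for label in REGION_LABELS}

    def genome_size(self) -> int:
        return sum(len(a) for a in self.labels.values())


def partition_regions(
    genes: Sequence[GeneModel],
    chrom_sizes: dict,
    flank: int = 2000,
    precedence: Sequence[str] = ("promoter", "tes_flank", "intragenic"),
) -> RegionPartition:
    """Partition every chromosome into the four functional regions.

    Windows are clipped to chromosome bounds. The result is independent
    of gene input order; overlapping windows resolve by ``precedence``
    (highest first), with intergenic as the residual label.
    """
    labels = {}
    for chrom, size in chrom_sizes.items():
        labels[chrom] = np.full(size, _LABEL_CODE["intergenic"], dtype=np.uint8)
    for g in genes:
        if g.interval.chrom not in chrom_sizes:
            raise KeyError(f"gene {g.name} on unknown chromosome {g.interval.chrom}")

    def windows(g: GeneModel, kind: str):
        # flank windows anchor on the gene's half-open boundary coordinates
        # (start/end), so TES +/- 2 kb of a + gene [4000,7000) is [5000,9000)
        size = chrom_sizes[g.interval.chrom]
        if kind == "promoter":
            anchor = g.interval.start if g.strand == "+" else g.interval.end
            lo, hi = anchor - flank, anchor + flank
        elif kind == "tes_flank":
            anchor = g.interval.end if g.strand == "+" else g.interval.start
            lo, hi = anchor - flank, anchor + flank
        else:
            lo, hi = g.interval.start, g.interval.end
        return max(0, lo), min(size, hi)

    # paint lowest precedence first so higher precedence overwrites
    for kind in reversed(precedence):
        code = _LABEL_CODE[kind]
        for g in genes:
            lo, hi = windows(g, kind)
            if lo < hi:
                labels[g.interval.chrom][lo:hi] = code
    return RegionPartition(labels, flank)


def _item_interval(item) -> GenomicInterval:
    if isinstance(item, GenomicInterval):
        return item
    return item.interval


def assign_to_regions(
    items: Sequence, partition: RegionPartition, rule: str = "midpoint"
) -> dict:
    """Count items per region label and return counts plus fractions.

    ``midpoint`` assigns each item to the single label at its integer
    midpoint (fractions then sum to 1); ``any_overlap`` counts an item
    once per label its span touches (reads-style accounting).
    """
    if rule not in ASSIGN_RULES:
        raise ValueError(f"unknown assignment rule {rule!r}")
    counts = {label: 0 for label in REGION_LABELS}
    for item in items:
        iv = _item_interval(item)
        arr = partition.labels[iv.chrom]
        if rule == "midpoint":
            counts[REGION_LABELS[arr[iv.midpoint]]] += 1
        else:
            for code in np.unique(arr[iv.start : iv.end]):
                counts[REGION_LABELS[code]] += 1
    total_items = len(items)
    fractions = {
        label: (counts[label] / total_items if total_items else 0.0)
        for label in REGION_LABELS
    }
    return {"counts": counts, "fractions": fractions, "rule": rule, "n_items": total_items}


def pqs_load(
    genes: Sequence[GeneModel],
    motifs: Sequence,
    half_width: int = 3000,
    per_subtype: bool = False,
) -> dict:
    """Count PQS motifs overlapping each gene's TSS +/- ``half_width`` window.

    Overlap is by >= 1 nt against the half-open window
    ``[tss - half_width, tss + half_width)``, both strands counted.
    Returns gene name -> count, or gene name -> {subtype: count} with
    ``per_subtype=True`` (a motif carrying several subtypes increments
    each of them).
    """
    trees: dict = {}
    for m in motifs:
        iv = _item_interval(m)
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, m)
    out: dict = {}
    for g in genes:
        lo = max(0, g.tss - half_width)
        hi = g.tss + half_width
        tree = trees.get(g.interval.chrom)
        hits = sorted(tree.overlap(lo, hi), key=lambda h: (h.begin, h.end)) if tree else []
        if per_subtype:
            per: dict = {}
            for h in hits:
                for st in h.data.subtypes:
                    per[st] = per.get(st, 0) + 1
            out[g.name] = per
        else:
            out[g.name] = len(hits)
    return out


def tss_subtype_strata(
    genes: Sequence[GeneModel], motifs: Sequence, half_width: int = 3000
) -> dict:
    """Group TSSs by the set of motif subtypes present in TSS +/- half_width.

    Returns subtype -> list of genes whose window carries motifs of *only*
    that subtype (TSSs with more than one subtype, or none, are excluded) —
    the stratification used to test each subtype's contribution separately.
    """
    loads = pqs_load(genes, motifs, half_width=half_width, per_subtype=True)
    strata: dict = {}
    for g in genes:
        present = {st for st, c in loads[g.name].items() if c > 0}
        if len(present) == 1:
            strata.setdefault(next(iter(present)), []).append(g)
    return strata
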