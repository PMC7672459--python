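"""Peak-PQS overlap statistics, fold-change stratification and summaries.

All overlap here ignores motif strand: a called peak is double-stranded
DNA and a G4 on either strand is detectable by the pulldown. Fold
enrichment is always the value carried on the peak record (peak calling
itself is outside this package).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome_annotation import REGION_LABELS, RegionPartition, assign_to_regions
from .io_formats import Peak
from .pqs_scan import PqsMotif, subtype_combination_counts
from .signal_profile import CoverageTrack, SignalMatrix, reference_point_matrix


def _motif_tree(motifs: Sequence) -> dict:
    trees: dict = {}
    for m in motifs:
        iv = m.interval if hasattr(m, "interval") else m
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, m)
    return trees


def peak_pqs_overlap(peaks: Sequence[Peak], motifs: Sequence) -> dict:
    """Fraction of peaks overlapping at least one PQS by >= 1 nt.

    Returns the fraction, per-peak boolean flags (input order), and the
    count. Restrict ``motifs`` to a subtype subset to reproduce e.g. the
    "four subtypes only" versus "hybrids counted in" comparison.
    """
    if not peaks:
        raise ValueError("peak list is empty")
    trees = _motif_tree(motifs)
    flags = []
    for p in peaks:
        tree = trees.get(p.interval.chrom)
        flags.append(bool(tree and tree.overlap(p.interval.start, p.interval.end)))
    flags_arr = np.array(flags, dtype=bool)
    return {
        "fraction": float(flags_arr.mean()),
        "flags": flags_arr,
        "n_positive": int(flags_arr.sum()),
        "n_peaks": len(peaks),
    }


@dataclass
class StratificationTable:
    """Peak counts/percentages per region label across fold-change thresholds."""

    table: pd.DataFrame  # index: threshold; columns: MultiIndex (label, count|percent)
    thresholds: tuple

    def counts(self, label: str) -> np.ndarray:
        return self.table[(label, "count")].to_numpy()

    def total_passing(self) -> np.ndarray:
        return self.table["n_passing"].to_numpy()


def stratify_peaks(
    peaks: Sequence[Peak],
    partition: RegionPartition,
    thresholds: Sequence[float],
    label_union: Optional[Sequence[str]] = None,
) -> StratificationTable:
    """Region composition of peaks as a function of fold-change threshold.

    For each threshold t, peaks with fold_enrichment >= t are assigned to
    a region by the midpoint rule and reported as counts and as percent
    of the peaks passing t. ``label_union`` additionally reports the
    percent of passing peaks whose label falls in that union (e.g.
    promoter + intragenic + TES flank for a "gene +/- 2 kb" curve).
    """
    thresholds = tuple(thresholds)
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    folds = np.array([p.fold_enrichment for p in peaks])
    rows = []
    for t in thresholds:
        passing = [p for p, f in zip(peaks, folds) if f >= t]
        assigned = assign_to_regions(passing, partition, rule="midpoint")
        row: dict = {"n_passing": len(passing)}
        for label in REGION_LABELS:
            c = assigned["counts"][label]
            row[(label, "count")] = c
            row[(label, "percent")] = 100.0 * c / len(passing) if passing else 0.0
        if label_union is not None:
            in_union = sum(assigned["counts"][l] for l in label_union)
            row["union_percent"] = 100.0 * in_union / len(passing) if passing else 0.0
        rows.append(row)
    table = pd.DataFrame(rows, index=pd.Index(thresholds, name="threshold"))
    return StratificationTable(table, thresholds)


def enrichment_by_load(
    matrix: SignalMatrix, loads: Sequence[int], load_strata: Sequence
) -> dict:
    """Mean profile per PQS-load stratum.

    ``loads`` gives the motif count for each matrix row (same order);
    ``load_strata`` is a list of (label, predicate) pairs or (label, set)
    pairs over load values. Strata must be disjoint. Returns
    label -> {"profile": mean curve, "n": rows in stratum}.
    """
    loads_arr = np.asarray(loads)
    if loads_arr.shape[0] != matrix.n_rows:
        raise ValueError("loads must align with matrix rows")
    masks = {}
    for label, sel in load_strata:
        if callable(sel):
            mask = np.array([bool(sel(l)) for l in loads_arr])
        else:
            mask = np.isin(loads_arr, list(sel))
        masks[label] = mask
    total = np.zeros(matrix.n_rows, dtype=int)
    for mask in masks.values():
        total += mask.astype(int)
    if (total > 1).any():
        raise ValueError("load strata are not disjoint")
    out = {}
    for label, mask in masks.items():
        n = int(mask.sum())
        profile = matrix.values[mask].mean(axis=0) if n else np.zeros(matrix.values.shape[1])
        out[label] = {"profile": profile, "n": n}
    return out


def enrichment_at_subtypes(
    track: CoverageTrack,
    motifs_by_subtype: dict,
    half_width: int = 1000,
    bin_size: int = 50,
) -> dict:
    """Mean signal profile at motif centers, per subtype.

    ``track`` should already be a subtract-mode, depth-normalized signal
    (probe minus input). Motif center is the integer midpoint (ties
    toward start). Subtypes with no motifs report an empty profile.
    """
    out = {}
    for subtype, motifs in motifs_by_subtype.items():
        if not motifs:
            out[subtype] = {"profile": np.array([]), "n": 0}
            continue
        mat = reference_point_matrix(track, list(motifs), half_width, bin_size)
        out[subtype] = {"profile": mat.column_profile(), "n": mat.n_rows}
    return out


def summary_report(
    motifs: Sequence[PqsMotif],
    peaks: Sequence[Peak],
    partition: RegionPartition,
    thresholds: Sequence[float] = (1.0, 2.0, 4.0, 8.0, 16.0),
) -> str:
    """One deterministic TSV aggregating the pipeline's headline statistics.

    Sections: motif counts per subtype combination; percent of peaks
    PQS-positive for the four core subtypes alone and with hybrid motifs
    counted in; nucleotide percent per region; and the fold-change
    stratification table. Re-running on identical inputs yields a
    byte-identical report.
    """
    lines = ["section\tkey\tvalue"]
    for combo, count in subtype_combination_counts(motifs).items():
        lines.append(f"motif_counts\t{combo}\t{count}")

    core = [m for m in motifs if m.subtypes & {"4G", "4GL15", "GVBQ", "Bulge"}]
    if peaks:
        with_core = peak_pqs_overlap(peaks, core)
        with_all = peak_pqs_overlap(peaks, motifs)
        lines.append(f"peak_pqs\tpct_positive_core_subtypes\t{100 * with_core['fraction']:.4f}")
        lines.append(f"peak_pqs\tpct_positive_with_hybrids\t{100 * with_all['fraction']:.4f}")

    for label, frac in partition.nucleotide_fractions().items():
        lines.append(f"region_nt\t{label}\t{100 * frac:.4f}")

    if peaks:
        strat = stratify_peaks(peaks, partition, thresholds)
        for t in strat.thresholds:
            row = strat.table.loc[t]
            lines.append(f"stratification\tn_passing_fold_ge_{t:g}\t{int(row['n_passing'])}")
            for label in REGION_LABELS:
                lines.append(
                    f"stratification\tpct_{label}_fold_ge_{t:g}\t{row[(label, 'percent')]:.4f}"
                )
    return "\n".join(lines) + "\n"
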