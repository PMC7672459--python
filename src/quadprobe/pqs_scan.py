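"""Genome-wide identification of putative G-quadruplex sequences (PQS).

Six motif classes are recognized on both strands:

* ``4G`` — canonical PQS, the consensus G>=3(N1-7 G>=3)>=3: at least four
  G-tracts of three or more guanines separated by loops of 1-7 nt.
* ``4GL15`` — four G-tracts with exactly one long loop of 8-15 nt.
* ``GVBQ`` — G-vacancy-bearing quadruplex: one terminal tract is short by
  one guanine (a bare ``GG``), leaving a vacancy in a quartet.
* ``Bulge`` — one tract of three guanines interrupted by a single non-G
  nucleotide (``G.GG`` or ``GG.G``); the other three tracts are intact.
* ``Hybrid2`` / ``Hybrid3`` — two- or three-tract motifs that could
  complete a quadruplex with G-tracts donated by the RNA transcript
  (DNA:RNA hybrid G4s).

Canonical matching reproduces the exact behaviour of the published
regular expression ``G{3,}(.{1,7}?G{3,}){3,}`` under standard backtracking
engine semantics: greedy G-runs, lazy (minimal) loops, leftmost
non-overlapping matches with scanning resuming after each match. It is
implemented natively here (not via :mod:`re`) so that a stock regex
engine can serve as an independent oracle in the test suite.

Non-canonical classes are found by a candidate search followed by
filtering rounds: tracts must be maximal G-runs, loops may not contain a
G-run of three or more, and any candidate overlapping a canonical 4G
span on the same strand by at least one nucleotide is discarded.
Within a subtype, overlaps are resolved left to right (earlier start
wins; at equal starts the shortest candidate wins).

``N`` is treated as an unknown base: it may not occur anywhere inside a
motif (tract, loop, or bulge) and truncates candidates.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .io_formats import GenomicInterval, SequenceRecord

CORE_SUBTYPES = ("4G", "4GL15", "GVBQ", "Bulge")
HYBRID_SUBTYPES = ("Hybrid2", "Hybrid3")
ALL_SUBTYPES = CORE_SUBTYPES + HYBRID_SUBTYPES

LOOP_CHARS = frozenset("ACGT")  # N never participates in a motif

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GTract:
    """One G-tract of a motif, in motif-relative coordinates.

    ``g_count`` counts guanines in the tract (2 only for the GVBQ vacancy
    tract). A bulged tract additionally records the motif-relative offset
    and identity of its single non-G interruption.
    """

    offset: int
    g_count: int
    bulge_offset: Optional[int] = None
    bulge_base: Optional[str] = None

    @property
    def length(self) -> int:
        return self.g_count + (1 if self.bulge_offset is not None else 0)

    def render(self) -> str:
        if self.bulge_offset is None:
            return "G" * self.g_count
        left = self.bulge_offset - self.offset
        return "G" * left + self.bulge_base + "G" * (self.g_count - left)


@dataclass(frozen=True)
class PqsMotif:
    """A PQS call: interval, subtype label(s), tract structure and loops.

    ``loops`` holds the literal loop sequences in scanned (strand)
    orientation, so the motif can be reconstructed base-by-base from its
    parts; for minus-strand motifs the reconstruction equals the reverse
    complement of the plus-strand genome slice.
    """

    interval: GenomicInterval
    subtypes: frozenset
    tracts: tuple = ()
    loops: tuple = ()

    def __post_init__(self) -> None:
        if not self.subtypes:
            raise ValueError("motif must carry at least one subtype")
        if self.tracts and len(self.loops) != len(self.tracts) - 1:
            raise ValueError("need exactly one loop fewer than tracts")

    @property
    def loop_lengths(self) -> tuple:
        return tuple(len(l) for l in self.loops)

    @property
    def strand(self) -> str:
        return self.interval.strand

    def reconstruct(self) -> str:
        """Rebuild the motif sequence from tracts and loops (strand-oriented)."""
        parts = []
        for i, tract in enumerate(self.tracts):
            parts.append(tract.render())
            if i < len(self.loops):
                parts.append(self.loops[i])
        return "".join(parts)


# ---------------------------------------------------------------------------
# shared run-table machinery
# ---------------------------------------------------------------------------


def _g_run_from(seq: str) -> list:
    """run_from[i] = length of the run of G starting at i (0 if seq[i] != G)."""
    n = len(seq)
    run = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        if seq[i] == "G":
            run[i] = run[i + 1] + 1
    return run


def _max_g_runs(seq: str) -> list:
    """Maximal G-runs as (start, length) pairs, left to right."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] == "G":
            j = i
            while j < n and seq[j] == "G":
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def _n_prefix(seq: str) -> list:
    """Prefix counts of N so candidate windows can be N-checked in O(1)."""
    acc = [0]
    c = 0
    for ch in seq:
        if ch == "N":
            c += 1
        acc.append(c)
    return acc


# ---------------------------------------------------------------------------
# canonical 4G scanner (regex-engine-faithful backtracking)
# ---------------------------------------------------------------------------


def _parse_4g_at(seq: str, i: int, run_from, memo) -> Optional[tuple]:
    """First 4G parse starting at ``i`` in backtracking-engine order.

    Returns (tract_lens, loop_strs, end) or None. Loops are restricted to
    {A,C,G,T}: an N truncates the candidate (documented deviation from
    the bare ``.`` of the published pattern, which would match N).
    """
    lead = run_from[i]
    if lead < 3:
        return None

    n = len(seq)

    def reps(pos: int, count: int):
        key = (pos, count if count < 3 else 3)
        if key in memo:
            return memo[key]
        result = None
        # greedy repetition: always try to extend before stopping
        for l in range(1, 8):
            if pos + l > n:
                break
            ch = seq[pos + l - 1]
            if ch not in LOOP_CHARS:  # N in loop truncates all longer loops too
                break
            tr = run_from[pos + l]
            if tr < 3:
                continue
            hit = None
            for t in range(tr, 2, -1):  # greedy tract
                tail = reps(pos + l + t, count + 1)
                if tail is not None:
                    hit = ((l, t),) + tail
                    break
            if hit is not None:
                result = hit
                break
        if result is None and count >= 3:
            result = ()
        memo[key] = result
        return result

    for lead_len in range(lead, 2, -1):  # greedy leading tract
        tail = reps(i + lead_len, 0)
        if tail is not None:
            tracts = [lead_len] + [t for (_, t) in tail]
            pos = i + lead_len
            loops = []
            for l, t in tail:
                loops.append(seq[pos : pos + l])
                pos += l + t
            return tracts, loops, pos
    return None


def find_4g(sequence: str) -> list:
    """Find canonical 4G motifs, exactly as the consensus regex behaves.

    Matches are leftmost and non-overlapping; after each match scanning
    resumes at the base following its end.
    """
    run_from = _g_run_from(sequence)
    memo: dict = {}
    out = []
    i, n = 0, len(sequence)
    while i < n:
        if run_from[i] < 3:
            i += 1
            continue
        parsed = _parse_4g_at(sequence, i, run_from, memo)
        if parsed is None:
            i += 1
            continue
        tract_lens, loops, end = parsed
        tracts = []
        pos = i
        for k, t in enumerate(tract_lens):
            tracts.append(GTract(offset=pos - i, g_count=t))
            pos += t
            if k < len(loops):
                pos += len(loops[k])
        out.append(
            PqsMotif(_motif_iv(i, end), frozenset({"4G"}), tuple(tracts), tuple(loops))
        )
        i = end
    return out


def _motif_iv(start: int, end: int) -> GenomicInterval:
    # placeholder chromosome; scan_genome rewrites chrom/strand/coordinates
    return GenomicInterval("_", start, end, "+")


# ---------------------------------------------------------------------------
# non-canonical candidate generation
# ---------------------------------------------------------------------------


def _candidates_4gl15(seq: str, runs3: list) -> list:
    """Four maximal tracts, exactly one loop of 8-15 nt, others 1-7 nt."""
    cands = []
    for k in range(len(runs3) - 3):
        window = runs3[k : k + 4]
        gaps = [window[j + 1][0] - (window[j][0] + window[j][1]) for j in range(3)]
        long_idx = [j for j, g in enumerate(gaps) if 8 <= g <= 15]
        if len(long_idx) != 1:
            continue
        if any(not (1 <= g <= 7) for j, g in enumerate(gaps) if j != long_idx[0]):
            continue
        start = window[0][0]
        end = window[3][0] + window[3][1]
        tracts = tuple(GTract(offset=s - start, g_count=l) for s, l in window)
        loops = tuple(
            seq[window[j][0] + window[j][1] : window[j + 1][0]] for j in range(3)
        )
        cands.append((start, end, tracts, loops))
    return cands


def _gvbq_terminal(seq: str, runs: list, runs3: list) -> list:
    """Vacancy tract (exactly ``GG``) at the first or last position."""
    cands = []
    starts3 = [s for s, _ in runs3]
    ends3 = [s + l for s, l in runs3]
    for vs, vl in runs:
        if vl != 2:
            continue
        # vacancy first: GG, then the next three tracts
        k = bisect_left(starts3, vs + vl)
        if k + 2 < len(runs3):
            window = runs3[k : k + 3]
            units = [(vs, vl, True)] + [(s, l, False) for s, l in window]
            cand = _assemble_units(seq, units)
            if cand is not None:
                cands.append(cand)
        # vacancy last: three tracts, then GG
        k = bisect_right(ends3, vs) - 1
        if k >= 2:
            window = runs3[k - 2 : k + 1]
            units = [(s, l, False) for s, l in window] + [(vs, vl, True)]
            cand = _assemble_units(seq, units)
            if cand is not None:
                cands.append(cand)
    return cands


def _gvbq_interior(seq: str, runs: list, runs3: list) -> list:
    """Optional interior-vacancy structures (slot 2 or 3 of 4)."""
    cands = []
    starts3 = [s for s, _ in runs3]
    ends3 = [s + l for s, l in runs3]
    for vs, vl in runs:
        if vl != 2:
            continue
        before = bisect_right(ends3, vs) - 1
        after = bisect_left(starts3, vs + vl)
        for n_before in (1, 2):
            n_after = 3 - n_before
            if before - n_before + 1 < 0 or after + n_after - 1 >= len(runs3):
                continue
            if before < 0 or n_before > before + 1:
                continue
            pre = runs3[before - n_before + 1 : before + 1]
            post = runs3[after : after + n_after]
            if len(pre) != n_before or len(post) != n_after:
                continue
            units = (
                [(s, l, False) for s, l in pre]
                + [(vs, vl, True)]
                + [(s, l, False) for s, l in post]
            )
            cand = _assemble_units(seq, units)
            if cand is not None:
                cands.append(cand)
    return cands


def _assemble_units(seq: str, units: list) -> Optional[tuple]:
    """Validate a 4-tract unit chain (gaps 1-7, no tract-capable run skipped)."""
    for j in range(3):
        gap = units[j + 1][0] - (units[j][0] + units[j][1])
        if not (1 <= gap <= 7):
            return None
    start = units[0][0]
    end = units[3][0] + units[3][1]
    tracts = tuple(GTract(offset=s - start, g_count=l) for s, l, _ in units)
    loops = tuple(
        seq[units[j][0] + units[j][1] : units[j + 1][0]] for j in range(3)
    )
    # loops may hold stray G/GG but never a full tract (>= 3 G)
    if any(_has_g3(l) for l in loops):
        return None
    return (start, end, tracts, loops)


def _has_g3(s: str) -> bool:
    return "GGG" in s


def _candidates_bulge(seq: str, runs: list, runs3: list) -> list:
    """Exactly one tract of three Gs broken by a single non-G base."""
    cands = []
    starts3 = [s for s, _ in runs3]
    ends3 = [s + l for s, l in runs3]
    # bulge pairs: consecutive maximal runs, 1-nt gap, 3 Gs in total
    pairs = []
    for j in range(len(runs) - 1):
        (s1, l1), (s2, l2) = runs[j], runs[j + 1]
        if s2 - (s1 + l1) == 1 and l1 + l2 == 3 and seq[s1 + l1] in "ACT":
            pairs.append((s1, l1, s2, l2))
    for s1, l1, s2, l2 in pairs:
        p_start, p_end = s1, s2 + l2
        bulge_unit = (p_start, p_end - p_start, (s1 + l1, seq[s1 + l1], l1 + l2))
        for slot in range(4):
            n_before, n_after = slot, 3 - slot
            kb = bisect_right(ends3, p_start) - 1
            ka = bisect_left(starts3, p_end)
            if n_before > kb + 1 or ka + n_after > len(runs3):
                continue
            pre = runs3[kb - n_before + 1 : kb + 1] if n_before else []
            post = runs3[ka : ka + n_after] if n_after else []
            units = (
                [(s, l, None) for s, l in pre]
                + [(bulge_unit[0], bulge_unit[1], bulge_unit[2])]
                + [(s, l, None) for s, l in post]
            )
            ok = True
            for j in range(3):
                gap = units[j + 1][0] - (units[j][0] + units[j][1])
                if not (1 <= gap <= 7):
                    ok = False
                    break
            if not ok:
                continue
            start = units[0][0]
            end = units[3][0] + units[3][1]
            loops = tuple(
                seq[units[j][0] + units[j][1] : units[j + 1][0]] for j in range(3)
            )
            if any(_has_g3(l) for l in loops):
                continue
            tracts = []
            for s, l, extra in units:
                if extra is None:
                    tracts.append(GTract(offset=s - start, g_count=l))
                else:
                    b_off, b_base, g_count = extra
                    tracts.append(
                        GTract(
                            offset=s - start,
                            g_count=g_count,
                            bulge_offset=b_off - start,
                            bulge_base=b_base,
                        )
                    )
            cands.append((start, end, tuple(tracts), loops))
    return cands


# ---------------------------------------------------------------------------
# filtering and selection
# ---------------------------------------------------------------------------


def _overlaps_any(start: int, end: int, spans: list, min_nt: int) -> bool:
    # spans sorted by start; motif spans are short, so the scan exits early
    for s, e in spans:
        if s >= end:
            break
        if min(end, e) - max(start, s) >= min_nt:
            return True
    return False


def _select_left_to_right(cands: list) -> list:
    """Earlier start wins; at equal starts the shortest candidate wins."""
    out = []
    last_end = -1
    for cand in sorted(cands, key=lambda c: (c[0], c[1])):
        if cand[0] >= last_end:
            out.append(cand)
            last_end = cand[1]
    return out


def find_noncanonical(
    sequence: str,
    subtype: str,
    canonical_spans: Sequence,
    interior_vacancy: bool = False,
    overlap_filter_nt: int = 1,
) -> list:
    """Find 4GL15 / GVBQ / Bulge motifs, filtered against canonical spans.

    ``canonical_spans`` must be the spans of :func:`find_4g` on the same
    strand (as (start, end) pairs or objects with ``start``/``end``);
    surviving candidates are reported left to right, non-overlapping
    within the subtype.
    """
    spans = sorted(_coerce_spans(canonical_spans))
    runs = _max_g_runs(sequence)
    runs3 = [(s, l) for s, l in runs if l >= 3]
    if subtype == "4GL15":
        cands = _candidates_4gl15(sequence, runs3)
    elif subtype == "GVBQ":
        cands = _gvbq_terminal(sequence, runs, runs3)
        if interior_vacancy:
            cands += _gvbq_interior(sequence, runs, runs3)
    elif subtype == "Bulge":
        cands = _candidates_bulge(sequence, runs, runs3)
    else:
        raise ValueError(f"unknown non-canonical subtype {subtype!r}")

    nprefix = _n_prefix(sequence)
    kept = []
    for start, end, tracts, loops in cands:
        if nprefix[end] - nprefix[start] > 0:  # N anywhere inside truncates
            continue
        if _overlaps_any(start, end, spans, overlap_filter_nt):
            continue
        kept.append((start, end, tracts, loops))
    return [
        PqsMotif(_motif_iv(s, e), frozenset({subtype}), tr, lp)
        for s, e, tr, lp in _select_left_to_right(kept)
    ]


def _coerce_spans(spans) -> list:
    out = []
    for sp in spans:
        if isinstance(sp, PqsMotif):
            out.append((sp.interval.start, sp.interval.end))
        elif isinstance(sp, GenomicInterval):
            out.append((sp.start, sp.end))
        else:
            s, e = sp
            out.append((int(s), int(e)))
    return out


def find_hybrid(sequence: str, all_four_tract_spans: Sequence) -> list:
    """Find two- and three-tract hybrid-G4 motifs.

    Maximal chains of G>=3 tracts linked by 1-7 nt loops containing
    exactly 2 or 3 tracts; chains overlapping any four-tract motif span
    are discarded, and a 3-tract chain is one Hybrid3, never two Hybrid2.
    """
    spans = sorted(_coerce_spans(all_four_tract_spans))
    runs3 = [(s, l) for s, l in _max_g_runs(sequence) if l >= 3]
    nprefix = _n_prefix(sequence)
    out = []
    chain: list = []
    for run in runs3 + [(len(sequence) + 100, 0)]:  # sentinel flushes last chain
        if chain and 1 <= run[0] - (chain[-1][0] + chain[-1][1]) <= 7:
            chain.append(run)
            continue
        if len(chain) in (2, 3):
            start = chain[0][0]
            end = chain[-1][0] + chain[-1][1]
            loops = tuple(
                sequence[chain[j][0] + chain[j][1] : chain[j + 1][0]]
                for j in range(len(chain) - 1)
            )
            if (
                nprefix[end] - nprefix[start] == 0
                and not any(_has_g3(l) for l in loops)
                and not _overlaps_any(start, end, spans, 1)
            ):
                label = "Hybrid2" if len(chain) == 2 else "Hybrid3"
                tracts = tuple(GTract(offset=s - start, g_count=l) for s, l in chain)
                out.append(PqsMotif(_motif_iv(start, end), frozenset({label}), tracts, loops))
        chain = [run] if run[1] else []
    return out


# ---------------------------------------------------------------------------
# genome-level scan
# ---------------------------------------------------------------------------


def scan_strand(
    sequence: str,
    subtypes: Sequence[str] = ALL_SUBTYPES,
    interior_vacancy: bool = False,
    overlap_filter_nt: int = 1,
) -> list:
    """Scan one strand-oriented sequence; coordinates are sequence-local."""
    for st in subtypes:
        if st not in ALL_SUBTYPES:
            raise ValueError(f"unknown subtype {st!r}")
    canonical = find_4g(sequence)
    canonical_spans = [(m.interval.start, m.interval.end) for m in canonical]
    out = list(canonical) if "4G" in subtypes else []
    four_tract = list(canonical_spans)
    for st in ("4GL15", "GVBQ", "Bulge"):
        found = find_noncanonical(
            sequence,
            st,
            canonical_spans,
            interior_vacancy=interior_vacancy,
            overlap_filter_nt=overlap_filter_nt,
        )
        four_tract += [(m.interval.start, m.interval.end) for m in found]
        if st in subtypes:
            out += found
    if "Hybrid2" in subtypes or "Hybrid3" in subtypes:
        hybrids = find_hybrid(sequence, four_tract)
        out += [m for m in hybrids if next(iter(m.subtypes)) in subtypes]
    return sorted(out, key=lambda m: (m.interval.start, m.interval.end))


def scan_genome(
    records: Iterable[SequenceRecord],
    subtypes: Sequence[str] = ALL_SUBTYPES,
    strands: Sequence[str] = ("+", "-"),
    interior_vacancy: bool = False,
    overlap_filter_nt: int = 1,
) -> list:
    """Scan whole genome records on the requested strands.

    The plus strand is scanned directly; the minus strand is scanned on
    the reverse complement and mapped back to plus-strand coordinates
    (``start' = L - end``) with strand ``-``. Output is sorted by
    (chrom, start, end, strand).
    """
    if not subtypes:
        raise ValueError("subtype list must not be empty")
    out = []
    for rec in records:
        L = len(rec.sequence)
        for strand in strands:
            seq = rec.sequence if strand == "+" else reverse_complement(rec.sequence)
            for m in scan_strand(
                seq,
                subtypes,
                interior_vacancy=interior_vacancy,
                overlap_filter_nt=overlap_filter_nt,
            ):
                s, e = m.interval.start, m.interval.end
                if strand == "-":
                    s, e = L - m.interval.end, L - m.interval.start
                out.append(
                    PqsMotif(
                        GenomicInterval(rec.name, s, e, strand),
                        m.subtypes,
                        m.tracts,
                        m.loops,
                    )
                )
    return sorted(
        out, key=lambda m: (m.interval.chrom, m.interval.start, m.interval.end, m.strand)
    )


def merge_subtype_calls(motifs: Sequence[PqsMotif]) -> list:
    """Merge overlapping calls of different subtypes into multi-subtype motifs.

    Calls on the same chromosome and strand whose spans overlap by >= 1 nt
    are combined transitively: the merged interval is the union span and
    the subtype set the union. The tract structure of the component with
    the most tracts is retained as representative (a union span has no
    single well-defined decomposition).
    """
    by_key: dict = {}
    for m in motifs:
        by_key.setdefault((m.interval.chrom, m.strand), []).append(m)
    out = []
    for (chrom, strand), group in sorted(by_key.items()):
        group.sort(key=lambda m: (m.interval.start, m.interval.end))
        cluster: list = []
        cluster_end = -1
        for m in group + [None]:
            if m is not None and (not cluster or m.interval.start < cluster_end):
                cluster.append(m)
                cluster_end = max(cluster_end, m.interval.end)
                continue
            if cluster:
                if len(cluster) == 1:
                    out.append(cluster[0])
                else:
                    rep = max(cluster, key=lambda c: len(c.tracts))
                    subtypes = frozenset().union(*(c.subtypes for c in cluster))
                    start = min(c.interval.start for c in cluster)
                    out.append(
                        PqsMotif(
                            GenomicInterval(chrom, start, cluster_end, strand),
                            subtypes,
                            rep.tracts,
                            rep.loops,
                        )
                    )
            if m is not None:
                cluster = [m]
                cluster_end = m.interval.end
    return sorted(
        out, key=lambda m: (m.interval.chrom, m.interval.start, m.interval.end, m.strand)
    )


def subtype_combination_counts(motifs: Sequence[PqsMotif]) -> dict:
    """Venn-style counts keyed by sorted subtype combination (e.g. '4G|Bulge')."""
    counts: dict = {}
    for m in motifs:
        key = "|".join(sorted(m.subtypes))
        counts[key] = counts.get(key, 0) + 1
    return dict(sorted(counts.items()))
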