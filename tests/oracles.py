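"""Independent brute-force oracles for the motif scanner.

These deliberately avoid the scanner's run-table machinery: the 4G
oracle is the stock :mod:`re` engine evaluating the published consensus
pattern, and the non-canonical oracles enumerate all substrings and test
each against a plain predicate, then apply the same left-to-right
selection and canonical-overlap filter the scanner defines.
"""

from __future__ import annotations

import re

PAT_4G = re.compile(r"G{3,}(?:.{1,7}?G{3,}){3,}")


def oracle_4g_spans(seq: str) -> list:
    """Reference regex engine evaluating the printed canonical pattern."""
    return [(m.start(), m.end()) for m in PAT_4G.finditer(seq)]


def _runs(sub: str) -> list:
    runs = []
    i = 0
    while i < len(sub):
        if sub[i] == "G":
            j = i
            while j < len(sub) and sub[j] == "G":
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def _is_4gl15(sub: str) -> bool:
    runs3 = [r for r in _runs(sub) if r[1] >= 3]
    if len(runs3) != 4:
        return False
    if runs3[0][0] != 0 or runs3[-1][0] + runs3[-1][1] != len(sub):
        return False
    gaps = [runs3[k + 1][0] - (runs3[k][0] + runs3[k][1]) for k in range(3)]
    return sum(8 <= g <= 15 for g in gaps) == 1 and sum(1 <= g <= 7 for g in gaps) == 2


def _is_gvbq(sub: str) -> bool:
    runs = _runs(sub)
    runs3 = [r for r in runs if r[1] >= 3]
    if len(runs3) != 3 or len(runs) < 4:
        return False
    first, last = runs[0], runs[-1]
    for units in (
        [first] + runs3 if first[1] == 2 else None,
        runs3 + [last] if last[1] == 2 else None,
    ):
        if units is None:
            continue
        if units[0][0] != 0 or units[-1][0] + units[-1][1] != len(sub):
            continue
        starts = [u[0] for u in units]
        if starts != sorted(starts) or len(set(starts)) != 4:
            continue
        gaps = [units[k + 1][0] - (units[k][0] + units[k][1]) for k in range(3)]
        if all(1 <= g <= 7 for g in gaps):
            return True
    return False


def _is_bulge(sub: str) -> bool:
    runs = _runs(sub)
    runs3 = [r for r in runs if r[1] >= 3]
    if len(runs3) != 3:
        return False
    for a in range(len(runs) - 1):
        (s1, l1), (s2, l2) = runs[a], runs[a + 1]
        if s2 - (s1 + l1) != 1 or l1 + l2 != 3 or sub[s1 + l1] not in "ACT":
            continue
        pair = (s1, s2 + l2 - s1)
        units = sorted(runs3 + [pair])
        if len(units) != 4 or units[0][0] != 0:
            continue
        if units[-1][0] + units[-1][1] != len(sub):
            continue
        gaps = [units[k + 1][0] - (units[k][0] + units[k][1]) for k in range(3)]
        if all(1 <= g <= 7 for g in gaps):
            return True
    return False


_PREDICATES = {"4GL15": _is_4gl15, "GVBQ": _is_gvbq, "Bulge": _is_bulge}
_MIN_LEN = {"4GL15": 20, "GVBQ": 13, "Bulge": 15}


def _select_ltr(spans: list) -> list:
    out = []
    last = -1
    for s, e in sorted(spans):
        if s >= last:
            out.append((s, e))
            last = e
    return out


def _flanks_non_g(seq: str, i: int, j: int) -> bool:
    return (i == 0 or seq[i - 1] != "G") and (j == len(seq) or seq[j] != "G")


def oracle_noncanonical_spans(seq: str, subtype: str, canonical_spans: list) -> list:
    """Exhaustive substring enumeration + predicate + filter + selection."""
    pred = _PREDICATES[subtype]
    max_run = max((l for _, l in _runs(seq)), default=0)
    cap = 4 * max_run + 50
    cands = []
    for i in range(len(seq)):
        if seq[i] != "G" or (i > 0 and seq[i - 1] == "G"):
            continue
        for j in range(i + _MIN_LEN[subtype], min(len(seq), i + cap) + 1):
            if seq[j - 1] != "G" or (j < len(seq) and seq[j] == "G"):
                continue
            sub = seq[i:j]
            if "N" in sub:
                continue
            if pred(sub):
                cands.append((i, j))
    kept = [
        (s, e)
        for s, e in cands
        if not any(min(e, ce) - max(s, cs) >= 1 for cs, ce in canonical_spans)
    ]
    return _select_ltr(kept)


def oracle_hybrid_spans(seq: str, four_tract_spans: list) -> list:
    """Substring-enumerated 2/3-tract chains, maximal in their context."""
    runs3 = [r for r in _runs(seq) if r[1] >= 3]
    ends3 = [s + l for s, l in runs3]
    starts3 = [s for s, _ in runs3]
    cands = []
    for i in range(len(seq)):
        if seq[i] != "G" or (i > 0 and seq[i - 1] == "G"):
            continue
        for j in range(i + 7, min(len(seq), i + 3 * 20 + 20) + 1):
            if seq[j - 1] != "G" or (j < len(seq) and seq[j] == "G"):
                continue
            sub = seq[i:j]
            if "N" in sub:
                continue
            r3 = [r for r in _runs(sub) if r[1] >= 3]
            if len(r3) not in (2, 3):
                continue
            if r3[0][0] != 0 or r3[-1][0] + r3[-1][1] != len(sub):
                continue
            gaps = [r3[k + 1][0] - (r3[k][0] + r3[k][1]) for k in range(len(r3) - 1)]
            if not all(1 <= g <= 7 for g in gaps):
                continue
            # maximality: no further tract chains on within 7 nt on either side
            if any(0 < i - e <= 7 for e in ends3):
                continue
            if any(0 < s - j <= 7 or s == j for s in starts3):
                continue
            cands.append((i, j))
    kept = [
        (s, e)
        for s, e in cands
        if not any(min(e, ce) - max(s, cs) >= 1 for cs, ce in four_tract_spans)
    ]
    return _select_ltr(kept)


def oracle_scan_all(seq: str) -> dict:
    """Full independent per-subtype span sets for one strand of one sequence."""
    canonical = oracle_4g_spans(seq)
    out = {"4G": canonical}
    four_tract = list(canonical)
    for st in ("4GL15", "GVBQ", "Bulge"):
        spans = oracle_noncanonical_spans(seq, st, canonical)
        out[st] = spans
        four_tract += spans
    hybrids = oracle_hybrid_spans(seq, four_tract)
    out["Hybrid2"] = []
    out["Hybrid3"] = []
    for s, e in hybrids:
        n_tracts = len([r for r in _runs(seq[s:e]) if r[1] >= 3])
        out["Hybrid2" if n_tracts == 2 else "Hybrid3"].append((s, e))
    return out
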