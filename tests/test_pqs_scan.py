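import random

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import oracle_scan_all
from quadprobe.io_formats import SequenceRecord
from quadprobe.pqs_scan import (
    ALL_SUBTYPES,
    find_4g,
    find_hybrid,
    find_noncanonical,
    merge_subtype_calls,
    scan_genome,
    scan_strand,
    subtype_combination_counts,
)


def spans(motifs):
    return [(m.interval.start, m.interval.end) for m in motifs]


class TestFind4G:
    def test_minimal_consensus_instance(self):
        (m,) = find_4g("GGGAGGGTGGGAGGG")
        assert (m.interval.start, m.interval.end) == (0, 15)
        assert len(m.tracts) == 4
        assert m.loop_lengths == (1, 1, 1)

    def test_three_tracts_is_not_enough(self):
        assert find_4g("GGGAGGGTGGG") == []

    def test_all_g_minimal_match_length(self):
        # the printed pattern needs 3 + 3*(1+3) = 15 bases minimum
        assert find_4g("G" * 12) == []
        assert spans(find_4g("G" * 15)) == [(0, 15)]

    def test_empty_sequence(self):
        assert find_4g("") == []

    def test_n_truncates_motifs(self):
        # the loop N breaks the match even though "." would accept it
        assert find_4g("GGGAGGGTGGGNGGG") == []

    def test_reconstruction_equals_slice(self):
        seq = "TTGGGAGGGTGGGAGGGTT" + "G" * 16
        for m in find_4g(seq):
            assert m.reconstruct() == seq[m.interval.start : m.interval.end]


class TestFindNoncanonical:
    def test_long_loop_motif(self):
        (m,) = find_noncanonical("GGGAGGGTGGGTTTTTTTTTGGG", "4GL15", [])
        assert (m.interval.start, m.interval.end) == (0, 23)
        assert m.loop_lengths == (1, 1, 9)

    def test_terminal_vacancy(self):
        (m,) = find_noncanonical("GGTGGGAGGGTGGG", "GVBQ", [])
        assert (m.interval.start, m.interval.end) == (0, 14)
        assert tuple(t.g_count for t in m.tracts) == (2, 3, 3, 3)

    def test_gvbq_filtered_inside_canonical_motif(self):
        seq = "GGGAGGGTGGGAGGG"
        canonical = spans(find_4g(seq))
        assert find_noncanonical(seq, "GVBQ", canonical) == []

    def test_bulge_two_plus_one(self):
        (m,) = find_noncanonical("GGAGTGGGAGGGTGGG", "Bulge", [])
        assert (m.interval.start, m.interval.end) == (0, 16)
        bulged = m.tracts[0]
        assert (bulged.g_count, bulged.bulge_offset, bulged.bulge_base) == (3, 2, "A")
        assert m.reconstruct() == "GGAGTGGGAGGGTGGG"

    def test_bulge_one_plus_two(self):
        (m,) = find_noncanonical("GAGGTGGGAGGGTGGG", "Bulge", [])
        assert m.tracts[0].bulge_offset == 1

    def test_all_tracts_intact_is_not_a_bulge(self):
        assert find_noncanonical("GGGGTGGGAGGGTGGG", "Bulge", []) == []

    def test_unknown_subtype_rejected(self):
        with pytest.raises(ValueError):
            find_noncanonical("GGG", "5G", [])

    def test_n_anywhere_inside_truncates(self):
        assert find_noncanonical("GGTGGGANGGTGGG", "GVBQ", []) == []


class TestFindHybrid:
    def test_two_tracts(self):
        (m,) = find_hybrid("GGGAGGG", [])
        assert m.subtypes == frozenset({"Hybrid2"})
        assert (m.interval.start, m.interval.end) == (0, 7)

    def test_three_tracts_reported_once(self):
        (m,) = find_hybrid("GGGAGGGTGGG", [])
        assert m.subtypes == frozenset({"Hybrid3"})
        assert (m.interval.start, m.interval.end) == (0, 11)

    def test_inside_canonical_span_discarded(self):
        seq = "GGGAGGGTGGGAGGG"
        assert find_hybrid(seq, spans(find_4g(seq))) == []


class TestScanGenome:
    def test_minus_strand_coordinates_mirrored(self):
        (m,) = scan_genome([SequenceRecord("c1", "CCCTCCCACCCTCCC")])
        assert (m.interval.start, m.interval.end, m.strand) == (0, 15, "-")
        assert m.subtypes == frozenset({"4G"})

    def test_no_g_or_c_runs_yields_nothing(self):
        assert scan_genome([SequenceRecord("c1", "ATATATATAT" * 10)]) == []

    def test_two_chromosomes_sorted(self):
        recs = [
            SequenceRecord("c2", "TT" + "GGGAGGGTGGGAGGG" + "TT"),
            SequenceRecord("c1", "GGGAGGGTGGGAGGG"),
        ]
        motifs = scan_genome(recs)
        assert [m.interval.chrom for m in motifs] == ["c1", "c2"]

    def test_empty_subtype_list_rejected(self):
        with pytest.raises(ValueError):
            scan_genome([SequenceRecord("c1", "GGG")], subtypes=[])


class TestMergeSubtypeCalls:
    def _motif(self, start, end, subtype, strand="+"):
        from quadprobe.io_formats import GenomicInterval
        from quadprobe.pqs_scan import GTract, PqsMotif

        tracts = tuple(GTract(offset=i * 4, g_count=3) for i in range(4))
        return PqsMotif(
            GenomicInterval("c1", start, end, strand), frozenset({subtype}), tracts, ("A", "A", "A")
        )

    def test_union_span_and_subtypes(self):
        merged = merge_subtype_calls(
            [self._motif(0, 23, "4GL15"), self._motif(0, 20, "Bulge")]
        )
        assert len(merged) == 1
        assert merged[0].subtypes == frozenset({"4GL15", "Bulge"})
        assert (merged[0].interval.start, merged[0].interval.end) == (0, 23)

    def test_disjoint_calls_untouched(self):
        merged = merge_subtype_calls([self._motif(0, 15, "4G"), self._motif(40, 54, "GVBQ")])
        assert len(merged) == 2

    def test_transitive_union(self):
        merged = merge_subtype_calls(
            [self._motif(0, 20, "4G"), self._motif(18, 40, "Bulge"), self._motif(38, 60, "GVBQ")]
        )
        assert len(merged) == 1
        assert merged[0].subtypes == frozenset({"4G", "Bulge", "GVBQ"})

    def test_opposite_strands_never_merge(self):
        merged = merge_subtype_calls([self._motif(0, 20, "4G", "+"), self._motif(0, 20, "GVBQ", "-")])
        assert len(merged) == 2

    def test_combination_counts(self):
        merged = merge_subtype_calls(
            [self._motif(0, 23, "4GL15"), self._motif(0, 20, "Bulge"), self._motif(50, 65, "4G")]
        )
        assert subtype_combination_counts(merged) == {"4G": 1, "4GL15|Bulge": 1}


def _scan_spans_by_subtype(seq):
    by = {st: [] for st in ALL_SUBTYPES}
    for m in scan_strand(seq):
        (subtype,) = m.subtypes
        by[subtype].append((m.interval.start, m.interval.end))
    return by


@given(st.text(alphabet="ACGT", min_size=0, max_size=120))
@settings(deadline=None, max_examples=120, derandomize=True)
def test_scanner_agrees_with_bruteforce_oracle(seq):
    """All six motif classes match exhaustive substring enumeration."""
    assert _scan_spans_by_subtype(seq) == oracle_scan_all(seq)


@given(st.text(alphabet="GACGT", min_size=0, max_size=100))
@settings(deadline=None, max_examples=80, derandomize=True)
def test_scanner_oracle_agreement_g_rich(seq):
    assert _scan_spans_by_subtype(seq) == oracle_scan_all(seq)


@given(st.text(alphabet="ACGT", min_size=1, max_size=150))
@settings(deadline=None, max_examples=80, derandomize=True)
def test_strand_symmetry(seq):
    """Minus-strand scan equals the mirrored plus-strand scan of the revcomp."""
    rec = SequenceRecord("c", seq)
    minus = scan_genome([rec], strands=("-",))
    rc = str(Seq(seq).reverse_complement())
    plus_of_rc = scan_genome([SequenceRecord("c", rc)], strands=("+",))
    L = len(seq)
    mirrored = sorted(
        (L - m.interval.end, L - m.interval.start, tuple(sorted(m.subtypes)))
        for m in plus_of_rc
    )
    got = sorted(
        (m.interval.start, m.interval.end, tuple(sorted(m.subtypes))) for m in minus
    )
    assert got == mirrored


@given(st.text(alphabet="ACGTN", min_size=1, max_size=120))
@settings(deadline=None, max_examples=80, derandomize=True)
def test_reconstruction_and_filter_soundness(seq):
    """Motifs rebuild their genome slice; non-canonical calls avoid 4G spans; N never inside."""
    canonical = [(m.interval.start, m.interval.end) for m in find_4g(seq)]
    for m in scan_strand(seq):
        s, e = m.interval.start, m.interval.end
        assert m.reconstruct() == seq[s:e]
        assert "N" not in seq[s:e]
        if m.subtypes != frozenset({"4G"}):
            assert not any(min(e, ce) - max(s, cs) >= 1 for cs, ce in canonical)


def test_scanner_handles_random_200mers_like_reference_engine():
    rng = random.Random(42)
    from oracles import oracle_4g_spans

    for _ in range(300):
        seq = "".join(rng.choice("ACGT") for _ in range(200))
        assert spans(find_4g(seq)) == oracle_4g_spans(seq)
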