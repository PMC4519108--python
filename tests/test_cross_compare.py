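import numpy as np
import pytest

from oracles import oracle_revcomp
from ssrforge.cross_compare import (
    CompareConfig, ComparisonCall, MatchPair, bidirectional_reconcile,
    direction_counts, internal_match, load_match_table, pair_ssrs,
)
from ssrforge.pipeline import verdict_accuracy
from ssrforge.seqio_assembly import SeqRecord
from ssrforge.ssr_detect import SSRConfig, SSRLocus, find_ssrs

BASES = "ACGT"


def _blast_row(q="q1", s="s1", ident=99.0, aln=500, qs=1, qe=500, ss=1, se=500,
               ev=1e-20, bits=900.0, mism=5, gaps=0):
    return f"{q}\t{s}\t{ident}\t{aln}\t{mism}\t{gaps}\t{qs}\t{qe}\t{ss}\t{se}\t{ev}\t{bits}"


class TestLoadMatchTable:
    def test_evalue_threshold(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(_blast_row(ev=1e-12) + "\n" + _blast_row(q="q2", ev=1e-6) + "\n")
        pairs = load_match_table(path)
        assert [p.query_id for p in pairs] == ["q1"]  # 1e-6 exceeds e-9

    def test_minus_orientation_flag(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(_blast_row(ss=500, se=1) + "\n")
        assert load_match_table(path)[0].minus

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(_blast_row() + "\nnot\ta\tvalid\trow\n" + _blast_row(q="q3") + "\n")
        with pytest.raises(ValueError, match="line 2"):
            load_match_table(path)


def _random_seq(rng, n):
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


class TestInternalMatch:
    def test_identical_contigs_full_length_match(self):
        rng = np.random.default_rng(0)
        seq = _random_seq(rng, 500)
        pairs = internal_match([SeqRecord(id="a", seq=seq)],
                               [SeqRecord(id="b", seq=seq)])
        assert len(pairs) == 1
        m = pairs[0]
        assert (m.pct_identity, m.aln_len) == (100.0, 500)
        assert (m.q_start, m.q_end, m.s_start, m.s_end) == (1, 500, 1, 500)
        assert m.evalue == 0.0

    def test_no_shared_kmer_no_pair(self):
        rng = np.random.default_rng(1)
        a, b = _random_seq(rng, 300), _random_seq(rng, 300)
        assert internal_match([SeqRecord(id="a", seq=a)],
                              [SeqRecord(id="b", seq=b)]) == []

    def test_planted_substitution_identity(self):
        # 2% substitutions -> identity ~98, verified against direct Hamming
        rng = np.random.default_rng(2)
        seq = list(_random_seq(rng, 800))
        mutated = seq.copy()
        sites = rng.choice(800, size=16, replace=False)
        for i in sites:
            mutated[i] = BASES[(BASES.index(mutated[i]) + 1) % 4]
        q, s = "".join(seq), "".join(mutated)
        hamming_identity = 100 * sum(a == b for a, b in zip(q, s)) / 800
        pairs = internal_match([SeqRecord(id="a", seq=q)], [SeqRecord(id="b", seq=s)])
        assert len(pairs) == 1
        assert pairs[0].pct_identity == pytest.approx(hamming_identity, abs=0.5)

    def test_reverse_complement_match_flagged_minus(self):
        rng = np.random.default_rng(3)
        seq = _random_seq(rng, 400)
        pairs = internal_match([SeqRecord(id="a", seq=seq)],
                               [SeqRecord(id="b", seq=oracle_revcomp(seq))])
        assert len(pairs) == 1
        assert pairs[0].minus

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            internal_match([], [SeqRecord(id="b", seq="ACGT")])


def _locus(seq_id, motif, copies, start=300):
    period = len(motif)
    return SSRLocus(seq_id=seq_id, start=start, end=start + period * copies,
                    period=period, motif=motif, copies=copies)


def _match(q, s, ident=100.0, aln=600, minus=False):
    if minus:
        return MatchPair(query_id=q, subject_id=s, pct_identity=ident, aln_len=aln,
                         q_start=1, q_end=aln, s_start=aln, s_end=1, evalue=1e-30)
    return MatchPair(query_id=q, subject_id=s, pct_identity=ident, aln_len=aln,
                     q_start=1, q_end=aln, s_start=1, s_end=aln, evalue=1e-30)


class TestPairSSRs:
    def test_length_difference_of_full_period_is_polymorphic(self):
        calls = pair_ssrs([_match("q", "s")],
                          [_locus("q", "AT", 12)], [_locus("s", "AT", 10)])
        assert calls[0].verdict == "polymorphic"
        assert (calls[0].p1_tract_len, calls[0].p2_tract_len) == (24, 20)

    def test_equal_tracts_monomorphic(self):
        calls = pair_ssrs([_match("q", "s")],
                          [_locus("q", "AAG", 8)], [_locus("s", "AAG", 8)])
        assert calls[0].verdict == "monomorphic"

    def test_unmatched_contig_is_no_match(self):
        calls = pair_ssrs([], [_locus("q", "AT", 12)], [])
        assert calls[0].verdict == "no_match"
        assert calls[0].p2_seq_id is None

    def test_motif_mismatch_is_no_match(self):
        calls = pair_ssrs([_match("q", "s")],
                          [_locus("q", "AT", 12)], [_locus("s", "AAG", 8)])
        assert calls[0].verdict == "no_match"

    def test_distant_midpoint_is_no_match(self):
        calls = pair_ssrs([_match("q", "s")],
                          [_locus("q", "AT", 12, start=100)],
                          [_locus("s", "AT", 12, start=400)])
        assert calls[0].verdict == "no_match"

    def test_minus_orientation_motif_adjustment(self):
        # AAG on the query reads CTT-class on a minus-strand subject
        q_loc = _locus("q", "AAG", 8, start=288)  # midpoint at ~300 of 600
        s_loc = _locus("s", "CTT", 8, start=288)
        calls = pair_ssrs([_match("q", "s", minus=True)], [q_loc], [s_loc])
        assert calls[0].verdict == "monomorphic"

    def test_unknown_id_with_validation(self):
        with pytest.raises(ValueError, match="unknown"):
            pair_ssrs([_match("ghost", "s")], [_locus("q", "AT", 12)], [],
                      known_ids=({"q"}, {"s"}))

    def test_every_query_ssr_gets_exactly_one_call(self, sim_pair, pipeline_result):
        res = pipeline_result
        assert len(res.calls_1v2) == len(res.ssrs_p1)
        counts = direction_counts(res.calls_1v2)
        assert sum(counts.values()) == len(res.ssrs_p1)

    def test_planted_truth_table_reproduced(self, sim_pair, pipeline_result):
        """200-locus noise-free panel: calls match the planted verdicts."""
        assert verdict_accuracy(pipeline_result.calls_1v2, sim_pair.truth) == 1.0


class TestBidirectionalReconcile:
    def _call(self, p1, p2, verdict="polymorphic", motif="AT"):
        return ComparisonCall(p1_seq_id=p1, p2_seq_id=p2, motif=motif,
                              p1_tract_len=24, p2_tract_len=20, verdict=verdict,
                              period=len(motif))

    def test_symmetric_polymorphic_retained(self):
        fwd = [self._call("a", "b")]
        rev = [self._call("b", "a")]
        assert bidirectional_reconcile(fwd, rev) == fwd

    def test_asymmetric_best_hit_dropped(self):
        fwd = [self._call("a", "b")]
        rev = [self._call("b", "c")]  # reciprocal direction picked another contig
        assert bidirectional_reconcile(fwd, rev) == []

    def test_monomorphic_never_in_final_panel(self):
        fwd = [self._call("a", "b", verdict="monomorphic")]
        rev = [self._call("b", "a", verdict="monomorphic")]
        assert bidirectional_reconcile(fwd, rev) == []

    def test_engineered_asymmetric_subset(self):
        fwd = [self._call(f"a{i}", f"b{i}") for i in range(6)]
        rev = [self._call(f"b{i}", f"a{i}") for i in range(3)]  # 3 asymmetric
        rev += [self._call(f"b{i}", f"z{i}") for i in range(3, 6)]
        final = bidirectional_reconcile(fwd, rev)
        assert [c.p1_seq_id for c in final] == ["a0", "a1", "a2"]

    def test_swap_invariance_on_symmetric_data(self, sim_pair, pipeline_result):
        fwd = bidirectional_reconcile(pipeline_result.calls_1v2, pipeline_result.calls_2v1)
        rev = bidirectional_reconcile(pipeline_result.calls_2v1, pipeline_result.calls_1v2)
        key_fwd = {(c.p1_seq_id, c.p2_seq_id) for c in fwd}
        key_rev = {(c.p2_seq_id, c.p1_seq_id) for c in rev}
        assert key_fwd == key_rev


def test_compare_config_validation():
    with pytest.raises(ValueError):
        CompareConfig(max_evalue=0)
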