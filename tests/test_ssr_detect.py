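import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import oracle_revcomp, oracle_rotations, oracle_ssrs
from ssrforge.seqio_assembly import SeqRecord
from ssrforge.ssr_detect import (
    SSRConfig, canonical_motif, find_ssrs, is_primitive, strand_free_motif,
)

BASES = "ACGT"


def _scan(seq, **cfg):
    loci = find_ssrs(SeqRecord(id="s", seq=seq), SSRConfig(**cfg))
    return [(l.start, l.end, l.period, l.copies) for l in loci]


class TestFindSSRs:
    def test_tract_exactly_at_threshold(self):
        loci = find_ssrs(SeqRecord(id="s", seq="AT" * 10))
        assert len(loci) == 1
        l = loci[0]
        assert (l.period, l.motif, l.copies, l.tract_len) == (2, "AT", 10, 20)

    def test_tract_below_threshold_empty(self):
        assert _scan("AT" * 9) == []

    def test_flanked_tract_coordinates(self):
        seq = "GCGTCC" + "GAA" * 8 + "TTGCAC"  # guard bases: no phase shift
        loci = find_ssrs(SeqRecord(id="s", seq=seq))
        assert [(l.start, l.end, l.motif, l.copies) for l in loci] == [(6, 30, "AAG", 8)]

    def test_left_anchoring_on_phase_completing_flank(self):
        # flank base 'A' completes a rotation, so the maximal run starts 1 bp
        # earlier; detector and oracle agree on the leftmost anchoring
        seq = "GCGTCA" + "GAA" * 8 + "TTGCAC"
        assert _scan(seq) == oracle_ssrs(seq) == [(5, 29, 3, 8)]

    def test_true_period_only(self):
        # ATAT...: reported once, at period 2, never at period 4 or 6
        loci = find_ssrs(SeqRecord(id="s", seq="C" + "AT" * 15 + "G"))
        assert [l.period for l in loci] == [2]

    def test_mononucleotide_runs_excluded(self):
        assert _scan("A" * 50) == []

    def test_forbidden_n_in_tract(self):
        seq = "AT" * 6 + "NT" + "AT" * 6
        assert all("N" not in "s"[s:e] for s, e, *_ in _scan(seq))
        assert _scan(seq) == []

    def test_trailing_partial_copy_not_counted(self):
        seq = "CCT" + "AATG" * 6 + "AA" + "CGC"  # 6 full copies + partial "AA"
        loci = find_ssrs(SeqRecord(id="s", seq=seq))
        assert len(loci) == 1
        assert loci[0].copies == 6
        assert loci[0].trailing_bp == 2

    def test_planted_tracts_recovered_exactly(self):
        rng = np.random.default_rng(99)
        plan = [("AT", 12), ("AAG", 9), ("AAAT", 7), ("AACCT", 5), ("AAATGG", 4)]
        parts, truth, pos = [], [], 0
        prev_motif = None
        for motif, copies in plan:
            flank = "".join(
                BASES[i] for i in rng.integers(0, 4, size=200))
            # guard bases so each planted tract stays exactly maximal
            if prev_motif and flank[0] == prev_motif[0]:
                flank = ("C" if prev_motif[0] != "C" else "G") + flank[1:]
            if flank[-1] == motif[-1]:
                flank = flank[:-1] + ("C" if motif[-1] != "C" else "G")
            prev_motif = motif
            parts.append(flank)
            pos += len(flank)
            truth.append((pos, pos + len(motif) * copies, len(motif), copies))
            parts.append(motif * copies)
            pos += len(motif) * copies
        tail = "".join(BASES[i] for i in rng.integers(0, 4, size=200))
        parts.append(tail)
        seq = "".join(parts)
        detected = _scan(seq)
        expected = oracle_ssrs(seq)
        assert detected == expected
        for t in truth:  # every planted tract present with exact coordinates
            assert t in detected

    def test_equals_brute_force_on_random_sequences(self):
        # repeat-enriched alphabet to provoke borderline tracts
        rng = np.random.default_rng(2024)
        for _ in range(60):
            seq = "".join(
                rng.choice(list("ACGTATATGAGA"), size=500))
            assert _scan(seq) == oracle_ssrs(seq)

    def test_no_locus_contained_in_smaller_period_locus(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            seq = "".join(rng.choice(list("ATAG"), size=400))
            loci = find_ssrs(SeqRecord(id="s", seq=seq))
            for a in loci:
                for b in loci:
                    if a is not b and b.period < a.period:
                        assert not (b.start <= a.start and a.end <= b.end)

    def test_short_sequence_empty(self):
        assert _scan("ACGTACGTAC") == []


class TestCanonicalMotif:
    def test_plus_rotation(self):
        assert canonical_motif("TA", "plus") == "AT"

    def test_minus_is_smallest_rotation_of_revcomp(self):
        # revcomp(GAA) = TTC; rotations TTC, TCT, CTT -> CTT
        assert canonical_motif("GAA", "minus") == "CTT"
        assert canonical_motif("GAA", "minus") == min(
            oracle_rotations(oracle_revcomp("GAA")))

    def test_palindromic_class(self):
        assert canonical_motif("AT", "minus") == "AT"

    def test_invalid_characters(self):
        with pytest.raises(ValueError):
            canonical_motif("ANT")

    @given(st.text(alphabet="ACGT", min_size=2, max_size=7),
           st.sampled_from(["plus", "minus"]))
    @settings(deadline=None)
    def test_idempotence(self, motif, orientation):
        once = canonical_motif(motif, orientation)
        assert canonical_motif(once, "plus") == once

    @given(st.text(alphabet="ACGT", min_size=2, max_size=7))
    @settings(deadline=None)
    def test_strand_free_symmetric(self, motif):
        assert strand_free_motif(motif) == strand_free_motif(oracle_revcomp(motif))


@pytest.mark.parametrize("motif,expected", [
    ("AT", True), ("AA", False), ("ATAT", False), ("AAAT", True),
    ("ACACAC", False), ("AAATGG", True),
])
def test_is_primitive(motif, expected):
    assert is_primitive(motif) is expected


def test_config_validation():
    with pytest.raises(ValueError):
        SSRConfig(min_period=1)
    with pytest.raises(ValueError):
        SSRConfig(min_tract_len=3)
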