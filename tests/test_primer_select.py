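import numpy as np
import pytest

from ssrforge.primer_select import (
    PrimerConfig, design_panel, design_primers, melting_temp, primer_occurrences,
    uniqueness_screen,
)
from ssrforge.seqio_assembly import SeqRecord
from ssrforge.ssr_detect import SSRConfig, find_ssrs, reverse_complement

BASES = "ACGT"


def _record_with_tract(seed=0, length=1000, motif="AAG", copies=10, pos=500):
    rng = np.random.default_rng(seed)
    flank = lambda n: "".join(BASES[i] for i in rng.integers(0, 4, size=n))
    left, right = flank(pos), flank(length - pos - len(motif) * copies)
    if left[-1] == motif[-1]:
        left = left[:-1] + "C" if motif[-1] != "C" else left[:-1] + "G"
    if right[0] == motif[0]:
        right = ("C" if motif[0] != "C" else "G") + right[1:]
    rec = SeqRecord(id="r", seq=left + motif * copies + right)
    locus = find_ssrs(rec, SSRConfig())[0]
    return rec, locus


class TestDesignPrimers:
    def test_amplicon_contains_tract(self):
        rec, locus = _record_with_tract(seed=1)
        pair = design_primers(rec, locus)
        assert pair is not None
        assert pair.fwd_start + len(pair.fwd_seq) <= locus.start
        assert pair.rev_start - len(pair.rev_seq) + 1 >= locus.end
        assert pair.product_len == pair.rev_start - pair.fwd_start + 1
        # primers lie on the parent sequence
        assert rec.seq[pair.fwd_start:pair.fwd_start + len(pair.fwd_seq)] == pair.fwd_seq
        r0 = pair.rev_start - len(pair.rev_seq) + 1
        assert reverse_complement(rec.seq[r0:pair.rev_start + 1]) == pair.rev_seq

    def test_constraints_respected(self):
        rec, locus = _record_with_tract(seed=2)
        cfg = PrimerConfig()
        pair = design_primers(rec, locus, cfg)
        for seq, tm in ((pair.fwd_seq, pair.tm_fwd), (pair.rev_seq, pair.tm_rev)):
            assert cfg.len_range[0] <= len(seq) <= cfg.len_range[1]
            gc = (seq.count("G") + seq.count("C")) / len(seq)
            assert cfg.gc_range[0] <= gc <= cfg.gc_range[1]
            assert cfg.tm_range[0] <= tm <= cfg.tm_range[1]
        assert cfg.product_range[0] <= pair.product_len <= cfg.product_range[1]

    def test_insufficient_flank_returns_null(self):
        rng = np.random.default_rng(3)
        seq = "AT" * 12 + "".join(BASES[i] for i in rng.integers(0, 4, size=400))
        rec = SeqRecord(id="r", seq="GG" + seq)  # tract ~2 bp from the start
        locus = find_ssrs(rec, SSRConfig())[0]
        assert locus.start <= 3
        assert design_primers(rec, locus) is None

    def test_deterministic(self):
        rec, locus = _record_with_tract(seed=4)
        assert design_primers(rec, locus) == design_primers(rec, locus)

    def test_locus_off_record_errors(self):
        rec, locus = _record_with_tract(seed=5)
        other = SeqRecord(id="other", seq=rec.seq)
        with pytest.raises(ValueError):
            design_primers(other, locus)


class TestMeltingTemp:
    @pytest.mark.parametrize("method", ["wallace", "nn"])
    def test_monotone_in_gc_at_fixed_length(self, method):
        # replace A/T by G/C one position at a time in a fixed 20-mer
        seq = list("ATATTAGCATTAGCATATTA")
        last = melting_temp("".join(seq), method)
        for i, base in enumerate(seq):
            if base in "AT":
                seq[i] = "G" if base == "A" else "C"
                tm = melting_temp("".join(seq), method)
                assert tm >= last
                last = tm

    def test_wallace_rule_value(self):
        # 2+4 rule: 2*(A+T) + 4*(G+C)
        assert melting_temp("AATTGGCC", "wallace") == pytest.approx(2 * 4 + 4 * 4)


class TestUniquenessScreen:
    def test_unique_primer_retained_and_duplicate_dropped(self):
        rec, locus = _record_with_tract(seed=6)
        pair = design_primers(rec, locus)
        cand_panel, _ = design_panel([rec], [locus])
        kept = uniqueness_screen(cand_panel, [rec])
        assert len(kept) == 1 and kept[0].unique
        # planting the forward primer inside a second contig kills uniqueness
        rng = np.random.default_rng(7)
        filler = "".join(BASES[i] for i in rng.integers(0, 4, size=300))
        dup = SeqRecord(id="dup", seq=filler + pair.fwd_seq + filler[:50])
        assert uniqueness_screen(cand_panel, [rec, dup]) == []

    def test_reverse_complement_counts(self):
        rec, locus = _record_with_tract(seed=8)
        pair = design_primers(rec, locus)
        rng = np.random.default_rng(9)
        filler = "".join(BASES[i] for i in rng.integers(0, 4, size=300))
        dup = SeqRecord(id="dup", seq=filler + reverse_complement(pair.rev_seq))
        panel, _ = design_panel([rec], [locus])
        assert uniqueness_screen(panel, [rec, dup]) == []

    def test_engineered_duplicates_exact_count(self, sim_pair):
        """50-candidate panel with 5 engineered duplicate primer sites."""
        records = [r for r in sim_pair.p1 if r.id.startswith("ctg_")][:50]
        loci = [find_ssrs(r, SSRConfig())[0] for r in records]
        panel, n_failed = design_panel(records, loci)
        assert n_failed == 0 and len(panel) == 50
        # append 5 contigs each carrying a copy of one panel primer
        extra = []
        rng = np.random.default_rng(10)
        for i, cand in enumerate(panel[:5]):
            filler = "".join(BASES[j] for j in rng.integers(0, 4, size=250))
            extra.append(SeqRecord(id=f"x{i}", seq=filler + cand.primers.fwd_seq))
        kept = uniqueness_screen(panel, records + extra)
        assert len(kept) == 45
        # postcondition re-count: every retained primer occurs exactly once
        for cand in kept:
            assert primer_occurrences(cand.primers.fwd_seq, records + extra) == 1
            assert primer_occurrences(cand.primers.rev_seq, records + extra) == 1

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            uniqueness_screen([], [])
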