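"""Cross-genotype contig matching and SSR polymorphism calling.

SSR-bearing contigs of genotype 1 are matched against genotype 2 (and
reciprocally).  Matches come either from an external tabular alignment file
(the 12-column BLAST outfmt-6 dialect, filtered at a maximum E-value) or
from the built-in exact-seed / ungapped-extension matcher, so the pipeline
runs with no external aligner.  Each query SSR is then paired with the SSR
at the corresponding position of its best-matched partner contig and called

    polymorphic   both tracts present, |length difference| >= one period
    monomorphic   both present, difference smaller than one period
    no_match      no partner contig, or no corresponding SSR on it

(in a perfect tract the lengths differ by whole periods, so the one-period
threshold is the smallest observable length polymorphism).  The final
marker panel is the intersection of the polymorphic calls of the two
directions — asymmetric best-hits drop out, mirroring reciprocal matching.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seqio_assembly import SeqRecord
from .ssr_detect import SSRLocus, canonical_motif, reverse_complement, strand_free_motif

VERDICTS = ("polymorphic", "monomorphic", "no_match")


@dataclass(frozen=True)
class CompareConfig:
    max_evalue: float = 1e-9
    min_identity: float = 90.0  # percent
    min_aln_len: int = 100  # bp
    flank_tol: int = 10  # bp, midpoint correspondence tolerance
    seed_k: int = 21  # internal matcher seed length

    def __post_init__(self) -> None:
        if min(self.max_evalue, self.min_identity, self.min_aln_len,
               self.flank_tol, self.seed_k) <= 0:
            raise ValueError("all comparison thresholds must be positive")


@dataclass(frozen=True)
class MatchPair:
    """One pairwise alignment hit; coordinates 1-based inclusive, with
    s_start > s_end signalling minus orientation."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float

    @property
    def minus(self) -> bool:
        return self.s_start > self.s_end


@dataclass(frozen=True)
class ComparisonCall:
    """Verdict for one query-genotype SSR.  For direction 2-vs-1 the roles
    of the two fields swap: p1_seq_id holds the query (genotype-2) contig."""

    p1_seq_id: str
    p2_seq_id: str | None
    motif: str
    p1_tract_len: int
    p2_tract_len: int | None
    verdict: str
    period: int = 0


def load_match_table(path, config: CompareConfig | None = None) -> list[MatchPair]:
    """Parse a 12-column tabular alignment file, discarding rows whose
    E-value exceeds ``config.max_evalue``.  Malformed rows raise with their
    line number."""
    config = config or CompareConfig()
    pairs: list[MatchPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                pair = MatchPair(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_len=int(fields[3]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if pair.evalue <= config.max_evalue:
                pairs.append(pair)
    return pairs


def _low_complexity(kmer: str, max_period: int = 7) -> bool:
    """True for seeds that are perfect tandem repetitions (period <= 7).

    Seeds inside SSR tracts match every tract of the same motif anywhere in
    the database, producing spurious tract-only alignments between unrelated
    contigs; masking them (the seed-level analogue of BLAST's low-complexity
    filter) restricts matching to unique flank sequence."""
    for p in range(1, min(max_period, len(kmer) - 1) + 1):
        if kmer[p:] == kmer[:-p]:
            return True
    return False


def _repeat_mask(seq: str, max_period: int = 7, min_run: int = 12) -> "np.ndarray":
    """Boolean mask of positions inside perfect tandem runs (period 1..7,
    raw run length >= min_run).  Alignments are required to cover unique
    (unmasked) sequence, so two unrelated contigs sharing a repeat tract
    can never satisfy the minimum alignment length through the tract alone."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    mask = np.zeros(len(arr), dtype=bool)
    for p in range(1, max_period + 1):
        if len(arr) <= p:
            break
        eq = (arr[p:] == arr[:-p]).astype(np.int8)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], eq, [0]))))
        for run_start, run_end in zip(edges[::2], edges[1::2]):
            if (run_end - run_start) + p >= min_run:
                mask[run_start : run_end + p] = True
    return mask


def _extend_xdrop(
    q: str, s: str, diag: int, seed_lo: int, seed_hi: int, xdrop: int = 20
) -> tuple[int, int, int]:
    """Ungapped x-drop extension of a seed run along one diagonal.

    q positions i align s positions i - diag.  Returns (q_lo, q_hi, matches)
    for the best-scoring segment (match +1, mismatch -2) containing the seed.
    """
    # rightward from seed_hi
    best_hi, best_score = seed_hi, 0
    score = 0
    i = seed_hi
    while i < len(q) and (i - diag) < len(s):
        score += 1 if q[i] == s[i - diag] else -2
        i += 1
        if score > best_score:
            best_score, best_hi = score, i
        elif best_score - score > xdrop:
            break
    # leftward from seed_lo
    best_lo, best_score = seed_lo, 0
    score = 0
    i = seed_lo - 1
    while i >= 0 and (i - diag) >= 0:
        score += 1 if q[i] == s[i - diag] else -2
        if score > best_score:
            best_score, best_lo = score, i
        elif best_score - score > xdrop:
            break
        i -= 1
    matches = sum(1 for i in range(best_lo, best_hi) if q[i] == s[i - diag])
    return best_lo, best_hi, matches


def internal_match(
    p1: Sequence[SeqRecord], p2: Sequence[SeqRecord], config: CompareConfig | None = None
) -> list[MatchPair]:
    """Exact-seed, ungapped-extension matcher between two contig sets.

    For each (query, subject, strand) the most seed-supported diagonal is
    extended with an x-drop rule; hits with identity >= min_identity over
    >= min_aln_len aligned bases are emitted (one best hit per contig pair;
    E-value is the 0.0 sentinel meaning "internally matched").  Deterministic.
    """
    config = config or CompareConfig()
    if not p1 or not p2:
        raise ValueError("internal_match requires two non-empty contig sets")
    k = config.seed_k
    index: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for sj, rec in enumerate(p2):
        seq = rec.seq
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if not _low_complexity(kmer):
                index[kmer].append((sj, i))

    out: list[MatchPair] = []
    for rec in p1:
        best_by_subject: dict[int, tuple[float, MatchPair]] = {}
        for strand, q in (("+", rec.seq), ("-", reverse_complement(rec.seq))):
            nq = len(q)
            unique_mask = ~_repeat_mask(q)
            # diagonal votes per subject
            diags: dict[tuple[int, int], list[int]] = defaultdict(list)
            for i in range(nq - k + 1):
                for sj, spos in index.get(q[i : i + k], ()):
                    diags[(sj, i - spos)].append(i)
            votes: dict[int, tuple[int, int]] = {}
            for (sj, diag), positions in diags.items():
                n_seed = len(positions)
                if sj not in votes or (n_seed, -diag) > (votes[sj][0], -votes[sj][1]):
                    votes[sj] = (n_seed, diag)
            for sj, (_, diag) in votes.items():
                positions = diags[(sj, diag)]
                q_lo, q_hi, matches = _extend_xdrop(
                    q, p2[sj].seq, diag, min(positions), max(positions) + k
                )
                aln_len = q_hi - q_lo
                if aln_len < config.min_aln_len:
                    continue
                # anchor in unique sequence: the tract itself never counts
                if int(unique_mask[q_lo:q_hi].sum()) < config.min_aln_len:
                    continue
                identity = 100.0 * matches / aln_len
                if identity < config.min_identity:
                    continue
                s_lo, s_hi = q_lo - diag, q_hi - diag  # 0-based half-open on subject
                if strand == "+":
                    pair = MatchPair(
                        query_id=rec.id, subject_id=p2[sj].id,
                        pct_identity=round(identity, 2), aln_len=aln_len,
                        q_start=q_lo + 1, q_end=q_hi,
                        s_start=s_lo + 1, s_end=s_hi, evalue=0.0,
                    )
                else:
                    # map back to the forward strand of the query
                    pair = MatchPair(
                        query_id=rec.id, subject_id=p2[sj].id,
                        pct_identity=round(identity, 2), aln_len=aln_len,
                        q_start=nq - q_hi + 1, q_end=nq - q_lo,
                        s_start=s_hi, s_end=s_lo + 1, evalue=0.0,
                    )
                score = identity * aln_len
                if sj not in best_by_subject or score > best_by_subject[sj][0]:
                    best_by_subject[sj] = (score, pair)
        out.extend(pair for _, (_, pair) in sorted(
            best_by_subject.items(), key=lambda kv: kv[0]))
    return out


def _best_match_per_query(matches: Iterable[MatchPair]) -> dict[str, MatchPair]:
    """Best hit per query: smallest E-value, then highest identity, then
    lexicographically smallest subject id."""
    best: dict[str, MatchPair] = {}
    for m in matches:
        cur = best.get(m.query_id)
        if cur is None:
            best[m.query_id] = m
            continue
        key = (m.evalue, -m.pct_identity, m.subject_id)
        cur_key = (cur.evalue, -cur.pct_identity, cur.subject_id)
        if key < cur_key:
            best[m.query_id] = m
    return best


def _map_through(m: MatchPair, q_pos: float) -> float:
    """Map a 1-based query coordinate through an ungapped alignment."""
    if m.minus:
        return m.s_start - (q_pos - m.q_start)
    return m.s_start + (q_pos - m.q_start)


def pair_ssrs(
    matches: Sequence[MatchPair],
    ssrs_query: Sequence[SSRLocus],
    ssrs_subject: Sequence[SSRLocus],
    config: CompareConfig | None = None,
    known_ids: tuple[set[str], set[str]] | None = None,
) -> list[ComparisonCall]:
    """One ComparisonCall per query SSR.

    A subject SSR corresponds to a query SSR iff the canonical motifs agree
    after orientation adjustment (reverse-complement canonicalization for
    minus-strand matches) and the query tract midpoint, mapped through the
    alignment, lies within ``flank_tol`` of the subject tract midpoint.
    The closest such subject SSR decides the verdict; query SSRs without a
    matched contig or a corresponding SSR are called no_match.

    ``known_ids`` (query-id set, subject-id set) enables validation that
    every match references known sequences.
    """
    config = config or CompareConfig()
    if known_ids is not None:
        q_known, s_known = known_ids
        for m in matches:
            if m.query_id not in q_known or m.subject_id not in s_known:
                raise ValueError(
                    f"match references unknown sequence id: "
                    f"{m.query_id} / {m.subject_id}"
                )
    best = _best_match_per_query(matches)
    subj_ssrs: dict[str, list[SSRLocus]] = defaultdict(list)
    for loc in ssrs_subject:
        subj_ssrs[loc.seq_id].append(loc)

    calls: list[ComparisonCall] = []
    for loc in ssrs_query:
        m = best.get(loc.seq_id)
        if m is None:
            calls.append(ComparisonCall(
                p1_seq_id=loc.seq_id, p2_seq_id=None, motif=loc.motif,
                p1_tract_len=loc.tract_len, p2_tract_len=None,
                verdict="no_match", period=loc.period,
            ))
            continue
        want = canonical_motif(loc.motif, "minus" if m.minus else "plus")
        mapped_mid = _map_through(m, loc.midpoint + 0.5)  # 1-based midpoint
        partner: SSRLocus | None = None
        partner_dist = None
        for cand in subj_ssrs.get(m.subject_id, ()):
            if cand.motif != want:
                continue
            dist = abs((cand.midpoint + 0.5) - mapped_mid)
            if dist <= config.flank_tol and (partner_dist is None or dist < partner_dist):
                partner, partner_dist = cand, dist
        if partner is None:
            calls.append(ComparisonCall(
                p1_seq_id=loc.seq_id, p2_seq_id=m.subject_id, motif=loc.motif,
                p1_tract_len=loc.tract_len, p2_tract_len=None,
                verdict="no_match", period=loc.period,
            ))
        else:
            delta = abs(loc.tract_len - partner.tract_len)
            verdict = "polymorphic" if delta >= loc.period else "monomorphic"
            calls.append(ComparisonCall(
                p1_seq_id=loc.seq_id, p2_seq_id=m.subject_id, motif=loc.motif,
                p1_tract_len=loc.tract_len, p2_tract_len=partner.tract_len,
                verdict=verdict, period=loc.period,
            ))
    return calls


def direction_counts(calls: Iterable[ComparisonCall]) -> dict[str, int]:
    """Monomorphic / polymorphic / no-match tallies for one direction."""
    counts = {v: 0 for v in VERDICTS}
    for c in calls:
        counts[c.verdict] += 1
    return counts


def _triple(call: ComparisonCall, swapped: bool) -> tuple[str, str, str]:
    a, b = call.p1_seq_id, call.p2_seq_id or ""
    if swapped:
        a, b = b, a
    return (a, b, strand_free_motif(call.motif))


def bidirectional_reconcile(
    calls_1v2: Sequence[ComparisonCall], calls_2v1: Sequence[ComparisonCall]
) -> list[ComparisonCall]:
    """Calls polymorphic in both directions, keyed on the genotype-1 contig,
    genotype-2 contig and orientation-free canonical motif.  Per-direction
    counts remain available via :func:`direction_counts`."""
    poly_2v1 = {
        _triple(c, swapped=True) for c in calls_2v1 if c.verdict == "polymorphic"
    }
    return [
        c for c in calls_1v2
        if c.verdict == "polymorphic" and _triple(c, swapped=False) in poly_2v1
    ]


COMPARISON_COLUMNS = (
    "p1_seq_id", "p2_seq_id", "motif", "p1_tract_len", "p2_tract_len", "verdict",
)


def write_comparison_table(calls: Sequence[ComparisonCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(COMPARISON_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                f"{c.p1_seq_id}\t{c.p2_seq_id or '.'}\t{c.motif}\t"
                f"{c.p1_tract_len}\t"
                f"{c.p2_tract_len if c.p2_tract_len is not None else '.'}\t"
                f"{c.verdict}\n"
            )
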