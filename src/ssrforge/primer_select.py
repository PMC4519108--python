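"""Flanking-primer design and panel uniqueness screening.

For each SSR locus a forward/reverse primer pair is chosen from the flanks
so that the amplicon contains the whole repeat tract.  Candidates are
enumerated exhaustively within the product-size window, filtered on length,
melting temperature, GC content and homopolymer runs, and the surviving
pair with the smallest Tm difference (then the shortest product) wins —
fully deterministic.  Primer pairs whose sequence recurs elsewhere in the
contig background (either strand) are then discarded: a marker must amplify
a single locus.

Melting temperatures use the nearest-neighbor model with unified published
parameters (Bio.SeqUtils.MeltingTemp.Tm_NN); the simple Wallace 2+4 rule is
available as ``tm_method="wallace"``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from Bio.SeqUtils import MeltingTemp as _mt

from .seqio_assembly import SeqRecord
from .ssr_detect import SSRLocus, reverse_complement

# 5' tails used by the tailed fluorescent genotyping chemistry; purely a
# reporting convenience, never part of design or uniqueness screening.
FWD_TAIL = "CAGTTTTCCCAGTCACGAC"
REV_TAIL = "GTTT"

# cap on candidates carried into pairwise Tm matching, per side; candidates
# are ranked by closeness to the Tm-window midpoint, ties by position
_MAX_CANDIDATES_PER_SIDE = 120


@dataclass(frozen=True)
class PrimerConfig:
    len_range: tuple[int, int] = (18, 24)
    tm_range: tuple[float, float] = (55.0, 62.0)
    gc_range: tuple[float, float] = (0.40, 0.60)
    max_homopolymer: int = 4
    product_range: tuple[int, int] = (100, 400)
    tm_method: str = "nn"  # "nn" (nearest-neighbor) or "wallace"

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (*self.len_range, "len_range"),
            (*self.tm_range, "tm_range"),
            (*self.gc_range, "gc_range"),
            (*self.product_range, "product_range"),
        ):
            if lo > hi:
                raise ValueError(f"{name} is empty: {(lo, hi)}")
        if self.tm_method not in ("nn", "wallace"):
            raise ValueError(f"unknown tm_method {self.tm_method!r}")


@dataclass(frozen=True)
class PrimerPair:
    """fwd on the plus strand, rev on the minus strand, both written 5'->3'.

    fwd_start / rev_start are 0-based positions of each primer's 5' base on
    the parent sequence; product_len is the amplicon span in bp.
    """

    fwd_seq: str
    rev_seq: str
    fwd_start: int
    rev_start: int
    tm_fwd: float
    tm_rev: float
    product_len: int


@dataclass(frozen=True)
class MarkerCandidate:
    locus: SSRLocus
    primers: PrimerPair
    unique: bool = True


def melting_temp(seq: str, method: str = "nn") -> float:
    if method == "wallace":
        return float(_mt.Tm_Wallace(seq))
    return float(_mt.Tm_NN(seq))


def _homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _passes(seq: str, config: PrimerConfig) -> float | None:
    """Tm if the primer satisfies all per-primer constraints, else None."""
    if set(seq) - set("ACGT"):
        return None
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    if not (config.gc_range[0] <= gc <= config.gc_range[1]):
        return None
    if _homopolymer_run(seq) > config.max_homopolymer:
        return None
    tm = melting_temp(seq, config.tm_method)
    if not (config.tm_range[0] <= tm <= config.tm_range[1]):
        return None
    return tm


def design_primers(
    record: SeqRecord, locus: SSRLocus, config: PrimerConfig | None = None
) -> PrimerPair | None:
    """Best-scoring primer pair whose amplicon contains the tract, or None.

    Scoring: minimal |Tm_fwd - Tm_rev|, then minimal product length, then
    leftmost positions — deterministic for fixed input.  Returns None when
    no candidate satisfies the constraints (an expected outcome for short
    or low-complexity flanks).
    """
    config = config or PrimerConfig()
    if locus.seq_id != record.id or locus.end > len(record.seq):
        raise ValueError(f"locus {locus.seq_id}:{locus.start} does not lie on record {record.id}")
    s = record.seq
    n = len(s)
    len_lo, len_hi = config.len_range
    prod_lo, prod_hi = config.product_range

    # forward candidates: (tm, f0, length); amplicon 5' end is f0
    fwd: list[tuple[float, int, int]] = []
    f_min = max(0, locus.end - prod_hi + len_lo)
    for f0 in range(f_min, locus.start - len_lo + 1):
        for L in range(len_lo, len_hi + 1):
            if f0 + L > locus.start:
                break
            tm = _passes(s[f0 : f0 + L], config)
            if tm is not None:
                fwd.append((tm, f0, L))
    # reverse candidates keyed by amplicon 3' end r_end (exclusive)
    rev: list[tuple[float, int, int]] = []
    r0_max = min(n - len_lo, locus.start + prod_hi - len_lo)
    for r0 in range(locus.end, r0_max + 1):
        for L in range(len_lo, len_hi + 1):
            if r0 + L > n:
                break
            tm = _passes(reverse_complement(s[r0 : r0 + L]), config)
            if tm is not None:
                rev.append((tm, r0, L))
    if not fwd or not rev:
        return None

    mid_tm = (config.tm_range[0] + config.tm_range[1]) / 2.0
    fwd.sort(key=lambda c: (abs(c[0] - mid_tm), c[1], c[2]))
    rev.sort(key=lambda c: (abs(c[0] - mid_tm), c[1], c[2]))
    fwd = fwd[:_MAX_CANDIDATES_PER_SIDE]
    rev = rev[:_MAX_CANDIDATES_PER_SIDE]

    best: tuple[float, int, int, int] | None = None
    best_pair: PrimerPair | None = None
    for tm_f, f0, lf in fwd:
        for tm_r, r0, lr in rev:
            product = (r0 + lr) - f0
            if not (prod_lo <= product <= prod_hi):
                continue
            key = (abs(tm_f - tm_r), product, f0, r0)
            if best is None or key < best:
                best = key
                best_pair = PrimerPair(
                    fwd_seq=s[f0 : f0 + lf],
                    rev_seq=reverse_complement(s[r0 : r0 + lr]),
                    fwd_start=f0,
                    rev_start=r0 + lr - 1,
                    tm_fwd=round(tm_f, 2),
                    tm_rev=round(tm_r, 2),
                    product_len=product,
                )
    return best_pair


def design_panel(
    records: Sequence[SeqRecord],
    loci: Sequence[SSRLocus],
    config: PrimerConfig | None = None,
) -> tuple[list[MarkerCandidate], int]:
    """Design primers for every locus; returns (candidates, n_failed)."""
    config = config or PrimerConfig()
    by_id = {r.id: r for r in records}
    candidates: list[MarkerCandidate] = []
    failed = 0
    for locus in loci:
        pair = design_primers(by_id[locus.seq_id], locus, config)
        if pair is None:
            failed += 1
        else:
            candidates.append(MarkerCandidate(locus=locus, primers=pair))
    return candidates, failed


def primer_occurrences(primer: str, background: Sequence[SeqRecord]) -> int:
    """Exact occurrence count of a primer over both strands of the background."""
    rc = reverse_complement(primer)
    total = 0
    for rec in background:
        total += rec.seq.count(primer)
        if rc != primer:
            total += rec.seq.count(rc)
    return total


def uniqueness_screen(
    candidates: Iterable[MarkerCandidate], background: Sequence[SeqRecord]
) -> list[MarkerCandidate]:
    """Keep candidates whose primers each occur at most once in the background.

    A primer's own design site counts as one occurrence, so any additional
    hit — on either strand, in any contig — marks the pair non-unique.
    """
    if not background:
        raise ValueError("uniqueness screen requires a non-empty background")
    kept: list[MarkerCandidate] = []
    for cand in candidates:
        n_f = primer_occurrences(cand.primers.fwd_seq, background)
        n_r = primer_occurrences(cand.primers.rev_seq, background)
        unique = n_f <= 1 and n_r <= 1
        cand = replace(cand, unique=unique)
        if unique:
            kept.append(cand)
    return kept


PANEL_COLUMNS = (
    "seq_id", "start", "end", "period", "motif", "copies",
    "fwd_primer", "rev_primer", "tm_fwd", "tm_rev", "product_len",
)


def write_panel_table(
    candidates: Sequence[MarkerCandidate], path, tailed: bool = False
) -> None:
    """Marker panel table (1-based coordinates).  With ``tailed=True`` two
    extra columns append the genotyping 5' tails to each primer verbatim."""
    cols = PANEL_COLUMNS + (("fwd_tailed", "rev_tailed") if tailed else ())
    with open(path, "w") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        fh.write("\t".join(cols) + "\n")
        for c in candidates:
            l, p = c.locus, c.primers
            row = [
                l.seq_id, str(l.start + 1), str(l.end), str(l.period), l.motif,
                str(l.copies), p.fwd_seq, p.rev_seq, f"{p.tm_fwd:.2f}",
                f"{p.tm_rev:.2f}", str(p.product_len),
            ]
            if tailed:
                row += [FWD_TAIL + p.fwd_seq, REV_TAIL + p.rev_seq]
            fh.write("\t".join(row) + "\n")
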