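"""Perfect tandem-repeat (SSR) detection and motif canonicalization.

An SSR locus here is a *perfect* tandem repetition of a primitive 2-7 bp
motif whose full-copy span reaches a configurable minimum tract length
(default 20 bp, i.e. 10 copies of a dinucleotide).  Mononucleotide runs are
excluded, as are motifs that are themselves repetitions of a shorter unit
("ATAT" is period-2 in disguise).  Coordinates are 0-based half-open in
memory; table writers emit 1-based inclusive positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqio_assembly import SeqRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SSRConfig:
    """Detector thresholds.

    min_tract_len counts only full motif copies; a trailing partial copy is
    reported separately (``trailing_bp``) and never contributes to ``copies``.
    """

    min_period: int = 2
    max_period: int = 7
    min_tract_len: int = 20
    forbid_N: bool = True

    def __post_init__(self) -> None:
        if not (1 < self.min_period <= self.max_period):
            raise ValueError("require 1 < min_period <= max_period")
        if self.min_tract_len < 2 * self.min_period:
            raise ValueError("min_tract_len must allow at least two motif copies")


@dataclass(frozen=True)
class SSRLocus:
    """A maximal perfect tandem tract on one sequence.

    ``motif`` is the canonical (lexicographically smallest rotation) form;
    the subsequence [start, end) equals some rotation of it repeated
    ``copies`` times.  ``trailing_bp`` records a partial extra copy to the
    right of ``end`` (informational; maximality is judged in whole periods).
    """

    seq_id: str
    start: int
    end: int
    period: int
    motif: str
    copies: int
    trailing_bp: int = 0

    @property
    def tract_len(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _smallest_rotation(s: str) -> str:
    return min(s[i:] + s[:i] for i in range(len(s)))


def is_primitive(motif: str) -> bool:
    """True iff the motif is not a whole-number repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_motif(motif: str, orientation: str = "plus") -> str:
    """Canonical representative of a repeat unit.

    plus: lexicographically smallest rotation of the motif.
    minus: smallest rotation of its reverse complement (the motif as it
    would read on the opposite strand).  Idempotent for fixed orientation
    composed with plus.
    """
    if not (2 <= len(motif) <= 7):
        raise ValueError(f"motif length must be in [2, 7], got {motif!r}")
    bad = set(motif) - set("ACGT")
    if bad:
        raise ValueError(f"motif {motif!r} contains invalid characters {sorted(bad)}")
    if orientation == "plus":
        return _smallest_rotation(motif)
    if orientation == "minus":
        return _smallest_rotation(reverse_complement(motif))
    raise ValueError(f"orientation must be 'plus' or 'minus', got {orientation!r}")


def strand_free_motif(motif: str) -> str:
    """Orientation-independent canonical motif: the smaller of the plus- and
    minus-strand canonical forms.  Used when comparing loci across sequences
    whose relative orientation is unknown or reversed."""
    return min(canonical_motif(motif, "plus"), canonical_motif(motif, "minus"))


def find_ssrs(record: SeqRecord, config: SSRConfig | None = None) -> list[SSRLocus]:
    """All maximal perfect tandem tracts of ``record`` meeting ``config``.

    A tract with true (smallest) period p is reported only at p: candidate
    motifs that are repetitions of a shorter unit are rejected, and any
    locus contained in a reported locus of smaller period is suppressed.
    Result is sorted by (start, period).
    """
    config = config or SSRConfig()
    s = record.seq
    n = len(s)
    loci: list[SSRLocus] = []
    if n < config.min_tract_len:
        return loci
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    for p in range(config.min_period, config.max_period + 1):
        if n < max(config.min_tract_len, 2 * p):
            continue
        eq = (arr[p:] == arr[:-p]).astype(np.int8)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], eq, [0]))))
        for run_start, run_end in zip(edges[::2], edges[1::2]):
            raw_len = int(run_end - run_start) + p  # span allowing a partial copy
            copies = raw_len // p
            tract_len = copies * p
            if tract_len < config.min_tract_len or copies < 2:
                continue
            start = int(run_start)
            motif = s[start : start + p]
            if not is_primitive(motif):
                continue
            if config.forbid_N and "N" in s[start : start + raw_len]:
                continue
            loci.append(
                SSRLocus(
                    seq_id=record.id,
                    start=start,
                    end=start + tract_len,
                    period=p,
                    motif=canonical_motif(motif, "plus"),
                    copies=copies,
                    trailing_bp=raw_len - tract_len,
                )
            )
    loci.sort(key=lambda l: (l.start, l.period))
    return _suppress_contained(loci)


def _suppress_contained(loci: list[SSRLocus]) -> list[SSRLocus]:
    """Drop any locus contained within another locus of smaller period."""
    kept: list[SSRLocus] = []
    for loc in loci:
        contained = any(
            other.period < loc.period
            and other.start <= loc.start
            and loc.end <= other.end
            for other in loci
            if other is not loc
        )
        if not contained:
            kept.append(loc)
    return kept


def scan_records(
    records: Sequence[SeqRecord], config: SSRConfig | None = None
) -> list[SSRLocus]:
    """find_ssrs over a collection, concatenated in input record order."""
    config = config or SSRConfig()
    out: list[SSRLocus] = []
    for rec in records:
        out.extend(find_ssrs(rec, config))
    return out


SSR_TABLE_COLUMNS = ("seq_id", "start", "end", "period", "motif", "copies", "tract_len")


def write_ssr_table(loci: Sequence[SSRLocus], path) -> None:
    """Tab-separated SSR table; start/end are 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        fh.write("\t".join(SSR_TABLE_COLUMNS) + "\n")
        for l in loci:
            fh.write(
                f"{l.seq_id}\t{l.start + 1}\t{l.end}\t{l.period}\t{l.motif}\t"
                f"{l.copies}\t{l.tract_len}\n"
            )


def read_ssr_table(path) -> list[SSRLocus]:
    """Read a table produced by :func:`write_ssr_table` back to loci."""
    loci: list[SSRLocus] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("seq_id\t"):
                continue
            seq_id, start, end, period, motif, copies, _tract = line.split("\t")
            loci.append(
                SSRLocus(
                    seq_id=seq_id,
                    start=int(start) - 1,
                    end=int(end),
                    period=int(period),
                    motif=motif,
                    copies=int(copies),
                )
            )
    return loci
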