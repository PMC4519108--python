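"""FASTA I/O, assembly statistics, and N50-based contig enrichment.

Two independently assembled genotypes enter the marker pipeline as plain
multi-FASTA contig sets.  Because short-read assemblies contain very large
numbers of short contigs, the pipeline's first data-reduction step keeps
only contigs longer than the assembly's N50 — roughly the longer half of
the assembled bases, where repeat tracts have enough flank for primers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence over {A,C,G,T,N}, stored uppercase."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id must be a non-empty token, got {self.id!r}")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters outside A/C/G/T/N: "
                f"{sorted(bad)} (IUPAC ambiguity codes other than N are not supported)"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AssemblyStats:
    """Length and base-composition summary of a contig collection.

    ``at_fraction``/``gc_fraction`` are computed over non-N bases only;
    N bases still count toward lengths (scaffold gaps are real sequence span).
    """

    n_contigs: int
    total_bp: int
    n50: int
    min_len: int
    max_len: int
    mean_len: float
    at_fraction: float
    gc_fraction: float


def read_fasta(path) -> list[SeqRecord]:
    """Read a multi-FASTA file into a list of :class:`SeqRecord`.

    Sequences are uppercased; record order is preserved.  A duplicated id is
    a hard error (downstream tables key on contig ids); an empty file yields
    an empty list with a warning.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id in {path}: {rec.id!r}")
        seen.add(rec.id)
        records.append(SeqRecord(id=rec.id, seq=str(rec.seq).upper()))
    if not records:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[SeqRecord], path, width: int = 70) -> None:
    """Write records as wrapped multi-FASTA."""
    bio = (_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def n50(lengths: Sequence[int]) -> int:
    """N50: the contig length L such that contigs of length >= L hold at
    least half of the total bases (computed on descending-sorted lengths
    by cumulative sum)."""
    if not lengths:
        raise ValueError("N50 of an empty length collection is undefined")
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if 2 * acc >= total:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def assembly_stats(records: Sequence[SeqRecord]) -> AssemblyStats:
    """Compute contig count, span, N50, length range, and AT/GC composition."""
    if not records:
        raise ValueError("cannot compute assembly statistics of an empty collection")
    lengths = [len(r) for r in records]
    at = sum(r.seq.count("A") + r.seq.count("T") for r in records)
    gc = sum(r.seq.count("G") + r.seq.count("C") for r in records)
    denom = at + gc
    return AssemblyStats(
        n_contigs=len(records),
        total_bp=sum(lengths),
        n50=n50(lengths),
        min_len=min(lengths),
        max_len=max(lengths),
        mean_len=sum(lengths) / len(lengths),
        at_fraction=at / denom if denom else 0.0,
        gc_fraction=gc / denom if denom else 0.0,
    )


def n50_filter(records: Sequence[SeqRecord], strict: bool = True) -> list[SeqRecord]:
    """Enrich a contig set by the N50-length rule.

    With ``strict=True`` (default) keeps contigs strictly longer than the
    collection's N50; ``strict=False`` keeps those of length >= N50.
    Input order is preserved.
    """
    threshold = n50([len(r) for r in records])
    if strict:
        return [r for r in records if len(r) > threshold]
    return [r for r in records if len(r) >= threshold]
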