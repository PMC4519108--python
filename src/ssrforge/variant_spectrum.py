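"""VCF hard filtering and nucleotide substitution spectra.

Sites are retained when they carry at least ``min_depth`` supporting reads
(INFO/DP) and a mapping quality of at least ``min_mq`` (INFO/MQ) — the
site-level annotations written by samtools/bcftools pipelines.  Surviving
records are classified as biallelic SNVs, indels (any non-SNV biallelic
allele pair), or multiallelic sites, and biallelic SNVs are tallied into
the 12 directed substitution classes (A->C ... T->G, strands reported
separately, not collapsed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from cyvcf2 import VCF

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
SUBSTITUTIONS = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)  # 12 directed classes


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: tuple[str, ...]
    depth: int | None  # INFO/DP
    map_q: float | None  # INFO/MQ

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref:
            raise ValueError("REF allele must be non-empty")


@dataclass
class FilterStats:
    n_seen: int = 0
    n_pass: int = 0
    n_fail: int = 0
    n_missing_info: int = 0  # dropped for absent DP or MQ


@dataclass
class SpectrumCounts:
    """12-cell directed substitution spectrum plus site-class tallies."""

    substitutions: dict[str, int] = field(
        default_factory=lambda: {s: 0 for s in SUBSTITUTIONS}
    )
    n_snp: int = 0
    n_indel: int = 0
    n_multiallelic: int = 0

    @property
    def ti_tv(self) -> float | None:
        """Transition/transversion ratio over the biallelic SNV spectrum;
        None when no transversions were counted."""
        ti = sum(
            n for sub, n in self.substitutions.items()
            if set(sub.split(">")) <= PURINES or set(sub.split(">")) <= PYRIMIDINES
        )
        tv = self.n_snp - ti
        return ti / tv if tv else None

    def fractions(self) -> dict[str, float]:
        total = self.n_snp
        return {s: (n / total if total else 0.0) for s, n in self.substitutions.items()}


def read_vcf(path) -> Iterator[VariantRecord]:
    """Stream a VCF 4.x file (plain or bgzipped) as VariantRecord objects."""
    for v in VCF(str(path)):
        dp = v.INFO.get("DP")
        mq = v.INFO.get("MQ")
        yield VariantRecord(
            chrom=v.CHROM,
            pos=v.POS,
            ref=v.REF,
            alt=tuple(v.ALT),
            depth=int(dp) if dp is not None else None,
            map_q=float(mq) if mq is not None else None,
        )


def hard_filter(
    records: Iterable[VariantRecord],
    min_depth: int = 10,
    min_mq: float = 30.0,
    stats: FilterStats | None = None,
) -> Iterator[VariantRecord]:
    """Yield records with depth >= min_depth and MQ >= min_mq (inclusive
    bounds), preserving order.  Records missing either annotation are
    dropped and counted in ``stats.n_missing_info``."""
    if min_depth <= 0 or min_mq <= 0:
        raise ValueError("filter thresholds must be positive")
    for rec in records:
        if stats is not None:
            stats.n_seen += 1
        if rec.depth is None or rec.map_q is None:
            if stats is not None:
                stats.n_missing_info += 1
                stats.n_fail += 1
            continue
        if rec.depth >= min_depth and rec.map_q >= min_mq:
            if stats is not None:
                stats.n_pass += 1
            yield rec
        elif stats is not None:
            stats.n_fail += 1


def classify_and_count(records: Iterable[VariantRecord]) -> SpectrumCounts:
    """Classify every record exactly once and tally the SNV spectrum.

    Multiallelic sites (>1 ALT allele) are counted once and excluded from
    the 12-cell spectrum; biallelic records where REF and ALT are single
    bases are SNVs; all other biallelic records land in the indel bucket.
    """
    counts = SpectrumCounts()
    for rec in records:
        if len(rec.alt) != 1:
            counts.n_multiallelic += 1
            continue
        alt = rec.alt[0]
        if len(rec.ref) == 1 and len(alt) == 1 and rec.ref != alt:
            counts.n_snp += 1
            counts.substitutions[f"{rec.ref}>{alt}"] += 1
        else:
            counts.n_indel += 1
    return counts


def spectrum_from_vcf(
    path, min_depth: int = 10, min_mq: float = 30.0
) -> tuple[SpectrumCounts, FilterStats]:
    """Hard-filter a VCF and count its substitution spectrum in one pass."""
    stats = FilterStats()
    counts = classify_and_count(hard_filter(read_vcf(path), min_depth, min_mq, stats))
    return counts, stats


def write_spectrum_table(counts: SpectrumCounts, path) -> None:
    """Tidy TSV: one row per directed substitution, then site-class totals."""
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for sub in SUBSTITUTIONS:
            fh.write(f"{sub}\t{counts.substitutions[sub]}\n")
        fh.write(f"n_snp\t{counts.n_snp}\n")
        fh.write(f"n_indel\t{counts.n_indel}\n")
        fh.write(f"n_multiallelic\t{counts.n_multiallelic}\n")
        titv = counts.ti_tv
        fh.write(f"ti_tv\t{titv if titv is None else f'{titv:.4f}'}\n")
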