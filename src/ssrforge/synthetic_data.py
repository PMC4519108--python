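"""Paired two-genotype genome fixtures with planted SSR truth.

The generator emulates the situation the marker pipeline is built for: two
closely related assemblies (P1, P2) sharing contigs on which perfect SSR
tracts differ in copy number.  Each planted locus draws a verdict —
polymorphic (copy-number delta of at least one unit in P2), monomorphic
(identical copies), or no_match (partner contig deleted from P2) — and the
emitted truth table records it.  Around the planted tracts:

* flank bases adjacent to a tract are constrained so the tract cannot be
  extended by even one base (planted loci are exactly maximal);
* every contig is verified with the detector and re-sampled until it
  carries exactly its planted loci and nothing else, so noise-free
  fixtures have a zero accidental-SSR guarantee;
* short SSR-free "filler" contigs supply more than half of each assembly's
  bases, so the N50 enrichment step provably retains every planted contig;
* organellar decoy contigs carry polymorphic tracts plus annotation hits
  with blacklist descriptors, exercising the keyword-exclusion stage.

All randomness flows from one numpy Generator seeded by ``SimConfig.seed``;
outputs are byte-identical across runs for a fixed configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotation_filter import AnnotationHit
from .seqio_assembly import SeqRecord, write_fasta
from .ssr_detect import SSRConfig, SSRLocus, canonical_motif, find_ssrs, is_primitive

_BASES = "ACGT"

# default planted motifs, spanning di- through hepta-nucleotide classes
DEFAULT_MOTIFS = (
    "AT", "AG", "AC", "CT",
    "AAG", "ATC", "AAT", "CCG",
    "AAAT", "AAAG",
    "AACCT",
    "AAATGG",
    "AAAATCC",
)

_DECOY_DESCRIPTORS = (
    "Chloroplast ribulose-1,5-bisphosphate carboxylase large subunit",
    "mitochondria NADH dehydrogenase subunit 4",
    "Retro-Element pol polyprotein",
    "GAG Protein, Ty3/gypsy family",
    "chloroplast maturase K",
)

_BENIGN_DESCRIPTORS = (
    "hypothetical protein", "putative serine/threonine kinase",
    "MYB transcription factor", "heat shock protein 70",
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated genotype pair.

    ``contig_len_range`` applies to SSR-bearing (and decoy) contigs;
    SSR-free filler contigs draw from ``filler_len_range`` and exist so
    that N50 enrichment keeps every planted contig.  Verdict probabilities:
    a locus is no_match with ``p_no_match``, else polymorphic with
    ``p_polymorphic``, else monomorphic.
    """

    n_contigs: int = 900
    contig_len_range: tuple[int, int] = (800, 1200)
    filler_len_range: tuple[int, int] = (400, 600)
    n_planted_ssrs: int = 200
    motif_alphabet: tuple[str, ...] = DEFAULT_MOTIFS
    copies_range: tuple[int, int] = (10, 18)
    p_polymorphic: float = 0.4
    p_no_match: float = 0.1
    delta_range: tuple[int, int] = (1, 2)
    flank_snp_rate: float = 0.0
    n_decoys: int = 5
    min_tract_len: int = 20
    min_flank: int = 150  # bp of clean flank per side, room for primers
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_polymorphic <= 1.0 and 0.0 <= self.p_no_match <= 1.0
                and self.p_polymorphic + self.p_no_match <= 1.0):
            raise ValueError("verdict probabilities must be in [0,1] and sum to <= 1")
        if not (0.0 <= self.flank_snp_rate <= 1.0):
            raise ValueError("flank_snp_rate must be a probability")
        if self.n_planted_ssrs > self.n_contigs:
            raise ValueError("n_planted_ssrs cannot exceed n_contigs")
        periods = {len(m) for m in self.motif_alphabet}
        if not periods or not periods <= set(range(2, 8)):
            raise ValueError("motif_alphabet must contain motifs of length 2-7")
        for m in self.motif_alphabet:
            if not is_primitive(m):
                raise ValueError(f"motif {m!r} is a repetition of a shorter unit")
        if self.copies_range[0] * min(periods) < self.min_tract_len:
            raise ValueError(
                "copies_range lower bound times the smallest period must reach "
                f"min_tract_len={self.min_tract_len} so planted tracts are detectable"
            )
        max_tract = (self.copies_range[1] + self.delta_range[1]) * max(periods)
        if max_tract + 2 * self.min_flank > self.contig_len_range[0]:
            raise ValueError(
                f"largest possible tract ({max_tract} bp) plus flanks does not fit "
                f"the smallest contig ({self.contig_len_range[0]} bp)"
            )


@dataclass(frozen=True)
class TruthRecord:
    p1_seq_id: str
    p2_seq_id: str | None  # None when the partner contig was deleted
    motif: str  # canonical, plus strand
    period: int
    copies_p1: int
    copies_p2: int | None
    expected_verdict: str

    @property
    def tract_len_p1(self) -> int:
        return self.copies_p1 * self.period


@dataclass
class SimResult:
    p1: list[SeqRecord]
    p2: list[SeqRecord]
    truth: list[TruthRecord]
    annotations: list[AnnotationHit]
    decoy_ids: list[str] = field(default_factory=list)
    config: SimConfig | None = None


def _random_seq(rng: np.random.Generator, length: int) -> list[str]:
    return [_BASES[i] for i in rng.integers(0, 4, size=length)]


def _plant_contig(
    rng: np.random.Generator,
    seq_id: str,
    motif: str,
    copies_p1: int,
    copies_p2: int | None,
    config: SimConfig,
    detect_cfg: SSRConfig,
    max_attempts: int = 60,
) -> tuple[SeqRecord, SeqRecord | None]:
    """One P1 contig with an exactly-maximal planted tract, plus its P2
    partner (same flanks, possibly different copies, optional flank SNPs).
    Re-samples until the detector sees exactly the planted locus in each
    genotype."""
    p = len(motif)
    for _ in range(max_attempts):
        length = int(rng.integers(config.contig_len_range[0], config.contig_len_range[1] + 1))
        tract1 = motif * copies_p1
        start = int(rng.integers(config.min_flank, length - len(tract1) - config.min_flank + 1))
        left = _random_seq(rng, start)
        right = _random_seq(rng, length - start - len(tract1))
        # guard bases: no partial extension of the tract into either flank
        if left[-1] == motif[p - 1]:
            left[-1] = _BASES[(_BASES.index(motif[p - 1]) + 1 + int(rng.integers(0, 3))) % 4]
        if right[0] == motif[0]:
            right[0] = _BASES[(_BASES.index(motif[0]) + 1 + int(rng.integers(0, 3))) % 4]
        seq1 = "".join(left) + tract1 + "".join(right)
        rec1 = SeqRecord(id=seq_id, seq=seq1)
        if not _exactly_planted(rec1, start, p, copies_p1, detect_cfg):
            continue
        if copies_p2 is None:
            return rec1, None
        tract2 = motif * copies_p2
        left2, right2 = list(left), list(right)
        if config.flank_snp_rate > 0:
            _mutate(rng, left2, config.flank_snp_rate)
            _mutate(rng, right2, config.flank_snp_rate)
            if left2[-1] == motif[p - 1] or right2[0] == motif[0]:
                continue
        seq2 = "".join(left2) + tract2 + "".join(right2)
        rec2 = SeqRecord(id=seq_id, seq=seq2)
        if not _exactly_planted(rec2, start, p, copies_p2, detect_cfg):
            continue
        return rec1, rec2
    raise RuntimeError(
        f"could not generate a clean contig for {seq_id} ({motif} x {copies_p1}) "
        f"in {max_attempts} attempts"
    )


def _exactly_planted(
    rec: SeqRecord, start: int, period: int, copies: int, detect_cfg: SSRConfig
) -> bool:
    loci = find_ssrs(rec, detect_cfg)
    return (
        len(loci) == 1
        and loci[0].start == start
        and loci[0].period == period
        and loci[0].copies == copies
        and loci[0].trailing_bp == 0
    )


def _mutate(rng: np.random.Generator, bases: list[str], rate: float) -> None:
    hits = np.flatnonzero(rng.random(len(bases)) < rate)
    for i in hits:
        cur = bases[i]
        bases[i] = _BASES[(_BASES.index(cur) + 1 + int(rng.integers(0, 3))) % 4]


def _filler_contig(
    rng: np.random.Generator, seq_id: str, config: SimConfig, detect_cfg: SSRConfig,
    max_attempts: int = 60,
) -> SeqRecord:
    for _ in range(max_attempts):
        length = int(rng.integers(config.filler_len_range[0], config.filler_len_range[1] + 1))
        rec = SeqRecord(id=seq_id, seq="".join(_random_seq(rng, length)))
        if not find_ssrs(rec, detect_cfg):
            return rec
    raise RuntimeError(f"could not generate an SSR-free filler contig {seq_id}")


def _min_copies(period: int, min_tract: int) -> int:
    return max(2, math.ceil(min_tract / period))


def generate_pair(config: SimConfig | None = None) -> SimResult:
    """Generate the paired fixture: P1/P2 contig sets, truth table, and
    annotation hits (organellar descriptors on decoys, benign descriptors
    on a third of planted contigs)."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    detect_cfg = SSRConfig(min_tract_len=config.min_tract_len)
    p1: list[SeqRecord] = []
    p2: list[SeqRecord] = []
    truth: list[TruthRecord] = []
    annotations: list[AnnotationHit] = []

    motifs = [canonical_motif(m, "plus") for m in config.motif_alphabet]
    for i in range(config.n_planted_ssrs):
        seq_id = f"ctg_{i + 1:04d}"
        motif = motifs[int(rng.integers(0, len(motifs)))]
        period = len(motif)
        lo = max(config.copies_range[0], _min_copies(period, config.min_tract_len))
        copies1 = int(rng.integers(lo, config.copies_range[1] + 1))
        u = rng.random()
        if u < config.p_no_match:
            verdict, copies2 = "no_match", None
        elif u < config.p_no_match + config.p_polymorphic:
            verdict = "polymorphic"
            delta = int(rng.integers(config.delta_range[0], config.delta_range[1] + 1))
            sign = -1 if rng.random() < 0.5 else 1
            if copies1 + sign * delta < _min_copies(period, config.min_tract_len):
                sign = 1
            copies2 = copies1 + sign * delta
        else:
            verdict, copies2 = "monomorphic", copies1
        rec1, rec2 = _plant_contig(rng, seq_id, motif, copies1, copies2, config, detect_cfg)
        p1.append(rec1)
        if rec2 is not None:
            p2.append(rec2)
        truth.append(TruthRecord(
            p1_seq_id=seq_id, p2_seq_id=seq_id if rec2 is not None else None,
            motif=motif, period=period, copies_p1=copies1, copies_p2=copies2,
            expected_verdict=verdict,
        ))
        if rng.random() < 1 / 3:
            desc = _BENIGN_DESCRIPTORS[int(rng.integers(0, len(_BENIGN_DESCRIPTORS)))]
            lo_q = int(rng.integers(1, max(2, len(rec1.seq) // 2)))
            hi_q = int(rng.integers(lo_q, len(rec1.seq) + 1))
            annotations.append(AnnotationHit(
                seq_id=seq_id, descriptor=desc, q_start=lo_q, q_end=hi_q,
                evalue=float(10.0 ** -rng.integers(10, 31)),
            ))

    decoy_ids: list[str] = []
    for i in range(config.n_decoys):
        seq_id = f"decoy_{i + 1:03d}"
        decoy_ids.append(seq_id)
        motif = motifs[int(rng.integers(0, len(motifs)))]
        period = len(motif)
        lo = max(config.copies_range[0], _min_copies(period, config.min_tract_len))
        copies1 = int(rng.integers(lo, config.copies_range[1] + 1))
        delta = int(rng.integers(config.delta_range[0], config.delta_range[1] + 1))
        rec1, rec2 = _plant_contig(
            rng, seq_id, motif, copies1, copies1 + delta, config, detect_cfg)
        p1.append(rec1)
        p2.append(rec2)
        annotations.append(AnnotationHit(
            seq_id=seq_id,
            descriptor=_DECOY_DESCRIPTORS[i % len(_DECOY_DESCRIPTORS)],
            q_start=1, q_end=len(rec1.seq), evalue=1e-40,
        ))

    n_filler = config.n_contigs - config.n_planted_ssrs
    for i in range(n_filler):
        p1.append(_filler_contig(rng, f"fillA_{i + 1:04d}", config, detect_cfg))
    for i in range(n_filler):
        p2.append(_filler_contig(rng, f"fillB_{i + 1:04d}", config, detect_cfg))

    return SimResult(p1=p1, p2=p2, truth=truth, annotations=annotations,
                     decoy_ids=decoy_ids, config=config)


TRUTH_COLUMNS = (
    "p1_seq_id", "p2_seq_id", "motif", "period",
    "copies_p1", "copies_p2", "expected_verdict",
)


def write_truth_table(truth: Sequence[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truth:
            fh.write(
                f"{t.p1_seq_id}\t{t.p2_seq_id or '.'}\t{t.motif}\t{t.period}\t"
                f"{t.copies_p1}\t{t.copies_p2 if t.copies_p2 is not None else '.'}\t"
                f"{t.expected_verdict}\n"
            )


def write_simulation(result: SimResult, outdir) -> None:
    """Write FASTA x2, truth TSV and annotation TSV into ``outdir``."""
    from pathlib import Path

    from .annotation_filter import write_annotation_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(result.p1, out / "p1.fasta")
    write_fasta(result.p2, out / "p2.fasta")
    write_truth_table(result.truth, out / "truth.tsv")
    write_annotation_table(result.annotations, out / "annotations.tsv")
    if result.config is not None:
        with open(out / "sim_config.txt", "w") as fh:
            fh.write(f"# seed = {result.config.seed}\n{result.config}\n")


# --- synthetic VCF ---------------------------------------------------------

# directed substitution weights loosely shaped like a plant genome resequencing
# spectrum: transitions dominate, C<->G rarest
DEFAULT_SPECTRUM_WEIGHTS = {
    "G>A": 0.15, "C>T": 0.15, "A>G": 0.12, "T>C": 0.12,
    "A>T": 0.075, "T>A": 0.075,
    "A>C": 0.07, "T>G": 0.07, "C>A": 0.07, "G>T": 0.07,
    "C>G": 0.015, "G>C": 0.015,
}

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=ssrforge-simulate
##contig=<ID=chr1,length=100000000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def simulate_vcf(
    path,
    n_records: int = 1000,
    seed: int = 0,
    spectrum_weights: dict[str, float] | None = None,
    p_indel: float = 0.05,
    p_multiallelic: float = 0.02,
    p_missing_info: float = 0.02,
    depth_range: tuple[int, int] = (1, 30),
    mq_range: tuple[int, int] = (10, 60),
) -> list[dict]:
    """Write a synthetic single-sample-free VCF and return per-record truth.

    Depth and mapping quality are drawn uniformly across ranges straddling
    the default hard-filter thresholds, so roughly half the records fail.
    Biallelic SNV substitutions follow ``spectrum_weights``.
    """
    weights = spectrum_weights or DEFAULT_SPECTRUM_WEIGHTS
    subs = sorted(weights)
    probs = np.array([weights[s] for s in subs], dtype=float)
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    truth: list[dict] = []
    pos = 0
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for _ in range(n_records):
            pos += int(rng.integers(1, 200))
            u = rng.random()
            if u < p_multiallelic:
                ref = _BASES[int(rng.integers(0, 4))]
                alts = sorted(set(_BASES) - {ref})
                rng.shuffle(alts)
                alt = ",".join(alts[:2])
                kind = "multiallelic"
            elif u < p_multiallelic + p_indel:
                ref = "".join(_random_seq(rng, 1))
                alt = ref + "".join(_random_seq(rng, int(rng.integers(1, 4))))
                if rng.random() < 0.5:
                    ref, alt = alt, ref  # deletion
                kind = "indel"
            else:
                sub = subs[int(rng.choice(len(subs), p=probs))]
                ref, alt = sub.split(">")
                kind = "snp"
            depth = int(rng.integers(depth_range[0], depth_range[1] + 1))
            mq = int(rng.integers(mq_range[0], mq_range[1] + 1))
            info_parts, missing = [], False
            if rng.random() < p_missing_info:
                missing = True  # drop one of the two annotations
                if rng.random() < 0.5:
                    info_parts = [f"DP={depth}"]
                else:
                    info_parts = [f"MQ={mq}"]
            else:
                info_parts = [f"DP={depth}", f"MQ={mq}"]
            fh.write(f"chr1\t{pos}\t.\t{ref}\t{alt}\t50\tPASS\t{';'.join(info_parts)}\n")
            truth.append({
                "pos": pos, "ref": ref, "alt": alt, "kind": kind,
                "depth": depth, "mq": mq, "missing_info": missing,
            })
    return truth
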