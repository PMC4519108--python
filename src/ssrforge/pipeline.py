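"""End-to-end marker discovery: enrich -> scan -> primers -> reciprocal
compare -> reconcile -> keyword filter -> di/tri restriction.

Each stage logs its input/output counts; any stage failure raises
:class:`StageError` naming the stage.  The di/tri restriction mirrors the
validation practice of genotyping only di- and tri-nucleotide markers (the
motif classes easiest to score on fragment analyzers); it is on by default
here and off by default in library use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .annotation_filter import AnnotationHit, keyword_filter
from .config import PipelineConfig
from .cross_compare import (
    ComparisonCall,
    MatchPair,
    bidirectional_reconcile,
    direction_counts,
    internal_match,
    pair_ssrs,
)
from .primer_select import MarkerCandidate, design_panel, uniqueness_screen
from .seqio_assembly import SeqRecord, n50_filter
from .ssr_detect import SSRLocus, scan_records

logger = logging.getLogger("ssrforge.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class PipelineResult:
    enriched_p1: list[SeqRecord]
    enriched_p2: list[SeqRecord]
    ssrs_p1: list[SSRLocus]
    ssrs_p2: list[SSRLocus]
    candidates_p1: list[MarkerCandidate]
    candidates_p2: list[MarkerCandidate]
    n_primer_failed_p1: int
    n_primer_failed_p2: int
    matches_1v2: list[MatchPair]
    matches_2v1: list[MatchPair]
    calls_1v2: list[ComparisonCall]
    calls_2v1: list[ComparisonCall]
    reconciled: list[ComparisonCall]
    excluded_ids: set[str]
    final_calls: list[ComparisonCall]
    final_panel: list[MarkerCandidate]
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def counts_1v2(self) -> dict[str, int]:
        return direction_counts(self.calls_1v2)

    @property
    def counts_2v1(self) -> dict[str, int]:
        return direction_counts(self.calls_2v1)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
        return wrapper
    return deco


def run_pipeline(
    p1: Sequence[SeqRecord],
    p2: Sequence[SeqRecord],
    config: PipelineConfig | None = None,
    annotations: Sequence[AnnotationHit] = (),
    matches_1v2: Sequence[MatchPair] | None = None,
    matches_2v1: Sequence[MatchPair] | None = None,
) -> PipelineResult:
    """Run the full two-genotype marker pipeline.

    ``matches_1v2`` / ``matches_2v1`` may supply externally computed
    alignment tables (already E-value-filtered by the loader); otherwise
    the internal matcher is used.  ``annotations`` feed the keyword screen;
    with none supplied, no contig is excluded.
    """
    config = config or PipelineConfig()
    counts: dict[str, int] = {}

    @_stage("enrich")
    def _enrich(records, label):
        enriched = n50_filter(records, strict=config.enrich_strict) if records else []
        counts[f"contigs_{label}"] = len(records)
        counts[f"enriched_{label}"] = len(enriched)
        logger.info("enrich %s: %d -> %d contigs", label, len(records), len(enriched))
        return enriched

    enriched_p1 = _enrich(p1, "p1")
    enriched_p2 = _enrich(p2, "p2")

    @_stage("scan")
    def _scan(records, label):
        loci = scan_records(records, config.ssr)
        counts[f"ssrs_{label}"] = len(loci)
        logger.info("scan %s: %d SSR loci", label, len(loci))
        return loci

    ssrs_p1 = _scan(enriched_p1, "p1")
    ssrs_p2 = _scan(enriched_p2, "p2")

    @_stage("primers")
    def _primers(records, loci, label):
        designed, n_failed = design_panel(records, loci, config.primer)
        kept = uniqueness_screen(designed, records) if records else []
        counts[f"primed_{label}"] = len(designed)
        counts[f"primer_failed_{label}"] = n_failed
        counts[f"unique_{label}"] = len(kept)
        logger.info(
            "primers %s: %d designed (%d failed), %d unique",
            label, len(designed), n_failed, len(kept),
        )
        return kept, n_failed

    candidates_p1, failed_p1 = _primers(enriched_p1, ssrs_p1, "p1")
    candidates_p2, failed_p2 = _primers(enriched_p2, ssrs_p2, "p2")

    @_stage("compare")
    def _compare():
        primed_loci_p1 = [c.locus for c in candidates_p1]
        primed_loci_p2 = [c.locus for c in candidates_p2]
        primed_ids_p1 = {l.seq_id for l in primed_loci_p1}
        primed_ids_p2 = {l.seq_id for l in primed_loci_p2}
        rec_p1 = [r for r in enriched_p1 if r.id in primed_ids_p1]
        rec_p2 = [r for r in enriched_p2 if r.id in primed_ids_p2]
        m12 = (list(matches_1v2) if matches_1v2 is not None
               else internal_match(rec_p1, rec_p2, config.compare))
        m21 = (list(matches_2v1) if matches_2v1 is not None
               else internal_match(rec_p2, rec_p1, config.compare))
        calls12 = pair_ssrs(m12, primed_loci_p1, primed_loci_p2, config.compare)
        calls21 = pair_ssrs(m21, primed_loci_p2, primed_loci_p1, config.compare)
        counts["matches_1v2"] = len(m12)
        counts["matches_2v1"] = len(m21)
        logger.info("compare: %d / %d match pairs; per-direction calls %s | %s",
                    len(m12), len(m21),
                    direction_counts(calls12), direction_counts(calls21))
        return m12, m21, calls12, calls21

    m12, m21, calls12, calls21 = _compare()

    @_stage("reconcile")
    def _reconcile():
        rec = bidirectional_reconcile(calls12, calls21)
        counts["reconciled_polymorphic"] = len(rec)
        logger.info("reconcile: %d bidirectionally polymorphic", len(rec))
        return rec

    reconciled = _reconcile()

    @_stage("keyword_filter")
    def _filter():
        excluded = keyword_filter(
            annotations, config.filter.blacklist, config.filter.max_evalue
        ) if annotations else set()
        kept = [
            c for c in reconciled
            if c.p1_seq_id not in excluded and (c.p2_seq_id or "") not in excluded
        ]
        counts["keyword_excluded"] = len(reconciled) - len(kept)
        counts["after_keyword_filter"] = len(kept)
        logger.info("keyword filter: %d -> %d calls", len(reconciled), len(kept))
        return excluded, kept

    excluded_ids, filtered = _filter()

    @_stage("di_tri_restrict")
    def _restrict():
        if not config.di_tri_only:
            return list(filtered)
        kept = [c for c in filtered if c.period in (2, 3)]
        counts["final_panel"] = len(kept)
        logger.info("di/tri restriction: %d -> %d calls", len(filtered), len(kept))
        return kept

    final_calls = _restrict()

    by_locus = {(c.locus.seq_id, c.locus.start): c for c in candidates_p1}
    final_keys = {(c.p1_seq_id, c.motif) for c in final_calls}
    final_panel = [
        cand for (seq_id, _), cand in sorted(by_locus.items())
        if (seq_id, cand.locus.motif) in final_keys
    ]

    return PipelineResult(
        enriched_p1=enriched_p1, enriched_p2=enriched_p2,
        ssrs_p1=ssrs_p1, ssrs_p2=ssrs_p2,
        candidates_p1=candidates_p1, candidates_p2=candidates_p2,
        n_primer_failed_p1=failed_p1, n_primer_failed_p2=failed_p2,
        matches_1v2=m12, matches_2v1=m21,
        calls_1v2=calls12, calls_2v1=calls21,
        reconciled=reconciled, excluded_ids=excluded_ids,
        final_calls=final_calls, final_panel=final_panel,
        stage_counts=counts,
    )


def verdict_accuracy(calls: Sequence[ComparisonCall], truth) -> float:
    """Fraction of truth loci whose pipeline verdict matches the planted one.

    Truth records are matched to calls by genotype-1 contig id; a truth
    locus with no call at all counts as wrong (its contig was lost upstream).
    """
    by_id: dict[str, ComparisonCall] = {}
    for c in calls:
        by_id.setdefault(c.p1_seq_id, c)
    if not truth:
        raise ValueError("empty truth table")
    hits = sum(
        1 for t in truth
        if t.p1_seq_id in by_id and by_id[t.p1_seq_id].verdict == t.expected_verdict
    )
    return hits / len(truth)
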