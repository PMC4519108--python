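"""Homology-keyword exclusion and SSR position categorization.

Protein-homology hits (e.g. BLASTX against nr) serve two purposes here:

* contigs whose best hits describe organellar or repetitive sequence
  (chloroplast, mitochondria, retroelements, GAG protein, ribosomal RNA)
  are excluded from nuclear marker panels — leaf-tissue DNA preparations
  carry abundant organellar contigs;
* each SSR is categorized relative to its sequence's homology region as
  before / after / within (or no_homology), a proxy for whether the repeat
  sits in coding sequence.

Keyword matching is case-insensitive substring matching after stripping
non-alphanumeric characters, so "Retro-Element" matches "retroelement".
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .primer_select import MarkerCandidate
from .ssr_detect import SSRLocus

# transcript-derived (EST) screening terms and threshold
EST_BLACKLIST = ("ribosomal", "retro-element", "gag protein", "chloroplast", "mitochondria")
EST_MAX_EVALUE = 1e-3
# whole-genome screening terms and threshold
GENOMIC_BLACKLIST = ("chloroplast", "mitochondria", "retroelement", "gag protein")
GENOMIC_MAX_EVALUE = 1e-9

CATEGORIES = ("before", "after", "within", "no_homology")


@dataclass(frozen=True)
class AnnotationHit:
    """A protein-homology hit: free-text subject descriptor plus the
    1-based query coordinates of the homology region."""

    seq_id: str
    descriptor: str
    q_start: int
    q_end: int
    evalue: float

    @property
    def region(self) -> tuple[int, int]:
        return (min(self.q_start, self.q_end), max(self.q_start, self.q_end))


def _normalize(text: str) -> str:
    return re.sub(r"[^a-z0-9]", "", text.lower())


def keyword_filter(
    hits: Iterable[AnnotationHit],
    blacklist: Sequence[str] = GENOMIC_BLACKLIST,
    max_evalue: float = GENOMIC_MAX_EVALUE,
) -> set[str]:
    """Sequence ids to exclude: any hit at evalue <= max_evalue whose
    descriptor contains a blacklist keyword (normalized substring test)."""
    if not blacklist:
        raise ValueError("blacklist must be non-empty")
    norm_keys = [_normalize(k) for k in blacklist]
    excluded: set[str] = set()
    for hit in hits:
        if hit.evalue > max_evalue:
            continue
        desc = _normalize(hit.descriptor)
        if any(key in desc for key in norm_keys):
            excluded.add(hit.seq_id)
    return excluded


def position_category(locus: SSRLocus, best_hit: AnnotationHit | None) -> str:
    """before / after / within / no_homology for one SSR against the best hit.

    Any overlap between the tract and the homology region counts as within;
    the spreadsheet-era before/after labels require the tract entirely on
    one side of the region.
    """
    if best_hit is None:
        return "no_homology"
    if best_hit.seq_id != locus.seq_id:
        raise ValueError(
            f"hit sequence {best_hit.seq_id!r} does not match locus sequence "
            f"{locus.seq_id!r}"
        )
    lo, hi = best_hit.region
    tract_lo, tract_hi = locus.start + 1, locus.end  # 1-based inclusive
    if tract_hi < lo:
        return "before"
    if tract_lo > hi:
        return "after"
    return "within"


def best_hits(hits: Iterable[AnnotationHit]) -> dict[str, AnnotationHit]:
    """One best hit per sequence: smallest evalue, ties broken by
    lexicographically smallest descriptor."""
    best: dict[str, AnnotationHit] = {}
    for h in hits:
        cur = best.get(h.seq_id)
        if cur is None or (h.evalue, h.descriptor) < (cur.evalue, cur.descriptor):
            best[h.seq_id] = h
    return best


def categorize_panel(
    candidates: Sequence[MarkerCandidate], hits: Iterable[AnnotationHit]
) -> Mapping[str, int]:
    """Panel partition into the three reporting bins:

    outside_homology  homology found, SSR before or after the region
    no_homology       no hit anywhere on the sequence
    within_homology   homology region overlapping the SSR
    """
    per_seq = best_hits(hits)
    counts: Counter[str] = Counter(
        {"outside_homology": 0, "no_homology": 0, "within_homology": 0}
    )
    for cand in candidates:
        cat = position_category(cand.locus, per_seq.get(cand.locus.seq_id))
        if cat in ("before", "after"):
            counts["outside_homology"] += 1
        elif cat == "no_homology":
            counts["no_homology"] += 1
        else:
            counts["within_homology"] += 1
    return dict(counts)


def load_annotation_table(path) -> list[AnnotationHit]:
    """Read a tab-separated annotation table:
    seq_id, descriptor, q_start, q_end, evalue."""
    hits: list[AnnotationHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("seq_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(
                    f"{path}: line {lineno}: expected 5 columns, got {len(fields)}"
                )
            hits.append(AnnotationHit(
                seq_id=fields[0], descriptor=fields[1],
                q_start=int(fields[2]), q_end=int(fields[3]),
                evalue=float(fields[4]),
            ))
    return hits


def write_annotation_table(hits: Sequence[AnnotationHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tdescriptor\tq_start\tq_end\tevalue\n")
        for h in hits:
            fh.write(f"{h.seq_id}\t{h.descriptor}\t{h.q_start}\t{h.q_end}\t{h.evalue:g}\n")
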