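"""Summary tabulations for marker panels.

Cross-tabulates markers by motif period class (di- through hepta-nucleotide)
and validation status, and computes the panel-level rates used to compare
marker sources:

* percent polymorphic is taken over the markers that amplified
  (polymorphic + monomorphic) — a property of the working markers;
* percent failure is taken over everything tested — a property of the
  design pipeline.

The two different denominators are deliberate and are the only reading
under which both published-style rate pairs are internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

PERIOD_CLASSES = ("di", "tri", "tetra", "penta", "hexa", "hepta")
STATUSES = ("polymorphic", "monomorphic", "failed")

_PERIOD_TO_CLASS = {p: c for p, c in zip(range(2, 8), PERIOD_CLASSES)}


def period_class(period: int) -> str:
    """Motif-class label for a period in [2, 7]."""
    try:
        return _PERIOD_TO_CLASS[period]
    except KeyError:
        raise ValueError(f"period must be in [2, 7], got {period}") from None


@dataclass(frozen=True)
class MarkerSummary:
    """status x period-class count matrix with class totals and percents."""

    counts: pd.DataFrame  # index: STATUSES, columns: PERIOD_CLASSES
    totals: pd.Series  # per period class
    percents: pd.Series  # per period class, 2-decimal, of the grand total
    grand_total: int


@dataclass(frozen=True)
class PanelRates:
    n_poly: int
    n_mono: int
    n_failed: int
    pct_polymorphic: float  # of amplified markers, 2 decimals
    pct_failure: float  # of all tested markers, 2 decimals

    @property
    def display(self) -> tuple[int, int]:
        """(percent polymorphic, percent failure) rounded to integers."""
        return (round(self.pct_polymorphic), round(self.pct_failure))


def motif_distribution(markers: Iterable[tuple[str, str]]) -> MarkerSummary:
    """Cross-tabulate (period_class, status) pairs.

    Accepts class labels from PERIOD_CLASSES and statuses from STATUSES;
    percents are each class's share of the grand total, rounded to 2
    decimals.
    """
    rows = list(markers)
    for cls, status in rows:
        if cls not in PERIOD_CLASSES:
            raise ValueError(f"unknown period class {cls!r}")
        if status not in STATUSES:
            raise ValueError(f"unknown status {status!r}")
    counts = pd.DataFrame(0, index=list(STATUSES), columns=list(PERIOD_CLASSES))
    for cls, status in rows:
        counts.loc[status, cls] += 1
    totals = counts.sum(axis=0)
    grand = int(totals.sum())
    percents = (totals / grand * 100).round(2) if grand else totals.astype(float)
    return MarkerSummary(counts=counts, totals=totals, percents=percents, grand_total=grand)


def summary_from_counts(counts: Mapping[str, Mapping[str, int]]) -> MarkerSummary:
    """MarkerSummary from a {status: {period_class: count}} mapping —
    convenient when tallies, not individual markers, are the input."""
    pairs: list[tuple[str, str]] = []
    for status, per_class in counts.items():
        for cls, n in per_class.items():
            pairs.extend([(cls, status)] * int(n))
    return motif_distribution(pairs)


def panel_rates(n_poly: int, n_mono: int, n_failed: int) -> PanelRates:
    """Polymorphism and failure rates of a tested marker panel."""
    if min(n_poly, n_mono, n_failed) < 0:
        raise ValueError("counts must be non-negative")
    amplified = n_poly + n_mono
    tested = amplified + n_failed
    return PanelRates(
        n_poly=n_poly,
        n_mono=n_mono,
        n_failed=n_failed,
        pct_polymorphic=round(100.0 * n_poly / amplified, 2) if amplified else 0.0,
        pct_failure=round(100.0 * n_failed / tested, 2) if tested else 0.0,
    )


def alignment_outcome_summary(
    n_zero: int, n_once: int, n_multi: int
) -> dict[str, float]:
    """Share of reads/tags aligning zero / exactly one / multiple times,
    as percentages of the total, rounded to 2 decimals."""
    total = n_zero + n_once + n_multi
    if total <= 0:
        raise ValueError("alignment outcome counts must sum to a positive total")
    return {
        "zero": round(100.0 * n_zero / total, 2),
        "once": round(100.0 * n_once / total, 2),
        "multi": round(100.0 * n_multi / total, 2),
    }


def write_summary_table(summary: MarkerSummary, path) -> None:
    """TSV rendering of a MarkerSummary (counts, totals, percents)."""
    with open(path, "w") as fh:
        fh.write("markers\t" + "\t".join(PERIOD_CLASSES) + "\ttotal\n")
        for status in STATUSES:
            row = summary.counts.loc[status]
            fh.write(status + "\t" + "\t".join(str(int(v)) for v in row)
                     + f"\t{int(row.sum())}\n")
        fh.write("total\t" + "\t".join(str(int(v)) for v in summary.totals)
                 + f"\t{summary.grand_total}\n")
        fh.write("percent\t" + "\t".join(f"{v:.2f}" for v in summary.percents) + "\t\n")


def summarize_calls(calls: Sequence, n_failed_by_class: Mapping[str, int] | None = None
                    ) -> MarkerSummary:
    """MarkerSummary from ComparisonCall objects (verdict -> status); calls
    with verdict no_match are omitted, and primer-design failures can be
    supplied per class via ``n_failed_by_class``."""
    pairs: list[tuple[str, str]] = []
    for c in calls:
        if c.verdict == "no_match":
            continue
        pairs.append((period_class(c.period), c.verdict))
    if n_failed_by_class:
        for cls, n in n_failed_by_class.items():
            pairs.extend([(cls, "failed")] * int(n))
    return motif_distribution(pairs)
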