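"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's algorithms: the SSR oracle tests
every (start, period) pair by direct character comparison, and the N50
oracle enumerates every candidate threshold in the length multiset.
"""

from __future__ import annotations


def oracle_is_primitive(motif: str) -> bool:
    return all(
        motif != motif[:d] * (len(motif) // d)
        for d in range(1, len(motif))
        if len(motif) % d == 0
    )


def oracle_ssrs(
    seq: str, min_period: int = 2, max_period: int = 7, min_tract: int = 20
) -> list[tuple[int, int, int, int]]:
    """All maximal perfect tandem tracts as (start, end, period, copies).

    For every start and period, extends the perfect repetition as far as it
    goes, keeps left-maximal runs only, counts whole copies, demands a
    primitive N-free motif, and finally drops loci contained in a
    smaller-period locus.  Sorted by (start, period).
    """
    n = len(seq)
    found: list[tuple[int, int, int, int]] = []
    for p in range(min_period, max_period + 1):
        for start in range(0, n - 2 * p + 1):
            # left-maximality: the run must not extend one base to the left
            if start > 0 and start - 1 + p < n and seq[start - 1] == seq[start - 1 + p]:
                continue
            m = 0
            while start + m + p < n and seq[start + m] == seq[start + m + p]:
                m += 1
            raw = m + p
            copies = raw // p
            tract = copies * p
            if copies < 2 or tract < min_tract:
                continue
            motif = seq[start : start + p]
            if not oracle_is_primitive(motif) or "N" in seq[start : start + raw]:
                continue
            found.append((start, start + tract, p, copies))
    found.sort(key=lambda t: (t[0], t[2]))
    return [
        loc for loc in found
        if not any(
            o[2] < loc[2] and o[0] <= loc[0] and loc[1] <= o[1]
            for o in found if o != loc
        )
    ]


def oracle_n50(lengths: list[int]) -> int:
    """Largest length L in the multiset whose >=L cumulative sum reaches
    half the total (enumerates every candidate threshold)."""
    total = sum(lengths)
    candidates = [
        L for L in set(lengths) if sum(x for x in lengths if x >= L) * 2 >= total
    ]
    return max(candidates)


def oracle_rotations(motif: str) -> list[str]:
    return [motif[i:] + motif[:i] for i in range(len(motif))]


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def oracle_keyword_excluded(
    hits: list[tuple[str, str, float]], blacklist: list[str], max_evalue: float
) -> set[str]:
    """(seq_id, descriptor, evalue) triples -> excluded ids, by the
    strip-non-alphanumerics / lowercase / substring rule."""

    def norm(s: str) -> str:
        return "".join(c for c in s.lower() if c.isalnum())

    keys = [norm(k) for k in blacklist]
    return {
        sid for sid, desc, ev in hits
        if ev <= max_evalue and any(k in norm(desc) for k in keys)
    }
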