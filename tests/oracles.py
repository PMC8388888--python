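"""Independent brute-force oracles used to cross-check the implementation.

Everything here works on explicit per-position sets or literal fixpoint
loops — deliberately naive, sharing no code with the package's sweep-based
implementations.
"""

from __future__ import annotations

from typing import Optional, Sequence

from astrx.model import FeatureTable, GenomicFeature


def positions(rec) -> set[int]:
    return set(range(rec.start, rec.end + 1))


def span_set(table: FeatureTable) -> set[tuple[int, int, str]]:
    return {(r.start, r.end, r.strand) for r in table.records}


def brute_overlap_len(a: tuple[int, int], b: tuple[int, int]) -> int:
    return len(set(range(a[0], a[1] + 1)) & set(range(b[0], b[1] + 1)))


def _gap(a: GenomicFeature, b: GenomicFeature) -> int:
    first, second = (a, b) if a.start <= b.start else (b, a)
    return second.start - first.end - 1


def _fixpoint_merge(records, can_merge) -> list[GenomicFeature]:
    """Literal fixpoint loop: merge the first mergeable sorted-adjacent pair,
    restart, until stable."""
    recs = sorted(records, key=lambda r: (r.start, r.end, r.id))
    changed = True
    n = 0
    while changed:
        changed = False
        for i in range(len(recs) - 1):
            a, b = recs[i], recs[i + 1]
            if can_merge(a, b):
                n += 1
                merged = GenomicFeature(
                    id=f"m{n}_{a.id}_{b.id}"[:80],
                    start=min(a.start, b.start),
                    end=max(a.end, b.end),
                    strand=a.strand,
                    ftype=a.ftype if a.ftype == b.ftype else "other",
                )
                recs = recs[:i] + [merged] + recs[i + 2 :]
                recs.sort(key=lambda r: (r.start, r.end, r.id))
                changed = True
                break
    return recs


def brute_merge_overlaps(table: FeatureTable) -> set[tuple[int, int, str]]:
    out = []
    for strand in ("+", "-"):
        out += _fixpoint_merge(
            table.on_strand(strand),
            lambda a, b: len(positions(a) & positions(b)) > 0,
        )
    return {(r.start, r.end, r.strand) for r in out}


def brute_merge_gap(table: FeatureTable, max_gap: int) -> set[tuple[int, int, str]]:
    out = []
    for strand in ("+", "-"):
        out += _fixpoint_merge(
            table.on_strand(strand), lambda a, b: _gap(a, b) <= max_gap
        )
    return {(r.start, r.end, r.strand) for r in out}


def brute_collapse(
    table: FeatureTable, coverage, max_gap: int, min_depth: int
) -> set[tuple[int, int, str]]:
    def can(a: GenomicFeature, b: GenomicFeature) -> bool:
        if a.ftype != "ncRNA" or b.ftype != "ncRNA":
            return False
        g = _gap(a, b)
        if g > max_gap:
            return False
        if g <= 0:
            return True
        first, second = (a, b) if a.start <= b.start else (b, a)
        track = coverage.plus if a.strand == "+" else coverage.minus
        return all(
            track[p - 1] >= min_depth for p in range(first.end + 1, second.start)
        )

    out = []
    for strand in ("+", "-"):
        out += _fixpoint_merge(table.on_strand(strand), can)
    return {(r.start, r.end, r.strand) for r in out}


def brute_nearest(table: FeatureTable) -> dict[str, Optional[int]]:
    result: dict[str, Optional[int]] = {}
    for rec in table.records:
        best: Optional[int] = None
        for other in table.records:
            if other is rec or other.strand != rec.strand:
                continue
            d = max(0, _gap(rec, other))
            best = d if best is None else min(best, d)
        result[rec.id] = best
    return result


def brute_classify(candidate, opposite_features) -> tuple[str, float, set[str]]:
    """(class, containment fraction, target id set) by per-position counting."""
    cand = positions(candidate)
    covered: set[int] = set()
    targets: set[str] = set()
    for feat in opposite_features:
        if feat.strand == candidate.strand:
            continue
        shared = cand & positions(feat)
        if shared:
            covered |= shared
            targets.add(feat.id)
    if not targets:
        return "sRNA", 0.0, set()
    return "asRNA_I", len(covered) / len(cand), targets


def brute_pairs(tus, geometry: str) -> set[tuple[str, str, int, int]]:
    """All qualifying unordered terminal-overlap pairs, by position sets."""
    found = set()
    for i, a in enumerate(tus):
        for b in tus[i + 1 :]:
            if a.strand == b.strand:
                continue
            shared = set(range(a.start, a.end + 1)) & set(range(b.start, b.end + 1))
            if not shared:
                continue
            a_in = a.start in shared and a.end in shared
            b_in = b.start in shared and b.end in shared
            if a_in or b_in:  # containment: class-I geometry, no pair
                continue
            term = (
                (a.five_prime(), b.five_prime())
                if geometry == "divergent"
                else (a.three_prime(), b.three_prime())
            )
            if term[0] in shared and term[1] in shared:
                key = tuple(sorted((a.id, b.id))) + (min(shared), max(shared))
                found.add(key)
    return found
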