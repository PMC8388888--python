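"""Antisense classification of non-coding transcripts and TU pairs.

Three geometric classes of cis-antisense transcription are distinguished:

* **asRNA I** — a standalone non-coding transcript (own promoter) that
  overlaps >= 1 annotated feature on the opposite strand; a candidate with
  no opposite-strand overlap is a trans-encoded **sRNA**.
* **asRNA II** — divergent transcription: two opposite-strand gene-bearing
  TUs whose intersection contains the 5' terminus of both.
* **asRNA III (cutoRNA)** — convergent read-through: the intersection
  contains the 3' terminus of both units.

A TU fully contained in an opposite-strand TU has both of its termini in
the intersection and is emitted as neither class II nor III; containment is
the class-I cartoon and is handled by the candidate classifier instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .model import (
    AntisensePair,
    FeatureTable,
    GenomicFeature,
    NcRNARecord,
    TranscriptionalUnit,
    ValidationError,
)

CONTAINMENT_REPORT_THRESHOLD = 0.90

Interval = tuple[int, int]
Spanned = Union[GenomicFeature, TranscriptionalUnit, NcRNARecord]


def overlap_length(a: Interval, b: Interval) -> int:
    """Shared positions between two closed intervals (0 when disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def overlap_interval(a: Interval, b: Interval) -> Optional[Interval]:
    s, e = max(a[0], b[0]), min(a[1], b[1])
    return (s, e) if s <= e else None


@dataclass(frozen=True)
class AnnotationIndex:
    """Opposite-strand lookup context for candidate classification.

    ``tus`` are the gene-bearing units; ``genes`` the original annotated
    genes (CDS extents) plus any tRNA/pseudogene features; ``ncrna_units``
    the other gene-free candidate spans.
    """

    tus: tuple[TranscriptionalUnit, ...]
    genes: tuple[GenomicFeature, ...] = ()
    ncrna_units: tuple[TranscriptionalUnit, ...] = ()


def _target_kind_positions(
    candidate: Spanned, tu: TranscriptionalUnit, genes_by_id: dict[str, GenomicFeature]
) -> dict[str, int]:
    """Split a candidate/TU overlap into CDS vs UTR vs within-operon nt."""
    ov = overlap_interval(candidate.interval, tu.interval)
    assert ov is not None
    total = ov[1] - ov[0] + 1
    cds = 0
    for gid in tu.gene_ids:
        g = genes_by_id.get(gid)
        if g is not None:
            cds += overlap_length(ov, g.interval)
    non_cds = total - cds
    out: dict[str, int] = {}
    if cds:
        out["CDS"] = cds
    if non_cds:
        # non-CDS TU positions are UTR overhangs at the unit ends or
        # intercistronic (within_operon) stretches between member genes
        members = [genes_by_id[g] for g in tu.gene_ids if g in genes_by_id]
        if members:
            inner_start = min(g.start for g in members)
            inner_end = max(g.end for g in members)
            utr_nt = sum(
                overlap_length(ov, seg)
                for seg in ((tu.start, inner_start - 1), (inner_end + 1, tu.end))
                if seg[0] <= seg[1]
            )
            within = non_cds - utr_nt
            if utr_nt:
                out["UTR"] = utr_nt
            if within:
                out["within_operon"] = within
        else:
            out["UTR"] = non_cds
    return out


def classify_ncrna(
    candidate: Spanned,
    annotation: AnnotationIndex,
    containment_threshold: float = CONTAINMENT_REPORT_THRESHOLD,
) -> NcRNARecord:
    """Classify one surviving non-coding transcript as sRNA or asRNA I.

    The candidate is asRNA I iff it overlaps >= 1 opposite-strand annotated
    feature; targets and per-target overlaps are listed, the containment
    fraction is the portion of the candidate covered by any target, and
    target types follow the taxonomy CDS / UTR / within_operon / tRNA /
    pseudogene / ncRNA (plus "mixed" when more than one kind is hit).
    """
    genes_by_id = {g.id: g for g in annotation.genes}
    cand_iv = candidate.interval
    same_strand_hits = [
        g
        for g in annotation.genes
        if g.strand == candidate.strand
        and g.ftype == "gene"
        and overlap_length(cand_iv, g.interval) > 0
    ]
    if same_strand_hits:
        raise ValidationError(
            f"candidate {candidate.id!r} overlaps same-strand gene(s) "
            f"{[g.id for g in same_strand_hits]}; it should have been merged or "
            "trimmed by the re-annotation cascade"
        )

    length = cand_iv[1] - cand_iv[0] + 1
    covered = np.zeros(length, dtype=bool)
    targets: list[tuple[str, int]] = []
    kinds: set[str] = set()

    def note(interval: Interval) -> None:
        ov = overlap_interval(cand_iv, interval)
        if ov:
            covered[ov[0] - cand_iv[0] : ov[1] - cand_iv[0] + 1] = True

    in_tu_genes: set[str] = set()
    for tu in annotation.tus:
        if tu.strand == candidate.strand:
            continue
        ov_len = overlap_length(cand_iv, tu.interval)
        if ov_len == 0:
            continue
        targets.append((tu.id, ov_len))
        note(tu.interval)
        for kind, nt in _target_kind_positions(candidate, tu, genes_by_id).items():
            if nt:
                kinds.add(kind)
        in_tu_genes.update(tu.gene_ids)
    for g in annotation.genes:
        if g.strand == candidate.strand or g.id in in_tu_genes:
            continue
        ov_len = overlap_length(cand_iv, g.interval)
        if ov_len == 0:
            continue
        targets.append((g.id, ov_len))
        note(g.interval)
        kinds.add({"tRNA": "tRNA", "pseudogene": "pseudogene", "gene": "CDS"}.get(g.ftype, g.ftype))
    for unit in annotation.ncrna_units:
        if unit.strand == candidate.strand or unit.id == candidate.id:
            continue
        ov_len = overlap_length(cand_iv, unit.interval)
        if ov_len == 0:
            continue
        targets.append((unit.id, ov_len))
        note(unit.interval)
        kinds.add("ncRNA")

    if not targets:
        return NcRNARecord(
            id=candidate.id,
            start=cand_iv[0],
            end=cand_iv[1],
            strand=candidate.strand,
            ncclass="sRNA",
        )
    if len(kinds) > 1:
        kinds.add("mixed")
    return NcRNARecord(
        id=candidate.id,
        start=cand_iv[0],
        end=cand_iv[1],
        strand=candidate.strand,
        ncclass="asRNA_I",
        targets=tuple(sorted(targets)),
        containment_frac=float(covered.sum()) / length,
        target_types=frozenset(kinds),
    )


def below_containment_threshold(
    record: NcRNARecord, threshold: float = CONTAINMENT_REPORT_THRESHOLD
) -> bool:
    """Report flag: asRNA covering < ``threshold`` of its length on targets."""
    return record.ncclass == "asRNA_I" and record.containment_frac < threshold


def _terminal_pairs(
    tus: Sequence[TranscriptionalUnit], terminus: str
) -> list[AntisensePair]:
    """Shared detector for divergent (5') and convergent (3') pairs."""
    geometry = "divergent" if terminus == "5" else "convergent"
    plus = sorted((t for t in tus if t.strand == "+"), key=lambda t: t.start)
    minus = sorted((t for t in tus if t.strand == "-"), key=lambda t: t.start)
    pairs: list[AntisensePair] = []
    for p in plus:
        for m in minus:
            if m.start > p.end:
                break
            ov = overlap_interval(p.interval, m.interval)
            if ov is None:
                continue
            # full containment: both termini of the inner unit fall inside
            # the intersection -> class-I geometry, not a terminal pair
            if (p.start >= m.start and p.end <= m.end) or (
                m.start >= p.start and m.end <= p.end
            ):
                continue
            p_term = p.five_prime() if terminus == "5" else p.three_prime()
            m_term = m.five_prime() if terminus == "5" else m.three_prime()
            if ov[0] <= p_term <= ov[1] and ov[0] <= m_term <= ov[1]:
                pairs.append(
                    AntisensePair(
                        tu_a=p.id,
                        tu_b=m.id,
                        geometry=geometry,
                        overlap_start=ov[0],
                        overlap_end=ov[1],
                    )
                )
    pairs.sort(key=lambda pr: (pr.overlap_start, pr.overlap_end, pr.tu_a, pr.tu_b))
    return pairs


def detect_divergent_pairs(
    tus: Sequence[TranscriptionalUnit],
) -> list[AntisensePair]:
    """Opposite-strand TU pairs whose intersection holds both 5' termini."""
    return _terminal_pairs(tus, "5")


def detect_convergent_pairs(
    tus: Sequence[TranscriptionalUnit],
) -> list[AntisensePair]:
    """Opposite-strand TU pairs whose intersection holds both 3' termini."""
    return _terminal_pairs(tus, "3")


def summarize_classes(
    ncrnas: Sequence[NcRNARecord],
    pairs: Sequence[AntisensePair],
) -> dict:
    """Class counts, median lengths / overlap lengths and position lists."""

    def med(values: list) -> Optional[float]:
        return float(np.median(values)) if values else None

    srna = [r for r in ncrnas if r.ncclass == "sRNA"]
    asrna1 = [r for r in ncrnas if r.ncclass == "asRNA_I"]
    div = [p for p in pairs if p.geometry == "divergent"]
    conv = [p for p in pairs if p.geometry == "convergent"]
    return {
        "sRNA": {
            "count": len(srna),
            "median_length": med([r.length for r in srna]),
            "positions": [r.interval for r in srna],
        },
        "asRNA_I": {
            "count": len(asrna1),
            "median_length": med([r.length for r in asrna1]),
            "median_overlap_length": med([r.total_overlap() for r in asrna1]),
            "positions": [r.interval for r in asrna1],
        },
        "asRNA_II": {
            "count": len(div),
            "median_overlap_length": med([p.overlap_len for p in div]),
            "positions": [(p.overlap_start, p.overlap_end) for p in div],
        },
        "asRNA_III": {
            "count": len(conv),
            "median_overlap_length": med([p.overlap_len for p in conv]),
            "positions": [(p.overlap_start, p.overlap_end) for p in conv],
        },
    }


def classify_catalog(
    candidates: Sequence[TranscriptionalUnit],
    annotation: AnnotationIndex,
) -> list[NcRNARecord]:
    """Classify every gene-free candidate span against the annotation."""
    return [classify_ncrna(c, annotation) for c in candidates]
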