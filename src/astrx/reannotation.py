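"""Transcriptome re-annotation for a linear bacterial chromosome.

Per-timepoint transcript predictions (UTR-extended gene spans plus ncRNA
calls) are pooled and cleaned by a deterministic cascade:

1. same-strand overlap merging within each list,
2. pooling of the two lists with UTR/gene priority over ncRNA calls,
3. merging of same-strand neighbours separated by <= 15 nt,
4. collapsing of same-strand ncRNA neighbours separated by <= 500 nt when
   the strand-matched coverage track is continuous across the gap,
5. exclusion of ncRNA calls that fall mostly inside duplicated regions
   (inverted repeats force reads onto one copy and create false antisense
   predictions),
6. assembly of transcriptional units from the cleaned spans.

Gap convention: for 1-based closed intervals A before B on the same strand,
``gap(A, B) = B.start - A.end - 1`` (the count of intervening nucleotides);
overlapping intervals have a negative gap and abutting ones gap 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import (
    FeatureTable,
    GenomicFeature,
    StrandedCoverage,
    TranscriptionalUnit,
    ValidationError,
    concat_tables,
)

logger = logging.getLogger(__name__)

DEFAULT_MERGE_GAP = 15
DEFAULT_COLLAPSE_GAP = 500
DEFAULT_MIN_DEPTH = 1
DEFAULT_REPEAT_OVERLAP_FRAC = 0.5
TU_GENE_COUNT_WARNING = 25


def gap_between(a: GenomicFeature, b: GenomicFeature) -> int:
    """Nucleotides strictly between two intervals (negative if overlapping)."""
    first, second = (a, b) if a.start <= b.start else (b, a)
    return second.start - first.end - 1


def _merged_id(ids: Iterable[str]) -> str:
    # strip "@n" disambiguation suffixes added by concat_tables
    base = {i.split("@", 1)[0] for i in ids}
    return "|".join(sorted(base))


def _merged_ftype(ftypes: Sequence[str]) -> str:
    distinct = set(ftypes)
    if len(distinct) == 1:
        return next(iter(distinct))
    utr = [t for t in ftypes if t in ("UTR5", "UTR3")]
    if utr:
        return utr[0]
    if "gene" in distinct:
        return "gene"
    return "other"


def _merge_cluster(cluster: list[GenomicFeature]) -> GenomicFeature:
    return GenomicFeature(
        id=_merged_id(r.id for r in cluster),
        start=min(r.start for r in cluster),
        end=max(r.end for r in cluster),
        strand=cluster[0].strand,
        ftype=_merged_ftype([r.ftype for r in cluster]),
        timepoints=frozenset().union(*(r.timepoints for r in cluster)),
    )


def _merge_by_gap_threshold(
    features: FeatureTable, max_gap: int, mergeable=None
) -> FeatureTable:
    """Union same-strand neighbours with gap <= max_gap, to fixpoint.

    After sorting by start within a strand, transitive closure over the gap
    relation equals a single left-to-right sweep. ``mergeable(a, b)``
    optionally restricts which adjacent cluster/feature pairs may join.
    """
    out: list[GenomicFeature] = []
    for strand in ("+", "-"):
        recs = sorted(
            features.on_strand(strand), key=lambda r: (r.start, r.end, r.id)
        )
        cluster: list[GenomicFeature] = []
        for rec in recs:
            if not cluster:
                cluster = [rec]
                continue
            merged = _merge_cluster(cluster)
            if gap_between(merged, rec) <= max_gap and (
                mergeable is None or mergeable(merged, rec)
            ):
                cluster.append(rec)
            else:
                out.append(merged)
                cluster = [rec]
        if cluster:
            out.append(_merge_cluster(cluster))
    out.sort(key=lambda r: (r.strand, r.start, r.end, r.id))
    return features.replace_records(out)


def merge_same_strand_overlaps(features: FeatureTable) -> FeatureTable:
    """Replace same-strand intervals sharing >= 1 position by their union.

    Opposite strands are never merged; abutting intervals (gap 0) are left
    for the gap rule. Resolves small start/end inconsistencies between
    per-timepoint predictions of the same element.
    """
    return _merge_by_gap_threshold(features, max_gap=-1)


def merge_within_gap(
    features: FeatureTable, max_gap: int = DEFAULT_MERGE_GAP
) -> FeatureTable:
    """Union same-strand neighbours separated by <= ``max_gap`` nucleotides.

    Repairs the upstream predictor's tendency to split long UTRs and long
    ncRNAs into adjacent records separated by few or no nucleotides.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    return _merge_by_gap_threshold(features, max_gap=max_gap)


def pool_with_utr_priority(
    genes_extended: FeatureTable, ncrnas: FeatureTable
) -> FeatureTable:
    """Pool UTR-extended gene spans with ncRNA calls, gene/UTR span winning.

    Where an ncRNA call overlaps a same-strand extended gene span, the
    overlapped portion is ceded to the gene list: fully contained calls are
    dropped, partial overlaps are trimmed to the non-overlapping remainder
    (one record per remaining contiguous segment). Gene records are never
    altered.
    """
    if (
        genes_extended.chromosome_id != ncrnas.chromosome_id
        or genes_extended.chromosome_length != ncrnas.chromosome_length
    ):
        raise ValidationError("gene and ncRNA tables refer to different chromosomes")
    pooled: list[GenomicFeature] = list(genes_extended.records)
    spans = {
        strand: sorted(
            (r.start, r.end) for r in genes_extended.on_strand(strand)
        )
        for strand in ("+", "-")
    }
    for nc in ncrnas.records:
        segments = _subtract_intervals(nc.interval, spans[nc.strand])
        if len(segments) == 1 and segments[0] == nc.interval:
            pooled.append(nc)
        elif not segments:
            logger.debug("ncRNA %s dropped: contained in an extended gene span", nc.id)
        else:
            for i, (s, e) in enumerate(segments):
                seg_id = nc.id if len(segments) == 1 else f"{nc.id}.{i + 1}"
                pooled.append(replace(nc, id=seg_id, start=s, end=e))
    pooled.sort(key=lambda r: (r.strand, r.start, r.end, r.id))
    return genes_extended.replace_records(pooled)


def _subtract_intervals(
    interval: tuple[int, int], blockers: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Closed-interval set difference, returning maximal remaining segments."""
    segments: list[tuple[int, int]] = []
    cursor, end = interval
    for bs, be in blockers:
        if be < cursor or bs > end:
            continue
        if bs > cursor:
            segments.append((cursor, bs - 1))
        cursor = max(cursor, be + 1)
        if cursor > end:
            break
    if cursor <= end:
        segments.append((cursor, end))
    return segments


def collapse_by_coverage(
    features: FeatureTable,
    coverage: StrandedCoverage,
    max_gap: int = DEFAULT_COLLAPSE_GAP,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> FeatureTable:
    """Collapse nearby same-strand ncRNAs bridged by continuous coverage.

    Two ncRNA neighbours with gap <= ``max_gap`` are unioned iff every
    intervening position has strand-matched depth >= ``min_depth``; applied
    to fixpoint. Only ncRNA-type records collapse; other feature types pass
    through untouched and never join a collapse cluster.
    """
    if coverage.chromosome_length != features.chromosome_length:
        raise ValidationError("coverage length does not match chromosome")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")

    def continuous(a: GenomicFeature, b: GenomicFeature) -> bool:
        if a.ftype != "ncRNA" or b.ftype != "ncRNA":
            return False
        g = gap_between(a, b)
        if g <= 0:
            return True
        first, second = (a, b) if a.start <= b.start else (b, a)
        depths = coverage.depth_slice(a.strand, first.end + 1, second.start - 1)
        return bool((depths >= min_depth).all())

    return _merge_by_gap_threshold(features, max_gap=max_gap, mergeable=continuous)


def exclude_repeat_artifacts(
    ncrnas: FeatureTable,
    repeats: Sequence[tuple[int, int]],
    min_overlap_frac: float = DEFAULT_REPEAT_OVERLAP_FRAC,
) -> tuple[FeatureTable, FeatureTable]:
    """Partition ncRNAs into (kept, excluded) by repeat-region overlap.

    A record whose overlap with the union of repeat intervals covers
    >= ``min_overlap_frac`` of its own length is excluded: predictions over
    duplicated genes/regions are untrustworthy because multi-mapping reads
    are forced onto one copy, producing false antisense calls.
    """
    for s, e in repeats:
        if not (1 <= s <= e):
            raise ValidationError(f"invalid repeat interval [{s}, {e}]")
    merged_repeats = _merge_plain_intervals(repeats)
    kept: list[GenomicFeature] = []
    excluded: list[GenomicFeature] = []
    for rec in ncrnas.records:
        overlap = sum(
            max(0, min(rec.end, re) - max(rec.start, rs) + 1)
            for rs, re in merged_repeats
        )
        if merged_repeats and overlap / rec.length >= min_overlap_frac:
            excluded.append(rec)
        else:
            kept.append(rec)
    if excluded:
        logger.info(
            "excluded %d ncRNA call(s) overlapping duplicated regions: %s",
            len(excluded),
            ", ".join(r.id for r in excluded),
        )
    return ncrnas.replace_records(kept), ncrnas.replace_records(excluded)


def _merge_plain_intervals(
    intervals: Sequence[tuple[int, int]],
) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def assemble_tus(
    pooled: FeatureTable,
    original_genes: FeatureTable,
    return_orphans: bool = False,
):
    """Turn cleaned transcript spans into transcriptional units.

    Each non-ncRNA span becomes one TU owning the original genes it fully
    contains on its own strand, in coordinate order; UTR lengths are the
    span's overhangs beyond the outermost member genes. Spans containing no
    gene are ncRNA-unit candidates for antisense classification (also
    returned as TUs with ``kind == "ncRNA_unit"``).
    """
    tus: list[TranscriptionalUnit] = []
    owner: dict[str, str] = {}
    genes_by_strand = {
        strand: sorted(original_genes.on_strand(strand), key=lambda g: g.start)
        for strand in ("+", "-")
    }
    spans = sorted(pooled.records, key=lambda r: (r.strand, r.start, r.end))
    for strand in ("+", "-"):
        prev_end = None
        for rec in (r for r in spans if r.strand == strand):
            if prev_end is not None and rec.start <= prev_end:
                raise ValidationError(
                    f"spans overlap on strand {strand} near {rec.start}; "
                    "run the merge cascade before TU assembly"
                )
            prev_end = rec.end
    counter = 0
    for rec in spans:
        members = [
            g
            for g in genes_by_strand[rec.strand]
            if g.start >= rec.start and g.end <= rec.end
        ]
        for g in members:
            if g.id in owner:
                raise ValidationError(
                    f"gene {g.id!r} contained in two TU spans "
                    f"({owner[g.id]!r} and {rec.id!r})"
                )
        counter += 1
        if members:
            first, last = members[0], members[-1]
            left = first.start - rec.start
            right = rec.end - last.end
            utr5, utr3 = (left, right) if rec.strand == "+" else (right, left)
            ordered = members if rec.strand == "+" else members[::-1]
            tu = TranscriptionalUnit(
                id=f"TU_{counter:05d}",
                start=rec.start,
                end=rec.end,
                strand=rec.strand,
                gene_ids=tuple(g.id for g in ordered),
                utr5_len=utr5,
                utr3_len=utr3,
            )
            if tu.n_genes > TU_GENE_COUNT_WARNING:
                logger.warning(
                    "TU %s contains %d genes (> %d); check for runaway merging",
                    tu.id,
                    tu.n_genes,
                    TU_GENE_COUNT_WARNING,
                )
            for g in members:
                owner[g.id] = rec.id
        else:
            tu = TranscriptionalUnit(
                id=f"TU_{counter:05d}",
                start=rec.start,
                end=rec.end,
                strand=rec.strand,
            )
        tus.append(tu)
    orphans = [g.id for g in original_genes.records if g.id not in owner]
    if orphans:
        logger.warning("%d gene(s) not contained in any TU span: %s", len(orphans), orphans)
    if return_orphans:
        return tus, orphans
    return tus


def transcriptome_genome_fraction(
    tus: Sequence[TranscriptionalUnit],
    ncrnas: Optional[FeatureTable],
    chromosome_length: int,
) -> float:
    """Fraction of chromosome positions transcribed on either strand.

    Positions transcribed on both strands count once.
    """
    covered = np.zeros(chromosome_length, dtype=bool)
    for tu in tus:
        covered[tu.start - 1 : tu.end] = True
    if ncrnas is not None:
        for rec in ncrnas.records:
            covered[rec.start - 1 : rec.end] = True
    return float(covered.sum()) / chromosome_length


def nearest_same_strand_distance(
    features: FeatureTable,
) -> dict[str, Optional[int]]:
    """Distance from each feature to its nearest same-strand neighbour.

    Distance is the gap (intervening nucleotides), clamped at 0 for
    overlapping or abutting neighbours. A feature alone on its strand maps
    to ``None``.
    """
    distances: dict[str, Optional[int]] = {}
    for strand in ("+", "-"):
        recs = sorted(features.on_strand(strand), key=lambda r: (r.start, r.end, r.id))
        n = len(recs)
        if n == 1:
            distances[recs[0].id] = None
            continue
        # left neighbour gap via running max of ends; right via next start
        max_end_before = [0] * n
        running = None
        for i, rec in enumerate(recs):
            max_end_before[i] = running if running is not None else -1
            running = rec.end if running is None else max(running, rec.end)
        for i, rec in enumerate(recs):
            best: Optional[int] = None
            if i > 0:
                best = max(0, rec.start - max_end_before[i] - 1)
            if i < n - 1:
                right = max(0, recs[i + 1].start - rec.end - 1)
                best = right if best is None else min(best, right)
            distances[rec.id] = best
    return distances


# ---------------------------------------------------------------------------
# the full cascade


@dataclass
class ReannotationResult:
    """Outcome of the full cascade."""

    pooled: FeatureTable  # cleaned transcript spans (genes/UTRs + kept ncRNAs)
    excluded: FeatureTable  # ncRNA calls removed by the repeat rule
    tus: list[TranscriptionalUnit]
    orphan_genes: list[str]

    @property
    def gene_tus(self) -> list[TranscriptionalUnit]:
        return [t for t in self.tus if t.n_genes > 0]

    @property
    def ncrna_candidates(self) -> list[TranscriptionalUnit]:
        return [t for t in self.tus if t.n_genes == 0]

    def summary(self) -> dict:
        gene_tus = self.gene_tus
        mono = [t for t in gene_tus if t.kind == "monocistronic"]
        poly = [t for t in gene_tus if t.kind == "polycistronic"]
        return {
            "n_tus": len(gene_tus),
            "n_monocistronic": len(mono),
            "n_polycistronic": len(poly),
            "max_genes_per_tu": max((t.n_genes for t in gene_tus), default=0),
            "n_ncrna_candidates": len(self.ncrna_candidates),
            "n_excluded_repeat_artifacts": len(self.excluded),
            "median_monocistronic_length": _median([t.length for t in mono]),
            "median_polycistronic_length": _median([t.length for t in poly]),
        }


def _median(values: Sequence[float]) -> Optional[float]:
    return float(np.median(values)) if len(values) else None


def reannotate(
    predictions: Sequence[tuple[FeatureTable, FeatureTable]],
    original_genes: FeatureTable,
    coverage: Optional[StrandedCoverage] = None,
    repeats: Sequence[tuple[int, int]] = (),
    max_gap: int = DEFAULT_MERGE_GAP,
    collapse_gap: int = DEFAULT_COLLAPSE_GAP,
    min_depth: int = DEFAULT_MIN_DEPTH,
    repeat_overlap_frac: float = DEFAULT_REPEAT_OVERLAP_FRAC,
) -> ReannotationResult:
    """Run the full re-annotation cascade.

    ``predictions`` holds per-timepoint (extended-genes, ncRNAs) table
    pairs. Per-timepoint tables are individually overlap-merged, then
    concatenated per list, and the cascade runs once on the pool.
    """
    merged_gene_tables = [merge_same_strand_overlaps(g) for g, _ in predictions]
    merged_nc_tables = [merge_same_strand_overlaps(n) for _, n in predictions]
    genes = merge_same_strand_overlaps(concat_tables(merged_gene_tables))
    ncrnas = merge_same_strand_overlaps(concat_tables(merged_nc_tables))

    pooled = pool_with_utr_priority(genes, ncrnas)
    pooled = merge_within_gap(pooled, max_gap=max_gap)
    if coverage is not None:
        pooled = collapse_by_coverage(
            pooled, coverage, max_gap=collapse_gap, min_depth=min_depth
        )
    nc_part = pooled.of_type("ncRNA")
    other_part = pooled.of_type("gene", "UTR5", "UTR3", "tRNA", "pseudogene", "other")
    kept_nc, excluded = exclude_repeat_artifacts(
        nc_part, repeats, min_overlap_frac=repeat_overlap_frac
    )
    cleaned = pooled.replace_records(
        sorted(
            list(other_part.records) + list(kept_nc.records),
            key=lambda r: (r.strand, r.start, r.end, r.id),
        )
    )
    tus, orphans = assemble_tus(cleaned, original_genes, return_orphans=True)
    return ReannotationResult(
        pooled=cleaned, excluded=excluded, tus=tus, orphan_genes=orphans
    )
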