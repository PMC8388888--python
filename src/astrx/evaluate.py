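"""Comparison of a re-annotation run against synthetic ground truth.

Features are matched by exact (start, end, strand) span — the recovery
claim is exactness, not tolerance — and classified catalogs additionally
by class label. Precision/recall are reported per feature kind.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .antisense import (
    AnnotationIndex,
    classify_catalog,
    detect_convergent_pairs,
    detect_divergent_pairs,
)
from .model import NcRNARecord, TranscriptionalUnit
from .reannotation import ReannotationResult
from .simulate import SyntheticTruth


@dataclass
class RecoveryReport:
    tu_true: int
    tu_recovered: int
    tu_matched: int
    ncrna_true: int
    ncrna_recovered: int
    ncrna_matched: int  # span + class label both correct
    pairs_true: int
    pairs_recovered: int
    pairs_matched: int

    @property
    def tu_precision(self) -> float:
        return self.tu_matched / self.tu_recovered if self.tu_recovered else float("nan")

    @property
    def tu_recall(self) -> float:
        return self.tu_matched / self.tu_true if self.tu_true else float("nan")

    @property
    def ncrna_precision(self) -> float:
        return (
            self.ncrna_matched / self.ncrna_recovered
            if self.ncrna_recovered
            else float("nan")
        )

    @property
    def ncrna_recall(self) -> float:
        return self.ncrna_matched / self.ncrna_true if self.ncrna_true else float("nan")

    @property
    def exact(self) -> bool:
        return (
            self.tu_matched == self.tu_true == self.tu_recovered
            and self.ncrna_matched == self.ncrna_true == self.ncrna_recovered
            and self.pairs_matched == self.pairs_true == self.pairs_recovered
        )


def _tu_key(tu: TranscriptionalUnit) -> tuple:
    return (tu.start, tu.end, tu.strand, tu.gene_ids, tu.utr5_len, tu.utr3_len)


def _nc_key(nc: NcRNARecord) -> tuple:
    return (nc.start, nc.end, nc.strand, nc.ncclass)


def classify_result(
    result: ReannotationResult,
) -> tuple[list[NcRNARecord], list, list]:
    """Classify a re-annotation result's candidates and detect TU pairs."""
    gene_tus = result.gene_tus
    candidates = result.ncrna_candidates
    annotation = AnnotationIndex(
        tus=tuple(gene_tus),
        genes=(),
        ncrna_units=tuple(candidates),
    )
    catalog = classify_catalog(candidates, annotation)
    return (
        catalog,
        detect_divergent_pairs(gene_tus),
        detect_convergent_pairs(gene_tus),
    )


def compare_to_truth(
    truth: SyntheticTruth,
    result: ReannotationResult,
    catalog: Sequence[NcRNARecord],
    divergent: Sequence,
    convergent: Sequence,
) -> RecoveryReport:
    """Exact-span recovery report against the synthetic ground truth.

    TUs match on (span, strand, member gene ids in 5'->3' order, UTR
    lengths); ncRNAs on (span, strand, class label); pairs on (geometry,
    overlap interval).
    """
    true_tus = {_tu_key(t) for t in truth.tus}
    rec_tus = {_tu_key(t) for t in result.gene_tus}
    true_nc = {_nc_key(n) for n in truth.ncrnas}
    rec_nc = {_nc_key(n) for n in catalog}

    def pair_key(p) -> tuple:
        return (p.geometry, p.overlap_start, p.overlap_end)

    true_pairs = {pair_key(p) for p in truth.divergent_pairs} | {
        pair_key(p) for p in truth.convergent_pairs
    }
    rec_pairs = {pair_key(p) for p in divergent} | {pair_key(p) for p in convergent}

    return RecoveryReport(
        tu_true=len(true_tus),
        tu_recovered=len(rec_tus),
        tu_matched=len(true_tus & rec_tus),
        ncrna_true=len(true_nc),
        ncrna_recovered=len(rec_nc),
        ncrna_matched=len(true_nc & rec_nc),
        pairs_true=len(true_pairs),
        pairs_recovered=len(rec_pairs),
        pairs_matched=len(true_pairs & rec_pairs),
    )
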