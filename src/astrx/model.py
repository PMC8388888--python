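"""Core in-memory containers for the stranded-interval pipeline.

All coordinates are 1-based, closed intervals ``[start, end]`` with
``start <= end``, matching GFF3. BED-style half-open inputs are converted
at the I/O boundary. Every feature carries a mandatory strand because each
rule in the re-annotation cascade is strand-conditional.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

FEATURE_TYPES = frozenset(
    {"gene", "UTR5", "UTR3", "ncRNA", "tRNA", "pseudogene", "other"}
)
STRANDS = ("+", "-")


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass(frozen=True)
class GenomicFeature:
    """One stranded interval on the chromosome.

    ``timepoints`` records the growth timepoints (hours) at which the
    feature was predicted; it is unioned when features merge.
    """

    id: str
    start: int
    end: int
    strand: str
    ftype: str = "other"
    timepoints: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(
                f"feature {self.id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.ftype not in FEATURE_TYPES:
            raise ValidationError(
                f"feature {self.id!r}: unknown feature type {self.ftype!r}"
            )
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"feature {self.id!r}: invalid interval [{self.start}, {self.end}]"
            )
        object.__setattr__(self, "timepoints", frozenset(self.timepoints))

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def five_prime(self) -> int:
        """Chromosomal coordinate of the 5' terminus (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass
class FeatureTable:
    """Ordered collection of features on one chromosome."""

    records: list[GenomicFeature]
    chromosome_id: str
    chromosome_length: int

    def __post_init__(self) -> None:
        if self.chromosome_length < 1:
            raise ValidationError("chromosome_length must be positive")
        seen: set[str] = set()
        for rec in self.records:
            if rec.end > self.chromosome_length:
                raise ValidationError(
                    f"feature {rec.id!r} interval [{rec.start}, {rec.end}] exceeds "
                    f"chromosome length {self.chromosome_length}"
                )
            if rec.id in seen:
                raise ValidationError(f"duplicate feature id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GenomicFeature]:
        return iter(self.records)

    def sorted(self) -> "FeatureTable":
        recs = sorted(self.records, key=lambda r: (r.strand, r.start, r.end, r.id))
        return FeatureTable(recs, self.chromosome_id, self.chromosome_length)

    def on_strand(self, strand: str) -> list[GenomicFeature]:
        return [r for r in self.records if r.strand == strand]

    def of_type(self, *ftypes: str) -> "FeatureTable":
        recs = [r for r in self.records if r.ftype in ftypes]
        return FeatureTable(recs, self.chromosome_id, self.chromosome_length)

    def replace_records(self, records: Sequence[GenomicFeature]) -> "FeatureTable":
        return FeatureTable(list(records), self.chromosome_id, self.chromosome_length)


def concat_tables(tables: Iterable[FeatureTable]) -> FeatureTable:
    """Concatenate tables over the same chromosome.

    Colliding ids (the same feature predicted at several timepoints) are
    disambiguated with an ``@<n>`` suffix; merging later unions them back.
    """
    tables = list(tables)
    if not tables:
        raise ValidationError("cannot concatenate zero tables")
    chrom = tables[0].chromosome_id
    length = tables[0].chromosome_length
    for t in tables[1:]:
        if t.chromosome_id != chrom or t.chromosome_length != length:
            raise ValidationError("tables refer to different chromosomes")
    records: list[GenomicFeature] = []
    seen: dict[str, int] = {}
    for t in tables:
        for rec in t.records:
            n = seen.get(rec.id, 0)
            seen[rec.id] = n + 1
            if n:
                rec = replace(rec, id=f"{rec.id}@{n}")
            records.append(rec)
    return FeatureTable(records, chrom, length)


@dataclass
class StrandedCoverage:
    """Per-base read depth on each strand; index 0 holds position 1."""

    plus: np.ndarray
    minus: np.ndarray

    def __post_init__(self) -> None:
        self.plus = np.asarray(self.plus, dtype=np.int64)
        self.minus = np.asarray(self.minus, dtype=np.int64)
        if self.plus.shape != self.minus.shape or self.plus.ndim != 1:
            raise ValidationError("plus/minus tracks must be 1-D and equal length")
        if (self.plus < 0).any() or (self.minus < 0).any():
            raise ValidationError("coverage depths must be non-negative")

    @property
    def chromosome_length(self) -> int:
        return int(self.plus.shape[0])

    def track(self, strand: str) -> np.ndarray:
        return self.plus if strand == "+" else self.minus

    def depth_slice(self, strand: str, start: int, end: int) -> np.ndarray:
        """Depths over the closed interval [start, end] (1-based)."""
        return self.track(strand)[start - 1 : end]


@dataclass(frozen=True)
class TranscriptionalUnit:
    """A merged transcript span owning >= 0 annotated genes."""

    id: str
    start: int
    end: int
    strand: str
    gene_ids: tuple[str, ...] = ()
    utr5_len: int = 0
    utr3_len: int = 0

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(f"TU {self.id!r}: bad strand {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"TU {self.id!r}: invalid span [{self.start}, {self.end}]"
            )
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def kind(self) -> str:
        if self.n_genes == 0:
            return "ncRNA_unit"
        return "monocistronic" if self.n_genes == 1 else "polycistronic"

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end

    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class NcRNARecord:
    """A retained non-coding transcript with its antisense annotation.

    ``ncclass`` is ``"sRNA"`` (no opposite-strand overlap: a trans-encoded
    RNA with its own promoter) or ``"asRNA_I"`` (overlaps >= 1 annotated
    feature on the opposite strand). ``containment_frac`` is the fraction
    of the ncRNA's own length covered by opposite-strand targets.
    """

    id: str
    start: int
    end: int
    strand: str
    ncclass: str
    targets: tuple[tuple[str, int], ...] = ()
    containment_frac: float = 0.0
    target_types: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.ncclass not in ("sRNA", "asRNA_I"):
            raise ValidationError(f"unknown ncRNA class {self.ncclass!r}")
        if (self.ncclass == "asRNA_I") != bool(self.targets):
            raise ValidationError(
                f"ncRNA {self.id!r}: class {self.ncclass} inconsistent with "
                f"{len(self.targets)} targets"
            )
        if not 0.0 <= self.containment_frac <= 1.0:
            raise ValidationError("containment_frac outside [0, 1]")
        object.__setattr__(self, "targets", tuple(self.targets))
        object.__setattr__(self, "target_types", frozenset(self.target_types))

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def total_overlap(self) -> int:
        """Total nucleotides of the ncRNA overlapped by its targets."""
        return int(round(self.containment_frac * self.length))


@dataclass(frozen=True)
class AntisensePair:
    """Two opposite-strand TUs with terminal overlap.

    ``geometry`` is ``"divergent"`` (overlapping 5' ends, head-to-head) or
    ``"convergent"`` (overlapping 3' ends, the cutoRNA configuration).
    """

    tu_a: str
    tu_b: str
    geometry: str
    overlap_start: int
    overlap_end: int

    def __post_init__(self) -> None:
        if self.geometry not in ("divergent", "convergent"):
            raise ValidationError(f"unknown pair geometry {self.geometry!r}")
        if self.overlap_start > self.overlap_end:
            raise ValidationError("empty overlap interval in antisense pair")

    @property
    def overlap_len(self) -> int:
        return self.overlap_end - self.overlap_start + 1

    @property
    def members(self) -> frozenset[str]:
        return frozenset((self.tu_a, self.tu_b))


@dataclass
class CountMatrix:
    """Raw feature x sample counts with per-sample metadata.

    ``counts`` is a pandas DataFrame (features as index, samples as
    columns); ``metadata`` is indexed by sample id and carries at least
    ``strain``, ``timepoint_h`` and ``replicate``.
    """

    counts: "pd.DataFrame"  # noqa: F821 - imported lazily to keep model light
    metadata: "pd.DataFrame"  # noqa: F821

    def __post_init__(self) -> None:
        import pandas as pd

        if not isinstance(self.counts, pd.DataFrame):
            raise ValidationError("counts must be a DataFrame")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.metadata.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        for col in ("strain", "timepoint_h", "replicate"):
            if col not in self.metadata.columns:
                raise ValidationError(f"metadata lacks required column {col!r}")

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_where(
        self, strain: Optional[str] = None, timepoint_h: Optional[int] = None
    ) -> list[str]:
        md = self.metadata.loc[self.samples]
        mask = np.ones(len(md), dtype=bool)
        if strain is not None:
            mask &= (md["strain"] == strain).to_numpy()
        if timepoint_h is not None:
            mask &= (md["timepoint_h"] == timepoint_h).to_numpy()
        return list(md.index[mask])
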