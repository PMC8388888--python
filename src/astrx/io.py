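"""Readers and writers for the external formats the pipeline touches.

Supported dialects
------------------
* GFF3 — primary annotation exchange; 1-based closed, identical to the
  internal convention. ``##sequence-region`` carries the chromosome length.
* BED6 — 0-based half-open; converted on ingestion.
* Rockhopper-style TSV — columns (start, stop, strand, type, name) where
  ``start > stop`` encodes the minus strand; normalized on read.
* bedGraph — per-strand coverage, one file per strand, 0-based half-open.
* featureCounts-style TSV + sample-metadata TSV for count matrices.

The pipeline models a single (linear) chromosome; multi-chromosome inputs
are rejected.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .model import (
    CountMatrix,
    FeatureTable,
    GenomicFeature,
    StrandedCoverage,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

DIALECTS = ("gff3", "bed6", "rockhopper_tsv")

# GFF3 type column <-> internal feature type
_GFF_TO_FTYPE = {
    "gene": "gene",
    "five_prime_UTR": "UTR5",
    "three_prime_UTR": "UTR3",
    "ncRNA": "ncRNA",
    "tRNA": "tRNA",
    "pseudogene": "pseudogene",
}
_FTYPE_TO_GFF = {v: k for k, v in _GFF_TO_FTYPE.items()}


class ParseError(ValueError):
    """Malformed line in an input file; carries the offending line number."""

    def __init__(self, path: PathLike, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


def _parse_timepoints(text: str) -> frozenset[int]:
    if not text:
        return frozenset()
    return frozenset(int(tok) for tok in text.split(",") if tok)


def _format_timepoints(tps: frozenset[int]) -> str:
    return ",".join(str(t) for t in sorted(tps))


# ---------------------------------------------------------------------------
# feature tables


def read_feature_table(
    path: PathLike,
    dialect: str = "gff3",
    chromosome_length: Optional[int] = None,
    chromosome_id: Optional[str] = None,
) -> FeatureTable:
    """Read a feature table, normalizing onto 1-based closed coordinates.

    ``chromosome_length`` is mandatory for BED6 and Rockhopper inputs; for
    GFF3 it is taken from the ``##sequence-region`` directive when present.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if dialect == "gff3":
        return _read_gff3(path, chromosome_length, chromosome_id)
    if dialect == "bed6":
        return _read_bed6(path, chromosome_length, chromosome_id)
    return _read_rockhopper(path, chromosome_length, chromosome_id)


def _require_single_chromosome(path: PathLike, lineno: int, seen: str, new: str) -> None:
    if seen != new:
        raise ParseError(
            path,
            lineno,
            f"multiple chromosomes ({seen!r}, {new!r}); this pipeline models a "
            "single linear chromosome",
        )


def _read_gff3(
    path: PathLike, chromosome_length: Optional[int], chromosome_id: Optional[str]
) -> FeatureTable:
    records: list[GenomicFeature] = []
    chrom: Optional[str] = chromosome_id
    length = chromosome_length
    anonymous = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##sequence-region"):
                toks = line.split()
                if len(toks) != 4:
                    raise ParseError(path, lineno, "malformed ##sequence-region")
                if chrom is None:
                    chrom = toks[1]
                if length is None:
                    length = int(toks[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(path, lineno, f"expected 9 columns, got {len(cols)}")
            seqid, _source, gtype, start_s, end_s, _score, strand, _phase, attrs = cols
            if chrom is None:
                chrom = seqid
            _require_single_chromosome(path, lineno, chrom, seqid)
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            if strand not in ("+", "-"):
                raise ParseError(
                    path, lineno, f"strand must be '+' or '-', got {strand!r}"
                )
            attr_map = {}
            for part in attrs.split(";"):
                if "=" in part:
                    k, v = part.split("=", 1)
                    attr_map[k.strip()] = v.strip()
            fid = attr_map.get("ID")
            if fid is None:
                anonymous += 1
                fid = f"feature_{anonymous}"
            try:
                records.append(
                    GenomicFeature(
                        id=fid,
                        start=start,
                        end=end,
                        strand=strand,
                        ftype=_GFF_TO_FTYPE.get(gtype, "other"),
                        timepoints=_parse_timepoints(attr_map.get("timepoints", "")),
                    )
                )
            except ValidationError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    if chrom is None:
        chrom = "chr"
    if length is None:
        length = max((r.end for r in records), default=1)
    try:
        return FeatureTable(records, chrom, length)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def _read_bed6(
    path: PathLike, chromosome_length: Optional[int], chromosome_id: Optional[str]
) -> FeatureTable:
    records: list[GenomicFeature] = []
    chrom = chromosome_id
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ParseError(path, lineno, f"expected >= 6 columns, got {len(cols)}")
            seqid, start_s, end_s, name, _score, strand = cols[:6]
            if chrom is None:
                chrom = seqid
            _require_single_chromosome(path, lineno, chrom, seqid)
            try:
                start0, end0 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            if end0 <= start0:
                raise ParseError(path, lineno, "BED interval must satisfy end > start")
            if strand not in ("+", "-"):
                raise ParseError(
                    path, lineno, f"strand must be '+' or '-', got {strand!r}"
                )
            try:
                # BED half-open 0-based -> 1-based closed
                records.append(
                    GenomicFeature(id=name, start=start0 + 1, end=end0, strand=strand)
                )
            except ValidationError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    if chrom is None:
        chrom = "chr"
    if chromosome_length is None:
        chromosome_length = max((r.end for r in records), default=1)
    try:
        return FeatureTable(records, chrom, chromosome_length)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def _read_rockhopper(
    path: PathLike, chromosome_length: Optional[int], chromosome_id: Optional[str]
) -> FeatureTable:
    records: list[GenomicFeature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if lineno == 1 and not cols[0].lstrip("-").isdigit():
                continue  # header row
            if len(cols) < 5:
                raise ParseError(path, lineno, f"expected 5 columns, got {len(cols)}")
            start_s, stop_s, strand, ftype, name = cols[:5]
            try:
                start, stop = int(start_s), int(stop_s)
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            # start > stop encodes the minus strand in Rockhopper output
            if start > stop:
                start, stop = stop, start
                inferred = "-"
            else:
                inferred = "+"
            if strand in ("+", "-"):
                if strand != inferred and start_s != stop_s:
                    pass  # explicit strand column wins
                inferred = strand
            if ftype not in _GFF_TO_FTYPE.values() and ftype not in _GFF_TO_FTYPE:
                mapped = "other"
            else:
                mapped = _GFF_TO_FTYPE.get(ftype, ftype)
            try:
                records.append(
                    GenomicFeature(
                        id=name, start=start, end=stop, strand=inferred, ftype=mapped
                    )
                )
            except ValidationError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    if chromosome_length is None:
        chromosome_length = max((r.end for r in records), default=1)
    try:
        return FeatureTable(records, chromosome_id or "chr", chromosome_length)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_feature_table(
    table: FeatureTable, path: PathLike, dialect: str = "gff3"
) -> None:
    if dialect == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(
                f"##sequence-region {table.chromosome_id} 1 {table.chromosome_length}\n"
            )
            for rec in table.records:
                attrs = f"ID={rec.id}"
                if rec.timepoints:
                    attrs += f";timepoints={_format_timepoints(rec.timepoints)}"
                fh.write(
                    "\t".join(
                        (
                            table.chromosome_id,
                            "astrx",
                            _FTYPE_TO_GFF.get(rec.ftype, rec.ftype),
                            str(rec.start),
                            str(rec.end),
                            ".",
                            rec.strand,
                            ".",
                            attrs,
                        )
                    )
                    + "\n"
                )
    elif dialect == "bed6":
        with open(path, "w") as fh:
            for rec in table.records:
                fh.write(
                    "\t".join(
                        (
                            table.chromosome_id,
                            str(rec.start - 1),
                            str(rec.end),
                            rec.id,
                            "0",
                            rec.strand,
                        )
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"cannot write dialect {dialect!r}")


# ---------------------------------------------------------------------------
# coverage


def _read_bedgraph_track(path: PathLike, chromosome_length: int) -> np.ndarray:
    depth = np.zeros(chromosome_length, dtype=np.int64)
    claimed = np.zeros(chromosome_length, dtype=bool)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ParseError(path, lineno, f"expected 4 columns, got {len(cols)}")
            _chrom, start_s, end_s, value_s = cols
            try:
                start0, end0, value = int(start_s), int(end_s), int(float(value_s))
            except ValueError:
                raise ParseError(path, lineno, "non-numeric field") from None
            if value < 0:
                raise ParseError(path, lineno, f"negative coverage value {value}")
            if not (0 <= start0 < end0 <= chromosome_length):
                raise ParseError(
                    path,
                    lineno,
                    f"interval [{start0}, {end0}) outside chromosome of length "
                    f"{chromosome_length}",
                )
            if claimed[start0:end0].any():
                raise ParseError(path, lineno, "overlapping bedGraph intervals")
            claimed[start0:end0] = True
            depth[start0:end0] = value
    return depth


def read_stranded_coverage(
    plus_path: PathLike, minus_path: PathLike, chromosome_length: int
) -> StrandedCoverage:
    """Read a pair of per-strand bedGraph files; unlisted positions are 0."""
    return StrandedCoverage(
        plus=_read_bedgraph_track(plus_path, chromosome_length),
        minus=_read_bedgraph_track(minus_path, chromosome_length),
    )


def _write_bedgraph_track(depth: np.ndarray, chromosome_id: str, path: PathLike) -> None:
    with open(path, "w") as fh:
        n = depth.shape[0]
        # run-length encode; zero runs are omitted
        boundaries = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n]))
        for s, e in zip(starts, ends):
            v = int(depth[s])
            if v:
                fh.write(f"{chromosome_id}\t{s}\t{e}\t{v}\n")


def write_stranded_coverage(
    coverage: StrandedCoverage,
    chromosome_id: str,
    plus_path: PathLike,
    minus_path: PathLike,
) -> None:
    _write_bedgraph_track(coverage.plus, chromosome_id, plus_path)
    _write_bedgraph_track(coverage.minus, chromosome_id, minus_path)


# ---------------------------------------------------------------------------
# repeats (plain BED intervals, strandless)


def read_repeat_bed(path: PathLike) -> list[tuple[int, int]]:
    """Read repeat/duplicated-region intervals from a 3+ column BED file."""
    repeats: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(path, lineno, "expected >= 3 columns")
            try:
                start0, end0 = int(cols[1]), int(cols[2])
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            if end0 <= start0:
                raise ParseError(path, lineno, "BED interval must satisfy end > start")
            repeats.append((start0 + 1, end0))
    return repeats


def write_repeat_bed(
    repeats: list[tuple[int, int]], chromosome_id: str, path: PathLike
) -> None:
    with open(path, "w") as fh:
        for start, end in repeats:
            fh.write(f"{chromosome_id}\t{start - 1}\t{end}\n")


# ---------------------------------------------------------------------------
# count matrices

_ANNOTATION_COLS = {"Chr", "Start", "End", "Strand", "Length"}


def read_count_matrix(path: PathLike, metadata_path: PathLike) -> CountMatrix:
    """Read a featureCounts-style count table plus a sample-metadata TSV.

    The first column holds feature ids; any of the featureCounts annotation
    columns (Chr/Start/End/Strand/Length) are dropped; the remainder must
    match the ``sample_id`` column of the metadata.
    """
    table = pd.read_csv(path, sep="\t", comment="#")
    feature_col = table.columns[0]
    table = table.set_index(feature_col)
    table = table.drop(columns=[c for c in table.columns if c in _ANNOTATION_COLS])
    metadata = pd.read_csv(metadata_path, sep="\t")
    if "sample_id" not in metadata.columns:
        raise ValidationError(f"{metadata_path}: metadata lacks a sample_id column")
    metadata = metadata.set_index("sample_id")

    unmatched = [c for c in table.columns if c not in metadata.index]
    if unmatched:
        raise ValidationError(
            f"{path}: count columns without metadata rows: {unmatched}"
        )
    for col in table.columns:
        values = table[col]
        if not np.issubdtype(values.dtype, np.integer):
            as_float = values.astype(float)
            if not np.allclose(as_float, np.round(as_float)):
                raise ValidationError(
                    f"{path}: non-integer counts in sample {col!r}"
                )
            table[col] = as_float.round().astype(np.int64)
        if int(values.sum()) == 0:
            warnings.warn(f"sample {col!r} has all-zero counts", stacklevel=2)
            logger.warning("sample %r has all-zero counts", col)
    return CountMatrix(counts=table.astype(np.int64), metadata=metadata)


def write_count_matrix(
    matrix: CountMatrix, counts_path: PathLike, metadata_path: PathLike
) -> None:
    out = matrix.counts.copy()
    out.index.name = "Geneid"
    out.to_csv(counts_path, sep="\t")
    md = matrix.metadata.copy()
    md.index.name = "sample_id"
    md.to_csv(metadata_path, sep="\t")
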