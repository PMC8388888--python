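"""Synthetic ground-truth chromosomes, noisy predictions, coverage and counts.

The generator lays out non-overlapping "blocks" along a linear chromosome,
each realizing one structure exactly by construction:

* an operon block — one mono- or polycistronic TU with UTR overhangs;
* an sRNA block — a standalone ncRNA with no opposite-strand feature;
* an asRNA-I block — a single-gene TU plus an opposite-strand ncRNA fully
  or partially inside its span;
* a divergent block — two opposite-strand TUs overlapping at their 5' ends;
* a convergent block — two opposite-strand TUs overlapping at their 3'
  ends (the cutoRNA configuration);
* a repeat block — a TU wrapped in a duplicated-region interval, which at
  prediction time spawns false antisense ncRNA calls.

Prediction noise emulates the upstream predictor's known artifacts: long
UTRs and ncRNAs split into adjacent fragments separated by small gaps, and
spurious opposite-strand calls inside duplicated regions. With split gaps
within the merge threshold (or bridged by continuous coverage within the
collapse threshold) the re-annotation cascade recovers the truth exactly;
that reversibility is the pipeline's central correctness property.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .antisense import overlap_interval, overlap_length
from .model import (
    AntisensePair,
    CountMatrix,
    FeatureTable,
    GenomicFeature,
    NcRNARecord,
    StrandedCoverage,
    TranscriptionalUnit,
    ValidationError,
)


@dataclass(frozen=True)
class TruthParams:
    """Layout settings for one synthetic chromosome.

    Defaults give the "paper-like" toy scenario: a 200 kb chromosome with
    convergent (cutoRNA) pairs as the most numerous antisense class,
    mirroring the relative class abundances seen in GC-rich linear
    actinobacterial chromosomes at a size small enough for seconds-scale
    tests.
    """

    chromosome_length: int = 200_000
    n_operons: int = 40
    genes_per_operon_range: tuple[int, int] = (1, 4)
    n_srna: int = 10
    n_asrna1: int = 15
    n_divergent: int = 8
    n_convergent: int = 25
    n_repeats: int = 4
    intergenic_gap_range: tuple[int, int] = (100, 600)
    gene_length_range: tuple[int, int] = (150, 600)
    intra_operon_gap_range: tuple[int, int] = (20, 60)
    utr5_range: tuple[int, int] = (20, 80)
    utr3_range: tuple[int, int] = (30, 150)
    ncrna_length_range: tuple[int, int] = (80, 300)
    pair_overlap_range: tuple[int, int] = (50, 200)

    def __post_init__(self) -> None:
        if self.intergenic_gap_range[0] <= 15:
            raise ValidationError(
                "intergenic gaps must exceed the 15 nt merge threshold, or "
                "distinct elements would be glued together by design"
            )
        for name in (
            "genes_per_operon_range",
            "intergenic_gap_range",
            "gene_length_range",
            "intra_operon_gap_range",
            "utr5_range",
            "utr3_range",
            "ncrna_length_range",
            "pair_overlap_range",
        ):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValidationError(f"{name} must satisfy 0 < lo <= hi")


@dataclass(frozen=True)
class NoiseParams:
    """Prediction-noise settings for :func:`fragment_predictions`."""

    p_split_utr: float = 0.3
    p_split_ncrna: float = 0.3
    split_gap_range: tuple[int, int] = (1, 15)
    p_repeat_false_antisense: float = 1.0
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_split_utr", "p_split_ncrna", "p_repeat_false_antisense"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.split_gap_range[0] < 0 or self.split_gap_range[0] > self.split_gap_range[1]:
            raise ValidationError("split_gap_range must be non-negative and ordered")
        if self.jitter_sd < 0:
            raise ValidationError("jitter_sd must be >= 0")


NOISELESS = NoiseParams(
    p_split_utr=0.0, p_split_ncrna=0.0, p_repeat_false_antisense=0.0, jitter_sd=0.0
)


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic chromosome."""

    chromosome_id: str
    chromosome_length: int
    seed: int
    params: TruthParams
    tus: list[TranscriptionalUnit]
    genes: FeatureTable
    ncrnas: list[NcRNARecord]
    divergent_pairs: list[AntisensePair]
    convergent_pairs: list[AntisensePair]
    repeat_regions: list[tuple[int, int]]
    # host TU span + strand per repeat region (spurious calls go antisense
    # to the host)
    repeat_hosts: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def transcript_spans(self) -> list[tuple[int, int, str, str]]:
        """(start, end, strand, kind) for every true transcript span."""
        spans = [(t.start, t.end, t.strand, "gene") for t in self.tus]
        spans += [(n.start, n.end, n.strand, "ncRNA") for n in self.ncrnas]
        return sorted(spans)


def _rint(rng: np.random.Generator, pair: tuple[int, int]) -> int:
    return int(rng.integers(pair[0], pair[1] + 1))


class _Layout:
    """Sequential block placement with feasibility checking."""

    def __init__(self, params: TruthParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self.cursor = 1 + _rint(rng, params.intergenic_gap_range)
        self.genes: list[GenomicFeature] = []
        self.tus: list[TranscriptionalUnit] = []
        self._tu_n = 0
        self._gene_n = 0

    def advance(self, used_until: int) -> None:
        self.cursor = used_until + 1 + _rint(self.rng, self.params.intergenic_gap_range)
        if self.cursor > self.params.chromosome_length:
            raise ValidationError(
                "synthetic layout does not fit: increase chromosome_length or "
                "reduce the requested feature counts"
            )

    def build_tu(self, strand: str, n_genes: int) -> TranscriptionalUnit:
        """Lay out one TU at the cursor; genes ordered 5'->3'."""
        p, rng = self.params, self.rng
        u5 = _rint(rng, p.utr5_range)
        u3 = _rint(rng, p.utr3_range)
        left_pad = u5 if strand == "+" else u3
        right_pad = u3 if strand == "+" else u5
        gene_start = self.cursor + left_pad
        coords: list[tuple[int, int]] = []
        pos = gene_start
        for i in range(n_genes):
            length = _rint(rng, p.gene_length_range)
            coords.append((pos, pos + length - 1))
            pos = pos + length + _rint(rng, p.intra_operon_gap_range)
        span = (self.cursor, coords[-1][1] + right_pad)
        members = []
        for s, e in coords:
            self._gene_n += 1
            members.append(
                GenomicFeature(
                    id=f"gene_{self._gene_n:04d}", start=s, end=e, strand=strand,
                    ftype="gene",
                )
            )
        self.genes.extend(members)
        ordered = members if strand == "+" else members[::-1]
        self._tu_n += 1
        tu = TranscriptionalUnit(
            id=f"true_tu_{self._tu_n:04d}",
            start=span[0],
            end=span[1],
            strand=strand,
            gene_ids=tuple(g.id for g in ordered),
            utr5_len=u5,
            utr3_len=u3,
        )
        self.tus.append(tu)
        return tu


def generate_truth(
    params: Optional[TruthParams] = None, seed: int = 0
) -> SyntheticTruth:
    """Generate a ground-truth chromosome; deterministic for a fixed seed.

    Each requested feature-class count is realized exactly; infeasible
    packings raise with a suggestion to lengthen the chromosome.
    """
    params = params or TruthParams()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    layout = _Layout(params, rng)

    blocks = (
        ["operon"] * params.n_operons
        + ["srna"] * params.n_srna
        + ["asrna1"] * params.n_asrna1
        + ["divergent"] * params.n_divergent
        + ["convergent"] * params.n_convergent
        + ["repeat"] * params.n_repeats
    )
    rng.shuffle(blocks)

    ncrnas: list[NcRNARecord] = []
    div_pairs: list[AntisensePair] = []
    conv_pairs: list[AntisensePair] = []
    repeats: list[tuple[int, int]] = []
    repeat_hosts: list[tuple[int, int, str]] = []
    n_srna = n_asrna = 0

    def rand_strand() -> str:
        return "+" if rng.random() < 0.5 else "-"

    for block in blocks:
        if block == "operon":
            n_genes = _rint(rng, params.genes_per_operon_range)
            tu = layout.build_tu(rand_strand(), n_genes)
            layout.advance(tu.end)
        elif block == "srna":
            n_srna += 1
            length = _rint(rng, params.ncrna_length_range)
            start = layout.cursor
            ncrnas.append(
                NcRNARecord(
                    id=f"srna_{n_srna:03d}",
                    start=start,
                    end=start + length - 1,
                    strand=rand_strand(),
                    ncclass="sRNA",
                )
            )
            layout.advance(start + length - 1)
        elif block == "asrna1":
            n_asrna += 1
            strand = rand_strand()
            tu = layout.build_tu(strand, 1)
            anti = "-" if strand == "+" else "+"
            length = min(_rint(rng, params.ncrna_length_range), tu.length - 2)
            if rng.random() < 0.4:
                # partial containment: extend past the TU's right edge
                frac = float(rng.uniform(0.6, 0.98))
                ov = max(1, int(round(length * frac)))
                start = tu.end - ov + 1
            else:
                start = int(rng.integers(tu.start, tu.end - length + 2))
            end = start + length - 1
            ov_len = overlap_length((start, end), tu.interval)
            kinds = {
                k
                for k in ("CDS", "UTR")
                if _hits_kind((start, end), tu, layout.genes, k)
            }
            if len(kinds) > 1:
                kinds.add("mixed")
            ncrnas.append(
                NcRNARecord(
                    id=f"asrna_{n_asrna:03d}",
                    start=start,
                    end=end,
                    strand=anti,
                    ncclass="asRNA_I",
                    targets=((tu.id, ov_len),),
                    containment_frac=ov_len / length,
                    target_types=frozenset(kinds),
                )
            )
            layout.advance(max(tu.end, end))
        elif block in ("divergent", "convergent"):
            first_strand = "-" if block == "divergent" else "+"
            tu1 = layout.build_tu(first_strand, _rint(rng, params.genes_per_operon_range))
            ov = _rint(rng, params.pair_overlap_range)
            ov = min(ov, tu1.length - 10)
            # second unit starts inside the first so the terminal regions overlap
            second_strand = "+" if first_strand == "-" else "-"
            layout.cursor = tu1.end - ov + 1
            tu2 = layout.build_tu(second_strand, _rint(rng, params.genes_per_operon_range))
            # minimum unit length (pads + one gene) always exceeds the
            # overlap cap, so neither unit can contain the other
            iv = overlap_interval(tu1.interval, tu2.interval)
            assert iv is not None
            pair = AntisensePair(
                tu_a=tu1.id,
                tu_b=tu2.id,
                geometry=block,
                overlap_start=iv[0],
                overlap_end=iv[1],
            )
            (div_pairs if block == "divergent" else conv_pairs).append(pair)
            layout.advance(tu2.end)
        elif block == "repeat":
            tu = layout.build_tu(rand_strand(), 1)
            pad_l = _rint(rng, (20, 60))
            pad_r = _rint(rng, (20, 60))
            region = (max(1, tu.start - pad_l), tu.end + pad_r)
            repeats.append(region)
            repeat_hosts.append((tu.start, tu.end, tu.strand))
            layout.advance(region[1])

    genes_table = FeatureTable(
        sorted(layout.genes, key=lambda g: (g.strand, g.start)),
        "chr",
        params.chromosome_length,
    )
    return SyntheticTruth(
        chromosome_id="chr",
        chromosome_length=params.chromosome_length,
        seed=seed,
        params=params,
        tus=layout.tus,
        genes=genes_table,
        ncrnas=ncrnas,
        divergent_pairs=div_pairs,
        convergent_pairs=conv_pairs,
        repeat_regions=repeats,
        repeat_hosts=repeat_hosts,
    )


def _hits_kind(
    interval: tuple[int, int],
    tu: TranscriptionalUnit,
    genes: Sequence[GenomicFeature],
    kind: str,
) -> bool:
    members = [g for g in genes if g.id in tu.gene_ids]
    cds = sum(overlap_length(interval, g.interval) for g in members)
    total = overlap_length(interval, tu.interval)
    return cds > 0 if kind == "CDS" else (total - cds) > 0


# ---------------------------------------------------------------------------
# noisy per-timepoint predictions


def _tu_gene_records(
    tu: TranscriptionalUnit, genes_by_id: dict[str, GenomicFeature], timepoint: int
) -> list[GenomicFeature]:
    """Emit per-gene UTR-extended records that tile the TU span exactly."""
    members = sorted(
        (genes_by_id[g] for g in tu.gene_ids), key=lambda g: g.start
    )
    cuts = [
        (a.end + b.start) // 2 for a, b in zip(members, members[1:])
    ]
    lefts = [tu.start] + [c + 1 for c in cuts]
    rights = cuts + [tu.end]
    return [
        GenomicFeature(
            id=f"{g.id}_pred",
            start=lo,
            end=hi,
            strand=tu.strand,
            ftype="gene",
            timepoints=frozenset({timepoint}),
        )
        for g, lo, hi in zip(members, lefts, rights)
    ]


def _split_fragments(
    span: tuple[int, int],
    n_splits: int,
    gap_range: tuple[int, int],
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Cut a span into adjacent fragments separated by drawn gaps."""
    frags = [span]
    for _ in range(n_splits):
        frags.sort(key=lambda f: f[0] - f[1])  # longest first
        fs, fe = frags[0]
        g = _rint(rng, gap_range)
        if fe - fs + 1 < g + 4:
            continue  # fragment too short to cut with this gap
        c = int(rng.integers(fs + 1, fe - g - 1 + 1))
        frags = [(fs, c), (c + g + 1, fe)] + frags[1:]
    return sorted(frags)


def fragment_predictions(
    truth: SyntheticTruth,
    noise: Optional[NoiseParams] = None,
    timepoint: int = 48,
    seed: int = 0,
) -> FeatureTable:
    """Emit one timepoint's noisy prediction table (genes + ncRNA calls).

    With all noise probabilities zero the output spans equal the truth's
    transcript spans exactly. Splits never extend past the true span, so a
    split gap is always an interior, covered stretch; boundary jitter is
    truncated so records never invert or leave the chromosome.
    """
    noise = noise or NoiseParams()
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, seed, timepoint, 2]))
    genes_by_id = {g.id: g for g in truth.genes}
    records: list[GenomicFeature] = []

    for tu in truth.tus:
        recs = _tu_gene_records(tu, genes_by_id, timepoint)
        # UTR-splitting artifact: the terminal record sheds its distal UTR
        # stretch as one or more adjacent "predicted ncRNA" fragments
        for side in ("left", "right"):
            terminal = recs[0] if side == "left" else recs[-1]
            members = [genes_by_id[g] for g in tu.gene_ids]
            inner = (
                min(g.start for g in members)
                if side == "left"
                else max(g.end for g in members)
            )
            utr_len = (inner - terminal.start) if side == "left" else (terminal.end - inner)
            g = _rint(rng, noise.split_gap_range)
            if utr_len >= g + 2 and rng.random() < noise.p_split_utr:
                if side == "right":
                    c = int(rng.integers(inner, terminal.end - g - 1 + 1))
                    trimmed = replace(terminal, end=c)
                    frag = GenomicFeature(
                        id=f"{terminal.id}_utrfrag_r",
                        start=c + g + 1,
                        end=terminal.end,
                        strand=tu.strand,
                        ftype="ncRNA",
                        timepoints=frozenset({timepoint}),
                    )
                    recs[-1] = trimmed
                else:
                    c = int(rng.integers(terminal.start + g + 1, inner + 1))
                    trimmed = replace(terminal, start=c)
                    frag = GenomicFeature(
                        id=f"{terminal.id}_utrfrag_l",
                        start=terminal.start,
                        end=c - g - 1,
                        strand=tu.strand,
                        ftype="ncRNA",
                        timepoints=frozenset({timepoint}),
                    )
                    recs[0] = trimmed
                records.append(frag)
        records.extend(recs)

    for nc in truth.ncrnas:
        if rng.random() < noise.p_split_ncrna:
            n_splits = 1 + int(rng.random() < 0.3)
            frags = _split_fragments(
                nc.interval, n_splits, noise.split_gap_range, rng
            )
        else:
            frags = [nc.interval]
        for i, (s, e) in enumerate(frags):
            fid = f"{nc.id}_pred" if len(frags) == 1 else f"{nc.id}_pred.{i + 1}"
            records.append(
                GenomicFeature(
                    id=fid,
                    start=s,
                    end=e,
                    strand=nc.strand,
                    ftype="ncRNA",
                    timepoints=frozenset({timepoint}),
                )
            )

    for idx, ((rs, re), (hs, he, hstrand)) in enumerate(
        zip(truth.repeat_regions, truth.repeat_hosts)
    ):
        if rng.random() < noise.p_repeat_false_antisense:
            anti = "-" if hstrand == "+" else "+"
            length = min(_rint(rng, (60, 150)), he - hs - 1)
            start = int(rng.integers(hs, he - length + 2))
            records.append(
                GenomicFeature(
                    id=f"repeat_artifact_{idx + 1}_tp{timepoint}",
                    start=start,
                    end=start + length - 1,
                    strand=anti,
                    ftype="ncRNA",
                    timepoints=frozenset({timepoint}),
                )
            )

    if noise.jitter_sd > 0:
        jittered = []
        L = truth.chromosome_length
        for rec in records:
            ds, de = rng.normal(0, noise.jitter_sd, 2)
            s = int(np.clip(rec.start + round(ds), 1, L))
            e = int(np.clip(rec.end + round(de), 1, L))
            if s > e:
                s, e = e, s
            jittered.append(replace(rec, start=s, end=e))
        records = jittered

    records.sort(key=lambda r: (r.strand, r.start, r.end, r.id))
    return FeatureTable(records, truth.chromosome_id, truth.chromosome_length)


def split_prediction(table: FeatureTable) -> tuple[FeatureTable, FeatureTable]:
    """Split a prediction table into the (extended genes, ncRNAs) list pair."""
    return (
        table.of_type("gene", "UTR5", "UTR3", "tRNA", "pseudogene", "other"),
        table.of_type("ncRNA"),
    )


# ---------------------------------------------------------------------------
# coverage and counts


def emit_coverage(
    truth: SyntheticTruth, depth: float = 50.0, seed: int = 0
) -> StrandedCoverage:
    """Strand-specific per-base coverage with continuous signal over truth spans.

    Every true transcript span gets depth >= 1 at every position on its own
    strand (Poisson noise around ``depth``, floored at 1); background is 0.
    """
    if depth <= 0:
        raise ValidationError("depth must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, seed, 3]))
    tracks = {
        "+": np.zeros(truth.chromosome_length, dtype=np.int64),
        "-": np.zeros(truth.chromosome_length, dtype=np.int64),
    }
    for start, end, strand, _kind in truth.transcript_spans:
        block = np.maximum(1, rng.poisson(depth, end - start + 1))
        np.maximum(tracks[strand][start - 1 : end], block, out=tracks[strand][start - 1 : end])
    return StrandedCoverage(plus=tracks["+"], minus=tracks["-"])


@dataclass
class ExpressionDesign:
    """Study design for count emission.

    ``fold_change_map`` maps ``(feature_id, strain, timepoint_h)`` to a
    multiplicative effect relative to baseline (unlisted combinations are
    1). Negative-binomial dispersion follows the RNA-seq convention
    ``variance = mean + dispersion * mean**2``; dispersion 0 is Poisson.
    """

    strains: list[str]
    timepoints_h: list[int]
    replicates: int
    baseline_mean: pd.Series
    fold_change_map: dict[tuple[str, str, int], float] = field(default_factory=dict)
    dispersion: float = 0.05
    library_size_factors: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if (self.baseline_mean <= 0).any():
            raise ValidationError("baseline means must be positive")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if any(fc <= 0 for fc in self.fold_change_map.values()):
            raise ValidationError("fold changes must be positive")
        if self.replicates < 1:
            raise ValidationError("need >= 1 replicate")

    def sample_ids(self) -> list[str]:
        return [
            f"{strain}_{tp}h_r{rep}"
            for strain in self.strains
            for tp in self.timepoints_h
            for rep in range(1, self.replicates + 1)
        ]

    def metadata(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": f"{strain}_{tp}h_r{rep}",
                "strain": strain,
                "timepoint_h": tp,
                "replicate": rep,
            }
            for strain in self.strains
            for tp in self.timepoints_h
            for rep in range(1, self.replicates + 1)
        ]
        return pd.DataFrame(rows).set_index("sample_id")


def emit_counts(design: ExpressionDesign, seed: int = 0) -> CountMatrix:
    """Draw a negative-binomial count matrix under the design; seeded."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    samples = design.sample_ids()
    lib = (
        design.library_size_factors.reindex(samples)
        if design.library_size_factors is not None
        else pd.Series(1.0, index=samples)
    )
    if lib.isna().any() or (lib <= 0).any():
        raise ValidationError("library size factors must be positive for all samples")
    metadata = design.metadata()
    features = list(design.baseline_mean.index)
    base = design.baseline_mean.to_numpy(dtype=float)
    mat = np.zeros((len(features), len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        strain = metadata.loc[sample, "strain"]
        tp = int(metadata.loc[sample, "timepoint_h"])
        fc = np.array(
            [design.fold_change_map.get((fid, strain, tp), 1.0) for fid in features]
        )
        means = base * fc * float(lib.loc[sample])
        if design.dispersion == 0:
            mat[:, j] = rng.poisson(means)
        else:
            n = 1.0 / design.dispersion
            mat[:, j] = rng.negative_binomial(n, n / (n + means))
    counts = pd.DataFrame(mat, index=features, columns=samples)
    return CountMatrix(counts=counts, metadata=metadata)


def paper_like_design(
    truth: SyntheticTruth,
    seed: int = 0,
    strains: Sequence[str] = ("wt", "pirA", "pirA_rpoBR"),
    timepoints_h: Sequence[int] = (48, 120),
    replicates: int = 2,
    dispersion: float = 0.05,
    baseline_depth: float = 100.0,
) -> ExpressionDesign:
    """A strain-contrast design over the truth's ncRNA catalog.

    Antisense RNAs are predominantly downregulated in the mutant strains
    (the regulatory signature the strain comparison is built to detect);
    sRNAs split roughly evenly between directions.
    """
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, seed, 5]))
    features = [n.id for n in truth.ncrnas]
    baseline = pd.Series(
        np.exp(rng.normal(np.log(baseline_depth), 0.4, len(features))),
        index=features,
        name="baseline_mean",
    )
    fc_map: dict[tuple[str, str, int], float] = {}
    mutants = [s for s in strains if s != "wt"]
    for nc in truth.ncrnas:
        for strain in mutants:
            de_prob = 0.7 if nc.ncclass == "asRNA_I" else 0.5
            if rng.random() >= de_prob:
                continue
            down_prob = 0.9 if nc.ncclass == "asRNA_I" else 0.5
            fc = 0.25 if rng.random() < down_prob else 4.0
            for tp in timepoints_h:
                fc_map[(nc.id, strain, int(tp))] = fc
    lib = pd.Series(
        rng.uniform(0.7, 1.3, len(strains) * len(timepoints_h) * replicates),
    )
    design = ExpressionDesign(
        strains=list(strains),
        timepoints_h=[int(t) for t in timepoints_h],
        replicates=replicates,
        baseline_mean=baseline,
        fold_change_map=fc_map,
        dispersion=dispersion,
    )
    lib.index = design.sample_ids()
    design.library_size_factors = lib
    return design


# ---------------------------------------------------------------------------
# scenario writer (all outputs are small plain-text formats)


def write_scenario(
    outdir,
    truth: SyntheticTruth,
    noise: Optional[NoiseParams] = None,
    timepoints: Sequence[int] = (48, 72, 96, 120),
    depth: float = 50.0,
    seed: int = 0,
) -> dict[str, str]:
    """Materialize a scenario on disk: GFF3 predictions, bedGraph coverage,
    counts + metadata TSVs, repeats BED and a truth-label table."""
    from pathlib import Path

    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    truth_records = [
        GenomicFeature(id=t.id, start=t.start, end=t.end, strand=t.strand, ftype="gene")
        for t in truth.tus
    ] + [
        GenomicFeature(id=n.id, start=n.start, end=n.end, strand=n.strand, ftype="ncRNA")
        for n in truth.ncrnas
    ]
    truth_table = FeatureTable(
        sorted(truth_records, key=lambda r: (r.strand, r.start)),
        truth.chromosome_id,
        truth.chromosome_length,
    )
    paths["truth"] = str(outdir / "truth.gff3")
    _io.write_feature_table(truth_table, paths["truth"], "gff3")

    for tp in timepoints:
        table = fragment_predictions(truth, noise, timepoint=tp, seed=seed)
        key = f"predictions_{tp}"
        paths[key] = str(outdir / f"predictions_{tp}h.gff3")
        _io.write_feature_table(table, paths[key], "gff3")

    coverage = emit_coverage(truth, depth=depth, seed=seed)
    paths["coverage_plus"] = str(outdir / "coverage_plus.bedgraph")
    paths["coverage_minus"] = str(outdir / "coverage_minus.bedgraph")
    _io.write_stranded_coverage(
        coverage, truth.chromosome_id, paths["coverage_plus"], paths["coverage_minus"]
    )

    paths["repeats"] = str(outdir / "repeats.bed")
    _io.write_repeat_bed(truth.repeat_regions, truth.chromosome_id, paths["repeats"])

    design = paper_like_design(truth, seed=seed)
    matrix = emit_counts(design, seed=seed)
    paths["counts"] = str(outdir / "counts.tsv")
    paths["metadata"] = str(outdir / "metadata.tsv")
    _io.write_count_matrix(matrix, paths["counts"], paths["metadata"])

    labels = pd.DataFrame(
        [
            {
                "feature_id": n.id,
                "start": n.start,
                "end": n.end,
                "strand": n.strand,
                "ncclass": n.ncclass,
                "containment_frac": n.containment_frac,
            }
            for n in truth.ncrnas
        ]
    )
    paths["truth_labels"] = str(outdir / "truth_labels.tsv")
    labels.to_csv(paths["truth_labels"], sep="\t", index=False)
    return paths
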