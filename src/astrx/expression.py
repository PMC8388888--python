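"""Count normalization, fold-change contrasts and regulation trend summaries.

Two size-factor rules are provided:

* total-count — each sample is scaled to the least-covered sample's mapped
  total (the convention used for the strain comparisons);
* median-of-ratios — the standard DESeq-style estimator over features with
  all-positive counts, for whole-transcriptome batches.

Differential calls here are threshold-based on the log2 fold change of
group means over normalized counts (with a fixed pseudocount), optionally
gated on externally supplied adjusted p-values. Negative-binomial testing
itself is delegated to dedicated tools; the outputs label the calls as
threshold calls.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import CountMatrix, ValidationError

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_LFC_THRESHOLD = 1.0
DEFAULT_ALPHA = 0.05

CONTRAST_COLUMNS = [
    "feature_id",
    "base_mean_ref",
    "base_mean_alt",
    "log2fc",
    "call",
    "contrast_label",
]


def size_factors_total_count(
    counts: CountMatrix, mapped_totals: Optional[pd.Series] = None
) -> pd.Series:
    """Per-sample factors from totals, least-covered sample pinned to 1.

    ``factor_s = total_s / min_s total_s``; dividing raw counts by the
    factor scales every sample down to the least-covered one. When
    ``mapped_totals`` (reads mapped to the chromosome) is not given, the
    matrix column sums stand in.
    """
    if mapped_totals is None:
        mapped_totals = counts.counts.sum(axis=0).astype(float)
    totals = mapped_totals.reindex(counts.samples)
    if totals.isna().any():
        missing = list(totals.index[totals.isna()])
        raise ValidationError(f"mapped totals missing for samples: {missing}")
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValidationError(f"non-positive mapped totals for samples: {bad}")
    return totals / totals.min()


def size_factors_median_ratio(counts: CountMatrix) -> pd.Series:
    """DESeq-style median-of-ratios size factors.

    For each feature with positive counts in every sample, the ratio of
    each sample's count to the feature's geometric mean is formed; the
    per-sample factor is the median ratio.
    """
    mat = counts.counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValidationError(
            "no feature has positive counts in every sample; use the "
            "total-count rule instead"
        )
    sub = mat[positive]
    log_geomean = np.log(sub).mean(axis=1, keepdims=True)
    ratios = sub / np.exp(log_geomean)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.samples, name="size_factor")


def normalize_counts(counts: CountMatrix, factors: pd.Series) -> pd.DataFrame:
    """Raw counts divided by per-sample size factors."""
    factors = factors.reindex(counts.samples)
    if factors.isna().any() or (factors <= 0).any():
        raise ValidationError("size factors must be positive and cover all samples")
    return counts.counts / factors


def log2_fold_change(
    norm: pd.DataFrame,
    ref_samples: Sequence[str],
    alt_samples: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    contrast_label: str = "",
) -> pd.DataFrame:
    """Per-feature log2((mean_alt + pc) / (mean_ref + pc)) over group means.

    Groups must be disjoint and non-empty; replicate handling is the plain
    group mean (the study design has biological duplicates).
    """
    ref, alt = list(ref_samples), list(alt_samples)
    if not ref or not alt:
        raise ValidationError("both contrast groups must be non-empty")
    if set(ref) & set(alt):
        raise ValidationError("contrast groups overlap")
    missing = [s for s in ref + alt if s not in norm.columns]
    if missing:
        raise ValidationError(f"samples not in matrix: {missing}")
    mean_ref = norm[ref].mean(axis=1)
    mean_alt = norm[alt].mean(axis=1)
    # difference of logs rather than log of ratio: swapping the groups
    # then negates the result exactly, bit for bit
    lfc = np.log2(mean_alt + pseudocount) - np.log2(mean_ref + pseudocount)
    return pd.DataFrame(
        {
            "feature_id": norm.index,
            "base_mean_ref": mean_ref.to_numpy(),
            "base_mean_alt": mean_alt.to_numpy(),
            "log2fc": lfc.to_numpy(),
            "call": "unchanged",
            "contrast_label": contrast_label,
        }
    ).set_index("feature_id", drop=False)


def call_regulation(
    results: pd.DataFrame,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    padj: Optional[pd.Series] = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Threshold calls: up/down when |log2fc| >= threshold (and padj <= alpha).

    ``padj`` values, when given, come from an external test (they are
    consumed, never computed here) and must cover every feature.
    """
    if lfc_threshold < 0:
        raise ValueError("lfc_threshold must be >= 0")
    out = results.copy()
    significant = np.ones(len(out), dtype=bool)
    if padj is not None:
        aligned = padj.reindex(out["feature_id"])
        if aligned.isna().any():
            missing = list(aligned.index[aligned.isna()])
            raise ValidationError(f"padj missing for features: {missing}")
        significant = (aligned <= alpha).to_numpy()
    lfc = out["log2fc"].to_numpy()
    call = np.where(
        significant & (lfc >= lfc_threshold),
        "up",
        np.where(significant & (lfc <= -lfc_threshold), "down", "unchanged"),
    )
    out["call"] = call
    return out


def trend_summary(
    results: pd.DataFrame,
    class_labels: pd.Series,
) -> pd.DataFrame:
    """Per (class, contrast) regulation trend among differentially called features.

    Returns columns n_total, n_de, n_up, n_down and fraction_down (share of
    down calls among DE features; NaN when nothing is DE).
    """
    labeled = results.copy()
    labeled["ncclass"] = class_labels.reindex(labeled["feature_id"]).to_numpy()
    rows = []
    for (cls, contrast), grp in labeled.groupby(["ncclass", "contrast_label"]):
        n_up = int((grp["call"] == "up").sum())
        n_down = int((grp["call"] == "down").sum())
        n_de = n_up + n_down
        rows.append(
            {
                "ncclass": cls,
                "contrast_label": contrast,
                "n_total": len(grp),
                "n_de": n_de,
                "n_up": n_up,
                "n_down": n_down,
                "fraction_down": (n_down / n_de) if n_de else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def growth_course_contrasts(
    counts: CountMatrix,
    strain: str,
    reference_timepoint: int = 48,
    factors: Optional[pd.Series] = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> pd.DataFrame:
    """Compare each later timepoint of one strain to the reference timepoint.

    Returns the concatenated called contrasts, one ``contrast_label`` per
    later timepoint (e.g. ``"wt:72h_vs_48h"``).
    """
    if factors is None:
        factors = size_factors_total_count(counts)
    norm = normalize_counts(counts, factors)
    ref = counts.samples_where(strain=strain, timepoint_h=reference_timepoint)
    if not ref:
        raise ValidationError(
            f"no samples for strain {strain!r} at {reference_timepoint} h"
        )
    md = counts.metadata.loc[counts.samples]
    later = sorted(
        t
        for t in md.loc[md["strain"] == strain, "timepoint_h"].unique()
        if t != reference_timepoint
    )
    frames = []
    for tp in later:
        alt = counts.samples_where(strain=strain, timepoint_h=int(tp))
        res = log2_fold_change(
            norm,
            ref,
            alt,
            pseudocount=pseudocount,
            contrast_label=f"{strain}:{int(tp)}h_vs_{reference_timepoint}h",
        )
        frames.append(call_regulation(res, lfc_threshold=lfc_threshold))
    return pd.concat(frames, ignore_index=True)


def upregulated_in_any_later_timepoint(course: pd.DataFrame) -> pd.Series:
    """Per-feature indicator: called up in >= 1 later-timepoint contrast."""
    return (
        course.groupby("feature_id")["call"]
        .apply(lambda calls: bool((calls == "up").any()))
        .rename("up_in_any_later_timepoint")
    )


def strain_contrasts(
    counts: CountMatrix,
    reference_strain: str,
    timepoint_h: int,
    factors: Optional[pd.Series] = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> pd.DataFrame:
    """Each non-reference strain vs the reference at one timepoint."""
    if factors is None:
        factors = size_factors_total_count(counts)
    norm = normalize_counts(counts, factors)
    ref = counts.samples_where(strain=reference_strain, timepoint_h=timepoint_h)
    if not ref:
        raise ValidationError(
            f"no samples for strain {reference_strain!r} at {timepoint_h} h"
        )
    md = counts.metadata.loc[counts.samples]
    strains = [s for s in md["strain"].unique() if s != reference_strain]
    frames = []
    for strain in strains:
        alt = counts.samples_where(strain=strain, timepoint_h=timepoint_h)
        if not alt:
            continue
        res = log2_fold_change(
            norm,
            ref,
            alt,
            pseudocount=pseudocount,
            contrast_label=f"{strain}_vs_{reference_strain}:{timepoint_h}h",
        )
        frames.append(call_regulation(res, lfc_threshold=lfc_threshold))
    if not frames:
        raise ValidationError("no alternative strains found for the contrast")
    return pd.concat(frames, ignore_index=True)
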