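"""COG functional-class counting and codon-usage tabulation.

Counting conventions for antisense targets: every (target, COG letter)
incidence contributes one count, so a target annotated with two classes
counts once per class, and a divergent/convergent pair — two overlapping
transcripts — contributes the letters of both members. Targets without a
COG assignment are excluded. No significance test is attached to the
enrichment ratios; the proportions themselves are the report, and a
two-proportion z-test is available as a clearly optional extension.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable as _BioCodonTable

from .model import ValidationError

# the 26 standard single-letter COG functional categories
COG_CATEGORIES = frozenset("JAKLBDYVTMNZWUOXCGEFHIPQRS")

CogMap = Mapping[str, Iterable[str]]


def parse_cog_map(table: pd.DataFrame) -> dict[str, frozenset[str]]:
    """Build feature_id -> COG letter set from a two-column table.

    Multi-letter CDD strings (e.g. ``"JC"`` or ``"J,C"``) are split into
    single letters, the common normalization for CDD-derived assignments.
    """
    if table.shape[1] < 2:
        raise ValidationError("COG table needs feature_id and cog_letters columns")
    out: dict[str, frozenset[str]] = {}
    for fid, letters in zip(table.iloc[:, 0], table.iloc[:, 1]):
        if pd.isna(letters):
            continue
        split = frozenset(c for c in str(letters) if c.isalpha())
        bad = split - COG_CATEGORIES
        if bad:
            raise ValidationError(f"unknown COG letters {sorted(bad)} for {fid!r}")
        if split:
            out[str(fid)] = split
    return out


def cog_class_counts(
    targets: Sequence[tuple[Sequence[str], str]],
    cog_map: CogMap,
) -> Counter:
    """Tally COG letters over target incidences.

    ``targets`` holds ``(member_feature_ids, asrna_class)`` entries: one
    entry per asRNA-I target gene (single-member tuple) and one per
    class-II/III pair carrying both members, so a pair's shared letter is
    counted twice. Unclassified members contribute nothing.
    """
    counts: Counter = Counter()
    for member_ids, _asrna_class in targets:
        for fid in member_ids:
            letters = cog_map.get(fid)
            if not letters:
                continue
            bad = set(letters) - COG_CATEGORIES
            if bad:
                raise ValidationError(
                    f"unknown COG letters {sorted(bad)} for {fid!r}"
                )
            for letter in letters:
                counts[letter] += 1
    return counts


def background_counts(feature_ids: Iterable[str], cog_map: CogMap) -> Counter:
    """Reference distribution over a feature set (whole genome, mono, poly)."""
    return cog_class_counts([((fid,), "background") for fid in feature_ids], cog_map)


def cog_enrichment_table(
    class_counts: Mapping[str, int],
    background: Mapping[str, int],
) -> pd.DataFrame:
    """Within-set fractions and class/background ratios per COG letter.

    The ratio is NaN where the background fraction is zero.
    """
    if not class_counts or sum(class_counts.values()) == 0:
        raise ValidationError("empty class count table")
    if not background or sum(background.values()) == 0:
        raise ValidationError("empty background count table")
    letters = sorted(set(class_counts) | set(background))
    total_c = sum(class_counts.values())
    total_b = sum(background.values())
    rows = []
    for letter in letters:
        fc = class_counts.get(letter, 0) / total_c
        fb = background.get(letter, 0) / total_b
        rows.append(
            {
                "cog": letter,
                "count_class": class_counts.get(letter, 0),
                "count_background": background.get(letter, 0),
                "fraction_class": fc,
                "fraction_background": fb,
                "ratio": (fc / fb) if fb > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("cog")


def two_proportion_test(
    class_counts: Mapping[str, int], background: Mapping[str, int]
) -> pd.DataFrame:
    """Optional extension: per-letter two-proportion z-test (normal approx).

    Not part of the core report — the core output is proportions and ratios.
    """
    from scipy.stats import norm

    table = cog_enrichment_table(class_counts, background)
    n1 = sum(class_counts.values())
    n2 = sum(background.values())
    pvals = []
    for letter, row in table.iterrows():
        x1, x2 = row["count_class"], row["count_background"]
        p_pool = (x1 + x2) / (n1 + n2)
        se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
        if se == 0:
            pvals.append(1.0)
            continue
        z = (x1 / n1 - x2 / n2) / se
        pvals.append(float(2 * norm.sf(abs(z))))
    out = table.copy()
    out["p_value"] = pvals
    return out


# ---------------------------------------------------------------------------
# codon usage

_BACTERIAL_TABLE = _BioCodonTable.unambiguous_dna_by_id[11]

CODONS = tuple(
    f"{a}{b}{c}" for a in "TCAG" for b in "TCAG" for c in "TCAG"
)


def _amino_acid(codon: str) -> str:
    if codon in _BACTERIAL_TABLE.stop_codons:
        return "*"
    return _BACTERIAL_TABLE.forward_table[codon]


def codon_usage(
    cds_sequences: Iterable[str],
    ambiguous: str = "error",
) -> pd.DataFrame:
    """Count in-frame codons over a set of CDS sequences.

    Every sequence must be in frame 0 with length divisible by 3 over the
    alphabet {A, C, G, T}. Returns one row per codon (all 64 present) with
    the raw count, frequency per 1000 codons, the encoded amino acid
    (bacterial code; ``*`` for stop), and the codon's relative fraction
    within its amino acid's synonymous family — the quantity used to judge
    whether a codon is rare for its amino acid.

    ``ambiguous`` controls non-ACGT bases: ``"error"`` raises,
    ``"skip"`` drops the offending codon.
    """
    if ambiguous not in ("error", "skip"):
        raise ValueError("ambiguous must be 'error' or 'skip'")
    counts: Counter = Counter()
    for idx, seq in enumerate(cds_sequences):
        s = str(seq).upper().replace("U", "T")
        if len(s) % 3 != 0:
            raise ValidationError(
                f"sequence #{idx} length {len(s)} is not divisible by 3"
            )
        for i in range(0, len(s), 3):
            codon = s[i : i + 3]
            if set(codon) - set("ACGT"):
                if ambiguous == "error":
                    raise ValidationError(
                        f"sequence #{idx}: ambiguous codon {codon!r} at position {i}"
                    )
                continue
            counts[codon] += 1
    total = sum(counts.values())
    rows = []
    aa_totals: Counter = Counter()
    for codon in CODONS:
        aa_totals[_amino_acid(codon)] += counts.get(codon, 0)
    for codon in CODONS:
        aa = _amino_acid(codon)
        c = counts.get(codon, 0)
        rows.append(
            {
                "codon": codon,
                "amino_acid": aa,
                "count": c,
                "per_1000": (1000.0 * c / total) if total else 0.0,
                "fraction_within_aa": (c / aa_totals[aa]) if aa_totals[aa] else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("codon")


def rare_codons(
    usage: pd.DataFrame, max_fraction: float = 0.25
) -> pd.DataFrame:
    """Codons under-used relative to their synonymous family.

    A codon is flagged when its within-amino-acid fraction is below
    ``max_fraction`` and the family has more than one member — the pattern
    behind regulatory rare-codon arguments (e.g. proline CCA in GC-rich
    genomes).
    """
    fam_sizes = usage.groupby("amino_acid").size()
    multi = usage["amino_acid"].map(fam_sizes) > 1
    return usage[multi & (usage["fraction_within_aa"] < max_fraction)]
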