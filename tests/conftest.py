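import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from astrx import simulate
from astrx.model import FeatureTable, GenomicFeature


@pytest.fixture(scope="session")
def truth():
    """One paper-like synthetic chromosome shared across tests."""
    return simulate.generate_truth(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_feature_table(
    rng: np.random.Generator,
    n: int,
    chromosome_length: int = 10_000,
    max_len: int = 400,
    ncrna_frac: float = 0.5,
    prefix: str = "f",
) -> FeatureTable:
    """Random stranded intervals for oracle cross-checks."""
    records = []
    for i in range(n):
        start = int(rng.integers(1, chromosome_length - max_len))
        length = int(rng.integers(1, max_len + 1))
        records.append(
            GenomicFeature(
                id=f"{prefix}{i}",
                start=start,
                end=start + length - 1,
                strand="+" if rng.random() < 0.5 else "-",
                ftype="ncRNA" if rng.random() < ncrna_frac else "gene",
            )
        )
    return FeatureTable(records, "chr", chromosome_length)


def make_table(records, length=10_000):
    return FeatureTable(list(records), "chr", length)


def feat(fid, start, end, strand="+", ftype="ncRNA", tps=()):
    return GenomicFeature(
        id=fid, start=start, end=end, strand=strand, ftype=ftype,
        timepoints=frozenset(tps),
    )
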