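import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from breedpop.genotypes import GenotypeMatrix, MarkerMap


def make_gm(calls, pos=None, chrom=None, sample_ids=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a raw call array with minimal ceremony."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    pos = np.asarray(pos, dtype=np.int64)
    if chrom is None:
        chrom = ["1"] * m
    markers = MarkerMap(
        np.asarray(chrom, dtype=object), pos,
        np.array([f"snp{j}" for j in range(m)], dtype=object),
        np.array(["A"] * m, dtype=object), np.array(["C"] * m, dtype=object),
    )
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    return GenotypeMatrix(sample_ids, markers, calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
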