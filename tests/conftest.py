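import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles/anchors importable

from pharmprio.variant_io import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix():
    """4 variants x 6 samples with one missing call and one major-alt site."""
    calls = np.array(
        [
            [0, 1, 2, 0, 1, -1],
            [0, 0, 0, 0, 0, 0],
            [2, 2, 2, 1, 2, 2],   # non-reference allele is the major allele
            [1, 1, 0, 2, 0, 1],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        [f"v{i}" for i in range(4)], [f"s{i}" for i in range(6)], calls
    )


def counts_to_calls(n0: int, n1: int, n2: int, n_missing: int = 0) -> np.ndarray:
    """Deterministic call vector with the given genotype counts."""
    return np.array([0] * n0 + [1] * n1 + [2] * n2 + [-1] * n_missing, dtype=np.int8)
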